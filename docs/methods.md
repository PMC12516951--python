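# Methods

This note documents the models behind `sewerflow`, the choices made where a
convention had to be fixed, what the synthetic-data generator does and does
not emulate, and the known limitations.

## Community containers and quality control

Count tables are samples × features matrices of non-negative integers at
ASV, species or genus resolution (`io_formats.CountTable`). Samples whose
total read count is not strictly above 5 000 are discarded; replicates
sharing a `replicate_group` are merged feature-wise by the mean count.
Means are rounded **half-up** to keep tables integral — the merging
convention itself does not prescribe a rounding rule, so ties (x.5) go up;
the comparison (`>` vs `≥`) and the threshold are configurable.
Aggregation to species or genus sums counts over shared labels; ASVs
without a classification keep their own identity as singleton features so
aggregation never deflates the diversity of the unknown fraction. Read
totals are conserved by aggregation and both the TSV and the dense
BIOM-style JSON dialect round-trip bit-exactly.

## Rarefaction

Rarefaction subsamples each sample to exactly the target depth *without*
replacement (multivariate hypergeometric), so expected feature counts are
depth × original proportion with the finite-population variance. Samples
below the depth are dropped (with a logged notice) rather than silently
kept at lower depth. Each sample draws from its own child seed spawned
from the master seed, so results are independent of sample order and of
which other samples are present. The default working depth is the median
total of the sewer-surface samples (lower-middle convention for even
counts, so the depth is always an attained total); alpha diversity uses a
fixed shallower depth so every sample survives.

## Core tiers, detected class, unified core

For each sewer habitat, a species' prevalence is the fraction of that
habitat's (rarefied) samples where it reaches the abundance cutoff of
0.01% — implemented inclusively (≥), with a strictness flag, since at
realistic depths the cutoff corresponds to ≥ 2 reads and the boundary case
is a single read either way. Tiers: strict ≥ 80%, general ≥ 50%, loose
≥ 20% prevalence; thresholds are nested, and the highest satisfied tier is
reported. Gut-flagged species are excluded from all core tiers (their
prevalence is still reported). Genera use a single "abundant core" flag at
0.05% abundance in ≥ 80% of samples.

Species that never reach a core tier but appear (≥ 1 read) in at least
three sewer samples form the *detected in the sewer microbiome* class.
Counting pools the three sewer habitats by default (configurable to
per-habitat counting), and the bar of three samples is configurable — one
could defend "more than one sample" instead; the stricter reading is the
default.

The unified core takes, per species, the best tier across the three sewer
habitats with priority strict > general > loose; species with no tier
anywhere fall back to *detected* or *none*.

## Gut flagging and sequence identity

A species is flagged as human-gut when its 16S fragment reaches the
species-level identity threshold of 98.7% against any gut reference. The
threshold is inclusive (≥ 0.987), following the usual species-boundary
convention; a strict (>) mode exists. Identity is defined as

    identity(a, b) = 1 − levenshtein(a, b) / max(|a|, |b|),

the fraction of the longer sequence untouched by a minimal global edit
script (computed with edlib). The more common "matches over alignment
columns excluding terminal gaps" depends on which co-optimal alignment an
aligner happens to return and is therefore not reproducible across
implementations; the edit-distance form is deterministic, symmetric,
monotone under added mutations, and identical to matches/columns whenever
the optimal alignment is gapless — which covers the reference fragments
the package generates and the typical same-region 16S comparison. Ties
between equally good gut references keep the lexicographically first
reference id.

## Source attribution

Sources partition all observed species with fixed precedence
gut > unified_strict > unified_general > unified_loose > detected_sewer >
unknown; *unknown* is exactly the remainder observed in IWW or AS with no
upstream assignment. Per-habitat summaries report, per source, the mean
over samples of the per-sample cumulative relative abundance (a pooled
mode — sum counts, then normalize — is available; the two differ when
sequencing depth varies systematically) and the number of distinct species
observed (≥ 1 read in ≥ 1 sample).

## Growth fates by mass balance

At steady state, a species' activated-sludge biomass balances immigration,
net growth and wastage:

    m · a_IWW + μ · a_AS = a_AS / SRT   ⇒   μ = 1/SRT − m · a_IWW / a_AS

with SRT the sludge retention time (default 20 d), m the fraction of the
AS biomass arriving daily with the influent (default 0.05), and abundances
taken as time-means over each plant's samples (the quantities being
compared are multi-year medians/means, not paired snapshots). μ is
strictly decreasing in a_IWW/a_AS and tends to 1/SRT (pure growth washout
limit) as a_IWW → 0; a_AS = 0 with influent presence yields −∞ (pure
die-off), both zero is not assessable.

Classification uses a dead band ε around zero, default 10% of 1/SRT
(0.005 d⁻¹ at the default SRT): growing μ > ε at every assessable plant,
disappearing μ < −ε at every plant, surviving |μ| ≤ ε, *variable* when
plants disagree in sign class, *unassigned* when the species stays below
the detection floor (default mean relative abundance 10⁻⁴) in both
influent and sludge at every plant. An externally supplied fate table can
override the internal classification when fates from a reference study
should be reused verbatim.

## Diversity statistics

Alpha diversity (observed features, Shannon −Σp ln p, inverse Simpson
1/Σp²) is computed on rarefied tables. Bray–Curtis operates on relative
abundances after zeroing entries below the 0.01% floor per sample (the
floor is per sample, not per dataset, matching how the cutoff is defined
elsewhere in the package); `None` disables it. PCoA is classical scaling
of the double-centred squared-distance matrix; negative eigenvalues (from
non-Euclidean distances) are dropped from both the coordinates and the
explained-variance denominator. PERMANOVA is single-factor: pseudo-F from
within/between sums of squared distances, p = (1 + #{F_perm ≥ F_obs}) /
(1 + n_permutations) under seeded label permutation — so the smallest
attainable p is 1/(n_perm + 1) and the test is exact-level by
construction; calibration is verified empirically in the suite. Welch's
t-test and ordinary least squares come from scipy.

## Rain dynamics

A *rain event* is a calendar day with ≥ 2 mm precipitation; a sample is
*rain-flagged* when ≥ 0.5 mm fell within the hour before sampling.
Time-since-rain (TSR) counts consecutive days with < 2 mm, and resets to
zero two days after an event day (the lag absorbs the 24-hour composite
sampling window and in-network travel). Conventions fixed here: with
consecutive event days, the reset anchors to the last event day of the run
(biomass accumulation restarts when rain ends); on the event day and the
single day before the reset takes effect, the TSR holds its previous value
(an "undefined" alternative is available); days before the first
observable reset are undefined and excluded from grouped analyses. The
implementation is translation-invariant in the date axis and is checked
against an independent day-by-day scan.

Rain analyses pair every water-phase sample (SWW or IWW) with every
sewer-surface sample exactly once, pool the Bray–Curtis distances per
group (rainy/dry flag, or TSR ≥ 3 vs < 3), compare groups with Welch's
t-test, and fit BC ~ TSR by least squares. Pairs pool across sampling
locations by default.

## Cell-biomass budget

Gravity-sewer length = (mains − pressure mains + branch pipes); branch
pipes are included because they are gravity lines — with the default
network (2216 − 222 + 460 km = 2454 km) and 4.2 g COD of cell biomass per
meter this gives 10 306.8 kg COD, clearing the 10-tonne mark that mains
alone (≈ 8 375 kg) would miss. The 4.2 g/m linear density is taken as a
given parameter — deriving it from the ~10 g COD/m² areal density requires
wetted-perimeter geometry that is network-specific. Daily cell-biomass
input = influent COD load × cell fraction (defaults 30 000 kg/day × 0.10 =
3 000 kg/day). The input-as-fraction-of-AS-inventory quantity requires the
inventory as an explicit input and returns a null sentinel otherwise.

## Synthetic data: what is emulated, what is not

The generator plants every structure the pipeline is meant to recover:

* **Habitat profiles.** Sewer habitats draw from geometric (ratio 0.93)
  rank-abundance profiles over their planted core members with a weight
  floor of 0.2%, so a handful of taxa dominate (>25% cumulative in the top
  few) and every core member sits comfortably above the 0.01% cutoff.
  Water-phase habitats are convex mixtures of a gut pool (geometric, ratio
  0.90) and the mean sewer-surface pool.
* **Gut gradient.** Planted cumulative gut fractions: 49% (gravity SWW),
  35% (end-of-pressure), 30% (IWW), 2% (sewer surfaces). The AS gut
  fraction is *not* free — it follows from the mass balance (~6% at the
  defaults).
* **Core occupancy.** Per-sample presence is Bernoulli at 0.97 / 0.66 /
  0.34 for strict/general/loose members — deliberately away from the
  0.80/0.50/0.20 prevalence thresholds so recovery is well-posed; 60 rare
  species at 0.005% weight and 0.45 occupancy populate the detected class
  without reaching core status. Twelve strict species are shared by all
  three sewer habitats, and each habitat carries one of its neighbour's
  strict species as loose, exercising the unified-merge priority.
* **Counts.** Dirichlet-multinomial around the per-sample profile with
  concentration 3000 (mild overdispersion; ∞ gives the multinomial limit).
  Sewer depths are uniform on 12–22 k reads, water-phase on 40–80 k,
  mirroring the grab-versus-composite depth imbalance, so median-depth
  rarefaction behaves as it does on real surveys. Species counts are split
  over 1–2 ASVs per species plus a sparse unclassified-ASV background.
* **Sludge.** Given the influent profile and a planted fate per species
  (target rates +0.03 / 0 / −0.20 d⁻¹), activated-sludge abundances are
  placed at the mass-balance steady state a_AS ∝ m·a_IWW/(1/SRT − μ).
  Because a full profile must sum to one, the targets are over-determined
  by one constraint; all rates are shifted by a common offset solved
  exactly (brentq), and the influent mass is allocated to fate classes
  (greedily, largest species first) so that offset is ≈ 0 — a scenario
  error is raised if the shift would flip any fate class. Species below
  0.02% planted influent mass are always assigned "disappearing": their
  rate is not estimable from finite counts, so planting growth there would
  make recovery ill-posed.
* **Rain.** Daily rainfall is a Bernoulli-exponential process (default:
  25% wet days, mean 6 mm) with optional hourly disaggregation whose daily
  sums match exactly. The water-phase sewer-pool weight is
  w₀ + c·B, with B the accumulated dry days (linear, capped at 10 days,
  scaled to [0,1]) at full strength on rain days and quarter strength
  otherwise — a deliberate *proxy* for biomass build-up and first-flush
  detachment that asserts monotonicity, not kinetics.
* **References.** Gut species' 16S fragments sit at 99% identity to their
  gut-database reference; non-gut fragments are random (≈50% identity)
  except a few planted at 96% to exercise the cutoff boundary.

Not emulated: sequencing error and chimeras (counts are sampled from the
true composition), within-habitat spatial structure beyond random
occupancy, seasonal/diurnal trends, taxonomic misannotation, compositional
correlations between species, and hydraulics (flow, shear). Passing the
recovery tests therefore shows the estimators are correct under the stated
noise model — not that real sewer surveys satisfy that model.

## Problem sizes and numerical choices

The default scenario uses 272 species (50 gut), ~130 samples, and the
depths above; recovery, calibration (200 null PERMANOVA replicates at 199
permutations each) and rain analyses all run in seconds on one core, which
keeps the whole suite and the acceptance script desk-scale. Boundary
handling in recovery checks: a species-habitat pair whose *realized*
prevalence lies within 0.16 of a tier threshold is treated as a boundary
case, since its tier is then decided by sampling noise rather than by the
planted occupancy. Degenerate inputs raise: empty influent profiles,
non-positive rarefaction depths, gapped daily rainfall series (no
imputation), PERMANOVA groups with fewer than two members.

## Limitations

* The mass balance is steady-state; transients (seasonal growth, upsets)
  bias μ toward the long-run mean, and relative (not absolute) abundances
  make all rates conditional on total-biomass stability.
* The identity convention slightly differs from aligner-reported
  matches/columns when optimal alignments contain internal gaps; at the
  98.7% species threshold on same-region fragments this is immaterial, but
  cross-region comparisons should use a dedicated aligner.
* PERMANOVA is one-factor; confounded designs (habitat × location) need
  external stratification.
* The biomass budget is linear bookkeeping on network-level averages; it
  ignores biofilm heterogeneity along the pipe network and any
  rain-dependent detachment of the standing stock.
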