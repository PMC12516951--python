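"""Rarefaction and core-community tiers for sewer habitats.

A species is core for a habitat when it reaches at least 0.01% per-sample
relative abundance in a sufficient fraction of that habitat's samples:
80% for the strict core, 50% for the general core, 20% for the loose core.
Species that never reach core status anywhere but are seen (any reads) in
more than two sewer samples form the "detected in the sewer microbiome"
class.  Gut-flagged species are excluded from all sewer core groups.  The
per-habitat assignments merge into a unified core with priority
strict > general > loose.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_formats import SEWER_HABITATS, CountTable

TIER_THRESHOLDS = {"strict": 0.80, "general": 0.50, "loose": 0.20}
TIER_PRIORITY = ("strict", "general", "loose")
SPECIES_ABUNDANCE_CUTOFF = 1e-4  # 0.01% relative abundance
GENUS_ABUNDANCE_CUTOFF = 5e-4  # 0.05% relative abundance


def rarefy(table: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer total reads than ``depth`` are dropped.  Each sample
    uses its own child seed spawned from the master seed, so results do not
    depend on the number or order of other samples.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    totals = table.totals()
    keep = [s for s in table.sample_ids if totals[s] >= depth]
    dropped = sorted(set(table.sample_ids) - set(keep))
    if dropped:
        import logging

        logging.getLogger(__name__).info(
            "rarefy: dropped %d samples below depth %d: %s", len(dropped), depth, dropped
        )
    children = np.random.SeedSequence(seed).spawn(len(keep))
    rows = np.empty((len(keep), len(table.feature_ids)), dtype=np.int64)
    for i, s in enumerate(keep):
        row = table.counts.loc[s].to_numpy()
        if totals[s] == depth:
            rows[i] = row
        else:
            rng = np.random.default_rng(children[i])
            rows[i] = rng.multivariate_hypergeometric(row, depth)
    out = pd.DataFrame(rows, index=keep, columns=table.feature_ids)
    return CountTable(out, level=table.level)


def min_reads_for_abundance(depth: int, cutoff: float = SPECIES_ABUNDANCE_CUTOFF) -> int:
    """Smallest integer read count whose relative abundance exceeds ``cutoff``
    at the given sequencing depth."""
    return int(np.floor(cutoff * depth)) + 1


def _prevalence(rel: pd.DataFrame, cutoff: float, inclusive: bool) -> pd.Series:
    hit = rel >= cutoff if inclusive else rel > cutoff
    return hit.mean(axis=0)


def classify_core_species(
    table: CountTable,
    meta: pd.DataFrame,
    habitats=SEWER_HABITATS,
    gut_species=frozenset(),
    abundance_cutoff: float = SPECIES_ABUNDANCE_CUTOFF,
    tiers: dict | None = None,
    inclusive: bool = True,
) -> pd.DataFrame:
    """Per-habitat core tier for every species.

    Returns a DataFrame (species_id, habitat, tier, prevalence, n_samples)
    where prevalence is the fraction of the habitat's samples in which the
    species reaches ``abundance_cutoff`` relative abundance.  Gut species are
    forced to tier ``none`` (their prevalence is still reported).
    """
    tiers = dict(TIER_THRESHOLDS) if tiers is None else tiers
    order = sorted(tiers, key=tiers.get, reverse=True)
    by_sample = meta.set_index("sample_id")["habitat"]
    rel = table.relative_abundance()
    records = []
    for hab in habitats:
        samples = [s for s in table.sample_ids if by_sample.get(s) == hab]
        if not samples:
            raise ValueError(f"no samples for habitat {hab!r}")
        prev = _prevalence(rel.loc[samples], abundance_cutoff, inclusive)
        for sp in table.feature_ids:
            p = float(prev[sp])
            tier = "none"
            if sp not in gut_species:
                for t in order:
                    if p >= tiers[t]:
                        tier = t
                        break
            records.append((sp, hab, tier, p, len(samples)))
    return pd.DataFrame(
        records, columns=["species_id", "habitat", "tier", "prevalence", "n_samples"]
    )


def classify_core_genera(
    table: CountTable,
    meta: pd.DataFrame,
    habitats=SEWER_HABITATS,
    abundance_cutoff: float = GENUS_ABUNDANCE_CUTOFF,
    prevalence: float = 0.80,
    inclusive: bool = True,
) -> pd.DataFrame:
    """Single-tier abundant-core flag per genus and habitat (0.05% in >=80%)."""
    if table.level != "genus":
        raise ValueError("classify_core_genera expects a genus-level table")
    by_sample = meta.set_index("sample_id")["habitat"]
    rel = table.relative_abundance()
    records = []
    for hab in habitats:
        samples = [s for s in table.sample_ids if by_sample.get(s) == hab]
        if not samples:
            raise ValueError(f"no samples for habitat {hab!r}")
        prev = _prevalence(rel.loc[samples], abundance_cutoff, inclusive)
        for g in table.feature_ids:
            p = float(prev[g])
            records.append((g, hab, bool(p >= prevalence), p, len(samples)))
    return pd.DataFrame(
        records,
        columns=["genus", "habitat", "abundant_core", "prevalence", "n_samples"],
    )


def detect_in_sewer(
    table: CountTable,
    meta: pd.DataFrame,
    core: pd.DataFrame,
    gut_species=frozenset(),
    min_samples: int = 3,
    pooled: bool = True,
) -> frozenset:
    """Species observed (any reads) in at least ``min_samples`` sewer samples.

    Gut species and species already holding a core tier in any sewer habitat
    are excluded.  Counting pools samples across the three sewer habitats by
    default; ``pooled=False`` requires the bar to be met within a single
    habitat instead.
    """
    by_sample = meta.set_index("sample_id")["habitat"]
    sewer = [s for s in table.sample_ids if by_sample.get(s) in SEWER_HABITATS]
    present = table.counts.loc[sewer] >= 1
    if pooled:
        n_obs = present.sum(axis=0)
        hit = n_obs >= min_samples
    else:
        habs = by_sample.loc[sewer]
        hit = present.groupby(habs.to_numpy()).sum().max(axis=0) >= min_samples
    core_species = set(core.loc[core["tier"] != "none", "species_id"])
    detected = {
        sp
        for sp in table.feature_ids
        if hit[sp] and sp not in gut_species and sp not in core_species
    }
    return frozenset(detected)


def unify_core(core: pd.DataFrame, detected=frozenset()) -> pd.DataFrame:
    """Merge per-habitat tiers into the unified core, priority strict>general>loose.

    Species without any core tier fall back to ``detected`` when they are in
    the detected-in-sewer set, else ``none``.
    """
    rank = {t: i for i, t in enumerate(TIER_PRIORITY)}
    best = {}
    for sp, tier in zip(core["species_id"], core["tier"]):
        if tier == "none":
            best.setdefault(sp, "none")
        elif best.get(sp, "none") == "none" or rank[tier] < rank[best[sp]]:
            best[sp] = tier
    for sp in detected:
        if best.get(sp, "none") == "none":
            best[sp] = "detected"
    out = pd.DataFrame(
        sorted(best.items()), columns=["species_id", "unified_tier"]
    )
    return out
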