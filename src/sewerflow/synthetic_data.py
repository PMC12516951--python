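"""Synthetic multi-habitat amplicon data with planted ground truth.

The generator emulates the structure of a combined-sewer catchment feeding
an activated-sludge plant, so that every downstream stage (gut flagging,
core tiers, source attribution, growth fates, rain dynamics) can be
exercised against known truth:

* seven habitats (gravity/end-of-pressure biofilm, sediment, gravity and
  end-of-pressure sewer wastewater, influent, activated sludge), each with a
  low-evenness species profile dominated by a few taxa;
* a gut-bacteria fraction that decays downstream (~49% in gravity sewer
  wastewater, ~35% at end-of-pressure, ~30% in influent, a few percent on
  sewer surfaces and in sludge);
* per-habitat planted core structure (strict/general/loose occupancy) plus
  a pool of rare species that are merely *detected* on sewer surfaces;
* rain-driven mixing: the sewer-surface share of the water phase grows with
  accumulated dry days and spikes on rain days (a linear, capped biomass
  proxy — no detachment kinetics are claimed);
* activated-sludge abundances placed at the steady state of the
  immigration/growth/wastage mass balance for each species' planted fate.

Counts are Dirichlet-multinomial around the habitat profile; every function
is deterministic given the scenario seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .growth_fate import MassBalanceParams, net_growth_rate
from .io_formats import HABITATS, SEWER_HABITATS, UNCLASSIFIED, CountTable


class ScenarioError(ValueError):
    """Raised when a scenario's planted structure is infeasible."""


DEFAULT_SAMPLES = {
    "biofilm_g": 24,
    "biofilm_ep": 24,
    "sediment": 24,
    "SWW_g": 14,
    "SWW_ep": 10,
    "IWW": 16,
    "AS": 16,
}

# planted cumulative gut-bacteria share of each habitat's profile; the AS
# share is not a free parameter — it falls out of the mass balance
DEFAULT_GUT_FRACTION = {
    "biofilm_g": 0.02,
    "biofilm_ep": 0.02,
    "sediment": 0.02,
    "SWW_g": 0.49,
    "SWW_ep": 0.35,
    "IWW": 0.30,
}

# occupancy (probability a species is present in a sample) planted per tier,
# chosen away from the 0.8 / 0.5 / 0.2 prevalence thresholds
TIER_OCCUPANCY = {"strict": 0.97, "general": 0.66, "loose": 0.34}
RARE_OCCUPANCY = 0.45
RARE_WEIGHT = 5e-5  # below the 0.01% core cutoff, above the 1-read floor
CORE_WEIGHT_FLOOR = 2e-3  # keeps every core species well above the cutoff

FATE_MU_TARGETS = {"growing": 0.03, "disappearing": -0.20, "surviving": 0.0}


@dataclass
class CommunityScenario:
    """Parameters and planted structure of a synthetic catchment.

    The defaults describe a desk-scale study: 272 species (50 of gut
    origin), ~130 samples across the seven habitats, sewer-surface read
    depths of 12-22 thousand against much deeper water-phase libraries
    (40-80 thousand, mirroring the typical depth imbalance between grab
    and composite samples), and a Dirichlet concentration of 3000 (mild
    overdispersion relative to multinomial sampling).
    """

    n_species: int = 272
    n_gut_species: int = 50
    samples_per_habitat: dict = field(default_factory=lambda: dict(DEFAULT_SAMPLES))
    gut_fraction: dict = field(default_factory=lambda: dict(DEFAULT_GUT_FRACTION))
    core_sizes: dict = field(
        default_factory=lambda: {"strict": 22, "general": 18, "loose": 22}
    )
    n_shared_strict: int = 12
    n_rare: int = 60
    sewer_depth_range: tuple = (12_000, 22_000)
    water_depth_range: tuple = (40_000, 80_000)
    overdispersion: float = 3000.0
    detachment_coefficient: float = 0.5
    detachment_dry_cap_days: int = 10
    base_sewer_weight: float = 0.25
    srt_days: float = 20.0
    m_daily_fraction: float = 0.05
    # desired split of the surviving vs disappearing influent mass; the
    # growing share is solved so the steady-state AS profile closes exactly
    surviving_share: float = 0.53
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_gut_species >= self.n_species:
            raise ScenarioError("need non-gut species")
        for hab, f in self.gut_fraction.items():
            if not 0 <= f <= 1:
                raise ScenarioError(f"gut_fraction[{hab}] outside [0, 1]")
        if not 0 <= self.detachment_coefficient <= 1:
            raise ScenarioError("detachment_coefficient outside [0, 1]")
        if TIER_OCCUPANCY["strict"] < 0.80:
            raise ScenarioError("strict occupancy below the 80% prevalence demand")
        if self.n_shared_strict > self.core_sizes["strict"]:
            raise ScenarioError("n_shared_strict exceeds strict core size")
        if self._n_allocated() + self.n_rare > self.n_species - self.n_gut_species:
            raise ScenarioError("core + rare structure exceeds available species")

    def _n_allocated(self) -> int:
        per_hab = (
            self.core_sizes["strict"]
            - self.n_shared_strict
            + self.core_sizes["general"]
            + self.core_sizes["loose"]
        )
        return self.n_shared_strict + 3 * per_hab

    # ------------------------------------------------------------------
    # species bookkeeping

    @property
    def species_ids(self) -> list:
        return [f"s{i:04d}" for i in range(self.n_species)]

    @property
    def gut_species(self) -> list:
        return self.species_ids[: self.n_gut_species]

    def genus_of(self, species_id: str) -> str:
        return f"g{int(species_id[1:]) // 3:03d}"

    def planted_cores(self) -> dict:
        """Per sewer habitat: {tier: [species]}; overlapping across habitats."""
        ids = self.species_ids
        g = self.n_gut_species
        shared = ids[g : g + self.n_shared_strict]
        cores = {}
        offset = g + self.n_shared_strict
        per_hab_strict = self.core_sizes["strict"] - self.n_shared_strict
        for hab in SEWER_HABITATS:
            strict = list(shared) + ids[offset : offset + per_hab_strict]
            offset += per_hab_strict
            general = ids[offset : offset + self.core_sizes["general"]]
            offset += self.core_sizes["general"]
            loose = ids[offset : offset + self.core_sizes["loose"]]
            offset += self.core_sizes["loose"]
            cores[hab] = {"strict": strict, "general": general, "loose": loose}
        # cross-habitat tier overlap: each habitat also carries, as a loose
        # member, one habitat-specific strict species of the next habitat —
        # this exercises the strict-over-loose priority of the unified merge
        habs = list(SEWER_HABITATS)
        for i, hab in enumerate(habs):
            donor = cores[habs[(i + 1) % 3]]["strict"][self.n_shared_strict :]
            if donor and donor[0] not in cores[hab]["loose"]:
                cores[hab]["loose"] = cores[hab]["loose"] + [donor[0]]
        return cores

    @property
    def rare_species(self) -> list:
        start = self.n_gut_species + self._n_allocated()
        return self.species_ids[start : start + self.n_rare]

    # ------------------------------------------------------------------
    # profiles

    @staticmethod
    def _geometric_weights(n: int, ratio: float) -> np.ndarray:
        w = ratio ** np.arange(n)
        return w / w.sum()

    def gut_profile(self) -> pd.Series:
        w = self._geometric_weights(self.n_gut_species, 0.90)
        return pd.Series(w, index=self.gut_species)

    def full_gut_profile(self) -> pd.Series:
        prof = pd.Series(0.0, index=self.species_ids)
        prof[self.gut_species] = self.gut_profile()
        return prof

    def sewer_profile(self, habitat: str) -> pd.Series:
        """Non-gut profile of a sewer habitat (sums to 1, low evenness)."""
        cores = self.planted_cores()[habitat]
        members = cores["strict"] + cores["general"] + cores["loose"]
        w = self._geometric_weights(len(members), 0.93)
        w = np.maximum(w, CORE_WEIGHT_FLOOR)
        prof = pd.Series(0.0, index=self.species_ids)
        prof[members] = w
        prof[self.rare_species] += RARE_WEIGHT
        return prof / prof.sum()

    def sewer_pool_profile(self) -> pd.Series:
        """Mean of the three sewer-surface profiles (the detachable pool)."""
        pool = sum(self.sewer_profile(h) for h in SEWER_HABITATS) / 3
        return pool / pool.sum()

    def water_base_profile(self, habitat: str) -> pd.Series:
        """Static (dry-weather) profile of a water-phase habitat."""
        gf = self.gut_fraction[habitat]
        prof = gf * self.full_gut_profile() + (1 - gf) * self.sewer_pool_profile()
        return prof / prof.sum()

    def habitat_profile(self, habitat: str) -> pd.Series:
        """Planted mean relative-abundance vector of a habitat (sums to 1)."""
        if habitat in SEWER_HABITATS:
            gf = self.gut_fraction[habitat]
            prof = gf * self.full_gut_profile() + (1 - gf) * self.sewer_profile(habitat)
        elif habitat in ("SWW_g", "SWW_ep", "IWW"):
            prof = self.water_base_profile(habitat)
        elif habitat == "AS":
            prof = self.as_profile()
        else:
            raise ScenarioError(f"unknown habitat {habitat!r}")
        prof = prof / prof.sum()
        assert abs(prof.sum() - 1) < 1e-9
        return prof

    # ------------------------------------------------------------------
    # growth fates

    def _fate_mass_targets(self) -> dict:
        """Influent-mass share per fate class making the AS simplex close.

        With target rates t_c, the steady state requires
        sum_c m * M_c / (1/SRT - t_c) = 1 over the class masses M_c of the
        influent.  Gut mass is forced into the disappearing class; the
        surviving share of the remaining mass is fixed by ``surviving_share``
        and the growing share is the closed-form solution of the linear
        closure equation.
        """
        m, inv = self.m_daily_fraction, 1.0 / self.srt_days
        dg = inv - FATE_MU_TARGETS["growing"]
        ds = inv - FATE_MU_TARGETS["surviving"]
        dd = inv - FATE_MU_TARGETS["disappearing"]
        if dg <= 0:
            raise ScenarioError("growing target rate must stay below 1/SRT")
        gm = self.gut_fraction["IWW"]
        r = 1.0 - gm
        sigma = self.surviving_share
        coef = m * (1 / dg - sigma / ds - (1 - sigma) / dd)
        const = m * (sigma * r / ds + ((1 - sigma) * r + gm) / dd)
        g = (1.0 - const) / coef
        if not 0 < g < r:
            raise ScenarioError("no feasible growing mass share for this scenario")
        return {
            "growing": g,
            "surviving": sigma * (r - g),
            "disappearing": (1 - sigma) * (r - g) + gm,
        }

    def fate_map(self) -> pd.Series:
        """Planted growth fate per species.

        Gut species all disappear in AS, as do species too rare in the
        influent (< 0.02% planted mass) to support a rate estimate — they
        may be entirely absent from a finite influent sample, so growth
        there would be ill-posed.  The remaining species are packed greedily
        (largest influent mass first) into the class with the largest
        remaining mass deficit, so realized class masses match the closure
        targets to within the smallest species mass.
        """
        iww = self.water_base_profile("IWW")
        fates = pd.Series("disappearing", index=self.species_ids)
        targets = self._fate_mass_targets()
        acc = {"growing": 0.0, "surviving": 0.0, "disappearing": self.gut_fraction["IWW"]}
        non_gut = self.species_ids[self.n_gut_species :]
        for sp in sorted(non_gut, key=lambda s: -iww[s]):
            if iww[sp] < 2e-4:
                acc["disappearing"] += float(iww[sp])
                continue
            cls = max(targets, key=lambda c: targets[c] - acc[c])
            fates[sp] = cls
            acc[cls] += float(iww[sp])
        return fates

    def as_profile(self) -> pd.Series:
        prof, _ = steady_state_as_profile(
            self.habitat_profile("IWW"),
            self.fate_map(),
            MassBalanceParams(self.srt_days, self.m_daily_fraction),
        )
        return prof

    def planted_truth(self) -> dict:
        """Everything downstream recovery tests may assert against."""
        params = MassBalanceParams(self.srt_days, self.m_daily_fraction)
        _, mu = steady_state_as_profile(
            self.habitat_profile("IWW"), self.fate_map(), params
        )
        eps = params.epsilon
        fate = pd.Series(
            np.where(mu > eps, "growing", np.where(mu < -eps, "disappearing", "surviving")),
            index=mu.index,
        )
        gut = self.full_gut_profile() > 0
        gut_fraction = {
            hab: float(self.habitat_profile(hab)[gut].sum()) for hab in HABITATS
        }
        return {
            "gut_species": list(self.gut_species),
            "gut_fraction": gut_fraction,
            "cores": self.planted_cores(),
            "rare_species": list(self.rare_species),
            "fate": fate.to_dict(),
            "mu": mu.to_dict(),
            "seed": self.seed,
        }


def steady_state_as_profile(
    iww_profile: pd.Series, fate_map: pd.Series, params: MassBalanceParams
):
    """AS relative abundances consistent with planted fates and the mass balance.

    For a target rate t the balance gives a_AS = m * a_IWW / (1/SRT - t).  A
    full profile must also sum to one, which over-determines the targets, so
    all targets are shifted by a common offset delta solved (brentq) so the
    implied profile is exactly a simplex.  Returns (profile over the input
    index, realized mu for species present in the influent); raises
    :class:`ScenarioError` if the shift pushes any species out of its
    planted fate class.
    """
    a_iww = iww_profile[iww_profile > 0]
    if a_iww.empty:
        raise ScenarioError("empty influent profile")
    t = fate_map.reindex(a_iww.index).map(FATE_MU_TARGETS).to_numpy(dtype=float)
    if np.isnan(t).any():
        raise ScenarioError("species with fate outside the planted classes")
    inv_srt = 1.0 / params.srt_days
    m = params.m_daily_fraction
    hi = inv_srt - t.max()  # delta must stay below this for positive a_AS

    def excess(delta):
        return (m * a_iww.to_numpy() / (inv_srt - t - delta)).sum() - 1.0

    delta = brentq(excess, -50.0, hi - 1e-9, xtol=1e-14)
    mu_t = t + delta
    a_as = m * a_iww / (inv_srt - mu_t)
    a_as = a_as / a_as.sum()
    realized = pd.Series(
        net_growth_rate(a_iww.to_numpy(), a_as.to_numpy(), params), index=a_iww.index
    )
    eps = params.epsilon
    classes = np.where(
        realized > eps, "growing", np.where(realized < -eps, "disappearing", "surviving")
    )
    mismatch = classes != fate_map.reindex(a_iww.index).to_numpy()
    if mismatch.any():
        bad = list(a_iww.index[mismatch])[:5]
        raise ScenarioError(
            f"fate targets infeasible for this influent (offset {delta:.4f}); "
            f"first mismatches: {bad}"
        )
    prof = pd.Series(0.0, index=iww_profile.index)
    prof[a_as.index] = a_as
    return prof, realized


# ---------------------------------------------------------------------------
# sampling machinery


def _draw_counts(rng, profile: np.ndarray, depth: int, conc: float) -> np.ndarray:
    """Dirichlet-multinomial draw around ``profile`` at the given depth."""
    pos = profile > 0
    if np.isfinite(conc):
        p = rng.dirichlet(profile[pos] * conc)
    else:
        p = profile[pos] / profile[pos].sum()
    out = np.zeros(len(profile), dtype=np.int64)
    out[pos] = rng.multinomial(depth, p / p.sum())
    return out


def _occupancy_vector(scenario: CommunityScenario, habitat: str) -> pd.Series:
    """Per-species probability of being present in a sample of the habitat."""
    occ = pd.Series(1.0, index=scenario.species_ids)
    if habitat in SEWER_HABITATS:
        cores = scenario.planted_cores()[habitat]
        occ[:] = 0.0
        for tier, members in cores.items():
            occ[members] = TIER_OCCUPANCY[tier]
        occ[scenario.rare_species] = RARE_OCCUPANCY
        occ[scenario.gut_species] = 1.0  # constant wastewater deposition
    return occ


def _sample_matrix(
    scenario: CommunityScenario,
    habitat: str,
    n_samples: int,
    rng,
    profiles=None,
) -> np.ndarray:
    """Count rows for one habitat; ``profiles`` optionally overrides per sample."""
    base = scenario.habitat_profile(habitat).to_numpy()
    occ = _occupancy_vector(scenario, habitat).to_numpy()
    lo, hi = (
        scenario.sewer_depth_range
        if habitat in SEWER_HABITATS
        else scenario.water_depth_range
    )
    rows = np.empty((n_samples, scenario.n_species), dtype=np.int64)
    for i in range(n_samples):
        prof = base if profiles is None else profiles[i]
        mask = rng.random(scenario.n_species) < occ
        w = prof * mask
        if w.sum() == 0:
            raise ScenarioError(f"habitat {habitat}: empty sample composition")
        depth = int(rng.integers(lo, hi + 1))
        rows[i] = _draw_counts(rng, w / w.sum(), depth, scenario.overdispersion)
    return rows


def _asv_split(scenario: CommunityScenario):
    """ASV layout: most species one ASV, every 11th species two, plus a few
    unclassified ASVs that belong to no species label."""
    asvs, tax_rows = [], []
    for i, sp in enumerate(scenario.species_ids):
        genus = scenario.genus_of(sp)
        if i % 11 == 3:
            for j, frac in enumerate((0.7, 0.3)):
                asv = f"ASV_{i:04d}_{j}"
                asvs.append((asv, sp, frac))
                tax_rows.append((asv, genus, sp, 0.99))
        else:
            asv = f"ASV_{i:04d}"
            asvs.append((asv, sp, 1.0))
            tax_rows.append((asv, genus, sp, 0.99))
    for k in range(6):
        asv = f"ASV_U{k:02d}"
        asvs.append((asv, None, 1.0))
        tax_rows.append((asv, UNCLASSIFIED, UNCLASSIFIED, 0.3))
    taxonomy = pd.DataFrame(
        tax_rows, columns=["feature_id", "genus", "species", "confidence"]
    )
    return asvs, taxonomy


def _species_to_asv_counts(scenario, species_counts: np.ndarray, rng) -> pd.DataFrame:
    """Split species-level counts onto the ASV layout (binomial thinning)."""
    asvs, _ = _asv_split(scenario)
    sp_index = {sp: k for k, sp in enumerate(scenario.species_ids)}
    cols = {}
    for asv, sp, frac in asvs:
        if sp is None:
            # unclassified ASVs: sparse background at ~0.005% per sample
            depth_tot = species_counts.sum(axis=1)
            cols[asv] = rng.binomial(np.maximum(depth_tot, 1), 5e-5)
        elif frac == 1.0:
            cols[asv] = species_counts[:, sp_index[sp]]
        elif asv.endswith("_0"):
            base = species_counts[:, sp_index[sp]]
            first = rng.binomial(base, frac)
            cols[asv] = first
            cols[asv[:-2] + "_1"] = base - first
    order = [a for a, _, _ in asvs]
    return pd.DataFrame({a: cols[a] for a in order})


# ---------------------------------------------------------------------------
# public simulators


def simulate_habitats(scenario: CommunityScenario):
    """Generate the full multi-habitat dataset under dry-weather conditions.

    Returns ``(CountTable (ASV level), metadata DataFrame, taxonomy DataFrame)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 1]))
    frames, meta_rows = [], []
    start = pd.Timestamp("2022-06-01")
    for hab, n in scenario.samples_per_habitat.items():
        species_counts = _sample_matrix(scenario, hab, n, rng)
        frames.append(species_counts)
        for i in range(n):
            sid = f"{hab}_{i:02d}"
            wwtp = ("AAW" if i % 2 == 0 else "AAE") if hab in ("IWW", "AS") else "none"
            loc = f"L{i % 9:02d}" if hab not in ("IWW", "AS") else "plant"
            meta_rows.append(
                {
                    "sample_id": sid,
                    "habitat": hab,
                    "location_id": loc,
                    "wwtp": wwtp,
                    "timestamp": (start + pd.Timedelta(days=7 * i)).isoformat(),
                    "sewer_type": "combined" if i % 3 else "separated",
                    "replicate_group": sid,
                }
            )
    species_counts = np.vstack(frames)
    asv_counts = _species_to_asv_counts(scenario, species_counts, rng)
    asv_counts.index = [r["sample_id"] for r in meta_rows]
    meta = pd.DataFrame(meta_rows)
    meta["timestamp"] = pd.to_datetime(meta["timestamp"])
    _, taxonomy = _asv_split(scenario)
    return CountTable(asv_counts, level="asv"), meta, taxonomy


def simulate_rainfall(
    n_days: int,
    event_rate: float = 0.25,
    event_mm_mean: float = 6.0,
    seed: int = 0,
    hourly: bool = False,
):
    """Sparse daily rainfall; wet days draw an exponential depth, others are dry.

    Returns a daily DataFrame (date, mm) and, when ``hourly`` is set, also an
    hourly DataFrame (datetime, mm) whose daily sums equal the daily series.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    dates = pd.date_range("2023-01-01", periods=n_days, freq="D")
    wet = rng.random(n_days) < event_rate
    mm = np.where(wet, np.round(rng.exponential(event_mm_mean, n_days), 2), 0.0)
    daily = pd.DataFrame({"date": dates, "mm": mm})
    if not hourly:
        return daily
    rows = []
    for d, total in zip(daily["date"], daily["mm"]):
        if total > 0:
            hours = np.sort(rng.choice(24, size=3, replace=False))
            split = rng.dirichlet(np.ones(3)) * total
            split = np.round(split, 4)
            split[-1] = round(total - split[:-1].sum(), 4)
            for h, v in zip(hours, split):
                rows.append((d + pd.Timedelta(hours=int(h)), float(v)))
    hourly_df = pd.DataFrame(rows, columns=["datetime", "mm"])
    return daily, hourly_df


def dry_days_before(daily: pd.DataFrame, date, event_threshold_mm: float = 2.0) -> int:
    """Consecutive days with < threshold rainfall strictly before ``date``."""
    dates = pd.to_datetime(daily["date"]).dt.normalize()
    mm = daily["mm"].to_numpy(dtype=float)
    date = pd.Timestamp(date).normalize()
    count = 0
    for d, v in sorted(zip(dates, mm), reverse=True):
        if d >= date:
            continue
        if v >= event_threshold_mm:
            break
        count += 1
    return count


def simulate_wastewater_mixing(
    scenario: CommunityScenario,
    rainfall: pd.DataFrame,
    habitat: str = "SWW_g",
    sample_dates=None,
):
    """Water-phase samples whose sewer-pool share responds to rainfall.

    Each sample's profile is a convex mixture of the habitat's dry-weather
    base and the detachable sewer pool.  The sewer-pool weight is
    ``w0 + c * B`` where B is accumulated dry days (capped, scaled to [0,1])
    and c the detachment coefficient — full strength on rain days, quarter
    strength otherwise.  Returns (CountTable at species level, metadata,
    per-sample mixture weights).
    """
    daily = rainfall
    dates = pd.to_datetime(daily["date"]).dt.normalize()
    if sample_dates is None:
        sample_dates = list(dates[:: max(1, len(dates) // 24)])
    sample_dates = [pd.Timestamp(d).normalize() for d in sample_dates]
    known = set(dates)
    missing = [d for d in sample_dates if d not in known]
    if missing:
        raise ValueError(f"rainfall does not cover sample dates: {missing[:3]}")
    mm_of = dict(zip(dates, daily["mm"].astype(float)))
    base = scenario.water_base_profile(habitat).to_numpy()
    pool = scenario.sewer_pool_profile().to_numpy()
    w0 = scenario.base_sewer_weight
    cap = scenario.detachment_dry_cap_days
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 23]))
    profiles, weights, meta_rows = [], [], []
    for i, d in enumerate(sample_dates):
        b = min(dry_days_before(daily, d), cap) / cap
        rain_day = mm_of[d] >= 2.0
        w = w0 + scenario.detachment_coefficient * b * (1.0 if rain_day else 0.25)
        w = min(w, 0.95)
        profiles.append((1 - w) * base + w * pool)
        weights.append(w)
        sid = f"{habitat}_r{i:02d}"
        meta_rows.append(
            {
                "sample_id": sid,
                "habitat": habitat,
                "location_id": f"L{i % 9:02d}",
                "wwtp": "AAW" if habitat == "IWW" else "none",
                "timestamp": (d + pd.Timedelta(hours=9)).isoformat(),
                "sewer_type": "combined",
                "replicate_group": sid,
            }
        )
    rows = _sample_matrix(scenario, habitat, len(sample_dates), rng, profiles=profiles)
    counts = pd.DataFrame(
        rows, index=[r["sample_id"] for r in meta_rows], columns=scenario.species_ids
    )
    meta = pd.DataFrame(meta_rows)
    meta["timestamp"] = pd.to_datetime(meta["timestamp"])
    return (
        CountTable(counts, level="species"),
        meta,
        pd.Series(weights, index=counts.index, name="sewer_weight"),
    )


def simulate_as(
    scenario: CommunityScenario,
    iww: CountTable,
    srt_days: float | None = None,
    m_daily_fraction: float | None = None,
    n_samples: int = 12,
    depth: int = 15_000,
):
    """Activated-sludge counts at the mass-balance steady state of each fate.

    ``iww`` must be a species-level table; its mean relative abundance is the
    influent term of the balance.  Returns (CountTable, realized mu Series
    over the species present in the influent).
    """
    params = MassBalanceParams(
        srt_days if srt_days is not None else scenario.srt_days,
        m_daily_fraction if m_daily_fraction is not None else scenario.m_daily_fraction,
    )
    a_iww = iww.relative_abundance().mean(axis=0)
    fate = scenario.fate_map().reindex(a_iww.index)
    grow_zero = (fate == "growing") & (a_iww == 0)
    if grow_zero.any():
        raise ScenarioError(
            f"growing species absent from IWW: {list(a_iww.index[grow_zero])[:5]}"
        )
    prof, mu = steady_state_as_profile(a_iww, fate, params)
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 31]))
    p = prof.reindex(a_iww.index).fillna(0.0).to_numpy()
    rows = np.stack([rng.multinomial(depth, p / p.sum()) for _ in range(n_samples)])
    counts = pd.DataFrame(
        rows,
        index=[f"AS_sim_{i:02d}" for i in range(n_samples)],
        columns=list(a_iww.index),
    )
    return CountTable(counts, level=iww.level), mu


# ---------------------------------------------------------------------------
# reference sequences


def simulate_references(
    species_ids,
    gut_species,
    region_length: int = 300,
    gut_identity: float = 0.99,
    near_miss_identity: float = 0.96,
    n_near_miss: int = 3,
    seed: int = 0,
):
    """Reference 16S fragments with planted identity structure.

    Gut species' fragments sit at ``gut_identity`` to their gut-database
    reference (above the 98.7% species cutoff); non-gut fragments are random
    (expected identity ~50%), except ``n_near_miss`` planted just below the
    cutoff at ``near_miss_identity``.  Returns (species FASTA dict, gut
    reference FASTA dict, truth dict of planted flags).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 41]))
    bases = np.array(list("ACGT"))

    def random_seq() -> str:
        return "".join(rng.choice(bases, region_length))

    def mutate(seq: str, identity: float) -> str:
        n_sub = round((1 - identity) * len(seq))
        pos = rng.choice(len(seq), size=n_sub, replace=False)
        out = list(seq)
        for p in pos:
            out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
        return "".join(out)

    gut_species = list(gut_species)
    species_refs, gut_refs, truth = {}, {}, {}
    for i, sp in enumerate(gut_species):
        ref = random_seq()
        gut_refs[f"gutdb_{i:04d}"] = ref
        species_refs[sp] = mutate(ref, gut_identity)
        truth[sp] = True
    non_gut = [sp for sp in species_ids if sp not in set(gut_species)]
    for j, sp in enumerate(non_gut):
        if j < n_near_miss and gut_refs:
            ref = gut_refs[f"gutdb_{j % len(gut_refs):04d}"]
            species_refs[sp] = mutate(ref, near_miss_identity)
        else:
            species_refs[sp] = random_seq()
        truth[sp] = False
    return species_refs, gut_refs, truth


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, default=str)
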