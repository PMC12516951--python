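"""Net growth rates in activated sludge from an influent/sludge mass balance.

At steady state a species' biomass in the activated sludge (AS) is set by
three flows: immigration with the influent (a fraction ``m`` of the AS
biomass arrives per day), net biological growth at rate ``mu`` (per day),
and wastage at rate 1/SRT where SRT is the sludge retention time:

    m * a_IWW + mu * a_AS = a_AS / SRT
    =>  mu = 1/SRT - m * (a_IWW / a_AS)

with ``a_IWW``/``a_AS`` the species' relative abundances in influent and
sludge.  mu > 0 means the species grows in AS (process-critical candidates),
mu < 0 that it dies off and persists only through immigration, mu ~ 0 that
immigration alone balances wastage.  Species whose rate sign differs between
treatment plants are "variable"; species too rare in both compartments to
estimate a rate are "unassigned".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import CountTable

FATES = ("growing", "disappearing", "surviving", "variable", "unassigned")


@dataclass
class MassBalanceParams:
    """Plant parameters for the steady-state rate estimate.

    srt_days: sludge retention time (days).
    m_daily_fraction: fraction of the AS biomass arriving daily with the
        influent (field estimate ~5%).
    epsilon: half-width of the "no growth" band around mu = 0, per day;
        defaults to 10% of 1/SRT.
    min_abundance: mean relative abundance below which (in both IWW and AS
        at a plant) the rate is considered not assessable.
    """

    srt_days: float
    m_daily_fraction: float = 0.05
    epsilon: float | None = None
    min_abundance: float = 1e-4

    def __post_init__(self) -> None:
        if self.srt_days <= 0:
            raise ValueError("srt_days must be positive")
        if not 0 < self.m_daily_fraction < 1:
            raise ValueError("m_daily_fraction must be in (0, 1)")
        if self.epsilon is None:
            self.epsilon = 0.1 / self.srt_days
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")


def net_growth_rate(a_iww, a_as, params: MassBalanceParams):
    """mu = 1/SRT - m * (a_IWW / a_AS), elementwise.

    a_AS = 0 with a_IWW > 0 yields -inf (pure washout); both zero yields NaN
    (not assessable).  Accepts scalars or array-likes.
    """
    a_iww = np.asarray(a_iww, dtype=float)
    a_as = np.asarray(a_as, dtype=float)
    if np.any(a_iww < 0) or np.any(a_as < 0):
        raise ValueError("abundances must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = 1.0 / params.srt_days - params.m_daily_fraction * (a_iww / a_as)
    mu = np.where((a_as == 0) & (a_iww > 0), -np.inf, mu)
    mu = np.where((a_as == 0) & (a_iww == 0), np.nan, mu)
    if mu.ndim == 0:
        return float(mu)
    return mu


def mean_abundance_by_wwtp(table: CountTable, meta: pd.DataFrame, habitat: str) -> pd.DataFrame:
    """Time-mean relative abundance per species (rows) and WWTP (columns)."""
    sel = meta.loc[meta["habitat"] == habitat]
    rel = table.relative_abundance()
    cols = {}
    for wwtp, grp in sel.groupby("wwtp"):
        samples = [s for s in grp["sample_id"] if s in rel.index]
        if samples:
            cols[wwtp] = rel.loc[samples].mean(axis=0)
    if not cols:
        raise ValueError(f"no {habitat} samples with a WWTP")
    return pd.DataFrame(cols)


def classify_fates(
    iww_abund: pd.DataFrame,
    as_abund: pd.DataFrame,
    params: MassBalanceParams,
) -> pd.DataFrame:
    """Per-species growth fate from per-WWTP mean abundances.

    ``iww_abund`` / ``as_abund``: species x WWTP mean relative abundances
    (matching columns).  A plant is assessable for a species when the species
    reaches ``min_abundance`` in its IWW or AS there.  Fate rules over the
    assessable plants: all mu > eps -> growing; all mu < -eps -> disappearing;
    all |mu| <= eps -> surviving; disagreement in sign class -> variable;
    nothing assessable -> unassigned.
    """
    wwtps = [w for w in iww_abund.columns if w in as_abund.columns]
    if not wwtps:
        raise ValueError("no common WWTP between IWW and AS abundances")
    species = iww_abund.index.union(as_abund.index)
    iww = iww_abund.reindex(index=species, columns=wwtps).fillna(0.0)
    a_s = as_abund.reindex(index=species, columns=wwtps).fillna(0.0)
    eps = params.epsilon
    records = []
    for sp in species:
        mus, classes = {}, []
        for w in wwtps:
            ai, aa = iww.at[sp, w], a_s.at[sp, w]
            if ai < params.min_abundance and aa < params.min_abundance:
                mus[f"mu_{w}"] = np.nan
                continue
            mu = net_growth_rate(ai, aa, params)
            mus[f"mu_{w}"] = mu
            if np.isnan(mu):
                continue
            classes.append("growing" if mu > eps else "disappearing" if mu < -eps else "surviving")
        if not classes:
            fate = "unassigned"
        elif len(set(classes)) == 1:
            fate = classes[0]
        else:
            fate = "variable"
        records.append({"species_id": sp, **mus, "fate": fate})
    out = pd.DataFrame(records).set_index("species_id")
    return out


def crosstab_fate_source(
    fates: pd.DataFrame,
    sources: pd.Series,
    table: CountTable,
    meta: pd.DataFrame,
    habitat: str = "AS",
) -> pd.DataFrame:
    """Cumulative abundance and species counts per (fate x source) cell.

    Abundance is the mean per-sample relative abundance in ``habitat``
    summed over the species of each cell; empty intersections keep a zero
    row so that marginals are explicit.
    """
    from .source_attribution import SOURCES

    by_sample = meta.set_index("sample_id")["habitat"]
    samples = [s for s in table.sample_ids if by_sample.get(s) == habitat]
    if not samples:
        raise ValueError(f"no samples for habitat {habitat!r}")
    rel = table.relative_abundance().loc[samples].mean(axis=0)
    fate_of = fates["fate"].reindex(rel.index).fillna("unassigned")
    src_of = sources.reindex(rel.index).fillna("unknown")
    records = []
    for fate in FATES:
        for src in SOURCES:
            mask = (fate_of == fate) & (src_of == src)
            records.append(
                (fate, src, float(rel[mask].sum()), int(mask.sum()))
            )
    return pd.DataFrame(
        records, columns=["fate", "source", "abundance_fraction", "n_species"]
    )
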