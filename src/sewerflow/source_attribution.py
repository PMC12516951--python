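"""Partition species and read abundance into mutually exclusive sources.

Every species observed in a habitat is attributed to exactly one source:
human gut, the unified sewer core (strict/general/loose), the low-abundance
detected-in-sewer class, or unknown (present in influent or activated sludge
with no upstream assignment).  Precedence is fixed:
gut > unified_strict > unified_general > unified_loose > detected_sewer > unknown.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_formats import CountTable

SOURCES = (
    "gut",
    "unified_strict",
    "unified_general",
    "unified_loose",
    "detected_sewer",
    "unknown",
)

_TIER_TO_SOURCE = {
    "strict": "unified_strict",
    "general": "unified_general",
    "loose": "unified_loose",
    "detected": "detected_sewer",
}


def assign_sources(
    gut_species,
    unified_core: pd.DataFrame,
    detected=frozenset(),
    observed_species=None,
) -> pd.Series:
    """One source label per species (index = species_id).

    ``observed_species`` optionally extends the label set to species seen
    only downstream (labelled ``unknown``).
    """
    labels = {}
    tier_of = dict(zip(unified_core["species_id"], unified_core["unified_tier"]))
    species = set(tier_of) | set(gut_species) | set(detected)
    if observed_species is not None:
        species |= set(observed_species)
    for sp in species:
        if sp in gut_species:
            labels[sp] = "gut"
        else:
            tier = tier_of.get(sp, "none")
            if tier == "none" and sp in detected:
                tier = "detected"
            labels[sp] = _TIER_TO_SOURCE.get(tier, "unknown")
    out = pd.Series(labels, name="source").sort_index()
    out.index.name = "species_id"
    return out


def summarize_attribution(
    table: CountTable,
    labels: pd.Series,
    meta: pd.DataFrame,
    habitats=None,
    mode: str = "mean",
) -> pd.DataFrame:
    """Per-habitat cumulative relative abundance and species counts per source.

    ``mode='mean'`` averages per-sample source fractions over the habitat's
    samples; ``mode='pooled'`` sums counts across samples first and then
    normalizes (a pooled-library fraction).  A species counts as observed in
    a habitat when it has at least one read in at least one sample.
    """
    if mode not in ("mean", "pooled"):
        raise ValueError("mode must be 'mean' or 'pooled'")
    by_sample = meta.set_index("sample_id")["habitat"]
    if habitats is None:
        habitats = list(dict.fromkeys(by_sample.loc[table.sample_ids]))
    lab = labels.reindex(table.feature_ids).fillna("unknown")
    records = []
    for hab in habitats:
        samples = [s for s in table.sample_ids if by_sample.get(s) == hab]
        if not samples:
            raise ValueError(f"no samples for habitat {hab!r}")
        sub = table.counts.loc[samples]
        if mode == "mean":
            rel = sub.div(sub.sum(axis=1), axis=0)
            frac = rel.T.groupby(lab.to_numpy()).sum().T.mean(axis=0)
        else:
            pooled = sub.sum(axis=0)
            frac = pooled.groupby(lab.to_numpy()).sum() / pooled.sum()
        observed = (sub >= 1).any(axis=0)
        n_sp = observed.groupby(lab.to_numpy()).sum()
        for src in SOURCES:
            records.append(
                (
                    hab,
                    src,
                    float(frac.get(src, 0.0)),
                    int(n_sp.get(src, 0)),
                )
            )
    return pd.DataFrame(
        records, columns=["habitat", "source", "abundance_fraction", "n_species"]
    )
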