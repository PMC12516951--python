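"""Percent-identity flagging of gut species against reference 16S fragments.

Species are labelled as human-gut bacteria when their 16S fragment is at
least 98.7% identical to any sequence in a gut reference set — the standard
species-level identity threshold in 16S profiling.  Identity here is the
edit-distance identity

    identity(a, b) = 1 - levenshtein(a, b) / max(|a|, |b|),

i.e. the fraction of positions of the longer sequence left untouched by a
minimal global edit script.  For substitution-only pairs this equals the
familiar matches-over-columns of a global alignment; unlike the latter it
does not depend on which co-optimal alignment a particular aligner returns,
so it is reproducible across implementations.
"""

from __future__ import annotations

import warnings

import edlib
import numpy as np
import pandas as pd

GUT_IDENTITY_CUTOFF = 0.987

_NUCLEOTIDES = frozenset("ACGT")


def _check_sequence(seq: str, name: str) -> str:
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    s = seq.upper()
    bad = set(s) - _NUCLEOTIDES
    if bad:
        raise ValueError(f"{name}: non-nucleotide characters {sorted(bad)}")
    return s


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Edit-distance identity between two nucleotide sequences, in [0, 1]."""
    a = _check_sequence(seq_a, "seq_a")
    b = _check_sequence(seq_b, "seq_b")
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def flag_gut_species(
    species_refs: dict,
    gut_refs: dict,
    cutoff: float = GUT_IDENTITY_CUTOFF,
    strict: bool = False,
) -> pd.DataFrame:
    """Flag each species by its best identity against the gut reference set.

    Parameters
    ----------
    species_refs
        ``{species_id: sequence}`` for the community being classified.  A
        species mapped to ``None``/empty is recorded as non-gut with identity
        0 and a warning (it cannot be assessed).
    gut_refs
        ``{reference_id: sequence}`` of gut 16S references.
    cutoff
        Identity threshold; inclusive (``>=``) by default, exclusive when
        ``strict`` is true.
    strict
        Use a strict ``>`` comparison at the cutoff.

    Returns
    -------
    DataFrame with columns species_id, is_gut, best_identity,
    best_gut_reference (None when no assessment was possible), sorted by
    species_id.  Ties on identity keep the lexicographically first reference.
    """
    if not species_refs or not gut_refs:
        raise ValueError("both sequence sets must be non-empty")
    gut_items = sorted(gut_refs.items())
    rows = []
    for sp in sorted(species_refs):
        seq = species_refs[sp]
        if not seq:
            warnings.warn(f"species {sp} has no sequence; recorded as non-gut")
            rows.append((sp, False, 0.0, None))
            continue
        best_id, best_ref = -1.0, None
        for ref, gseq in gut_items:
            ident = pairwise_identity(seq, gseq)
            if ident > best_id:
                best_id, best_ref = ident, ref
        is_gut = best_id > cutoff if strict else bool(best_id >= cutoff)
        rows.append((sp, is_gut, best_id, best_ref))
    return pd.DataFrame(
        rows, columns=["species_id", "is_gut", "best_identity", "best_gut_reference"]
    )


def gut_species_set(flags: pd.DataFrame) -> frozenset:
    """The set of species ids flagged as gut."""
    return frozenset(flags.loc[flags["is_gut"], "species_id"])
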