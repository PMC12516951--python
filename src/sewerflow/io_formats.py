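"""Reading, writing and quality filtering of amplicon count tables and companions.

The central object is the :class:`CountTable`: an integer samples-by-features
matrix of 16S amplicon read counts, at ASV, species or genus resolution.
External formats follow the common amplicon conventions: count TSVs carry
features as rows and samples as columns (first column = feature id), sample
metadata is a CSV with ISO-8601 timestamps, taxonomy is a TSV mapping each
feature to genus/species labels, rainfall series are two-column CSVs, and
reference sequences are plain FASTA.  A dense JSON dialect mirroring the
BIOM 1.0 table semantics (observation/sample axes) is supported for
interoperability.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

SEWER_HABITATS = ("biofilm_g", "biofilm_ep", "sediment")
WATER_HABITATS = ("SWW_g", "SWW_ep", "IWW", "AS")
HABITATS = SEWER_HABITATS + WATER_HABITATS
WWTPS = ("AAW", "AAE")
UNCLASSIFIED = "UNCLASSIFIED"

LEVELS = ("asv", "species", "genus")

METADATA_COLUMNS = (
    "sample_id",
    "habitat",
    "location_id",
    "wwtp",
    "timestamp",
    "sewer_type",
    "replicate_group",
)


class FormatError(ValueError):
    """Raised when an external file violates the expected format."""


class EmptyTableWarning(UserWarning):
    """Emitted when a filter removes every sample (a condition, not an error)."""


@dataclass
class CountTable:
    """Samples-by-features matrix of non-negative integer read counts.

    Parameters
    ----------
    counts
        DataFrame with sample ids as index and feature ids as columns.
    level
        Taxonomic resolution of the features: ``asv``, ``species`` or ``genus``.
    """

    counts: pd.DataFrame
    level: str = "asv"

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")
        c = self.counts
        if c.index.has_duplicates:
            raise FormatError("duplicate sample ids")
        if c.columns.has_duplicates:
            raise FormatError("duplicate feature ids")
        arr = c.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                raise FormatError("counts must be integers")
            self.counts = c.astype(np.int64)
            arr = self.counts.to_numpy()
        if arr.size and arr.min() < 0:
            raise FormatError("counts must be non-negative")

    @property
    def sample_ids(self) -> list:
        return list(self.counts.index)

    @property
    def feature_ids(self) -> list:
        return list(self.counts.columns)

    def totals(self) -> pd.Series:
        """Total reads per sample."""
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundance a = count / row sum."""
        tot = self.totals().to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            rel = self.counts.to_numpy(dtype=float) / tot[:, None]
        return pd.DataFrame(rel, index=self.counts.index, columns=self.counts.columns)

    def subset_samples(self, sample_ids) -> "CountTable":
        return replace(self, counts=self.counts.loc[list(sample_ids)])


# ---------------------------------------------------------------------------
# count tables


def read_count_table(path, format: str = "tsv") -> CountTable:
    """Read a count table from ``tsv`` (features x samples) or dense ``biom`` JSON."""
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except pd.errors.EmptyDataError as exc:
            raise FormatError(f"empty count table: {path}") from exc
        if df.empty and df.columns.empty:
            raise FormatError(f"count table has no samples: {path}")
        if df.index.has_duplicates:
            raise FormatError("duplicate feature ids")
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
        if len(set(header)) != len(header):
            raise FormatError("duplicate sample ids")
        mat = df.T  # samples x features, file order preserved
    elif format == "biom":
        with open(path) as fh:
            try:
                doc = json.load(fh)
            except json.JSONDecodeError as exc:
                raise FormatError(f"invalid BIOM JSON: {path}") from exc
        try:
            rows = [r["id"] for r in doc["rows"]]
            cols = [c["id"] for c in doc["columns"]]
            data = np.asarray(doc["data"])
        except (KeyError, TypeError) as exc:
            raise FormatError(f"missing BIOM fields in {path}") from exc
        if data.shape != (len(rows), len(cols)):
            raise FormatError("BIOM data shape disagrees with axes")
        mat = pd.DataFrame(data.T, index=cols, columns=rows)
    else:
        raise ValueError(f"unknown format {format!r}")
    arr = mat.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise FormatError("non-numeric cell in count table")
    if np.any(arr != np.floor(arr)):
        raise FormatError("non-integer cell in count table")
    if arr.size and arr.min() < 0:
        raise FormatError("negative cell in count table")
    return CountTable(mat.astype(np.int64))


def write_count_table(table: CountTable, path, format: str = "tsv") -> None:
    if format == "tsv":
        out = table.counts.T
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")
    elif format == "biom":
        doc = {
            "id": None,
            "format": "1.0.0-dense-json",
            "type": "OTU table",
            "matrix_type": "dense",
            "shape": [len(table.feature_ids), len(table.sample_ids)],
            "rows": [{"id": f, "metadata": None} for f in table.feature_ids],
            "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
            "data": table.counts.T.to_numpy().tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# metadata / taxonomy


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path)
    missing = set(METADATA_COLUMNS) - set(meta.columns)
    if missing:
        raise FormatError(f"metadata missing columns: {sorted(missing)}")
    meta["timestamp"] = pd.to_datetime(meta["timestamp"])
    validate_metadata(meta)
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, index=False)


def validate_metadata(meta: pd.DataFrame, table: CountTable | None = None) -> None:
    if meta["sample_id"].duplicated().any():
        raise FormatError("duplicate sample ids in metadata")
    bad = set(meta["habitat"]) - set(HABITATS)
    if bad:
        raise FormatError(f"unknown habitats: {sorted(bad)}")
    plant = meta["habitat"].isin(["IWW", "AS"])
    if plant.any() and not meta.loc[plant, "wwtp"].isin(WWTPS).all():
        raise FormatError("IWW/AS samples must carry a WWTP (AAW or AAE)")
    if table is not None:
        missing = set(table.sample_ids) - set(meta["sample_id"])
        if missing:
            raise FormatError(f"samples without metadata: {sorted(missing)}")


def read_taxonomy(path) -> pd.DataFrame:
    tax = pd.read_csv(path, sep="\t")
    missing = {"feature_id", "genus", "species", "confidence"} - set(tax.columns)
    if missing:
        raise FormatError(f"taxonomy missing columns: {sorted(missing)}")
    return tax


def write_taxonomy(tax: pd.DataFrame, path) -> None:
    tax.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# rainfall / FASTA


def read_rainfall(path, hourly: bool = False) -> pd.DataFrame:
    """Rainfall CSV: (date, mm) daily or (datetime, mm) hourly."""
    rain = pd.read_csv(path)
    col = "datetime" if hourly else "date"
    if col not in rain.columns or "mm" not in rain.columns:
        raise FormatError(f"rainfall CSV needs columns ({col}, mm)")
    rain[col] = pd.to_datetime(rain[col])
    if (rain["mm"] < 0).any():
        raise FormatError("negative rainfall")
    if not rain[col].is_monotonic_increasing or rain[col].duplicated().any():
        raise FormatError("rainfall time axis must be strictly increasing")
    return rain


def write_rainfall(rain: pd.DataFrame, path) -> None:
    rain.to_csv(path, index=False)


def read_fasta(path) -> dict:
    """FASTA file -> {id: uppercase sequence string}."""
    seqs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"duplicate sequence id {rec.id}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: dict, path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# sample QC


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(np.int64)


def filter_and_merge(
    table: CountTable,
    meta: pd.DataFrame,
    min_reads: int = 5000,
    strict: bool = True,
) -> CountTable:
    """Drop shallow samples and merge replicates by mean read count.

    Samples whose total read count is not above ``min_reads`` (strictly, by
    default) are removed.  Remaining samples sharing a ``replicate_group`` are
    merged feature-wise by the mean count, rounded half-up to keep the table
    integral; the merged sample takes the group identifier as its id.
    """
    if min_reads <= 0:
        raise ValueError("min_reads must be positive")
    totals = table.totals()
    keep = totals > min_reads if strict else totals >= min_reads
    kept = table.counts.loc[keep.to_numpy()]
    if kept.empty:
        warnings.warn("all samples removed by the read filter", EmptyTableWarning)
        return CountTable(kept, level=table.level)
    groups = meta.set_index("sample_id")["replicate_group"].reindex(kept.index)
    if groups.isna().any():
        raise FormatError(
            f"samples without metadata: {sorted(kept.index[groups.isna()])}"
        )
    merged = kept.groupby(groups, sort=False).mean()
    merged = pd.DataFrame(
        _round_half_up(merged.to_numpy()), index=merged.index, columns=merged.columns
    )
    merged.index.name = None
    return CountTable(merged, level=table.level)


def collapse_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Metadata for merged tables: one row per replicate_group (first row wins)."""
    out = meta.groupby("replicate_group", sort=False).first().reset_index()
    out["sample_id"] = out["replicate_group"]
    return out[list(METADATA_COLUMNS)]


def aggregate(table: CountTable, taxonomy: pd.DataFrame, level: str) -> CountTable:
    """Sum ASV counts over shared species/genus labels.

    Unclassified ASVs keep their own identity as singleton features so that
    diversity at the aggregated level is not deflated by lumping unknowns.
    """
    if level not in ("species", "genus"):
        raise ValueError("level must be 'species' or 'genus'")
    if table.level != "asv":
        raise ValueError("aggregate expects an ASV-level table")
    labels = taxonomy.set_index("feature_id")[level]
    missing = set(table.feature_ids) - set(labels.index)
    if missing:
        raise FormatError(f"features without taxonomy: {sorted(missing)[:5]}")
    labels = labels.reindex(table.feature_ids)
    own = labels == UNCLASSIFIED
    labels = labels.where(~own, labels.index.to_series())
    agg = table.counts.T.groupby(labels.to_numpy(), sort=False).sum().T
    return CountTable(agg, level=level)
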