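"""Ingestion and filtering of OTU read-count tables into binary community matrices.

A community matrix here is a samples x OTUs table. Read-count tables are
filtered in three steps before binarization:

1. samples with a read total below a minimum sequencing depth are removed
   (strictly "less than", so a sample exactly at the threshold is kept);
2. within each sample, OTUs contributing less than a given fraction of that
   sample's total reads are zeroed (again strict "less than");
3. samples flagged as contaminated (e.g. non-target host DNA detected) are
   removed.

The remaining counts are binarized to presence (1) / absence (0), and OTU
columns that lost all occurrences are dropped so that downstream OTU counts
refer to taxa actually present in the final matrix.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ReadCountTable",
    "BinaryCommunityMatrix",
    "PairSet",
    "TableParseError",
    "read_count_table",
    "read_metadata",
    "filter_low_read_samples",
    "filter_minor_otus",
    "drop_flagged_samples",
    "binarize",
    "screen_pairs",
    "prepare_binary_matrix",
]

METADATA_COLUMNS = ("sample_id", "host", "x", "y", "exclude_flag")


class TableParseError(ValueError):
    """Raised when a delimited OTU table cannot be parsed as integer counts."""


def _check_unique(ids, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dup = seen[seen.duplicated()].unique().tolist()
        raise TableParseError(f"duplicate {what} identifier(s): {dup}")


@dataclass
class ReadCountTable:
    """Read counts as a samples x OTUs integer DataFrame."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.counts.index, "sample")
        _check_unique(self.counts.columns, "OTU")
        values = self.counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            raise TableParseError("counts must be integers")
        if values.size and (values < 0).any():
            raise TableParseError("counts must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_csv(self, path) -> None:
        self.counts.to_csv(path)


def _drop_empty_otus(counts: pd.DataFrame) -> pd.DataFrame:
    keep = counts.sum(axis=0) > 0
    return counts.loc[:, keep]


def read_count_table(path, orientation: str = "samples_by_otus") -> ReadCountTable:
    """Read a delimited (CSV/TSV, sniffed) OTU table.

    ``orientation`` is ``"samples_by_otus"`` (rows are samples) or
    ``"otus_by_samples"`` (rows are OTUs; the table is transposed on load).
    """
    if orientation not in ("samples_by_otus", "otus_by_samples"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    header_ids = header.split(sep)[1:]
    _check_unique(header_ids, "header")  # pandas would silently mangle duplicates
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        series = df[col]
        if np.issubdtype(series.dtype, np.integer):
            continue
        as_float = pd.to_numeric(series, errors="coerce")
        bad = as_float.isna() | (as_float != np.floor(as_float))
        if bad.any():
            row = df.index[int(np.argmax(bad.to_numpy()))]
            raise TableParseError(
                f"non-integer count at row {row!r}, column {col!r}: {series[bad].iloc[0]!r}"
            )
        df[col] = as_float.astype(np.int64)
    if orientation == "otus_by_samples":
        df = df.T
    return ReadCountTable(df)


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata (sample_id, host, x, y, exclude_flag)."""
    md = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in METADATA_COLUMNS if c not in md.columns]
    if missing:
        raise TableParseError(f"metadata missing column(s): {missing}")
    md["sample_id"] = md["sample_id"].astype(str)
    _check_unique(md["sample_id"], "metadata sample")
    md["exclude_flag"] = md["exclude_flag"].astype(bool)
    coords = md[["x", "y"]].to_numpy(dtype=float)
    if np.isfinite(coords).size and not np.isfinite(coords[~np.isnan(coords)]).all():
        raise TableParseError("non-finite coordinate in metadata")
    return md


def filter_low_read_samples(table: ReadCountTable, min_reads: int = 20) -> ReadCountTable:
    """Remove samples whose read total is strictly below ``min_reads``."""
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    keep = table.sample_totals >= min_reads
    out = table.counts.loc[keep]
    if out.shape[0] == 0:
        warnings.warn("all samples removed by the read-depth filter", stacklevel=2)
    return ReadCountTable(_drop_empty_otus(out))


def filter_minor_otus(table: ReadCountTable, threshold: float = 0.05) -> ReadCountTable:
    """Zero counts below ``threshold`` of each sample's total, per sample.

    A count exactly equal to ``threshold * total`` is retained (strict
    "less than"). OTU columns left with no reads anywhere are dropped.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    counts = table.counts.to_numpy().copy()
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, counts / np.maximum(totals, 1), 0.0)
    counts[frac < threshold] = 0
    out = pd.DataFrame(counts, index=table.counts.index, columns=table.counts.columns)
    return ReadCountTable(_drop_empty_otus(out))


def drop_flagged_samples(table: ReadCountTable, metadata: pd.DataFrame) -> ReadCountTable:
    """Remove samples whose metadata ``exclude_flag`` is set."""
    md = metadata.set_index(metadata["sample_id"].astype(str))
    missing = [s for s in table.sample_ids if s not in md.index]
    if missing:
        raise KeyError(f"no metadata record for sample(s): {missing}")
    flagged = md.loc[table.sample_ids, "exclude_flag"].to_numpy(dtype=bool)
    out = table.counts.loc[~flagged]
    if out.shape[0] == 0:
        warnings.warn("all samples removed by the contamination filter", stacklevel=2)
    return ReadCountTable(_drop_empty_otus(out))


@dataclass
class BinaryCommunityMatrix:
    """Presence/absence matrix (samples x OTUs) with margins.

    ``occurrence`` (per-OTU column sums, R_k) and ``richness`` (per-sample
    row sums) are the margins preserved by the fixed-fixed null model.
    """

    presence: np.ndarray
    sample_ids: list[str]
    otu_ids: list[str]

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=np.uint8)
        if self.presence.ndim != 2:
            raise ValueError("presence must be 2-D")
        if not np.isin(self.presence, (0, 1)).all():
            raise ValueError("presence must be 0/1")
        if self.presence.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValueError("presence shape inconsistent with identifiers")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.otu_ids, "OTU")

    @property
    def n_samples(self) -> int:
        return self.presence.shape[0]

    @property
    def n_otus(self) -> int:
        return self.presence.shape[1]

    @property
    def occurrence(self) -> np.ndarray:
        """Per-OTU number of occupied samples (R_k)."""
        return self.presence.sum(axis=0).astype(np.int64)

    @property
    def richness(self) -> np.ndarray:
        """Per-sample number of OTUs present."""
        return self.presence.sum(axis=1).astype(np.int64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.presence, index=self.sample_ids, columns=self.otu_ids)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BinaryCommunityMatrix":
        return cls(df.to_numpy(dtype=np.uint8), list(map(str, df.index)), list(map(str, df.columns)))

    @classmethod
    def from_csv(cls, path, orientation: str = "samples_by_otus") -> "BinaryCommunityMatrix":
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
        if orientation == "otus_by_samples":
            df = df.T
        values = df.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise TableParseError("binary matrix file contains values other than 0/1")
        return cls.from_frame(df)

    def subset_samples(self, mask) -> "BinaryCommunityMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return BinaryCommunityMatrix(
            self.presence[idx], [self.sample_ids[i] for i in idx], list(self.otu_ids)
        )

    def subset_otus(self, idx) -> "BinaryCommunityMatrix":
        idx = np.asarray(idx)
        return BinaryCommunityMatrix(
            self.presence[:, idx], list(self.sample_ids), [self.otu_ids[i] for i in idx]
        )


def binarize(table: ReadCountTable) -> BinaryCommunityMatrix:
    """Convert counts to presence/absence; drop OTUs with no occurrences."""
    counts = _drop_empty_otus(table.counts)
    presence = (counts.to_numpy() > 0).astype(np.uint8)
    return BinaryCommunityMatrix(presence, list(counts.index), list(counts.columns))


@dataclass
class PairSet:
    """Unordered OTU index pairs retained for pairwise testing."""

    pairs: list[tuple[int, int]]
    min_occurrence: int
    min_pair_sum: int

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def as_array(self) -> np.ndarray:
        if not self.pairs:
            return np.empty((0, 2), dtype=np.int64)
        return np.asarray(self.pairs, dtype=np.int64)


def screen_pairs(
    matrix: BinaryCommunityMatrix, min_occurrence: int, min_pair_sum: int
) -> PairSet:
    """Retain pairs (i, j), i < j, with R_i, R_j >= min_occurrence and
    R_i + R_j >= min_pair_sum.

    Pairs with small occurrence counts have degenerate null score
    distributions, so they are screened out before randomization testing.
    """
    if min_occurrence < 0 or min_pair_sum < 0:
        raise ValueError("screening thresholds must be >= 0")
    occ = matrix.occurrence
    eligible = np.flatnonzero(occ >= min_occurrence)
    pairs = [
        (int(i), int(j))
        for i, j in itertools.combinations(eligible, 2)
        if occ[i] + occ[j] >= min_pair_sum
    ]
    if len(eligible) < 2 or not pairs:
        warnings.warn("fewer than two eligible OTUs; pair set is empty", stacklevel=2)
    return PairSet(pairs, min_occurrence, min_pair_sum)


def prepare_binary_matrix(
    table: ReadCountTable,
    metadata: pd.DataFrame | None = None,
    min_reads: int = 20,
    minor_threshold: float = 0.05,
) -> BinaryCommunityMatrix:
    """Apply the full filter sequence and binarize.

    Order: read-depth filter, per-sample minor-OTU filter, contaminated
    sample removal, binarization. Order matters because the minor-OTU rule
    uses per-sample totals.
    """
    table = filter_low_read_samples(table, min_reads=min_reads)
    table = filter_minor_otus(table, threshold=minor_threshold)
    if metadata is not None:
        table = drop_flagged_samples(table, metadata)
    return binarize(table)
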