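"""Checkerboard (C) and togetherness (T) scores for OTU pairs.

For a pair of OTUs with occurrences R_i, R_j, co-occurrence count S and N
samples:

    C = (R_i - S) (R_j - S)          (segregation: checkerboard units)
    T = S (N + S - R_i - R_j)        (aggregation: joint presences x joint absences)

Given fixed margins, S is constrained to [Smin, Smax] with
Smin = max(0, R_i + R_j - N) and Smax = min(R_i, R_j). C is strictly
decreasing and T strictly increasing in S over that range, so dividing by
the value at the extreme (C at Smin, T at Smax) standardizes each score to
[0, 1], where 1 is the most segregated (C) or most aggregated (T)
arrangement the margins allow. Degenerate margins where the maximum is 0
(e.g. an OTU in every sample) yield a standardized score of 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import BinaryCommunityMatrix, PairSet

__all__ = [
    "PairCounts",
    "pair_counts",
    "c_score",
    "t_score",
    "standardize_scores",
    "standardized_from_s",
    "score_pairs",
]


@dataclass(frozen=True)
class PairCounts:
    """Margin/co-occurrence summary (R_i, R_j, S, N) for one OTU pair."""

    r_i: int
    r_j: int
    s: int
    n: int

    def __post_init__(self) -> None:
        if min(self.r_i, self.r_j, self.s, self.n) < 0:
            raise ValueError("counts must be non-negative")
        if max(self.r_i, self.r_j) > self.n:
            raise ValueError("occurrences cannot exceed the number of samples")
        if not self.s_min <= self.s <= self.s_max:
            raise ValueError(
                f"S={self.s} outside feasible range [{self.s_min}, {self.s_max}]"
            )

    @property
    def s_min(self) -> int:
        return max(0, self.r_i + self.r_j - self.n)

    @property
    def s_max(self) -> int:
        return min(self.r_i, self.r_j)


def pair_counts(matrix: BinaryCommunityMatrix, i: int, j: int) -> PairCounts:
    """Count occurrences and co-occurrences of OTU columns ``i`` and ``j``."""
    if i == j:
        raise ValueError("a pair must consist of two distinct OTUs")
    col_i = matrix.presence[:, i]
    col_j = matrix.presence[:, j]
    return PairCounts(
        r_i=int(col_i.sum()),
        r_j=int(col_j.sum()),
        s=int(np.sum(col_i & col_j)),
        n=matrix.n_samples,
    )


def c_score(pc: PairCounts) -> int:
    """Checkerboard score (R_i - S)(R_j - S)."""
    return (pc.r_i - pc.s) * (pc.r_j - pc.s)


def t_score(pc: PairCounts) -> int:
    """Togetherness score S(N + S - R_i - R_j)."""
    return pc.s * (pc.n + pc.s - pc.r_i - pc.r_j)


def standardize_scores(pc: PairCounts) -> tuple[float, float]:
    """Standardized (C, T) in [0, 1] relative to the margin-feasible extremes."""
    c_std, t_std = standardized_from_s(
        np.array([pc.r_i]), np.array([pc.r_j]), np.array([pc.s]), pc.n
    )
    return float(c_std[0]), float(t_std[0])


def standardized_from_s(r_i, r_j, s, n) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized standardized scores; broadcasts over (r_i, r_j, s).

    Degenerate margins (maximum 0) give 0 rather than NaN.
    """
    r_i = np.asarray(r_i, dtype=np.int64)
    r_j = np.asarray(r_j, dtype=np.int64)
    s = np.asarray(s, dtype=np.int64)
    s_min = np.maximum(0, r_i + r_j - n)
    s_max = np.minimum(r_i, r_j)
    c = (r_i - s) * (r_j - s)
    t = s * (n + s - r_i - r_j)
    c_max = (r_i - s_min) * (r_j - s_min)
    t_max = s_max * (n + s_max - r_i - r_j)
    with np.errstate(invalid="ignore", divide="ignore"):
        c_std = np.where(c_max > 0, c / np.maximum(c_max, 1), 0.0)
        t_std = np.where(t_max > 0, t / np.maximum(t_max, 1), 0.0)
    return c_std, t_std


def score_pairs(matrix: BinaryCommunityMatrix, pairs: PairSet | list) -> pd.DataFrame:
    """Tabulate raw and standardized scores for each pair.

    Columns: otu_i, otu_j, r_i, r_j, s, n, c, t, c_std, t_std.
    """
    pair_arr = pairs.as_array() if isinstance(pairs, PairSet) else np.asarray(pairs)
    rows = []
    for i, j in pair_arr:
        pc = pair_counts(matrix, int(i), int(j))
        c_std, t_std = standardize_scores(pc)
        rows.append(
            {
                "otu_i": matrix.otu_ids[int(i)],
                "otu_j": matrix.otu_ids[int(j)],
                "r_i": pc.r_i,
                "r_j": pc.r_j,
                "s": pc.s,
                "n": pc.n,
                "c": c_score(pc),
                "t": t_score(pc),
                "c_std": c_std,
                "t_std": t_std,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["otu_i", "otu_j", "r_i", "r_j", "s", "n", "c", "t", "c_std", "t_std"],
    )
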