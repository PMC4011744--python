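"""Randomization tests for pairwise and community-level co-occurrence.

Three test layouts are supported, mirroring a two-host sampling design:

* per-dataset pair tests (each host separately, or both pooled): the
  observed standardized C (segregation) or T (aggregation) score of each
  screened pair is compared with its distribution over a margin-constrained
  null ensemble, one-sided in the upper tail;
* host-contrast tests: the difference of standardized scores between the
  two host subsets is tested by permuting host labels across samples;
* community-level tests: the mean standardized score over all pairs in a
  subset (e.g. a phylum or guild) is tested against the same ensemble, with
  a standard effect size SES = (obs - null mean) / null sd.

P values use the add-one permutation estimator (1 + b) / (1 + M) and are
adjusted with Benjamini-Hochberg FDR within each test family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .community import BinaryCommunityMatrix, PairSet, screen_pairs
from .nullmodels import NullEnsemble
from .scores import standardized_from_s

__all__ = [
    "bh_adjust",
    "pair_randomization_test",
    "host_difference_test",
    "community_score_test",
    "CommunityTestResult",
]

logger = logging.getLogger(__name__)

SCORE_TYPES = ("c_std", "t_std")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("P values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _observed_pair_stats(matrix: BinaryCommunityMatrix, pair_arr: np.ndarray):
    occ = matrix.occurrence
    cols_i = matrix.presence[:, pair_arr[:, 0]]
    cols_j = matrix.presence[:, pair_arr[:, 1]]
    s = np.sum(cols_i & cols_j, axis=0).astype(np.int64)
    return occ[pair_arr[:, 0]], occ[pair_arr[:, 1]], s


def _perm_pvalue(null: np.ndarray, observed: np.ndarray, m: int) -> np.ndarray:
    """(1 + #{null >= obs}) / (1 + M), columnwise."""
    b = np.sum(null >= observed[None, :] - 1e-12, axis=0)
    return (1.0 + b) / (1.0 + m)


def pair_randomization_test(
    matrix: BinaryCommunityMatrix,
    pairs: PairSet,
    ensemble: NullEnsemble,
    score_type: str = "t_std",
    test_id: str = "test",
) -> pd.DataFrame:
    """One-sided upper-tail randomization test per screened pair.

    Large standardized C = segregation; large standardized T = aggregation.
    Returns a DataFrame sorted by P with BH-adjusted q values.
    """
    if score_type not in SCORE_TYPES:
        raise ValueError(f"score_type must be one of {SCORE_TYPES}")
    pair_arr = pairs.as_array()
    if len(pair_arr) == 0:
        raise ValueError("empty pair set")
    if ensemble.shape != matrix.presence.shape or not np.array_equal(
        ensemble.presence.sum(axis=0), matrix.occurrence
    ):
        raise ValueError("ensemble was not built from this matrix")
    r_i, r_j, s_obs = _observed_pair_stats(matrix, pair_arr)
    c_obs, t_obs = standardized_from_s(r_i, r_j, s_obs, matrix.n_samples)
    observed = c_obs if score_type == "c_std" else t_obs

    s_null, ri_null, rj_null = ensemble.pair_stats(pair_arr)
    c_null, t_null = standardized_from_s(ri_null, rj_null, s_null, matrix.n_samples)
    null = c_null if score_type == "c_std" else t_null
    p = _perm_pvalue(null, observed, ensemble.m)

    out = pd.DataFrame(
        {
            "otu_i": [matrix.otu_ids[i] for i in pair_arr[:, 0]],
            "otu_j": [matrix.otu_ids[j] for j in pair_arr[:, 1]],
            "r_i": r_i,
            "r_j": r_j,
            "s": s_obs,
            "n": matrix.n_samples,
            "score_type": score_type,
            "observed": observed,
            "p": p,
            "q": bh_adjust(p),
            "m_used": ensemble.m,
            "test_id": test_id,
        }
    )
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def _subset_scores(presence_i, presence_j, presence_ij, mask, n_sub):
    """Standardized scores of each pair within the samples selected by mask."""
    maskf = mask.astype(np.float64)
    r_i = (maskf @ presence_i).astype(np.int64)
    r_j = (maskf @ presence_j).astype(np.int64)
    s = (maskf @ presence_ij).astype(np.int64)
    return standardized_from_s(r_i, r_j, s, n_sub)


def host_difference_test(
    matrix: BinaryCommunityMatrix,
    host_labels,
    min_occurrence: int = 5,
    min_pair_sum: int = 25,
    m: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Host-contrast randomization test (label permutation, two-sided).

    For each pair passing per-host screening in *both* host subsets, the
    observed contrast delta = score(host A) - score(host B) of the
    standardized C and T scores is compared with its distribution under
    random reassignment of host labels (group sizes preserved).
    """
    hosts = np.asarray(host_labels)
    if hosts.shape[0] != matrix.n_samples:
        raise ValueError("one host label per sample required")
    levels = sorted(pd.unique(hosts).tolist())
    if len(levels) != 2:
        raise ValueError(f"exactly two host labels required, got {levels}")
    host_a, host_b = levels
    mask_a = hosts == host_a
    sub_a = matrix.subset_samples(mask_a)
    sub_b = matrix.subset_samples(~mask_a)
    pairs_a = set(screen_pairs(sub_a, min_occurrence, min_pair_sum).pairs)
    pairs_b = set(screen_pairs(sub_b, min_occurrence, min_pair_sum).pairs)
    dropped = pairs_a ^ pairs_b
    for pair in sorted(dropped):
        logger.info("pair %s fails screening in one host subset; excluded", pair)
    pair_list = sorted(pairs_a & pairs_b)
    if not pair_list:
        raise ValueError("no pair passes screening in both host subsets")
    pair_arr = np.asarray(pair_list, dtype=np.int64)

    presence = matrix.presence
    pi = presence[:, pair_arr[:, 0]].astype(np.float64)
    pj = presence[:, pair_arr[:, 1]].astype(np.float64)
    pij = pi * pj
    n_a = int(mask_a.sum())
    n_b = matrix.n_samples - n_a

    def deltas(mask):
        c_a, t_a = _subset_scores(pi, pj, pij, mask, n_a)
        c_b, t_b = _subset_scores(pi, pj, pij, ~mask, n_b)
        return c_a - c_b, t_a - t_b

    dc_obs, dt_obs = deltas(mask_a)

    rng = np.random.default_rng(seed)
    dc_null = np.empty((m, len(pair_arr)))
    dt_null = np.empty((m, len(pair_arr)))
    base = np.zeros(matrix.n_samples, dtype=bool)
    for t in range(m):
        perm = base.copy()
        perm[rng.choice(matrix.n_samples, size=n_a, replace=False)] = True
        dc_null[t], dt_null[t] = deltas(perm)

    p_dc = _perm_pvalue(np.abs(dc_null), np.abs(dc_obs), m)
    p_dt = _perm_pvalue(np.abs(dt_null), np.abs(dt_obs), m)

    out = pd.DataFrame(
        {
            "otu_i": [matrix.otu_ids[i] for i in pair_arr[:, 0]],
            "otu_j": [matrix.otu_ids[j] for j in pair_arr[:, 1]],
            "host_a": host_a,
            "host_b": host_b,
            "delta_c": dc_obs,
            "delta_t": dt_obs,
            "p_delta_c": p_dc,
            "p_delta_t": p_dt,
            "q_delta_c": bh_adjust(p_dc),
            "q_delta_t": bh_adjust(p_dt),
            "m_used": m,
        }
    )
    return out.reset_index(drop=True)


@dataclass
class CommunityTestResult:
    """Community-level mean-score test outcome for one OTU subset."""

    subset: str
    score_type: str
    mean_score: float
    p: float
    ses: float
    m_used: int
    n_pairs: int

    def to_dict(self) -> dict:
        return {
            "subset": self.subset,
            "score_type": self.score_type,
            "mean_score": self.mean_score,
            "p": self.p,
            "ses": self.ses,
            "m_used": self.m_used,
            "n_pairs": self.n_pairs,
        }


def community_score_test(
    matrix: BinaryCommunityMatrix,
    subset,
    ensemble: NullEnsemble,
    score_type: str = "c_std",
    subset_label: str = "All",
) -> CommunityTestResult:
    """Mean standardized score over all pairs within an OTU subset.

    ``subset`` is an iterable of OTU column indices (all OTUs with positive
    occurrence are eligible; no pair screening is applied here). P is
    one-sided (greater); SES = (observed - null mean) / null sd.
    """
    if score_type not in SCORE_TYPES:
        raise ValueError(f"score_type must be one of {SCORE_TYPES}")
    occ = matrix.occurrence
    idx = np.asarray(sorted(int(i) for i in subset), dtype=np.int64)
    idx = idx[occ[idx] > 0]
    if len(idx) < 2:
        raise ValueError("community test needs at least 2 OTUs with occurrences")
    pair_arr = np.asarray(
        [(int(i), int(j)) for k, i in enumerate(idx) for j in idx[k + 1 :]], dtype=np.int64
    )
    r_i, r_j, s_obs = _observed_pair_stats(matrix, pair_arr)
    c_obs, t_obs = standardized_from_s(r_i, r_j, s_obs, matrix.n_samples)
    obs = float(np.mean(c_obs if score_type == "c_std" else t_obs))

    s_null, ri_null, rj_null = ensemble.pair_stats(pair_arr)
    c_null, t_null = standardized_from_s(ri_null, rj_null, s_null, matrix.n_samples)
    null_mean = np.mean(c_null if score_type == "c_std" else t_null, axis=1)

    b = int(np.sum(null_mean >= obs - 1e-12))
    p = (1.0 + b) / (1.0 + ensemble.m)
    sd = float(np.std(null_mean, ddof=1))
    ses = float((obs - float(np.mean(null_mean))) / sd) if sd > 0 else np.inf
    return CommunityTestResult(
        subset=subset_label,
        score_type=score_type,
        mean_score=obs,
        p=float(p),
        ses=ses,
        m_used=ensemble.m,
        n_pairs=len(pair_arr),
    )
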