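"""Diversity and spatial statistics supporting the co-occurrence analysis.

Contents: sample-based rarefaction (Mao Tau, analytic mean and SD),
Raup-Crick beta-diversity under an occupancy-weighted richness-preserving
null, Mantel correlogram, Moran's I with inverse-distance weights,
PERMANOVA (pseudo-F, R-squared), PERMDISP (distances to group centroids in
corrected principal-coordinate space), CLAM generalist/specialist
classification, and the Welch t-test on per-sample richness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as _skbio_permanova

from .community import BinaryCommunityMatrix

__all__ = [
    "mao_tau",
    "raup_crick",
    "mantel_correlogram",
    "morans_i",
    "permanova",
    "permdisp",
    "clam_test",
    "richness_welch_t",
    "SpatialAutocorResult",
    "GroupComparisonResult",
]


@dataclass
class SpatialAutocorResult:
    """Moran's I with its analytic null moments."""

    statistic: float
    expectation: float
    sd: float
    p: float


@dataclass
class GroupComparisonResult:
    """Container for two-group comparison outcomes."""

    method: str
    statistics: dict = field(default_factory=dict)
    p: float | None = None
    table: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# rarefaction


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return np.where(k > n, -np.inf, out)


def mao_tau(matrix: BinaryCommunityMatrix) -> pd.DataFrame:
    """Exact sample-based rarefaction curve with analytic SD.

    E[S_k] = sum_s [1 - C(N - n_s, k) / C(N, k)] where n_s is the number of
    samples occupied by species s. The variance uses the exact
    joint-absence probabilities C(N - u_st, k)/C(N, k) with u_st the number
    of samples occupied by s or t.
    """
    n = matrix.n_samples
    occ = matrix.occurrence
    occ = occ[occ > 0]
    s_total = len(occ)
    ks = np.arange(1, n + 1)
    presence = matrix.presence[:, matrix.occurrence > 0].astype(np.int64)
    both = presence.T @ presence  # co-occurrence counts m_st
    union = occ[:, None] + occ[None, :] - both  # u_st

    log_cnk = _log_comb(n, ks)  # (N,)
    # P(species s absent from a k-subset)
    with np.errstate(divide="ignore"):
        p_abs = np.exp(_log_comb((n - occ)[:, None], ks[None, :]) - log_cnk[None, :])
    expected = np.sum(1.0 - p_abs, axis=0)

    sd = np.empty(n)
    iu = np.triu_indices(s_total, k=1)
    union_pairs = union[iu]
    for idx, k in enumerate(ks):
        pa = p_abs[:, idx]
        var = np.sum(pa * (1.0 - pa))
        with np.errstate(divide="ignore"):
            p_joint = np.exp(_log_comb(n - union_pairs, k) - log_cnk[idx])
        var += 2.0 * np.sum(p_joint - pa[iu[0]] * pa[iu[1]])
        sd[idx] = np.sqrt(max(var, 0.0))
    return pd.DataFrame({"k": ks, "expected_richness": expected, "sd": sd})


# ---------------------------------------------------------------------------
# Raup-Crick


def _weighted_subsets(rng, weights, k, reps, n_species):
    """reps index sets of size k, weighted sampling without replacement.

    Efraimidis-Spirakis keys: take the k largest of u^(1/w).
    """
    keys = rng.random((reps, n_species)) ** (1.0 / weights)
    top = np.argpartition(keys, n_species - k, axis=1)[:, n_species - k :]
    member = np.zeros((reps, n_species), dtype=bool)
    rows = np.repeat(np.arange(reps), k)
    member[rows, top.ravel()] = True
    return member


def raup_crick(
    matrix: BinaryCommunityMatrix, reps: int = 999, seed: int = 0
) -> DistanceMatrix:
    """Raup-Crick dissimilarity on the probability scale [0, 1].

    For each sample pair, null communities preserve each sample's richness
    and draw species with probability proportional to their occupancy in
    the pool. D = [#(S_null > S_obs) + 0.5 #(S_null = S_obs)] / reps, so
    0.5 is the chance expectation, values near 0 indicate more sharing than
    expected (similarity) and values near 1 less sharing (dissimilarity).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    occ = matrix.occurrence
    pool = occ > 0
    presence = matrix.presence[:, pool].astype(bool)
    weights = occ[pool].astype(float)
    n = matrix.n_samples
    n_species = presence.shape[1]
    richness = presence.sum(axis=1)
    rng = np.random.default_rng(seed)

    # the null distribution of shared richness depends only on (k1, k2);
    # the two null communities of a pair must be independent draws
    member_cache: dict[tuple[int, int], np.ndarray] = {}

    def members(k, side):
        if (k, side) not in member_cache:
            member_cache[(k, side)] = _weighted_subsets(rng, weights, k, reps, n_species)
        return member_cache[(k, side)]

    shared_cache: dict[tuple[int, int], np.ndarray] = {}

    def null_shared(k1, k2):
        key = (min(k1, k2), max(k1, k2))
        if key not in shared_cache:
            shared_cache[key] = np.sum(members(key[0], 0) & members(key[1], 1), axis=1)
        return shared_cache[key]

    d = np.zeros((n, n))
    warned = False
    for i in range(n):
        for j in range(i + 1, n):
            k1, k2 = int(richness[i]), int(richness[j])
            if k1 == 0 or k2 == 0:
                if not warned:
                    warnings.warn(
                        "sample with zero richness; Raup-Crick set to 0.5", stacklevel=2
                    )
                    warned = True
                d[i, j] = d[j, i] = 0.5
                continue
            s_obs = int(np.sum(presence[i] & presence[j]))
            s_null = null_shared(k1, k2)
            val = (np.sum(s_null > s_obs) + 0.5 * np.sum(s_null == s_obs)) / reps
            d[i, j] = d[j, i] = val
    return DistanceMatrix(d, ids=matrix.sample_ids)


# ---------------------------------------------------------------------------
# Mantel correlogram


def _condensed(mat):
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def mantel_correlogram(
    community: DistanceMatrix,
    coords,
    class_width: float = 2.0,
    permutations: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Mantel correlogram over geographic distance classes.

    Per class, the statistic is minus the Pearson correlation between the
    community distances and the class-membership indicator over sample
    pairs, so positive r means within-class pairs are more similar than
    average (positive spatial autocorrelation). P per class is one-sided
    (positive autocorrelation) by permutation of sample identities, with
    progressive Bonferroni correction across classes.
    """
    coords = np.asarray(coords, dtype=float)
    dmat = np.asarray(community.data)
    n = dmat.shape[0]
    if coords.shape[0] != n:
        raise ValueError("coordinates must match the distance matrix")
    geo = squareform(pdist(coords))
    geo_cond = _condensed(geo)
    comm_cond = _condensed(dmat)
    max_d = geo_cond.max()
    edges = np.arange(0.0, max_d + class_width, class_width)
    rng = np.random.default_rng(seed)

    # class membership indicators over sample pairs (condensed form)
    classes = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_class = (geo >= lo) & (geo < hi)
        np.fill_diagonal(in_class, False)
        member_cond = _condensed(in_class).astype(float)
        n_pairs = int(member_cond.sum())
        if n_pairs < 2 or n_pairs == len(member_cond):
            continue
        classes.append((lo, hi, n_pairs, member_cond))
    if not classes:
        return pd.DataFrame(
            columns=["class_lo", "class_hi", "midpoint", "n_pairs", "r", "p", "p_corrected"]
        )

    members = np.stack([c[3] for c in classes])  # (n_classes, n_pairs)
    mem_centered = members - members.mean(axis=1, keepdims=True)
    mem_norm = np.sqrt((mem_centered**2).sum(axis=1))

    def all_class_r(cond):
        c = cond - cond.mean()
        denom = mem_norm * np.sqrt((c**2).sum())
        return -(mem_centered @ c) / denom

    r_obs = all_class_r(comm_cond)
    counts = np.ones(len(classes))
    for _ in range(permutations):
        perm = rng.permutation(n)
        r_perm = all_class_r(_condensed(dmat[np.ix_(perm, perm)]))
        counts += r_perm >= r_obs - 1e-12
    p_vals = counts / (permutations + 1)

    rows = []
    for k, ((lo, hi, n_pairs, _), r, p) in enumerate(zip(classes, r_obs, p_vals), start=1):
        rows.append(
            {
                "class_lo": lo,
                "class_hi": hi,
                "midpoint": 0.5 * (lo + hi),
                "n_pairs": n_pairs,
                "r": r,
                "p": p,
                "p_corrected": min(1.0, p * k),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["class_lo", "class_hi", "midpoint", "n_pairs", "r", "p", "p_corrected"],
    )


# ---------------------------------------------------------------------------
# Moran's I


def morans_i(values, coords, alternative: str = "two-sided") -> SpatialAutocorResult:
    """Moran's I with inverse-distance weights (not row-standardized).

    Expectation is -1/(n-1); the SD uses the normality-assumption variance
    and P is a normal-approximation test.
    """
    x = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 samples")
    if np.allclose(x, x[0]):
        raise ValueError("zero variance: values are constant")
    d = squareform(pdist(coords))
    off = ~np.eye(n, dtype=bool)
    if np.any(d[off] == 0):
        raise ValueError(
            "coincident sampling points (distance 0); jitter coordinates or "
            "exclude duplicated locations"
        )
    w = np.zeros_like(d)
    w[off] = 1.0 / d[off]
    w_sum = w.sum()
    z = x - x.mean()
    i_obs = (n / w_sum) * (z @ w @ z) / np.sum(z**2)
    expectation = -1.0 / (n - 1)
    s1 = 0.5 * np.sum((w + w.T) ** 2)
    s2 = np.sum((w.sum(axis=1) + w.sum(axis=0)) ** 2)
    var = (n**2 * s1 - n * s2 + 3 * w_sum**2) / (w_sum**2 * (n**2 - 1)) - expectation**2
    sd = np.sqrt(var)
    zstat = (i_obs - expectation) / sd
    if alternative == "two-sided":
        p = 2 * stats.norm.sf(abs(zstat))
    elif alternative == "greater":
        p = stats.norm.sf(zstat)
    elif alternative == "less":
        p = stats.norm.cdf(zstat)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return SpatialAutocorResult(
        statistic=float(i_obs), expectation=float(expectation), sd=float(sd), p=float(p)
    )


# ---------------------------------------------------------------------------
# PERMANOVA / PERMDISP


def _ss_from_distances(dmat, labels) -> tuple[float, float]:
    """Total and within-group sums of squares of a distance matrix."""
    n = dmat.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = np.sum(dmat[iu] ** 2) / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        sub = dmat[np.ix_(idx, idx)]
        iu_g = np.triu_indices(len(idx), k=1)
        ss_within += np.sum(sub[iu_g] ** 2) / len(idx)
    return ss_total, ss_within


def permanova(
    dist: DistanceMatrix, groups, permutations: int = 9999, seed: int = 0
) -> GroupComparisonResult:
    """PERMANOVA pseudo-F, R-squared and permutation P.

    The F statistic and P come from scikit-bio; R-squared is the
    between-group fraction of the distance-based sum of squares. With
    semimetric dissimilarities the partition can be marginally negative;
    it is truncated at 0.
    """
    labels = np.asarray(groups)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 groups with >= 2 samples each")
    np.random.seed(seed % (2**32))  # scikit-bio's permutations use global state
    res = _skbio_permanova(dist, labels, permutations=permutations)
    dmat = np.asarray(dist.data)
    ss_total, ss_within = _ss_from_distances(dmat, labels)
    r2 = max(0.0, (ss_total - ss_within) / ss_total) if ss_total > 0 else 0.0
    return GroupComparisonResult(
        method="permanova",
        statistics={"f": float(res["test statistic"]), "r2": float(r2)},
        p=float(res["p-value"]),
    )


def _centroid_distances(dmat, labels) -> np.ndarray:
    """Per-sample distance to its group centroid in corrected PCoA space.

    Negative eigenvalues contribute imaginary axes whose squared distances
    are subtracted (Anderson's correction); negative corrected squares are
    truncated at zero.
    """
    n = dmat.shape[0]
    a = -0.5 * dmat**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    eigval, eigvec = np.linalg.eigh((g + g.T) / 2)
    tol = 1e-10 * max(abs(eigval).max(), 1.0)
    pos = eigval > tol
    neg = eigval < -tol
    coords_pos = eigvec[:, pos] * np.sqrt(eigval[pos])
    coords_neg = eigvec[:, neg] * np.sqrt(-eigval[neg])
    z2 = np.empty(n)
    for g_label in np.unique(labels):
        idx = np.flatnonzero(labels == g_label)
        cen_pos = coords_pos[idx].mean(axis=0)
        cen_neg = coords_neg[idx].mean(axis=0)
        d2_pos = np.sum((coords_pos[idx] - cen_pos) ** 2, axis=1)
        d2_neg = np.sum((coords_neg[idx] - cen_neg) ** 2, axis=1)
        z2[idx] = d2_pos - d2_neg
    return np.sqrt(np.maximum(z2, 0.0))


def _anova_f(values, labels) -> float:
    grand = values.mean()
    ss_between = 0.0
    ss_within = 0.0
    k = 0
    for g in np.unique(labels):
        sub = values[labels == g]
        ss_between += len(sub) * (sub.mean() - grand) ** 2
        ss_within += np.sum((sub - sub.mean()) ** 2)
        k += 1
    n = len(values)
    if ss_within == 0:
        return 0.0 if ss_between == 0 else np.inf
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def permdisp(
    dist: DistanceMatrix, groups, permutations: int = 9999, seed: int = 0
) -> GroupComparisonResult:
    """Homogeneity of multivariate dispersions (distances to centroids).

    F is the one-way ANOVA statistic on the per-sample distances to group
    centroids; P permutes those distances among samples. Per-group mean
    distances are reported alongside.
    """
    labels = np.asarray(groups)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 groups with >= 2 samples each")
    dmat = np.asarray(dist.data)
    z = _centroid_distances(dmat, labels)
    f_obs = _anova_f(z, labels)
    rng = np.random.default_rng(seed)
    count = 1
    for _ in range(permutations):
        if _anova_f(rng.permutation(z), labels) >= f_obs - 1e-12:
            count += 1
    p = count / (permutations + 1)
    means = {str(g): float(z[labels == g].mean()) for g in uniq}
    table = pd.DataFrame(
        {"group": list(means), "mean_centroid_distance": list(means.values())}
    )
    return GroupComparisonResult(
        method="permdisp",
        statistics={"f": float(f_obs), "group_means": means},
        p=float(p),
        table=table,
    )


# ---------------------------------------------------------------------------
# CLAM


def _clam_q(pi: float, n1: float, n2: float) -> float:
    """Expected habitat-1 count fraction given true share pi and unequal
    sampling effort (n1, n2)."""
    return pi * n1 / (pi * n1 + (1.0 - pi) * n2)


def clam_test(
    counts_by_group: pd.DataFrame,
    group_sizes: tuple[float, float] | None = None,
    alpha: float = 0.001,
    specialization: float = 2.0 / 3.0,
    coverage_limit: int = 10,
) -> GroupComparisonResult:
    """Multinomial (CLAM) classification of taxa by habitat preference.

    ``counts_by_group`` has one row per OTU and two columns of occurrence
    counts (habitats A and B). ``group_sizes`` are the sampling efforts
    (numbers of samples per habitat; defaults to the column totals). Each
    OTU is classified with one-sided exact binomial tests at the
    supermajority threshold K (default 2/3, i.e. specialist if its true
    share in one habitat exceeds 2/3 after effort correction):

    * specialist of A if P(Y_A >= y_A | pi = K) <= alpha,
    * specialist of B symmetrically,
    * generalist if both one-third bounds are rejected,
    * too rare otherwise, or when counts are below ``coverage_limit`` in
      both habitats.
    """
    if counts_by_group.shape[1] != 2:
        raise ValueError("counts_by_group must have exactly two columns")
    col_a, col_b = counts_by_group.columns
    y_a = counts_by_group[col_a].to_numpy(dtype=np.int64)
    y_b = counts_by_group[col_b].to_numpy(dtype=np.int64)
    if (y_a < 0).any() or (y_b < 0).any():
        raise ValueError("counts must be non-negative")
    if group_sizes is None:
        group_sizes = (float(y_a.sum()), float(y_b.sum()))
    n1, n2 = group_sizes
    k_spec = specialization
    classes = []
    for ya, yb in zip(y_a, y_b):
        total = int(ya + yb)
        if total == 0 or (ya < coverage_limit and yb < coverage_limit):
            classes.append("too_rare")
            continue
        q_hi = _clam_q(k_spec, n1, n2)
        q_lo = _clam_q(1.0 - k_spec, n1, n2)
        spec_a = stats.binom.sf(ya - 1, total, q_hi) <= alpha
        spec_b = stats.binom.cdf(ya, total, q_lo) <= alpha
        gen = (
            stats.binom.cdf(ya, total, q_hi) <= alpha
            and stats.binom.sf(ya - 1, total, q_lo) <= alpha
        )
        if spec_a:
            classes.append(f"specialist_{col_a}")
        elif spec_b:
            classes.append(f"specialist_{col_b}")
        elif gen:
            classes.append("generalist")
        else:
            classes.append("too_rare")
    table = counts_by_group.copy()
    table["classification"] = classes
    return GroupComparisonResult(method="clam", statistics={}, p=None, table=table)


# ---------------------------------------------------------------------------
# richness t-test


def richness_welch_t(matrix: BinaryCommunityMatrix, groups) -> GroupComparisonResult:
    """Welch two-sample t-test on per-sample OTU richness."""
    labels = np.asarray(groups)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("exactly two groups required")
    rich = matrix.richness.astype(float)
    a = rich[labels == uniq[0]]
    b = rich[labels == uniq[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 samples")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("zero variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=False)
    return GroupComparisonResult(
        method="welch_t",
        statistics={
            "t": float(res.statistic),
            "df": float(res.df),
            "mean_a": float(a.mean()),
            "mean_b": float(b.mean()),
            "group_a": str(uniq[0]),
            "group_b": str(uniq[1]),
        },
        p=float(res.pvalue),
    )
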