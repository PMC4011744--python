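"""Diversity/spatial layer: rarefaction, Raup-Crick, Mantel, Moran's I,
PERMANOVA/PERMDISP, CLAM and the richness t-test."""

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from otupairs.community import BinaryCommunityMatrix
from otupairs.diversity import (
    clam_test,
    mantel_correlogram,
    mao_tau,
    morans_i,
    permanova,
    permdisp,
    raup_crick,
    richness_welch_t,
)

# vegan::specaccum(method="exact") expected richness on the tiny_binary
# fixture (means agree with the exact hypergeometric formula to 6 dp)
VEGAN_EXACT_RICHNESS = [
    3.000000, 4.800000, 5.908333, 6.614286, 7.079365,
    7.395238, 7.616667, 7.777778, 7.900000, 8.000000,
]


class TestMaoTau:
    def test_limits(self, tiny_binary):
        df = mao_tau(tiny_binary)
        assert df["expected_richness"].iloc[-1] == pytest.approx(tiny_binary.n_otus)
        assert df["expected_richness"].iloc[0] == pytest.approx(
            tiny_binary.richness.mean()
        )
        assert (np.diff(df["expected_richness"]) >= -1e-12).all()
        assert df["sd"].iloc[-1] == pytest.approx(0.0, abs=1e-9)

    def test_matches_external_reference_means(self, tiny_binary):
        df = mao_tau(tiny_binary)
        assert np.allclose(df["expected_richness"], VEGAN_EXACT_RICHNESS, atol=5e-7)

    def test_matches_resampling_oracle(self, tiny_binary):
        rng = np.random.default_rng(0)
        mat = tiny_binary.presence
        n = tiny_binary.n_samples
        df = mao_tau(tiny_binary)
        for k in (3, 5, 7):
            vals = np.array(
                [
                    (mat[rng.choice(n, size=k, replace=False)].sum(0) > 0).sum()
                    for _ in range(8000)
                ]
            )
            mc_se = vals.std() / np.sqrt(len(vals))
            assert df["expected_richness"].iloc[k - 1] == pytest.approx(
                vals.mean(), abs=4 * mc_se
            )
            assert df["sd"].iloc[k - 1] == pytest.approx(vals.std(), rel=0.05)


class TestRaupCrick:
    def _pool_matrix(self):
        # 12 samples over 10 species with a clear occupancy gradient
        rng = np.random.default_rng(3)
        p = np.linspace(0.15, 0.9, 10)
        mat = (rng.random((12, 10)) < p).astype(np.uint8)
        mat[0] = mat[1] = [1, 1, 0, 0, 0, 0, 0, 0, 0, 0]  # share only rare species
        mat[2] = [0, 0, 0, 0, 0, 0, 1, 1, 1, 1]
        mat[3] = [0, 0, 1, 1, 1, 1, 0, 0, 0, 0]  # disjoint from sample 2
        return BinaryCommunityMatrix(
            mat, [f"s{i}" for i in range(12)], [f"o{j}" for j in range(10)]
        )

    def test_sharing_rare_species_is_similar(self):
        m = self._pool_matrix()
        dm = raup_crick(m, reps=999, seed=1)
        assert dm["s0", "s1"] < 0.1

    def test_disjoint_common_species_is_dissimilar(self):
        m = self._pool_matrix()
        dm = raup_crick(m, reps=999, seed=1)
        assert dm["s2", "s3"] > 0.8

    def test_bounds_symmetry_and_chance_level(self):
        # samples assembled by the null process itself -> mean D ~ 0.5
        occupancy = np.array([8, 6, 5, 4, 3, 3, 2, 2, 1, 1], dtype=float)
        w = occupancy / occupancy.sum()
        means = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            mat = np.zeros((30, 10), dtype=np.uint8)
            for i in range(30):
                k = rng.integers(2, 6)
                mat[i, rng.choice(10, size=k, replace=False, p=w)] = 1
            m = BinaryCommunityMatrix(
                mat, [f"s{i}" for i in range(30)], [f"o{j}" for j in range(10)]
            )
            dm = raup_crick(m, reps=499, seed=seed + 100)
            vals = dm.condensed_form()
            assert ((vals >= 0) & (vals <= 1)).all()
            means.append(vals.mean())
        assert abs(np.mean(means) - 0.5) < 0.05

    def test_zero_richness_sample_gets_half_with_warning(self):
        mat = np.array([[1, 1], [0, 0], [1, 0]], dtype=np.uint8)
        m = BinaryCommunityMatrix(mat, ["a", "b", "c"], ["o1", "o2"])
        with pytest.warns(UserWarning, match="zero richness"):
            dm = raup_crick(m, reps=99, seed=0)
        assert dm["a", "b"] == 0.5


class TestMantelCorrelogram:
    def _clustered(self, seed=0, shuffle=False):
        # two spatial clusters with distinct compositions
        rng = np.random.default_rng(seed)
        n_per = 15
        coords = np.vstack(
            [rng.normal(0, 1.0, (n_per, 2)), rng.normal((20, 0), 1.0, (n_per, 2))]
        )
        comp = np.zeros((2 * n_per, 2 * n_per))
        labels = np.repeat([0, 1], n_per)
        if shuffle:
            labels = rng.permutation(labels)
        for i in range(2 * n_per):
            for j in range(2 * n_per):
                if i != j:
                    comp[i, j] = 0.2 if labels[i] == labels[j] else 0.9
        ids = [f"s{i}" for i in range(2 * n_per)]
        return DistanceMatrix(comp, ids=ids), coords

    def test_planted_structure_first_class_positive_and_significant(self):
        dm, coords = self._clustered()
        out = mantel_correlogram(dm, coords, class_width=2.0, permutations=499, seed=1)
        first = out.iloc[0]
        assert first["r"] > 0
        assert first["p_corrected"] < 0.05

    def test_seed_reproducible(self):
        dm, coords = self._clustered(seed=4)
        a = mantel_correlogram(dm, coords, permutations=199, seed=9)
        b = mantel_correlogram(dm, coords, permutations=199, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_no_structure_rarely_significant(self):
        hits = 0
        for seed in range(10):
            dm, coords = self._clustered(seed=seed, shuffle=True)
            out = mantel_correlogram(dm, coords, permutations=199, seed=seed)
            if (out["p_corrected"] < 0.05).any():
                hits += 1
        assert hits <= 2


class TestMoransI:
    def test_expectation_exact(self):
        rng = np.random.default_rng(0)
        for n in (5, 20, 50):
            res = morans_i(rng.random(n), rng.random((n, 2)) * 100)
            assert res.expectation == pytest.approx(-1.0 / (n - 1))

    def test_planted_clusters_positive(self):
        rng = np.random.default_rng(1)
        coords = np.vstack(
            [rng.normal(0, 1, (25, 2)), rng.normal((30, 30), 1, (25, 2))]
        )
        values = np.concatenate([rng.normal(0, 1, 25), rng.normal(5, 1, 25)])
        res = morans_i(values, coords)
        assert res.statistic > 0
        assert res.p < 0.01

    def test_null_rejection_rate_near_nominal(self):
        rng = np.random.default_rng(2)
        coords = rng.random((40, 2)) * 100
        rej = 0
        reps = 400
        for _ in range(reps):
            res = morans_i(rng.permutation(np.arange(40.0)), coords)
            rej += res.p < 0.05
        assert 0.02 < rej / reps < 0.09

    def test_error_conditions(self):
        with pytest.raises(ValueError, match="constant"):
            morans_i([1.0, 1.0, 1.0], [(0, 0), (1, 0), (0, 1)])
        with pytest.raises(ValueError, match="coincident"):
            morans_i([1.0, 2.0, 3.0], [(0, 0), (0, 0), (0, 1)])


def _two_cluster_dm(sep, n_per=20, seed=0):
    rng = np.random.default_rng(seed)
    pts = np.vstack(
        [rng.normal(0, 1, (n_per, 3)), rng.normal((sep, 0, 0), 1, (n_per, 3))]
    )
    from scipy.spatial.distance import pdist, squareform

    ids = [f"s{i}" for i in range(2 * n_per)]
    return DistanceMatrix(squareform(pdist(pts)), ids=ids), np.repeat(["a", "b"], n_per)


class TestPermanova:
    def test_r2_bounds_and_separated_clusters(self):
        dm, groups = _two_cluster_dm(sep=20.0)
        res = permanova(dm, groups, permutations=199, seed=1)
        assert 0.0 <= res.statistics["r2"] <= 1.0
        assert res.statistics["r2"] > 0.5
        assert res.p == pytest.approx(1.0 / 200)

    def test_null_p_roughly_uniform(self):
        ps = []
        for seed in range(30):
            dm, groups = _two_cluster_dm(sep=0.0, n_per=12, seed=seed)
            ps.append(permanova(dm, groups, permutations=99, seed=seed).p)
        assert 0.0 <= np.mean(np.array(ps) < 0.05) <= 0.15

    def test_single_sample_group_rejected(self):
        dm = DistanceMatrix(np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float),
                            ids=["a", "b", "c"])
        with pytest.raises(ValueError):
            permanova(dm, ["g1", "g2", "g2"], permutations=9, seed=0)


class TestPermdisp:
    def test_identical_groups_f_zero(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(0, 1, (15, 3))
        both = np.vstack([pts, pts])
        from scipy.spatial.distance import pdist, squareform

        dm = DistanceMatrix(squareform(pdist(both)), ids=[f"s{i}" for i in range(30)])
        res = permdisp(dm, np.repeat(["a", "b"], 15), permutations=99, seed=0)
        assert res.statistics["f"] == pytest.approx(0.0, abs=1e-10)
        assert res.p > 0.5

    def test_inflated_dispersion_detected_and_means_consistent(self):
        rng = np.random.default_rng(1)
        pts = np.vstack(
            [rng.normal(0, 1, (50, 3)), rng.normal(0, 3, (50, 3))]
        )
        from scipy.spatial.distance import pdist, squareform

        dm = DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(100)])
        groups = np.repeat(["tight", "wide"], 50)
        res = permdisp(dm, groups, permutations=199, seed=2)
        assert res.p < 0.01
        means = res.statistics["group_means"]
        assert means["wide"] > means["tight"]
        # reported means equal means of the recomputed per-sample distances
        from otupairs.diversity import _centroid_distances

        z = _centroid_distances(np.asarray(dm.data), groups)
        assert means["tight"] == pytest.approx(z[:50].mean())
        assert means["wide"] == pytest.approx(z[50:].mean())

    def test_f_statistic_agrees_with_skbio(self):
        from skbio.stats.distance import permdisp as skbio_permdisp

        dm, groups = _two_cluster_dm(sep=3.0, n_per=15, seed=5)
        ours = permdisp(dm, groups, permutations=49, seed=0)
        theirs = skbio_permdisp(dm, groups, permutations=49, test="centroid")
        assert ours.statistics["f"] == pytest.approx(
            float(theirs["test statistic"]), rel=1e-6
        )


class TestClam:
    def test_reference_classifications(self):
        counts = pd.DataFrame(
            {"h1": [25, 100, 1, 0], "h2": [0, 100, 0, 30]},
            index=["spec1", "gen", "rare", "spec2"],
        )
        res = clam_test(counts, group_sizes=(100, 100))
        got = dict(zip(counts.index, res.table["classification"]))
        assert got == {
            "spec1": "specialist_h1",
            "gen": "generalist",
            "rare": "too_rare",
            "spec2": "specialist_h2",
        }

    def test_unequal_effort_correction(self):
        # 25 vs 0 with unequal host sample sizes (249 vs 188) still a specialist
        counts = pd.DataFrame({"h1": [25], "h2": [0]})
        res = clam_test(counts, group_sizes=(249, 188))
        assert res.table["classification"].iloc[0] == "specialist_h1"

    def test_balanced_moderate_counts_fail_supermajority_at_strict_alpha(self):
        # 30/28 occurrences cannot reject either one-third bound at alpha=0.001
        counts = pd.DataFrame({"h1": [30], "h2": [28]})
        res = clam_test(counts, group_sizes=(100, 100))
        assert res.table["classification"].iloc[0] == "too_rare"


class TestWelch:
    def test_identical_groups_t_zero(self):
        # both groups contain one sample each of richness 1, 2 and 3
        presence = np.zeros((6, 3), dtype=np.uint8)
        for i, r in enumerate([1, 2, 3, 1, 2, 3]):
            presence[i, :r] = 1
        m = BinaryCommunityMatrix(presence, [f"s{i}" for i in range(6)], ["a", "b", "c"])
        res = richness_welch_t(m, ["g1"] * 3 + ["g2"] * 3)
        assert res.statistics["t"] == pytest.approx(0.0)

    def test_hand_computed_example(self):
        # richness groups (1,2,3) vs (4,5,6): t = -3.674..., df = 4
        presence = np.zeros((6, 6), dtype=np.uint8)
        for i, r in enumerate([1, 2, 3, 4, 5, 6]):
            presence[i, :r] = 1
        m = BinaryCommunityMatrix(presence, [f"s{i}" for i in range(6)],
                                  [f"o{j}" for j in range(6)])
        res = richness_welch_t(m, ["a", "a", "a", "b", "b", "b"])
        assert res.statistics["t"] == pytest.approx(-3.67423, abs=1e-4)
        assert res.statistics["df"] == pytest.approx(4.0)

    def test_zero_variance_rejected(self):
        mat = np.ones((4, 2), dtype=np.uint8)
        m = BinaryCommunityMatrix(mat, list("abcd"), ["o1", "o2"])
        with pytest.raises(ValueError, match="variance"):
            richness_welch_t(m, ["g1", "g1", "g2", "g2"])
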