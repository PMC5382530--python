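"""PCoA, PERMANOVA, dispersion homogeneity and Procrustes."""

import numpy as np
import pandas as pd
import pytest
import skbio.stats.distance as skd
import skbio.stats.ordination
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from microsucc.ordination import (
    dispersion_test,
    pairwise_permanova,
    pcoa,
    permanova,
    procrustes_test,
)
from .conftest import brute_force_permanova_exhaustive


def _dm_from_points(pts, ids=None):
    ids = ids or [f"s{i}" for i in range(len(pts))]
    return DistanceMatrix(squareform(pdist(pts)), ids=ids)


def _two_clouds(rng, n_per=3, sep=8.0, sd=1.0):
    pts = np.vstack([
        rng.normal(0, sd, (n_per, 2)),
        rng.normal(sep, sd, (n_per, 2)),
    ])
    return _dm_from_points(pts), ["x"] * n_per + ["y"] * n_per


class TestPCoA:
    def test_recovers_euclidean_configuration(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(12, 2))
        res = pcoa(_dm_from_points(pts))
        fit = procrustes_test(res.coordinates.to_numpy()[:, :2], pts, n_perm=9, seed=0)
        assert fit.m2 < 1e-10

    def test_all_zero_distances(self):
        dm = DistanceMatrix(np.zeros((4, 4)), ids=list("abcd"))
        res = pcoa(dm)
        assert np.allclose(res.coordinates.to_numpy(), 0.0)

    def test_equilateral_triangle_has_equal_eigenvalues(self):
        dm = DistanceMatrix(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float),
                            ids=list("abc"))
        res = pcoa(dm)
        pos = res.eigenvalues[res.eigenvalues > 1e-12]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1], abs=1e-12)

    def test_matches_skbio_on_random_distances(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(9, 4))
        dm = _dm_from_points(pts)
        ours = pcoa(dm)
        theirs = skbio.stats.ordination.pcoa(dm)
        np.testing.assert_allclose(
            np.sort(ours.eigenvalues[ours.eigenvalues > 1e-9]),
            np.sort(theirs.eigvals[theirs.eigvals > 1e-9].to_numpy()),
            atol=1e-8,
        )

    def test_proportions_over_positive_eigenvalues(self):
        # non-Euclidean dissimilarity: proportions still sum to 1 over pos axes
        data = np.array(
            [[0, 1, 4, 1], [1, 0, 1, 4], [4, 1, 0, 1], [1, 4, 1, 0]], float
        )
        res = pcoa(DistanceMatrix(data, ids=list("abcd")))
        assert (res.eigenvalues < -1e-9).any()  # negative axes reported
        assert res.proportion_explained.sum() == pytest.approx(1.0)


class TestPermanova:
    def test_exhaustive_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        dm, labels = _two_clouds(rng)
        res = permanova(dm, labels, exhaustive=True)
        f_oracle, p_oracle = brute_force_permanova_exhaustive(dm, labels)
        assert res.pseudo_F == pytest.approx(f_oracle, abs=1e-10)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)
        assert res.n_permutations == 20  # C(6,3) distinct assignments

    def test_pseudo_f_matches_skbio(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(10, 3))
        dm = _dm_from_points(pts)
        labels = ["a"] * 5 + ["b"] * 5
        ours = permanova(dm, labels, n_perm=9, seed=0)
        theirs = skd.permanova(
            dm, pd.Series(labels, index=dm.ids, name="g"), permutations=9
        )
        assert ours.pseudo_F == pytest.approx(float(theirs["test statistic"]), abs=1e-9)

    def test_separated_clouds_hit_p_floor(self):
        # groups of 8: the chance a random permutation reproduces the
        # separating split is ~2/12870, so p sits at the add-one floor
        rng = np.random.default_rng(1)
        dm, labels = _two_clouds(rng, n_per=8, sep=20.0)
        res = permanova(dm, labels, n_perm=199, seed=0)
        assert res.p_value == pytest.approx(1 / 200)
        assert res.R2 > 0.9

    def test_null_pvalues_roughly_uniform(self):
        """Random labels on one cloud: p should be uniform on its support."""
        rng = np.random.default_rng(2)
        ps = []
        for _ in range(300):
            pts = rng.normal(size=(10, 2))
            dm = _dm_from_points(pts)
            labels = list(rng.permutation(["a"] * 5 + ["b"] * 5))
            ps.append(permanova(dm, labels, n_perm=49, seed=int(rng.integers(2**31))).p_value)
        ps = np.array(ps)
        assert abs(ps.mean() - 0.5) < 0.06
        assert np.mean(ps <= 0.05) < 0.10

    def test_invariant_to_consistent_relabeling(self):
        rng = np.random.default_rng(4)
        dm, labels = _two_clouds(rng)
        perm = rng.permutation(len(labels))
        ids = list(dm.ids)
        dm2 = DistanceMatrix(dm.data[np.ix_(perm, perm)], ids=[ids[i] for i in perm])
        labels2 = [labels[i] for i in perm]
        assert permanova(dm2, labels2, n_perm=9, seed=0).pseudo_F == pytest.approx(
            permanova(dm, labels, n_perm=9, seed=0).pseudo_F
        )

    def test_single_group_rejected(self):
        rng = np.random.default_rng(0)
        dm, _ = _two_clouds(rng)
        with pytest.raises(ValueError):
            permanova(dm, ["g"] * 6, n_perm=9)

    def test_p_has_add_one_floor(self):
        rng = np.random.default_rng(9)
        dm, labels = _two_clouds(rng, sep=50.0)
        for n_perm in (9, 99):
            assert permanova(dm, labels, n_perm=n_perm, seed=1).p_value >= 1 / (n_perm + 1)


class TestPairwisePermanova:
    def _three_groups(self, rng):
        pts = np.vstack([rng.normal(c, 1.0, (4, 2)) for c in (0.0, 6.0, 12.0)])
        dm = _dm_from_points(pts)
        return dm, ["a"] * 4 + ["b"] * 4 + ["c"] * 4

    def test_three_groups_three_tests(self):
        rng = np.random.default_rng(0)
        dm, labels = self._three_groups(rng)
        out = pairwise_permanova(dm, labels, n_perm=49, seed=0)
        assert len(out) == 3

    def test_no_correction_reproduces_raw(self):
        rng = np.random.default_rng(1)
        dm, labels = self._three_groups(rng)
        out = pairwise_permanova(dm, labels, n_perm=49, correction="none", seed=3)
        assert (out["p_adjusted"] == out["p_value"]).all()

    def test_bh_never_decreases_p(self):
        rng = np.random.default_rng(2)
        dm, labels = self._three_groups(rng)
        out = pairwise_permanova(dm, labels, n_perm=49, seed=3)
        assert (out["p_adjusted"] >= out["p_value"] - 1e-12).all()


class TestDispersion:
    def test_matches_skbio_statistic(self):
        rng = np.random.default_rng(5)
        pts = np.vstack([rng.normal(0, 1, (5, 2)), rng.normal(0, 3, (5, 2))])
        dm = _dm_from_points(pts)
        labels = ["a"] * 5 + ["b"] * 5
        ours = dispersion_test(dm, labels, n_perm=19, seed=0)
        theirs = skd.permdisp(
            dm, pd.Series(labels, index=dm.ids, name="g"),
            test="centroid", permutations=19, dimensions=9,
        )
        assert ours.F == pytest.approx(float(theirs["test statistic"]), rel=1e-6)

    def test_inflated_cloud_detected(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            pts = np.vstack([rng.normal(0, 1, (8, 2)), rng.normal(0, 5, (8, 2))])
            dm = _dm_from_points(pts)
            res = dispersion_test(dm, ["a"] * 8 + ["b"] * 8, n_perm=99, seed=seed)
            hits += res.p_value <= 0.05
        assert hits >= 7

    def test_equal_spread_rarely_significant(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed + 100)
            pts = rng.normal(size=(12, 2))
            dm = _dm_from_points(pts)
            res = dispersion_test(dm, ["a"] * 6 + ["b"] * 6, n_perm=49, seed=seed)
            hits += res.p_value <= 0.05
        assert hits <= 4

    def test_degenerate_group_distance_zero(self):
        pts = np.array([[0, 0], [0, 0], [5, 5], [6, 5]], float)
        dm = _dm_from_points(pts)
        res = dispersion_test(dm, ["a", "a", "b", "b"], n_perm=9, seed=0)
        assert res.group_mean_distance["a"] == pytest.approx(0.0, abs=1e-9)

    def test_singleton_group_rejected(self):
        pts = np.random.default_rng(0).normal(size=(5, 2))
        with pytest.raises(ValueError):
            dispersion_test(_dm_from_points(pts), ["a", "a", "a", "a", "b"], n_perm=9)


class TestProcrustes:
    def test_self_alignment(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(8, 2))
        res = procrustes_test(pts, pts.copy(), n_perm=19, seed=0)
        assert res.m2 == pytest.approx(0.0, abs=1e-12)
        assert res.correlation == pytest.approx(1.0)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(8, 2))
        rot = np.array([[0.0, -1.0], [1.0, 0.0]])  # 90 degrees
        res = procrustes_test(pts, pts @ rot.T, n_perm=9, seed=0)
        assert res.m2 == pytest.approx(0.0, abs=1e-12)

    def test_null_p_centered(self):
        rng = np.random.default_rng(2)
        ps = [
            procrustes_test(
                rng.normal(size=(10, 2)), rng.normal(size=(10, 2)),
                n_perm=49, seed=int(rng.integers(2**31)),
            ).p_value
            for _ in range(60)
        ]
        assert 0.25 < np.mean(ps) < 0.75

    def test_mismatched_samples_rejected(self):
        a = pd.DataFrame(np.eye(3), index=["s1", "s2", "s3"])
        b = pd.DataFrame(np.eye(3), index=["s1", "s2", "s4"])
        with pytest.raises(ValueError):
            procrustes_test(a, b, n_perm=9)
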