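import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from micronet import bray_curtis, cca, env_pca, pcoa, permanova, procrustes_test
from micronet.io import ENV_VARS
from conftest import make_metadata, make_relative, make_table


class TestBrayCurtis:
    def test_identical_samples_distance_zero(self):
        d = bray_curtis(make_table([[3, 3], [7, 7]]))
        assert d["S1", "S2"] == pytest.approx(0.0)

    def test_disjoint_supports_distance_one(self):
        d = bray_curtis(make_table([[5, 0], [0, 9]]))
        assert d["S1", "S2"] == pytest.approx(1.0)

    def test_formula(self):
        # u=[2,4], v=[1,1]: 1 - 2*(1+1)/(6+2) = 0.5
        d = bray_curtis(make_table([[2, 1], [4, 1]]))
        assert d["S1", "S2"] == pytest.approx(0.5)

    def test_metric_properties(self, rng):
        t = make_table(rng.integers(0, 60, (25, 8)) + 1)
        d = bray_curtis(t).data
        assert np.allclose(np.diag(d), 0)
        assert np.allclose(d, d.T)
        assert (d >= 0).all() and (d <= 1).all()

    def test_single_sample_raises(self):
        with pytest.raises(ValueError):
            bray_curtis(make_table([[3], [7]]))


class TestPcoa:
    def test_collinear_points_single_axis(self):
        pts = np.array([[0.0], [1.0], [3.0]])
        d = DistanceMatrix(squareform(pdist(pts)), ids=["a", "b", "c"])
        res = pcoa(d)
        assert res.proportion_explained[0] == pytest.approx(1.0)

    def test_euclidean_reconstruction(self, rng):
        pts = rng.normal(size=(7, 2))
        d = DistanceMatrix(squareform(pdist(pts)),
                           ids=[f"s{i}" for i in range(7)])
        res = pcoa(d)
        coords = res.coordinates.to_numpy()[:, :2]
        np.testing.assert_allclose(
            squareform(pdist(coords)), d.data, atol=1e-8
        )

    def test_equilateral_tie(self):
        d = DistanceMatrix(1 - np.eye(3), ids=["a", "b", "c"])
        res = pcoa(d)
        assert res.proportion_explained[0] == pytest.approx(
            res.proportion_explained[1]
        )

    def test_all_zero_distances_degenerate(self):
        d = DistanceMatrix(np.zeros((3, 3)), ids=["a", "b", "c"])
        res = pcoa(d)
        assert res.degenerate

    def test_explained_nonincreasing(self, rng):
        t = make_table(rng.integers(0, 60, (30, 9)) + 1)
        res = pcoa(bray_curtis(t))
        assert (np.diff(res.proportion_explained) <= 1e-12).all()


class TestPermanova:
    def test_duplicated_groups_maximal_separation(self):
        d = DistanceMatrix(
            np.array([[0, 0, 1, 1], [0, 0, 1, 1],
                      [1, 1, 0, 0], [1, 1, 0, 0]], dtype=float),
            ids=list("abcd"),
        )
        res = permanova(d, ["g1", "g1", "g2", "g2"], n_perm=999, seed=0)
        assert res.r2 == pytest.approx(1.0)
        assert res.pseudo_f > 1e12 or np.isinf(res.pseudo_f)
        # only label permutations preserving the split tie the observed F
        assert res.p_value == pytest.approx(1 / 3, abs=0.06)

    def test_r2_is_between_over_total(self, rng):
        t = make_table(rng.integers(0, 50, (20, 12)) + 1)
        d = bray_curtis(t)
        groups = ["A"] * 6 + ["B"] * 6
        res = permanova(d, groups, n_perm=99, seed=1)
        assert 0 <= res.r2 <= 1
        # renaming labels changes nothing
        res2 = permanova(d, ["X" if g == "A" else "Y" for g in groups],
                        n_perm=99, seed=1)
        assert res2.r2 == pytest.approx(res.r2)
        assert res2.pseudo_f == pytest.approx(res.pseudo_f)

    def test_matches_reference_statistic(self, rng):
        """Pseudo-F from the distance partition agrees with scikit-bio."""
        from skbio.stats.distance import permanova as skbio_permanova
        t = make_table(rng.integers(0, 50, (15, 10)) + 1)
        d = bray_curtis(t)
        groups = ["A"] * 5 + ["B"] * 5
        ours = permanova(d, groups, n_perm=9, seed=0)
        ref = skbio_permanova(d, groups, permutations=9, seed=0)
        assert ours.pseudo_f == pytest.approx(float(ref["test statistic"]))

    def test_group_of_one_raises(self):
        d = DistanceMatrix(1 - np.eye(3), ids=["a", "b", "c"])
        with pytest.raises(ValueError, match="size one"):
            permanova(d, ["g1", "g1", "g2"])

    def test_single_group_raises(self):
        d = DistanceMatrix(1 - np.eye(4), ids=list("abcd"))
        with pytest.raises(ValueError, match="two groups"):
            permanova(d, ["g"] * 4)


class TestProcrustes:
    def test_identity_m2_zero(self, rng):
        x = rng.normal(size=(8, 2))
        res = procrustes_test(x, x.copy(), n_perm=99, seed=0)
        assert res.m2 == pytest.approx(0.0, abs=1e-12)

    def test_rotation_and_scale_invariance(self, rng):
        x = rng.normal(size=(9, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        y = 3.5 * x @ rot + 2.0
        res = procrustes_test(x, y, n_perm=99, seed=0)
        assert res.m2 == pytest.approx(0.0, abs=1e-10)

    def test_independent_noise_not_significant(self, rng):
        x = rng.normal(size=(12, 2))
        y = rng.normal(size=(12, 2))
        res = procrustes_test(x, y, n_perm=199, seed=5)
        assert res.m2 > 0.5
        assert res.p_value > 0.05

    def test_too_few_samples(self, rng):
        x = rng.normal(size=(2, 2))
        with pytest.raises(ValueError, match="three"):
            procrustes_test(x, x)


class TestCca:
    def test_planted_gradient_explained(self, rng):
        n = 20
        gradient = np.linspace(-1, 1, n)
        # rank-1 departure from independence, driven by the single gradient
        loadings = np.tile([1.0, -1.0], 5)
        resp = 1.0 + 0.5 * loadings[:, None] * gradient[None, :]
        rel = make_relative(resp / resp.sum(axis=0),
                            sample_ids=[f"S{j}" for j in range(n)])
        meta = make_metadata(rel.sample_ids, ["A"] * 10 + ["B"] * 10,
                             env={"pH": gradient + 8.0})
        res = cca(rel, meta, variables=["pH"])
        assert res.constrained_fraction > 0.9

    def test_noise_environment_explains_little(self, rng):
        n = 30
        counts = rng.integers(1, 60, (25, n))
        rel = make_relative(counts / counts.sum(axis=0),
                            sample_ids=[f"S{j}" for j in range(n)])
        meta = make_metadata(rel.sample_ids, ["A"] * 15 + ["B"] * 15, seed=9)
        res = cca(rel, meta, variables=["pH", "EC"])
        assert res.constrained_fraction < 0.35

    def test_constant_variable_errors(self):
        rel = make_relative(np.full((4, 6), 0.25))
        meta = make_metadata(rel.sample_ids, ["A"] * 3 + ["B"] * 3,
                             env={"pH": np.full(6, 7.0)})
        with pytest.raises(ValueError, match="varying"):
            cca(rel, meta, variables=["pH"])


class TestEnvPca:
    def test_axes_bounded_by_variables_and_samples(self):
        meta = make_metadata([f"S{i}" for i in range(5)],
                             ["A", "A", "B", "B", "B"])
        res = env_pca(meta)
        assert res.coordinates.shape == (5, min(len(ENV_VARS), 4))

    def test_constant_variables_dropped(self):
        meta = make_metadata([f"S{i}" for i in range(6)],
                             ["A"] * 3 + ["B"] * 3,
                             env={"pH": np.full(6, 7.0)})
        res = env_pca(meta)
        assert res.coordinates.shape[1] == min(len(ENV_VARS) - 1, 5)
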