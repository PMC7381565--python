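"""NMDS, envfit, Mantel and the distance-based variation partition.

The Mantel permutation scheme is checked against scikit-bio's independent
implementation, and the distance-matrix regressions against direct least
squares."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from divpart import (
    DistanceMatrix,
    PredictorTable,
    db_varpart,
    envfit,
    geographic_distance,
    mantel,
    nmds,
    predictor_distance,
)
from divpart.composition import _ols_r2adj
from divpart.varpart import COMBINATIONS


def _dm(points, labels=None):
    d = squareform(pdist(np.asarray(points, float)))
    labels = labels or [f"S{i}" for i in range(len(points))]
    return DistanceMatrix(labels, d)


@pytest.fixture(scope="module")
def planted_points():
    rng = np.random.default_rng(0)
    return rng.uniform(0, 10, size=(12, 2))


class TestNMDS:
    def test_embeddable_configuration_low_stress(self, planted_points):
        res = nmds(_dm(planted_points), k=2, n_starts=8, seed=0)
        assert res.stress < 0.01
        np.testing.assert_allclose(res.scores.mean(axis=0), 0, atol=1e-9)

    def test_extra_dimension_cannot_hurt(self, planted_points):
        d = _dm(planted_points)
        s2 = nmds(d, k=2, n_starts=16, seed=1).stress
        s3 = nmds(d, k=3, n_starts=16, seed=1).stress
        assert s3 <= s2 + 1e-6

    def test_deterministic_under_seed(self, planted_points):
        d = _dm(planted_points)
        a = nmds(d, k=2, n_starts=4, seed=3)
        b = nmds(d, k=2, n_starts=4, seed=3)
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError, match="sites"):
            nmds(_dm(np.eye(3)), k=2)


class TestEnvfit:
    def _env(self, scores, extra=None):
        n = scores.shape[0]
        sites = [f"S{i}" for i in range(n)]
        data = {"v_axis1": scores[:, 0]}
        if extra is not None:
            data.update(extra)
        labels = {k: "climatic" for k in data}
        return PredictorTable(sites, pd.DataFrame(data, index=sites), labels)

    def test_axis_aligned_variable_r2_one(self, planted_points):
        res = nmds(_dm(planted_points), k=2, n_starts=8, seed=0)
        table = envfit(res, self._env(res.scores), n_perm=99, seed=0)
        row = table.loc["v_axis1"]
        assert row.r2 == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(abs(row.axis1), 1.0, atol=1e-6)
        assert row.p == pytest.approx(1 / 100)

    def test_rotation_invariant_r2(self, planted_points):
        res = nmds(_dm(planted_points), k=2, n_starts=8, seed=0)
        env = self._env(res.scores)
        t1 = envfit(res, env, n_perm=49, seed=1)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        res2 = type(res)(
            scores=res.scores @ rot, stress=res.stress, k=2, n_starts=res.n_starts,
            converged=True, seed=res.seed, labels=res.labels,
        )
        t2 = envfit(res2, env, n_perm=49, seed=1)
        np.testing.assert_allclose(t1.r2.to_numpy(), t2.r2.to_numpy(), atol=1e-9)

    def test_constant_variable_warned_not_fatal(self, planted_points):
        res = nmds(_dm(planted_points), k=2, n_starts=4, seed=0)
        env = self._env(res.scores, extra={"flat": np.ones(12)})
        with pytest.warns(UserWarning, match="constant"):
            table = envfit(res, env, n_perm=29, seed=0)
        assert table.loc["flat"].r2 == 0.0
        assert table.loc["flat"].p == 1.0


class TestMantel:
    def test_self_correlation_one(self, planted_points):
        d = _dm(planted_points)
        assert mantel(d, d, n_perm=49, seed=0).r == pytest.approx(1.0)

    def test_affine_invariance(self, planted_points):
        d = _dm(planted_points)
        d2 = DistanceMatrix(d.labels, 3.0 * d.d + (1 - np.eye(d.n)) * 0.5)
        assert mantel(d, d2, n_perm=49, seed=0).r == pytest.approx(1.0)

    def test_matches_skbio_statistic_and_null_scheme(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(5)
        p1, p2 = rng.uniform(0, 1, (2, 9, 3))
        d1, d2 = _dm(p1), _dm(p2)
        ours = mantel(d1, d2, n_perm=999, seed=0)
        sk_r, sk_p, _ = skbio_distance.mantel(
            skbio_distance.DistanceMatrix(d1.d, d1.labels),
            skbio_distance.DistanceMatrix(d2.d, d2.labels),
            method="pearson", permutations=999, alternative="greater",
        )
        assert ours.r == pytest.approx(sk_r, abs=1e-12)
        assert ours.p == pytest.approx(sk_p, abs=0.06)  # independent null draws

    def test_null_matches_bruteforce_relabeling_oracle(self):
        # on n=5 all 120 relabelings are enumerable: the permutation null of r
        # must be a subsample of that exact set
        import itertools
        rng = np.random.default_rng(2)
        d1 = _dm(rng.uniform(0, 1, (5, 2)))
        d2 = _dm(rng.uniform(0, 1, (5, 2)))
        v1 = d1.condensed()
        v1c = v1 - v1.mean()
        exact = set()
        for perm in itertools.permutations(range(5)):
            m = d2.d[np.ix_(perm, perm)]
            v = squareform(m, checks=False)
            vc = v - v.mean()
            exact.add(round(float(v1c @ vc) / np.sqrt((v1c @ v1c) * (vc @ vc)), 12))
        # draw our nulls by running mantel with many permutations and checking
        # the observed statistic plus its permutation distribution support
        res = mantel(d1, d2, n_perm=200, seed=3)
        assert round(res.r, 12) in exact

    def test_mismatched_labels_rejected(self, planted_points):
        d1 = _dm(planted_points)
        d2 = _dm(planted_points, labels=[f"X{i}" for i in range(12)])
        with pytest.raises(ValueError, match="labels"):
            mantel(d1, d2)


class TestPredictorDistance:
    def test_rotation_identity_with_standardized_euclidean(self, env16):
        for pset in ("climatic", "soil", "historical"):
            dm = predictor_distance(env16, pset)
            X = env16.values[env16.variables(pset)].to_numpy(float)
            Z = (X - X.mean(0)) / X.std(0)
            direct = squareform(pdist(Z))
            np.testing.assert_allclose(dm.d, direct, atol=1e-10)

    def test_identical_sites_zero_distance(self):
        sites = ["A", "B", "C", "D"]
        df = pd.DataFrame(
            {"c1": [1.0, 1.0, 2.0, 3.0], "c2": [4.0, 4.0, 5.0, 6.0]}, index=sites
        )
        env = PredictorTable(sites, df, {"c1": "climatic", "c2": "climatic"})
        assert predictor_distance(env, "climatic").d[0, 1] == pytest.approx(0.0)

    def test_pythagorean_site_difference(self):
        # two standardized variables differing by (3, 4) SD -> distance 5
        sites = ["A", "B"]
        df = pd.DataFrame({"c1": [0.0, 3.0], "c2": [0.0, 4.0]}, index=sites)
        env = PredictorTable(sites, df, {"c1": "climatic", "c2": "climatic"})
        X = df.to_numpy()
        Z = (X - X.mean(0)) / X.std(0)
        d_expected = np.linalg.norm(Z[0] - Z[1])
        assert predictor_distance(env, "climatic").d[0, 1] == pytest.approx(d_expected)


class TestDbVarpart:
    def test_constructed_climatic_signal_recovered(self):
        # independent predictor sets, response distance an exact scaling of
        # the climatic distances: the partition must hand (almost) everything
        # to pure C
        from divpart import SimulationConfig, gen_env_tables
        env = gen_env_tables(SimulationConfig(n_sites=40, cross_set_correlation=0.0, seed=8))
        dc = predictor_distance(env, "climatic")
        resp = DistanceMatrix(dc.labels, 0.1 * dc.d, metric="synthetic")
        res = db_varpart(resp, env, n_perm=49, seed=0)
        assert res.full_model_r2adj == pytest.approx(1.0, abs=1e-9)
        assert res.fractions["C"] == pytest.approx(res.full_model_r2adj, abs=0.05)
        assert abs(res.fractions["S"]) < 0.02
        assert abs(res.fractions["H"]) < 0.02

    def test_fraction_sum_identity(self, env16):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 1, (16, 3))
        resp = DistanceMatrix(list(env16.sites), squareform(pdist(pts)))
        res = db_varpart(resp, env16, n_perm=29, seed=0)
        assert sum(res.fractions.values()) == pytest.approx(res.full_model_r2adj, abs=1e-10)

    def test_single_set_reduces_to_distance_regression(self, env16):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 1, (16, 3))
        resp = DistanceMatrix(list(env16.sites), squareform(pdist(pts)))
        res = db_varpart(resp, env16, n_perm=29, seed=0)
        y = resp.condensed()
        x = predictor_distance(env16, "climatic").condensed()
        assert res.totals["climatic"] == pytest.approx(_ols_r2adj(y, x[:, None]), abs=1e-12)

    def test_mismatched_labels_rejected(self, env16):
        resp = DistanceMatrix([f"X{i}" for i in range(16)], np.zeros((16, 16)))
        with pytest.raises(ValueError, match="labels"):
            db_varpart(resp, env16)


class TestGeographicDistance:
    def test_degenerate_and_known_separation(self):
        # one degree of latitude is ~111 km everywhere
        coords = np.array([[100.0, 30.0], [100.0, 31.0]])
        d = geographic_distance(coords, ["a", "b"])
        assert d.d[0, 1] == pytest.approx(111.2, abs=1.0)
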