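"""Fractal and nearest-neighbor-distance estimators."""

import numpy as np
import pytest

from idest.base import STATUS_DEGENERATE, STATUS_OK
from idest.core import NeighborTable, build_neighbor_table
from idest.datasets import generate
from idest.id_geometric import (
    KNN,
    MADA,
    MLE,
    MOM,
    TLE,
    CorrInt,
    MiND_ML,
    TwoNN,
    corrint,
    count_pairs_within,
    knn_graph_id,
    mada,
    mind_ml,
    mle_id,
    mom,
    tle,
    twonn,
)


def table_from_distances(dists):
    d = np.atleast_2d(np.asarray(dists, dtype=float))
    m, k = d.shape
    idx = np.tile(np.arange(1, k + 1), (m, 1))
    return NeighborTable(k=k, indices=idx, distances=d)


class TestCorrInt:
    def test_pair_counts_match_brute_force(self, rng):
        X = rng.standard_normal((100, 3))
        D = np.linalg.norm(X[:, None] - X[None], axis=2)
        iu = np.triu_indices(100, k=1)
        for r in (0.5, 1.0, 2.0):
            assert count_pairs_within(X, r) == int(np.count_nonzero(D[iu] <= r))

    def test_scale_invariance(self, ball3):
        d1, s1, _ = corrint(ball3)
        d2, s2, _ = corrint(ball3 * 17.3)
        assert s1 == s2 == STATUS_OK
        assert d1 == pytest.approx(d2, abs=1e-9)

    def test_uniform_segment_close_to_one(self, rng):
        X = rng.random((1000, 1))
        d, status, _ = corrint(X)
        assert status == STATUS_OK
        assert 0.8 <= d <= 1.2

    def test_k1_must_be_below_k2(self, ball3):
        with pytest.raises(ValueError, match="k1"):
            corrint(ball3, k1=20, k2=10)


class TestMLE:
    def test_single_point_closed_form(self):
        nt = table_from_distances([0.25, 0.5, 0.75, 1.0])
        expected = 3.0 / (np.log(4.0) + np.log(2.0) + np.log(4.0 / 3.0))
        d, status = mle_id(nt)
        assert status == STATUS_OK
        assert d == pytest.approx(expected, abs=1e-12)

    def test_global_mackay_equals_one_pass_oracle(self, ball3):
        nt = build_neighbor_table(ball3, k=20)
        d, _ = mle_id(nt, aggregate="global_mackay")
        # oracle: flat average of every (point, j) log-ratio, then invert
        oracle = 1.0 / np.mean(
            [
                np.log(nt.distances[i, -1] / nt.distances[i, j])
                for i in range(len(ball3))
                for j in range(nt.k - 1)
            ]
        )
        assert d == pytest.approx(oracle, abs=1e-12)

    def test_equal_distances_degenerate(self):
        nt = table_from_distances([0.5, 0.5, 0.5, 0.5])
        d, status = mle_id(nt)
        assert status == STATUS_DEGENERATE and np.isnan(d)

    def test_zero_distance_degenerate(self):
        nt = table_from_distances([0.0, 0.5, 1.0])
        assert mle_id(nt)[1] == STATUS_DEGENERATE

    def test_uniform_5ball_recovery(self):
        X = generate("hyperball", 2500, {"d": 5}, seed=0).points
        d = MLE(k=20).fit(X).dimension_
        assert 4.3 <= d <= 5.7


class TestTwoNN:
    def test_constant_mu_closed_forms(self):
        m = 100
        for mu, expected in ((np.e, 1.0), (np.e**0.5, 2.0)):
            nt = table_from_distances(np.column_stack([np.ones(m), np.full(m, mu)]))
            d, status = twonn(nt, discard_fraction=0.0, fit="mle")
            assert status == STATUS_OK
            assert d == pytest.approx(expected, abs=1e-12)

    def test_pareto_quantile_linear_fit(self):
        # exact Pareto(shape 3) quantiles: mu_(i) = (1 - i/(M+1))^{-1/3}
        m = 1000
        mu = (1.0 - np.arange(1, m + 1) / (m + 1)) ** (-1.0 / 3.0)
        nt = table_from_distances(np.column_stack([np.ones(m), mu]))
        d, status = twonn(nt, fit="linear")
        assert status == STATUS_OK
        assert d == pytest.approx(3.0, rel=0.05)

    def test_all_ties_degenerate(self):
        nt = table_from_distances(np.ones((50, 2)))
        assert twonn(nt)[1] == STATUS_DEGENERATE

    def test_zero_first_distance_degenerate(self):
        nt = table_from_distances(np.column_stack([np.zeros(10), np.ones(10)]))
        assert twonn(nt)[1] == STATUS_DEGENERATE


class TestMADA:
    @pytest.mark.parametrize(
        "rk,rh,expected", [(0.5, 0.25, 1.0), (0.5, 0.5 / np.sqrt(2.0), 2.0)]
    )
    def test_two_radius_closed_form(self, rk, rh, expected):
        k = 4
        dist = np.array([[0.05, rh, 0.9 * rk, rk]])  # ceil(k/2)=2nd entry
        nt = NeighborTable(k=k, indices=np.arange(1, 5)[None, :], distances=dist)
        d, status, _ = mada(nt)
        assert status == STATUS_OK
        assert d == pytest.approx(expected, abs=1e-12)

    def test_tied_points_reported_not_fatal(self):
        good = np.array([[0.1, 0.25, 0.3, 0.5]])
        tied = np.array([[0.1, 0.5, 0.5, 0.5]])
        dist = np.vstack([good, tied])
        nt = NeighborTable(k=4, indices=np.tile(np.arange(1, 5), (2, 1)), distances=dist)
        d, status, info = mada(nt)
        assert status == STATUS_OK
        assert info["invalid_fraction"] == pytest.approx(0.5)


class TestMOM:
    def test_closed_form_example(self):
        nt = table_from_distances([0.25, 0.5, 0.75, 1.0])
        d, status, _ = mom(nt)
        assert status == STATUS_OK
        assert d == pytest.approx(0.625 / 0.375, abs=1e-12)

    def test_linear_growth_matches_direct_arithmetic(self):
        k, w = 10, 2.0
        dists = w * np.arange(1, k + 1) / k
        m1 = dists.mean()
        d, status, _ = mom(table_from_distances(dists))
        assert status == STATUS_OK
        assert d == pytest.approx(m1 / (w - m1), abs=1e-12)

    def test_all_equal_invalid(self):
        d, status, _ = mom(table_from_distances(np.full(5, 0.3)))
        assert status == STATUS_DEGENERATE


class TestTLE:
    def test_uniform_disk_recovery(self, disk2000):
        est = TLE(k=20).fit(disk2000)
        assert est.status_ == STATUS_OK
        assert 1.6 <= est.dimension_ <= 2.4

    def test_scale_invariance(self, ball3):
        d1 = TLE(k=15).fit(ball3).dimension_
        d2 = TLE(k=15).fit(ball3 * 3.7).dimension_
        assert d1 == pytest.approx(d2, abs=1e-9)

    def test_duplicated_neighbors_surface_in_accounting(self):
        X = np.vstack([np.zeros((6, 2)), np.random.default_rng(0).random((30, 2))])
        est = TLE(k=5).fit(X)
        assert est.details_["invalid_fraction"] > 0
        assert len(est.details_["per_point"]) == len(X)


class TestMiND:
    @staticmethod
    def _rho_sample(d, k, n, seed):
        # inverse CDF of F(rho) = 1 - (1 - rho^d)^k
        u = np.random.default_rng(seed).random(n)
        return (1.0 - (1.0 - u) ** (1.0 / k)) ** (1.0 / d)

    def test_inverse_cdf_recovery(self):
        k = 10
        rho = self._rho_sample(3, k, 1000, seed=0)
        dists = np.column_stack([rho] + [np.ones(1000)] * (k - 1))
        nt = NeighborTable(k=k, indices=np.tile(np.arange(1, k + 1), (1000, 1)), distances=dists)
        d_int, s1 = mind_ml(nt, variant="MLi", D_max=10)
        d_cont, s2 = mind_ml(nt, variant="MLk", D_max=10)
        assert s1 == s2 == STATUS_OK
        assert d_int == 3.0
        assert d_cont == pytest.approx(3.0, abs=0.3)

    def test_integer_output_bounded(self, ball3):
        est = MiND_ML(ver="MLi", D_max=7).fit(ball3)
        assert est.dimension_ in set(float(v) for v in range(1, 8))

    def test_degenerate_all_ties(self):
        nt = table_from_distances(np.ones((20, 5)))
        assert mind_ml(nt, "MLi", 5)[1] == STATUS_DEGENERATE


class TestKNNGraph:
    def test_noiseless_grid_is_one_dimensional(self):
        X = np.linspace(0.0, 1.0, 500)[:, None]
        d, status, info = knn_graph_id(X, sizes=(100, 200, 400), seed=0)
        assert status == STATUS_OK
        assert d == 1.0
        assert abs(info["slope"]) < 0.2

    def test_uniform_disk(self, disk2000):
        d, status, _ = knn_graph_id(disk2000, sizes=(250, 500, 1000), seed=0)
        assert status == STATUS_OK
        assert d == 2.0

    def test_bootstrap_determinism(self, disk2000):
        a = knn_graph_id(disk2000, sizes=(250, 500), seed=3)
        b = knn_graph_id(disk2000, sizes=(250, 500), seed=3)
        assert a == b

    def test_needs_two_sizes(self, disk2000):
        with pytest.raises(ValueError, match="2 subsample sizes"):
            knn_graph_id(disk2000, sizes=(500,))


class TestInvariances:
    """Rigid-motion/permutation/scale invariance across the NN family."""

    estimators = [
        MLE(k=15),
        TwoNN(),
        MADA(k=14),
        MOM(k=15),
        TLE(k=12),
        MiND_ML(ver="MLi", D_max=5),
        CorrInt(k1=5, k2=10),
    ]

    @staticmethod
    def _rotation(p, seed):
        q, _ = np.linalg.qr(np.random.default_rng(seed).standard_normal((p, p)))
        return q

    @pytest.mark.parametrize("est", estimators, ids=lambda e: e._method_tag)
    def test_rigid_motion_and_permutation(self, est, rng):
        X = generate("hyperball", 400, {"d": 3}, seed=1).points
        base = est.fit(X).dimension_
        rot = X @ self._rotation(3, 5) + np.array([2.0, -1.0, 0.5])
        assert est.fit(rot).dimension_ == pytest.approx(base, abs=1e-6)
        perm = X[rng.permutation(len(X))]
        assert est.fit(perm).dimension_ == pytest.approx(base, abs=1e-6)

    @pytest.mark.parametrize("est", estimators, ids=lambda e: e._method_tag)
    def test_scale_invariance(self, est):
        X = generate("hyperball", 400, {"d": 3}, seed=1).points
        base = est.fit(X).dimension_
        assert est.fit(X * 0.037).dimension_ == pytest.approx(base, abs=1e-9)


@pytest.mark.parametrize("d", [1, 2, 3, 5])
def test_parameter_recovery_on_balls(d):
    """Each NN-family estimator lands within +-1 of the true dimension in at
    least 4 of 5 seeds on uniform d-balls."""
    wins = {m: 0 for m in ("MLE", "TwoNN", "MOM", "CorrInt", "MiND_MLi")}
    for seed in range(5):
        X = generate("hyperball", 800, {"d": d}, seed=seed).points
        for tag in wins:
            import idest

            e = idest.estimate(X, tag)
            if e.status == STATUS_OK and abs(e.value - d) <= 1:
                wins[tag] += 1
    assert all(v >= 4 for v in wins.values()), wins
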