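"""ABC core: distances, rejection, transforms, HPD, model choice,
parameter estimation."""

import numpy as np
import pytest

from divabc import abc as A
from divabc.demography import PriorSet
from divabc.reftable import ReferenceTable


def _table(model, stats, params=None, param_names=None, seed=0):
    n = stats.shape[0]
    if params is None:
        params = np.zeros((n, 1))
        param_names = ["N_hal"]
    return ReferenceTable(model, param_names, params,
                          [f"s{i}" for i in range(stats.shape[1])],
                          stats, seed)


class TestDistances:
    def test_zero_distance_for_matching_row(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 4))
        d = A.standardize_and_distance(X[7], X)
        assert d[7] == 0.0
        assert np.all(d >= 0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 5))
        obs = rng.normal(size=5)
        d1 = A.standardize_and_distance(obs, X)
        X2 = X.copy()
        X2[:, 2] *= 10
        obs2 = obs.copy()
        obs2[2] *= 10
        d2 = A.standardize_and_distance(obs2, X2)
        np.testing.assert_allclose(d1, d2, atol=1e-10)

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(100, 6))
        obs = rng.normal(size=6)
        scale = A.robust_scale(X)
        d = A.standardize_and_distance(obs, X, scale)
        for i in (0, 17, 99):
            brute = np.sqrt(sum(((X[i, j] - obs[j]) / scale[j]) ** 2
                                for j in range(6)))
            assert d[i] == pytest.approx(brute, abs=1e-12)

    def test_degenerate_columns_fall_back(self):
        X = np.ones((30, 3))
        X[:, 1] = np.arange(30)
        s = A.robust_scale(X)
        assert s[0] == 1.0 and s[2] == 1.0 and s[1] > 0


class TestRejection:
    def test_acceptance_count_and_kernel_endpoints(self):
        d = np.linspace(0, 1, 1000)
        idx, w = A.reject(d, acceptance_rate=0.01)
        assert len(idx) == 10
        np.testing.assert_array_equal(idx, np.arange(10))
        assert w[0] == pytest.approx(1.0)   # distance 0
        assert w[-1] == pytest.approx(0.0)  # at delta_max
        assert np.all(np.diff(w) <= 0)      # monotone in distance

    def test_too_few_accepted_raises(self):
        with pytest.raises(ValueError, match="< 2"):
            A.reject(np.arange(100.0), acceptance_rate=1e-5)

    def test_all_zero_distances(self):
        idx, w = A.reject(np.zeros(10), n_accept=5)
        np.testing.assert_array_equal(w, 1.0)


class TestTransforms:
    BOUNDS = [(0.0, 300_000.0), (0.0, 20.0), (1.0, 3.0)]

    def test_round_trip_1000_points(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([rng.uniform(lo, hi, 1000)
                             for lo, hi in self.BOUNDS])
        Y = A.transform_params(X, self.BOUNDS)
        back = A.inverse_transform_params(Y, self.BOUNDS)
        for j, (lo, hi) in enumerate(self.BOUNDS):
            np.testing.assert_allclose(back[:, j], X[:, j],
                                       atol=1e-10 * (hi - lo))

    def test_midpoint_finite_and_monotone(self):
        mids = np.array([[0.5 * (lo + hi) for lo, hi in self.BOUNDS]])
        y = A.transform_params(mids, self.BOUNDS)
        assert np.all(np.isfinite(y))
        assert np.allclose(y, 0.0, atol=1e-12)  # tan(pi/4)=1 -> log 1 = 0
        grid = np.linspace(0.01, 299_999.9, 50)
        ys = A.transform_params(
            np.column_stack([grid, np.full(50, 5.0), np.full(50, 2.0)]),
            self.BOUNDS)[:, 0]
        assert np.all(np.diff(ys) > 0)

    def test_boundaries_clamped_not_infinite(self):
        edge = np.array([[0.0, 20.0, 1.0]])
        y = A.transform_params(edge, self.BOUNDS)
        assert np.all(np.isfinite(y))
        back = A.inverse_transform_params(y, self.BOUNDS)
        np.testing.assert_allclose(back[0], [0.0, 20.0, 1.0], atol=1e-4)


class TestHPD:
    def test_standard_normal(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=100_000)
        lo, hi = A.hpd(x, level=0.95)
        # the width is sharply determined; endpoints wobble a little more
        # because the smallest-interval optimum is flat under noise
        assert (hi - lo) == pytest.approx(2 * 1.96, abs=0.08)
        assert lo == pytest.approx(-1.96, abs=0.12)
        assert hi == pytest.approx(1.96, abs=0.12)
        assert A.weighted_mode(x) == pytest.approx(0.0, abs=0.08)

    def test_uniform_interval_width(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 1, 50_000)
        lo, hi = A.hpd(x, level=0.95)
        assert (hi - lo) == pytest.approx(0.95, abs=0.04)

    def test_point_mass_zero_width(self):
        x = np.full(100, 3.7)
        lo, hi = A.hpd(x)
        assert lo == hi == pytest.approx(3.7)

    def test_weights_shift_interval(self):
        x = np.concatenate([np.zeros(500), np.ones(500)])
        x = x + np.random.default_rng(6).normal(0, 0.01, 1000)
        w = np.concatenate([np.full(500, 1e-6), np.full(500, 1.0)])
        lo, hi = A.hpd(x, w, level=0.9)
        assert lo > 0.5  # mass concentrated at 1


class TestModelChoice:
    def _separable_tables(self, n=500):
        rng = np.random.default_rng(7)
        a = _table("SIC", rng.normal(0, 1, size=(n, 3)))
        b = _table("CMC", rng.normal(8, 1, size=(n, 3)))
        return {"SIC": a, "CMC": b}

    def test_disjoint_supports_give_confident_posterior(self):
        tabs = self._separable_tables()
        st = A.ABCSettings(acceptance_rate=0.1, min_accept=20)
        mp = A.model_choice(np.zeros(3), tabs, st)
        assert mp.probs["SIC"] > 0.99
        assert mp.rejection_probs["SIC"] == pytest.approx(1.0)
        assert sum(mp.probs.values()) == pytest.approx(1.0)

    def test_rejection_only_equals_weighted_frequency_brute_force(self):
        rng = np.random.default_rng(8)
        tabs = {"SIC": _table("SIC", rng.normal(0, 2, size=(400, 3))),
                "CMC": _table("CMC", rng.normal(1, 2, size=(400, 3)))}
        obs = np.array([0.5, 0.5, 0.5])
        st = A.ABCSettings(acceptance_rate=0.05, min_accept=40,
                           method="rejection")
        mp = A.model_choice(obs, tabs, st)
        # brute force: pool, distances, nearest, Epanechnikov weights
        X = np.vstack([tabs["SIC"].stats, tabs["CMC"].stats])
        y = np.array(["CMC"] * 400 + ["SIC"] * 400)  # sorted order
        X = np.vstack([tabs["CMC"].stats, tabs["SIC"].stats])
        scale = A.robust_scale(X)
        d = np.sqrt((((X - obs) / scale) ** 2).sum(axis=1))
        order = np.argsort(d, kind="stable")[:40]
        dmax = d[order].max()
        w = 1 - (d[order] / dmax) ** 2
        exp = {m: w[y[order] == m].sum() / w.sum() for m in ("SIC", "CMC")}
        assert mp.probs["SIC"] == pytest.approx(exp["SIC"], abs=1e-10)

    def test_posteriors_sum_to_one(self):
        tabs = self._separable_tables()
        for method in ("rejection", "mnlogistic", "neuralnet"):
            st = A.ABCSettings(acceptance_rate=0.2, min_accept=50,
                               method=method, n_nets_choice=3, max_iter=50)
            mp = A.model_choice(np.full(3, 4.0), tabs, st)
            assert sum(mp.probs.values()) == pytest.approx(1.0)

    def test_pooled_draws_average_to_prior_share(self):
        rng = np.random.default_rng(9)
        tabs = {"SIC": _table("SIC", rng.normal(0, 2, size=(300, 2))),
                "CMC": _table("CMC", rng.normal(0.5, 2, size=(300, 2)))}
        st = A.ABCSettings(acceptance_rate=0.1, min_accept=30)
        pooled = np.vstack([t.stats for t in tabs.values()])
        ps = []
        for i in rng.choice(600, size=60, replace=False):
            mp = A.model_choice(pooled[i], tabs, st)
            ps.append(mp.probs["SIC"])
        assert np.mean(ps) == pytest.approx(0.5, abs=0.1)

    def test_hierarchical_structure(self):
        rng = np.random.default_rng(10)
        tabs = {}
        for scen in ("SI", "CM"):
            for mode, mean in (("C", 0.0), ("E", 3.0), ("B", 6.0)):
                shift = 0.0 if scen == "SI" else 20.0
                tabs[scen + mode] = _table(
                    scen + mode, rng.normal(mean + shift, 1, (300, 3)))
        st = A.ABCSettings(acceptance_rate=0.2, min_accept=30)
        res = A.hierarchical_model_choice(np.zeros(3), tabs, st)
        assert set(res["stage1"]) == {"SI", "CM"}
        for scen, info in res["stage1"].items():
            for label, mp in info["comparisons"].items():
                assert sum(mp.probs.values()) == pytest.approx(1.0)
        assert res["finalists"]["SI"] == "SIC"
        assert res["winner"] == "SIC"
        assert res["stage2"].probs["SIC"] > 0.9


class TestParameterEstimation:
    def _sic_table(self, n=3000, seed=11):
        # linear-ish synthetic mapping from parameters to statistics
        rng = np.random.default_rng(seed)
        priors = PriorSet()
        names = list(priors.bounds_for("SIC"))
        P = np.column_stack([rng.uniform(*priors.bounds_for("SIC")[k], n)
                             for k in names])
        S = np.column_stack([
            P[:, 0] / 1e5 + rng.normal(0, 0.05, n),
            P[:, 1] / 1e5 + rng.normal(0, 0.05, n),
            P[:, 2] / 1e6 + rng.normal(0, 0.05, n),
            P[:, 3] / 1e6 + rng.normal(0, 0.05, n),
        ])
        return ReferenceTable("SIC", names, P, list("wxyz"), S, seed)

    def test_adjusted_draws_stay_in_prior_support(self):
        t = self._sic_table()
        priors = PriorSet()
        obs = np.array([0.8, 1.2, 0.3, 1.5])
        st = A.ABCSettings(n_accept_est=400, n_nets_est=3, max_iter=100,
                           seed=1)
        post = A.estimate_parameters(obs, t, priors, st)
        assert post.adjusted_by_regression
        for j, name in enumerate(post.param_names):
            lo, hi = post.bounds[name]
            assert np.all(post.adjusted[:, j] >= lo - 1e-9)
            assert np.all(post.adjusted[:, j] <= hi + 1e-9)
            h_lo, h_hi = post.hpd[name]
            assert lo - 1e-9 <= h_lo <= h_hi <= hi + 1e-9

    def test_adjustment_improves_concentration(self):
        t = self._sic_table()
        obs = np.array([0.8, 1.2, 0.3, 1.5])
        st = A.ABCSettings(n_accept_est=600, n_nets_est=3, max_iter=150,
                           seed=2)
        post = A.estimate_parameters(obs, t, PriorSet(), st)
        j = post.param_names.index("N_hal")
        raw_err = abs(np.median(post.raw[:, j]) - 80_000)
        adj_err = abs(np.median(post.adjusted[:, j]) - 80_000)
        assert adj_err < raw_err

    def test_zero_variance_statistics_is_noop(self):
        rng = np.random.default_rng(12)
        priors = PriorSet()
        names = list(priors.bounds_for("SIC"))
        P = np.column_stack([rng.uniform(*priors.bounds_for("SIC")[k], 100)
                             for k in names])
        S = np.ones((100, 3))
        t = ReferenceTable("SIC", names, P, ["a", "b", "c"], S, 0)
        st = A.ABCSettings(n_accept_est=50)
        with pytest.warns(UserWarning, match="degenerate"):
            post = A.estimate_parameters(np.ones(3), t, priors, st)
        assert not post.adjusted_by_regression
        np.testing.assert_allclose(post.adjusted, post.raw, rtol=1e-6)
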