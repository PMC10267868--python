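import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import optimize

import linkmap as lm
from linkmap import mapfun

D_GRID = np.array([0.01, 0.1, 0.5, 1.0])


def haldane(d):
    return 0.5 * (1 - np.exp(-2 * np.asarray(d, dtype=float)))


def kosambi(d):
    return 0.5 * np.tanh(2 * np.asarray(d, dtype=float))


def carter_falconer_theta(d):
    """Independent oracle: invert d = ¼(atan 2θ + atanh 2θ) numerically."""
    def inv(x):
        if x <= 0:
            return 0.0
        return optimize.brentq(
            lambda t: 0.25 * (np.arctan(2 * t) + np.arctanh(2 * t)) - x,
            0.0, 0.5 - 1e-13, xtol=1e-13)
    return np.array([inv(x) for x in np.atleast_1d(d)])


class TestThetaFunctions:
    @pytest.mark.parametrize("family,param", [
        ("haldane_scaled", 2.0), ("rao", 0.5), ("felsenstein", 1.5),
        ("karlin_binomial", 3),
    ])
    def test_zero_distance_gives_zero(self, family, param):
        assert mapfun.theta(family, 0.0, param) == 0.0

    def test_haldane_closed_form(self):
        assert mapfun.theta("haldane_scaled", 0.5, 1.0) == pytest.approx(
            0.5 * (1 - np.exp(-1)), abs=1e-12)
        assert 0.5 * (1 - np.exp(-1)) == pytest.approx(0.3160603, abs=1e-7)

    def test_karlin_closed_form(self):
        assert mapfun.theta("karlin_binomial", 0.5, 2) == pytest.approx(0.375)
        # reaches 1/2 at d = N/2 and stays there
        assert mapfun.theta("karlin_binomial", 1.0, 2) == 0.5
        assert mapfun.theta("karlin_binomial", 5.0, 2) == 0.5

    @pytest.mark.parametrize("a,oracle,tol", [
        (1.0, haldane, 1e-8),
        (0.5, kosambi, 1e-8),
        (0.25, carter_falconer_theta, 1e-8),
    ])
    def test_rao_special_cases(self, a, oracle, tol):
        got = mapfun.theta("rao", D_GRID, a)
        np.testing.assert_allclose(got, oracle(D_GRID), atol=tol)

    def test_rao_morgan_limit(self):
        # a = 0 is the complete-interference (Morgan) function: theta = d up
        # to d = 1/2, then saturation
        d = np.array([0.05, 0.2, 0.45])
        np.testing.assert_allclose(mapfun.theta("rao", d, 0.0), d, atol=1e-9)
        assert mapfun.theta("rao", 0.9, 0.0) == 0.5

    @pytest.mark.parametrize("k,oracle,tol", [
        (1.0, haldane, 1e-12),
        (0.0, kosambi, 1e-12),
    ])
    def test_felsenstein_special_cases(self, k, oracle, tol):
        got = mapfun.theta("felsenstein", D_GRID, k)
        np.testing.assert_allclose(got, oracle(D_GRID), atol=tol)

    def test_karlin_large_n_approaches_haldane(self):
        d = np.linspace(0.01, 2.0, 50)
        err = np.abs(mapfun.karlin_theta(d, 1000) - haldane(d))
        assert err.max() < 1e-3

    @pytest.mark.parametrize("a", [0.0, 0.25, 0.5, 1.0])
    def test_rao_roundtrip(self, a):
        d = np.linspace(0.05, 2.0, 15)
        if a == 0.0:
            d = d[d < 0.5]  # Morgan saturates at 1/2
        theta = mapfun.rao_theta(d, a)
        np.testing.assert_allclose(mapfun.rao_distance(theta, a), d, atol=1e-8)

    @pytest.mark.parametrize("family,bad", [
        ("haldane_scaled", -1.0), ("haldane_scaled", 0.0),
        ("rao", 1.5), ("felsenstein", 2.0), ("karlin_binomial", 1),
    ])
    def test_domain_violations_rejected(self, family, bad):
        with pytest.raises(ValueError):
            mapfun.theta(family, 0.1, bad)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            mapfun.theta("haldane_scaled", -0.1, 1.0)

    @given(
        family=st.sampled_from(mapfun.FAMILIES),
        d=st.lists(st.floats(0, 5), min_size=2, max_size=6),
        u=st.floats(0.01, 0.99),
    )
    def test_monotone_and_bounded(self, family, d, u):
        lo, hi = {"haldane_scaled": (0.05, 10), "rao": (0, 1),
                  "felsenstein": (0, 1.99), "karlin_binomial": (2, 5)}[family]
        param = lo + u * (hi - lo)
        if family == "karlin_binomial":
            param = int(round(param))
        th = np.atleast_1d(mapfun.theta(family, np.sort(d), param))
        assert (th >= -1e-12).all() and (th <= 0.5 + 1e-12).all()
        assert (np.diff(th) >= -1e-9).all()


class TestFitting:
    @pytest.mark.parametrize("family,a_true", [
        ("haldane_scaled", 1.8), ("rao", 0.3), ("felsenstein", 1.4),
    ])
    def test_noise_free_recovery_continuous(self, family, a_true):
        rng = np.random.default_rng(0)
        d = rng.uniform(0.01, 1.5, 500)
        th = mapfun.theta(family, d, a_true)
        fit = mapfun.fit(d, th, family)
        assert abs(fit.parameter - a_true) < 1e-4
        assert fit.sse < 1e-12
        assert fit.converged

    @pytest.mark.parametrize("n_true", [2, 3, 4, 5])
    def test_noise_free_recovery_karlin(self, n_true):
        rng = np.random.default_rng(1)
        d = rng.uniform(0.01, 1.2, 300)
        th = mapfun.karlin_theta(d, n_true)
        fit = mapfun.fit(d, th, "karlin_binomial")
        assert fit.parameter == n_true
        # the winning N must be strictly best
        others = [mapfun.sse("karlin_binomial", d, th, n)
                  for n in mapfun.KARLIN_GRID if n != n_true]
        assert fit.sse < min(others)

    def test_all_zero_theta_hits_lower_boundary(self):
        d = np.linspace(0.1, 1.0, 20)
        fit = mapfun.fit(d, np.zeros(20), "haldane_scaled")
        assert fit.at_boundary and not fit.converged
        assert fit.parameter == pytest.approx(mapfun.DOMAINS["haldane_scaled"][0],
                                              rel=1e-2)

    def test_non_finite_pairs_skipped(self):
        d = np.array([0.1, 0.2, np.nan, 0.4])
        th = np.array([0.05, np.nan, 0.1, 0.2])
        fit = mapfun.fit(d, th, "haldane_scaled")
        assert fit.n_pairs == 2

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError, match="pairs"):
            mapfun.fit([], [], "haldane_scaled")

    def test_mse_is_sse_over_n(self):
        rng = np.random.default_rng(2)
        d = rng.uniform(0, 1, 50)
        th = np.clip(haldane(d) + rng.normal(0, 0.02, 50), 0, 0.5)
        fit = mapfun.fit(d, th, "haldane_scaled")
        assert fit.mse == pytest.approx(fit.sse / 50)


class TestSelectBest:
    def _fits(self, sses, key="k"):
        return [mapfun.MapFunctionFit(f, 1.0, s, s, 10, True, pairs_key=key)
                for f, s in zip(mapfun.FAMILIES, sses)]

    def test_argmin(self):
        best, ranked = mapfun.select_best(self._fits([0.4, 0.2, 0.3, 0.9]))
        assert best == "rao"
        assert [f.sse for f in ranked] == sorted([0.4, 0.2, 0.3, 0.9])

    def test_tie_broken_by_fixed_order(self):
        best, _ = mapfun.select_best(self._fits([0.2, 0.2, 0.5, 0.9]))
        assert best == "haldane_scaled"

    def test_different_pair_sets_rejected(self):
        fits = self._fits([0.1, 0.2, 0.3, 0.4])
        fits[1].pairs_key = "other"
        with pytest.raises(ValueError, match="different pair sets"):
            mapfun.select_best(fits)

    def test_model_selection_recovers_generating_family(self):
        # Carter-Falconer-generated data (rao a=0.25, reachable by no other
        # family) with noise sigma=0.01: rao wins in >= 90% of seeds
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            d = rng.uniform(0.01, 1.5, 2000)
            truth = mapfun.rao_theta(d, 0.25)
            th = np.clip(truth + rng.normal(0, 0.01, d.size), 0.0, 0.5)
            best, _ = mapfun.select_best(mapfun.fit_all(d, th))
            wins += best == "rao"
        assert wins >= 0.9 * n_seeds


class TestThinScatter:
    def test_small_input_is_identity(self):
        pts = np.random.default_rng(0).random((10, 2))
        out, idx = mapfun.thin_scatter(pts, n_keep=10)
        np.testing.assert_array_equal(out, pts)
        np.testing.assert_array_equal(idx, np.arange(10))

    def test_collinear_ties_keep_earliest(self):
        pts = np.column_stack([np.arange(5.0), np.zeros(5)])
        out, idx = mapfun.thin_scatter(pts, n_keep=3)
        np.testing.assert_array_equal(idx, [0, 1, 2])

    def test_against_exhaustive_sort_oracle(self):
        rng = np.random.default_rng(3)
        pts = rng.random((1000, 2))
        out, idx = mapfun.thin_scatter(pts, n_keep=100)
        dist = np.empty(1000)
        dist[0] = np.inf
        dist[1:] = np.sqrt(((pts[1:] - pts[:-1]) ** 2).sum(axis=1))
        oracle = sorted(sorted(range(1000), key=lambda i: (-dist[i], i))[:100])
        np.testing.assert_array_equal(idx, oracle)
        np.testing.assert_array_equal(out, pts[oracle])
        assert (np.diff(idx) > 0).all()

    def test_invalid_n_keep(self):
        with pytest.raises(ValueError, match="n_keep"):
            mapfun.thin_scatter(np.zeros((5, 2)), n_keep=0)

    @given(n=st.integers(2, 60), k=st.integers(1, 60))
    def test_output_size_and_order(self, n, k):
        rng = np.random.default_rng(n * 100 + k)
        pts = rng.random((n, 2))
        out, idx = mapfun.thin_scatter(pts, n_keep=k)
        assert out.shape[0] == min(n, k)
        assert (np.diff(idx) > 0).all()
        assert idx[0] == 0 or n <= k  # first point always kept when thinning
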