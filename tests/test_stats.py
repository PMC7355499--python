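import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq, minimize
from scipy.stats import chi2

import focimap as fm
from focimap.stats import (
    LOOP_PAIRS,
    CountVector,
    activation_pvalue,
    el_mean_interval,
    reported_pvalue,
)


def binary_el_bounds_closed_form(T: int, n1: int, alpha: float) -> tuple[float, float]:
    """Independent oracle: profile EL for a Bernoulli mean in closed form.

    The optimal weights are constant within the ones-group and the
    zeros-group, so the bound solves
    -2[n1 log(T mu / n1) + (T - n1) log(T (1 - mu) / (T - n1))] = chi2_{1,1-a}.
    """
    q = chi2.ppf(1.0 - alpha, df=1)
    if n1 == 0:
        return 0.0, 1.0 - np.exp(-q / (2.0 * T))
    if n1 == T:
        return np.exp(-q / (2.0 * T)), 1.0
    phat = n1 / T

    def ratio(mu):
        return -2.0 * (n1 * np.log(T * mu / n1) + (T - n1) * np.log(T * (1.0 - mu) / (T - n1))) - q

    lb = brentq(ratio, 1e-12, phat, xtol=1e-13)
    ub = brentq(ratio, phat, 1.0 - 1e-12, xtol=1e-13)
    return lb, ub


def el_bound_by_weight_optimization(z: np.ndarray, alpha: float, side: str) -> float:
    """Second oracle: optimize the weights directly (SLSQP over the simplex)."""
    T = len(z)
    q = chi2.ppf(1.0 - alpha, df=1)
    sign = 1.0 if side == "max" else -1.0
    res = minimize(
        lambda w: -sign * float(w @ z),
        np.full(T, 1.0 / T),
        method="SLSQP",
        bounds=[(1e-10, 1.0)] * T,
        constraints=[
            {"type": "eq", "fun": lambda w: w.sum() - 1.0},
            {"type": "ineq", "fun": lambda w: q + 2.0 * np.sum(np.log(T * w))},
        ],
        options={"maxiter": 500, "ftol": 1e-12},
    )
    assert res.success
    return float(res.x @ z)


class TestResampling:
    def test_zero_sigma_full_T_gives_identical_copies(self, noiseless_single_source):
        mat, _ = noiseless_single_source
        cfg = fm.StatsConfig(n_resamples_M=5, trials_T=mat.n_activations, lat_sd_sigma=0.0, seed=0)
        for r in fm.resample_lats(mat, cfg):
            np.testing.assert_array_equal(np.sort(r.activation_ids), mat.activation_ids)
            np.testing.assert_allclose(np.sort(r.lat, axis=0), np.sort(mat.lat, axis=0))

    def test_seed_determinism(self, noiseless_single_source):
        mat, _ = noiseless_single_source
        cfg = fm.StatsConfig(n_resamples_M=3, trials_T=30, lat_sd_sigma=1.0, seed=9)
        a = fm.resample_lats(mat, cfg)
        b = fm.resample_lats(mat, cfg)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.lat, y.lat)

    def test_perturbation_variance(self, noiseless_single_source):
        mat, _ = noiseless_single_source
        cfg = fm.StatsConfig(n_resamples_M=400, trials_T=mat.n_activations, lat_sd_sigma=2.0, seed=1)
        devs = np.concatenate([(r.lat - mat.lat).ravel() for r in fm.resample_lats(mat, cfg)])
        assert devs.var() == pytest.approx(4.0, rel=0.05)

    def test_T_larger_than_available_rejected(self, noiseless_single_source):
        mat, _ = noiseless_single_source
        with pytest.raises(ValueError, match="available"):
            fm.resample_lats(mat, fm.StatsConfig(trials_T=mat.n_activations + 1))


class TestIndicatorsAndCounts:
    def test_monotone_lats_first_and_last(self):
        lat = np.tile(np.arange(1.0, 11.0), (4, 1))  # pairs 1..19 get LATs 1..10
        mat = fm.ActivationMatrix(lat)
        first = fm.compute_indicators(mat, "first")
        last = fm.compute_indicators(mat, "last")
        # outer loop columns hold LATs 6..10 -> first pair 11, last pair 19
        assert np.all(first.indicators["outer"][:, 0] == 1)
        assert np.all(last.indicators["outer"][:, 4] == 1)

    def test_tie_breaks_to_smaller_pair_index(self):
        lat = np.full((3, 10), 5.0)
        mat = fm.ActivationMatrix(lat)
        first = fm.compute_indicators(mat, "first")
        assert np.all(first.indicators["outer"][:, 0] == 1)  # pair 11
        assert np.all(first.indicators["inner"][:, 0] == 1)  # pair 1

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(4)
        lat = rng.normal(100.0, 10.0, size=(50, 10))
        mat = fm.ActivationMatrix(lat)
        sample = fm.compute_indicators(mat, "last")
        counts = fm.count_first_last(sample)
        for loop in ("inner", "outer"):
            tally = np.zeros(5, dtype=int)
            for row in mat.loop_lat(loop):
                tally[int(np.argmax(row))] += 1
            np.testing.assert_array_equal(counts.counts[loop], tally)
            assert counts.counts[loop].sum() == 50

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_exactly_one_indicator_per_loop_per_activation(self, seed):
        lat = np.random.default_rng(seed).normal(size=(20, 10))
        sample = fm.compute_indicators(fm.ActivationMatrix(lat + 100.0), "first")
        for z in sample.indicators.values():
            np.testing.assert_array_equal(z.sum(axis=1), 1)


class TestEmpiricalLikelihoodBounds:
    def test_matches_binary_closed_form(self):
        for T in (10, 30):
            for n1 in (0, 1, T // 2, T - 1, T):
                z = np.array([1.0] * n1 + [0.0] * (T - n1))
                lb, ub = el_mean_interval(z, 0.05)
                elb, eub = binary_el_bounds_closed_form(T, n1, 0.05)
                assert lb == pytest.approx(elb, abs=1e-6)
                assert ub == pytest.approx(eub, abs=1e-6)

    def test_matches_direct_weight_optimization(self):
        z = np.array([1.0] * 4 + [0.0] * 6)
        lb, ub = el_mean_interval(z, 0.1)
        assert ub == pytest.approx(el_bound_by_weight_optimization(z, 0.1, "max"), abs=1e-4)
        assert lb == pytest.approx(el_bound_by_weight_optimization(z, 0.1, "min"), abs=1e-4)

    def test_reference_case_T30_half(self):
        z = np.array([1.0] * 15 + [0.0] * 15)
        lb, ub = el_mean_interval(z, 0.05)
        assert lb == pytest.approx(0.327, abs=5e-4)
        assert ub == pytest.approx(0.673, abs=5e-4)

    def test_degenerate_all_ones(self):
        lb, ub = el_mean_interval(np.ones(20), 0.05)
        assert ub == 1.0
        assert 0.0 < lb < 1.0

    def test_alpha_to_one_collapses_to_mean(self):
        z = np.array([1.0] * 7 + [0.0] * 13)
        lb, ub = el_mean_interval(z, 1.0 - 1e-12)
        assert lb == pytest.approx(0.35, abs=1e-5)
        assert ub == pytest.approx(0.35, abs=1e-5)

    def test_width_non_increasing_in_T(self):
        widths = []
        for T in (10, 30, 100):
            z = np.array([1.0] * (T // 2) + [0.0] * (T - T // 2))
            lb, ub = el_mean_interval(z, 0.1)
            widths.append(ub - lb)
        assert widths[0] > widths[1] > widths[2]

    def test_sandwich_on_indicator_sample(self, make_single_source):
        mat, _ = make_single_source(sigma=3.0, seed=8)
        sample = fm.compute_indicators(mat, "first")
        bounds = fm.el_probability_bounds(sample, alpha=0.1)
        for loop, z in sample.indicators.items():
            lb, ub = bounds[loop]
            mean = z.mean(axis=0)
            assert np.all(lb <= mean + 1e-9)
            assert np.all(ub >= mean - 1e-9)
            assert np.all((lb >= 0.0) & (ub <= 1.0))


def _grid_simplex_mle(c, lb, ub, step=1e-3):
    """Dense-grid oracle on the 2-simplex (D = 3)."""
    best, best_ll = None, -np.inf
    for i in np.arange(0.0, 1.0 + step / 2, step):
        for j in np.arange(0.0, 1.0 - i + step / 2, step):
            p = np.array([i, j, 1.0 - i - j])
            if np.any(p < lb - 1e-12) or np.any(p > ub + 1e-12):
                continue
            with np.errstate(divide="ignore", invalid="ignore"):
                ll = np.sum(np.where(c > 0, c * np.log(np.maximum(p, 1e-300)), 0.0))
            if ll > best_ll:
                best_ll, best = ll, p
    return best


class TestMultinomialMle:
    def _cv(self, counts):
        arr = np.asarray(counts)
        return CountVector(counts={"outer": arr, "inner": arr}, total_T=int(arr.sum()))

    def test_unconstrained_closed_form(self):
        p = fm.multinomial_mle([self._cv([10, 20, 0, 0, 0])])
        np.testing.assert_allclose(p["outer"], [1 / 3, 2 / 3, 0, 0, 0], atol=1e-12)

    def test_equal_counts_uniform(self):
        bounds = {"outer": (np.full(5, 0.1), np.full(5, 0.9)), "inner": (np.full(5, 0.1), np.full(5, 0.9))}
        p = fm.multinomial_mle([self._cv([6, 6, 6, 6, 6])], bounds)
        np.testing.assert_allclose(p["outer"], 0.2, atol=1e-9)

    def test_active_lower_bound(self):
        """Counts (28,1,1,0,0) with lb = 0.05: floor binds for the zero cells."""
        bounds = {"outer": (np.full(5, 0.05), np.ones(5)), "inner": (np.full(5, 0.05), np.ones(5))}
        p = fm.multinomial_mle([self._cv([28, 1, 1, 0, 0])], bounds)["outer"]
        # KKT: cells with count <= 1 rail at the floor, the dominant cell takes the rest
        np.testing.assert_allclose(p, [0.8, 0.05, 0.05, 0.05, 0.05], atol=1e-8)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_dense_grid_D3(self):
        rng = np.random.default_rng(0)
        for _ in range(3):
            c = rng.integers(0, 30, size=3).astype(float)
            c[0] += 1  # avoid the all-zero corner
            lb = rng.uniform(0.0, 0.15, size=3)
            ub = np.clip(lb + rng.uniform(0.3, 1.0, size=3), None, 1.0)
            cv = CountVector(counts={"outer": c.astype(int)}, total_T=int(c.sum()))
            p = fm.multinomial_mle([cv], {"outer": (lb, ub)})["outer"]
            grid = _grid_simplex_mle(c, lb, ub)
            np.testing.assert_allclose(p, grid, atol=2e-3)

    def test_infeasible_box_rejected(self):
        with pytest.raises(ValueError, match="lower"):
            fm.multinomial_mle([self._cv([1, 1, 1, 1, 1])], {"outer": (np.full(5, 0.3), np.ones(5)), "inner": (np.full(5, 0.3), np.ones(5))})
        with pytest.raises(ValueError, match="upper"):
            fm.multinomial_mle([self._cv([1, 1, 1, 1, 1])], {"outer": (np.zeros(5), np.full(5, 0.1)), "inner": (np.zeros(5), np.full(5, 0.1))})

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_normalization_and_box_membership(self, seed):
        rng = np.random.default_rng(seed)
        c = rng.integers(0, 50, size=5)
        if c.sum() == 0:
            c[0] = 1
        lb = rng.uniform(0.0, 0.18, size=5)
        ub = np.clip(lb + rng.uniform(0.25, 1.0, size=5), None, 1.0)
        cv = CountVector(counts={"outer": c}, total_T=int(c.sum()))
        p = fm.multinomial_mle([cv], {"outer": (lb, ub)})["outer"]
        assert p.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(p >= lb - 1e-6)
        assert np.all(p <= ub + 1e-6)


class TestHypothesisTest:
    @pytest.mark.parametrize(
        "p_star,expected",
        [(0.31, 0.06), (0.20, 0.16), (0.30, 0.07), (0.42, 0.02), (0.47, 0.01), (0.89, 0.01)],
    )
    def test_reported_pvalues(self, p_star, expected):
        assert reported_pvalue(activation_pvalue(p_star, 5)) == pytest.approx(expected)

    def test_zero_probability_gives_half(self):
        assert activation_pvalue(0.0, 5) == pytest.approx(0.5)

    def test_strictly_decreasing_in_p_star(self):
        ps = np.linspace(0.0, 1.0, 101)
        vals = [activation_pvalue(p, 5) for p in ps]
        assert np.all(np.diff(vals) < 0)


class TestSignificantPairs:
    def test_dominant_two_pairs(self):
        from focimap.worked_examples import TWO_DISTANT_SOURCES, estimates_from_table

        est = estimates_from_table(TWO_DISTANT_SOURCES, "first")
        sig = fm.significant_pairs(est, alpha=0.1)
        assert sig["outer"] == [13, 11]  # descending probability order
        assert sig["inner"] == [3, 1]

    def test_uniform_probabilities_not_significant(self):
        assert activation_pvalue(0.2, 5) > 0.1

    def test_certain_pair_only(self):
        p = {"outer": np.array([1.0, 0.0, 0.0, 0.0, 0.0])}
        est = fm.ProbabilityEstimate(
            mode="first",
            p_star=p,
            lb={"outer": np.zeros(5)},
            ub={"outer": np.ones(5)},
            p_value={"outer": np.array([activation_pvalue(v) for v in p["outer"]])},
        )
        assert fm.significant_pairs(est, alpha=0.1)["outer"] == [11]
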