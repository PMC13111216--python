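import itertools
import math

import numpy as np
import pytest

from mmpcr import fit_metrics, model_aic, ols_fit, stepwise_aic


def normal_equations_oracle(X, y):
    """Reference OLS: explicit normal equations on the augmented design."""
    M = np.column_stack([np.ones(len(y)), X])
    coef = np.linalg.solve(M.T @ M, M.T @ y)
    resid = y - M @ coef
    return coef, float(resid @ resid)


def exhaustive_min_aic(X, y, labels):
    """Brute-force global AIC minimum over all candidate subsets."""
    best = None
    for r in range(len(labels) + 1):
        for subset in itertools.combinations(range(len(labels)), r):
            fit = ols_fit(X[:, list(subset)], y, [labels[j] for j in subset])
            if best is None or fit.aic < best.aic:
                best = fit
    return best


class TestOLS:
    def test_noiseless_line_recovered_exactly(self, rng):
        x = rng.standard_normal(12)
        y = 3.0 - 2.0 * x
        fit = ols_fit(x, y)
        assert fit.beta0_hat == pytest.approx(3.0)
        assert fit.beta_hat[0] == pytest.approx(-2.0)
        assert fit.sse == pytest.approx(0.0, abs=1e-20)

    def test_intercept_only_hand_example(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        fit = ols_fit(np.empty((4, 0)), y, term_ids=[])
        assert fit.beta0_hat == pytest.approx(2.5)
        assert fit.sse == pytest.approx(5.0)

    def test_agrees_with_normal_equations_oracle(self, rng):
        X = rng.standard_normal((30, 4))
        y = X @ [1.0, -0.5, 0.0, 2.0] + rng.standard_normal(30)
        fit = ols_fit(X, y)
        coef, sse = normal_equations_oracle(X, y)
        np.testing.assert_allclose(
            np.concatenate([[fit.beta0_hat], fit.beta_hat]), coef, rtol=1e-10
        )
        assert fit.sse == pytest.approx(sse, rel=1e-10)

    def test_agrees_with_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        X = rng.standard_normal((25, 3))
        y = X @ [0.5, 1.0, -1.0] + rng.standard_normal(25)
        fit = ols_fit(X, y)
        ref = sm.OLS(y, sm.add_constant(X)).fit()
        np.testing.assert_allclose(
            np.concatenate([[fit.beta0_hat], fit.beta_hat]), ref.params, rtol=1e-8
        )

    def test_duplicated_column_is_rank_deficiency_error(self, rng):
        x = rng.standard_normal((10, 1))
        X = np.hstack([x, x])
        with pytest.raises(np.linalg.LinAlgError, match="rank deficient"):
            ols_fit(X, rng.standard_normal(10), term_ids=["a", "a_copy"])

    def test_insufficient_n_rejected(self, rng):
        with pytest.raises(ValueError, match="n >= k"):
            ols_fit(rng.standard_normal((4, 3)), rng.standard_normal(4))


class TestAIC:
    def test_intercept_only_value(self):
        fit = ols_fit(np.empty((4, 0)), np.array([1.0, 2.0, 3.0, 4.0]), term_ids=[])
        assert model_aic(fit) == pytest.approx(4 * math.log(5 / 4) + 2)

    def test_extra_predictor_at_equal_sse_costs_two(self, rng):
        # identical SSE, one more term: AIC difference is exactly the penalty
        fit_a = ols_fit(np.empty((4, 0)), np.array([1.0, 2.0, 3.0, 4.0]), term_ids=[])
        fit_b = ols_fit(np.empty((4, 0)), np.array([1.0, 2.0, 3.0, 4.0]), term_ids=[])
        fit_b.term_ids = ["phantom"]
        fit_b.beta_hat = np.array([0.0])
        assert model_aic(fit_b) - model_aic(fit_a) == pytest.approx(2.0)

    def test_halving_sse_shifts_by_n_log_half(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        fit = ols_fit(np.empty((4, 0)), y, term_ids=[])
        a1 = model_aic(fit)
        fit.sse /= 2
        assert model_aic(fit) - a1 == pytest.approx(4 * math.log(0.5))

    def test_perfect_fit_sentinel(self, rng):
        x = rng.standard_normal(10)
        fit = ols_fit(x, 2 * x)
        fit.sse = 0.0  # exact zero: numerical OLS leaves ~1e-30 roundoff
        assert model_aic(fit) == -math.inf


class TestStepwise:
    def test_no_candidates_gives_intercept_only(self, rng):
        y = rng.standard_normal(10)
        fit = stepwise_aic(np.empty((10, 0)), y, candidate_ids=[])
        assert fit.term_ids == []
        assert fit.beta0_hat == pytest.approx(y.mean())

    def test_matches_exhaustive_search_on_planted_fixture(self):
        rng = np.random.default_rng(7)
        n = 40
        X = rng.standard_normal((n, 4))
        y = 3.0 * X[:, 0] + rng.standard_normal(n)  # strong col 0, 3 noise cols
        labels = ["signal", "n1", "n2", "n3"]
        fit = stepwise_aic(X, y, candidate_ids=labels, start="full")
        oracle = exhaustive_min_aic(X, y, labels)
        assert set(fit.term_ids) == set(oracle.term_ids)
        assert fit.aic == pytest.approx(oracle.aic, abs=1e-9)
        assert "signal" in fit.term_ids

    @pytest.mark.parametrize("start", ["full", "null"])
    @pytest.mark.parametrize("seed", range(8))
    def test_local_optimality_on_random_fixtures(self, seed, start):
        """No single add or drop can lower the AIC of the returned model."""
        rng = np.random.default_rng(seed)
        n, m = 35, 6
        X = rng.standard_normal((n, m))
        beta = rng.standard_normal(m) * (rng.random(m) < 0.5)
        y = X @ beta + rng.standard_normal(n)
        labels = [f"c{j}" for j in range(m)]
        fit = stepwise_aic(X, y, candidate_ids=labels, start=start)
        chosen = [labels.index(t) for t in fit.term_ids]
        for j in range(m):
            if j in chosen:
                alt = [t for t in chosen if t != j]
            else:
                alt = sorted(chosen + [j])
            alt_fit = ols_fit(X[:, alt], y, [labels[t] for t in alt])
            assert alt_fit.aic >= fit.aic - 1e-9

    @pytest.mark.parametrize("seed", range(8))
    def test_full_start_agrees_with_exhaustive_where_path_unique(self, seed):
        rng = np.random.default_rng(100 + seed)
        n, m = 30, 5
        X = rng.standard_normal((n, m))
        y = X @ (rng.standard_normal(m) * 0.8) + rng.standard_normal(n)
        labels = [f"c{j}" for j in range(m)]
        fit = stepwise_aic(X, y, candidate_ids=labels, start="full")
        oracle = exhaustive_min_aic(X, y, labels)
        # greedy search may stop at a local optimum; when it differs from
        # the global one its AIC can only be higher, never lower
        assert fit.aic >= oracle.aic - 1e-9
        if set(fit.term_ids) != set(oracle.term_ids):
            assert fit.aic > oracle.aic - 1e-9

    def test_full_start_infeasible_with_too_many_candidates(self, rng):
        X = rng.standard_normal((6, 8))
        with pytest.raises(ValueError, match="null start"):
            stepwise_aic(X, rng.standard_normal(6), start="full")

    def test_stepwise_move_trace_recorded(self, rng):
        X = rng.standard_normal((30, 3))
        y = 2 * X[:, 0] + rng.standard_normal(30)
        fit = stepwise_aic(X, y, start="full")
        assert fit.aic_trace[0]["move"] == "start"
        aics = [t["aic"] for t in fit.aic_trace]
        assert all(b < a for a, b in zip(aics, aics[1:]))  # strict improvement


class TestFitMetrics:
    def test_perfect_fit(self, rng):
        y = rng.standard_normal(10)
        m = fit_metrics(y, y, p_used=2)
        assert m.adj_r2 == pytest.approx(1.0)
        assert m.rse == pytest.approx(0.0)
        assert m.pearson_r == pytest.approx(1.0)

    def test_null_model_adj_r2_zero(self, rng):
        y = rng.standard_normal(12)
        m = fit_metrics(y, np.full(12, y.mean()), p_used=0)
        assert m.adj_r2 == pytest.approx(0.0, abs=1e-12)

    def test_direct_formula_example(self):
        # n=10, SSE=2, SST=10, p=3 -> adj R2 = 1 - (2/6)/(10/9)
        y = np.array([3.0, -1.0, 0, 0, 0, 0, 0, 0, 0, -2.0])
        y = y - y.mean()
        y = y * np.sqrt(10 / (y @ y))  # SST = 10
        resid = np.zeros(10)
        resid[0] = np.sqrt(2.0)  # SSE = 2
        m = fit_metrics(y, y - resid, p_used=3)
        assert m.adj_r2 == pytest.approx(1 - (2 / 6) / (10 / 9), rel=1e-12)
        assert m.rse == pytest.approx(np.sqrt(2 / 6), rel=1e-12)

    def test_adj_r2_ranking_is_reverse_of_rse_ranking(self, rng):
        y = rng.standard_normal(20)
        metrics = [
            fit_metrics(y, y + rng.standard_normal(20) * s, p_used=2)
            for s in (0.1, 0.5, 1.0, 2.0)
        ]
        by_adj = sorted(range(4), key=lambda i: -metrics[i].adj_r2)
        by_rse = sorted(range(4), key=lambda i: metrics[i].rse)
        assert by_adj == by_rse

    def test_noise_predictor_lowers_adj_r2_at_fixed_sse(self, rng):
        y = rng.standard_normal(15)
        yhat = y + rng.standard_normal(15) * 0.3
        assert fit_metrics(y, yhat, p_used=3).adj_r2 < fit_metrics(y, yhat, p_used=2).adj_r2

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValueError, match="SST"):
            fit_metrics(np.ones(10), np.ones(10), p_used=1)
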