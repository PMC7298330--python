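"""Statistical-core tests: quadrature accuracy, recovery, nesting, EB estimates."""

import numpy as np
import pytest
from scipy import special, stats

from figmem.data import ResponseMatrix
from figmem.rpcm import (
    build_design,
    conditional_reliability,
    eb_person_estimates,
    easiness_table,
    fit_person_only,
    fit_rpcm,
    fit_rpcm_r,
    lrt,
    marginal_loglik,
    predict_mu,
)
from figmem.simulation import SimConfig, simulate_responses


def brute_force_loglik(data, beta, zeta, n_grid=200_001):
    """Independent oracle: fine trapezoid integration over theta."""
    sd = np.sqrt(zeta)
    t = np.linspace(-8 * sd, 8 * sd, n_grid)
    total = 0.0
    for v in range(data.n_persons):
        mu = np.exp(t[:, None] + beta[None, :])
        lp = (
            data.scores[v][None, :] * np.log(mu)
            - mu
            - special.gammaln(data.scores[v] + 1.0)[None, :]
        ).sum(axis=1)
        f = np.exp(lp) * stats.norm.pdf(t, 0.0, sd)
        total += np.log(np.trapezoid(f, t))
    return total


class TestMarginalLoglik:
    def test_matches_brute_force_oracle(self, tiny_data):
        beta = np.log([9.0, 7.0, 5.0])
        zeta = 0.229**2
        agq = marginal_loglik(beta, zeta, tiny_data, "items", quad_nodes=15)
        oracle = brute_force_loglik(tiny_data, beta, zeta)
        assert abs(agq - oracle) < 1e-6

    def test_degenerate_zero_variance_is_exact_poisson(self):
        y = np.array([[8], [12], [10], [9]])
        data = ResponseMatrix(scores=y, radical_levels=[1], incidental_ids=[1])
        val = marginal_loglik([np.log(10.0)], 0.0, data, "items")
        assert val == pytest.approx(stats.poisson.logpmf(y[:, 0], 10.0).sum(), abs=1e-12)

    def test_counts_scale_product_enters_pmf(self):
        # ability 2 x easiness 5 => expected score 10
        y = np.array([[7], [13]])
        data = ResponseMatrix(scores=y, radical_levels=[1], incidental_ids=[1])
        val = marginal_loglik([np.log(2.0) + np.log(5.0)], 0.0, data, "items")
        assert val == pytest.approx(stats.poisson.logpmf(y[:, 0], 10.0).sum(), abs=1e-12)

    def test_node_count_insensitivity(self, study_data):
        beta = np.log(study_data.scores.mean(axis=0))
        ll15 = marginal_loglik(beta, 0.05, study_data, "items", quad_nodes=15)
        ll61 = marginal_loglik(beta, 0.05, study_data, "items", quad_nodes=61)
        assert abs(ll15 - ll61) < 1e-4

    def test_rejects_bad_inputs(self, tiny_data):
        with pytest.raises(ValueError):
            marginal_loglik([np.nan, 0, 0], 0.1, tiny_data, "items")
        with pytest.raises(ValueError):
            marginal_loglik([1.0, 1.0, 1.0], -0.1, tiny_data, "items")
        with pytest.raises(ValueError):
            marginal_loglik([1.0, 1.0, 1.0], 0.1, tiny_data, "items", quad_nodes=2)


class TestFits:
    def test_person_only_recovers_common_mean(self):
        cfg = SimConfig(n_persons=400, item_log_easiness=np.log([8.0] * 5),
                        person_sd=0.2, seed=1, censor_at_max=False)
        data, _ = simulate_responses(cfg)
        fit = fit_person_only(data)
        assert fit.n_params == 2
        # intercept close to the common log mean (mixture mean exp(b + z/2))
        implied = np.exp(fit.beta[0] + fit.zeta / 2.0)
        se = data.scores.mean(axis=1).std(ddof=1) / np.sqrt(400)
        assert abs(implied - data.scores.mean()) < 3 * se + 0.05

    def test_loglik_nesting(self, study_fits):
        assert study_fits["person_only"].loglik <= study_fits["rpcm_r"].loglik
        assert study_fits["rpcm_r"].loglik <= study_fits["rpcm"].loglik

    def test_rpcm_recovery_within_3_mc_se(self):
        rng_items = np.log([10.8, 9.1, 7.1, 8.0, 11.5])
        cfg = SimConfig(n_persons=500, item_log_easiness=rng_items,
                        person_sd=0.25, seed=3, censor_at_max=False)
        data, truth = simulate_responses(cfg)
        fit = fit_rpcm(data)
        se = fit.beta_se()
        assert np.all(np.abs(fit.beta - rng_items) < 3 * se)
        assert fit.converged

    def test_item_column_permutation_invariance(self, study_data):
        fit = fit_rpcm(study_data)
        perm = np.array([4, 0, 7, 2, 8, 1, 5, 3, 6])
        fit_p = fit_rpcm(study_data.subset_items(perm))
        by_label = dict(zip(fit.param_names, fit.beta))
        by_label_p = dict(zip(fit_p.param_names, fit_p.beta))
        for k in by_label:
            assert by_label[k] == pytest.approx(by_label_p[k], abs=1e-5)

    def test_rpcm_r_single_family_equals_person_only(self):
        cfg = SimConfig(n_persons=100, item_log_easiness=np.log([9.0] * 4),
                        radical_levels=np.array([2, 2, 2, 2]), person_sd=0.2,
                        seed=9, censor_at_max=False)
        data, _ = simulate_responses(cfg)
        f_r = fit_rpcm_r(data)
        f_0 = fit_person_only(data)
        assert f_r.n_params == f_0.n_params
        assert f_r.loglik == pytest.approx(f_0.loglik, abs=1e-5)

    def test_all_zero_scores_degenerate(self):
        data = ResponseMatrix(scores=np.zeros((5, 3), dtype=int),
                              radical_levels=[1, 2, 3], incidental_ids=[1, 1, 1])
        with pytest.raises(ValueError, match="degenerate"):
            fit_rpcm(data)

    def test_easiness_table_positive_ci(self, study_fits):
        rows = easiness_table(study_fits["rpcm"])
        for r in rows:
            assert 0 < r["ci_low"] < r["easiness"] < r["ci_high"]


class TestLRT:
    def test_model_vs_itself_is_null(self, study_fits):
        chi2, df, p = lrt(study_fits["rpcm"], study_fits["rpcm"])
        assert chi2 == 0.0 and df == 0 and p == 1.0

    def test_statistic_nonnegative_and_df(self, study_fits):
        chi2, df, p = lrt(study_fits["person_only"], study_fits["rpcm"])
        assert chi2 >= 0.0 and df == 8
        chi2, df, p = lrt(study_fits["rpcm_r"], study_fits["rpcm"])
        assert chi2 >= 0.0 and df == 6

    def test_usage_errors(self, study_fits, tiny_data):
        with pytest.raises(ValueError, match="fewer"):
            lrt(study_fits["rpcm"], study_fits["person_only"])
        other = fit_person_only(tiny_data)
        with pytest.raises(ValueError, match="same data"):
            lrt(other, study_fits["rpcm"])


class TestPersonEstimates:
    def test_reliability_half_when_posterior_var_equals_zeta(self):
        assert conditional_reliability(0.05, np.sqrt(0.05)) == pytest.approx(0.5)

    def test_reliability_decreasing_in_se(self):
        rels = [conditional_reliability(0.05, s) for s in (0.05, 0.1, 0.2, 0.3)]
        assert all(a > b for a, b in zip(rels, rels[1:]))

    def test_theta_monotone_in_total_score(self, study_fits, study_data):
        est = eb_person_estimates(study_fits["rpcm"], study_data)
        theta = np.array([e.theta_log for e in est])
        totals = study_data.total_scores()
        order = np.argsort(totals, kind="stable")
        # identical totals => identical estimates; otherwise increasing
        t_sorted = theta[order]
        tot_sorted = totals[order]
        for a, b in zip(range(len(order) - 1), range(1, len(order))):
            if tot_sorted[b] > tot_sorted[a]:
                assert t_sorted[b] > t_sorted[a]
            else:
                assert t_sorted[b] == pytest.approx(t_sorted[a], abs=1e-8)

    def test_person_estimates_rpcm_vs_rpcm_r_nearly_identical(
        self, study_fits, study_data
    ):
        est_i = eb_person_estimates(study_fits["rpcm"], study_data)
        est_r = eb_person_estimates(study_fits["rpcm_r"], study_data)
        r = np.corrcoef(
            [e.theta_log for e in est_i], [e.theta_log for e in est_r]
        )[0, 1]
        assert r > 0.999

    def test_reliabilities_in_unit_interval(self, study_fits, study_data):
        est = eb_person_estimates(study_fits["rpcm"], study_data)
        assert all(0.0 <= e.reliability <= 1.0 for e in est)


class TestPredictMu:
    def test_average_ability_returns_counts_easiness(self, study_fits):
        fit = study_fits["rpcm"]
        for i in range(3):
            assert predict_mu(fit, 0.0, i) == pytest.approx(np.exp(fit.beta[i]))

    def test_matches_exp_sum_oracle(self, study_fits):
        fit = study_fits["rpcm"]
        rng = np.random.default_rng(0)
        for _ in range(20):
            th = rng.normal(0, 0.3)
            i = int(rng.integers(fit.design.shape[1]))
            assert predict_mu(fit, th, i) == pytest.approx(
                np.exp(th + fit.design[0, i] @ fit.beta)
            )

    def test_ability_two_easiness_five_gives_ten(self):
        y = np.array([[10, 9], [11, 10]])
        data = ResponseMatrix(scores=y, radical_levels=[1, 1], incidental_ids=[1, 2])
        fit = fit_rpcm(data)
        fit.beta[0] = np.log(5.0)
        assert predict_mu(fit, np.log(2.0), 0) == pytest.approx(10.0)


def test_design_shapes(study_data):
    X, names = build_design(study_data, "items")
    assert X.shape == (208, 9, 9) and len(names) == 9
    X, names = build_design(study_data, "radical")
    assert X.shape == (208, 9, 3) and names == ["eta1", "eta2", "eta3"]
    X, names = build_design(study_data, "intercept")
    assert X.shape == (208, 9, 1)
    with pytest.raises(ValueError):
        build_design(study_data, "quadratic")
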