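"""Diagnostics tests: residuals, dispersion, CAF, item fit, DIF, descriptives."""

import numpy as np
import pandas as pd
import pytest

from figmem.data import ResponseMatrix
from figmem.diagnostics import (
    caf_expected_frequencies,
    cronbach_alpha,
    descriptives,
    dif_analysis,
    dispersion_index,
    item_fit_chisq,
    pearson_residuals,
)
from figmem.rpcm import build_design, fit_person_only, fit_rpcm, fit_with_design
from figmem.simulation import SimConfig, simulate_responses


class TestPearsonResiduals:
    def test_residual_zero_where_observed_equals_predicted(self, study_fits, study_data):
        resid, long = pearson_residuals(study_fits["rpcm"], study_data)
        close = np.abs(long["observed"] - long["predicted"]) < 1e-9
        assert np.all(np.abs(long.loc[close, "residual"]) < 1e-9)
        assert resid.shape == study_data.scores.shape

    def test_most_residuals_within_two(self, study_fits, study_data):
        resid, _ = pearson_residuals(study_fits["rpcm"], study_data)
        assert (np.abs(resid) <= 2.0).mean() > 0.9

    def test_definitional_link_to_dispersion(self, study_fits, study_data):
        fit = study_fits["rpcm"]
        resid, _ = pearson_residuals(fit, study_data)
        phi = dispersion_index(fit, study_data)
        n_obs = study_data.n_obs
        assert phi == pytest.approx(
            (resid**2).mean() * n_obs / (n_obs - fit.n_params), rel=1e-12
        )


class TestDispersionIndex:
    def test_marginal_phi_near_one_on_model_exact_data(self):
        # Poisson-simulated data from known parameters: the marginal variant
        # concentrates at 1
        phis = []
        for s in range(30):
            cfg = SimConfig(n_persons=150, item_log_easiness=np.log([9.0, 7.0, 11.0]),
                            person_sd=0.2, seed=600 + s, censor_at_max=False)
            data, _ = simulate_responses(cfg)
            phis.append(dispersion_index(fit_rpcm(data), data, kind="marginal"))
        phis = np.array(phis)
        se = phis.std(ddof=1) / np.sqrt(len(phis))
        assert abs(phis.mean() - 1.0) < 3 * se + 0.02

    def test_conditional_phi_below_marginal(self, study_fits, study_data):
        # EB conditioning absorbs person variation, pushing the conditional
        # variant below the marginal one
        cond = dispersion_index(study_fits["rpcm"], study_data)
        marg = dispersion_index(study_fits["rpcm"], study_data, kind="marginal")
        assert cond < marg

    def test_censored_study_data_underdispersed(self, study_fits, study_data):
        assert dispersion_index(study_fits["rpcm"], study_data) < 1.0

    def test_unknown_kind(self, study_fits, study_data):
        with pytest.raises(ValueError, match="kind"):
            dispersion_index(study_fits["rpcm"], study_data, kind="robust")


class TestCAF:
    def test_expected_frequencies_normalise(self, study_fits, study_data):
        caf = caf_expected_frequencies(study_fits["rpcm"], study_data,
                                       score_range=np.arange(0, 80))
        assert caf["expected"].sum() == pytest.approx(study_data.n_obs, abs=1e-6)
        assert caf["observed"].sum() == study_data.n_obs

    def test_person_only_underestimates_low_scores(self):
        # heterogeneous item difficulty: ignoring it misses low-score mass
        cfg = SimConfig(n_persons=300, item_log_easiness=np.log([14.0, 9.0, 4.0]),
                        person_sd=0.2, seed=77, censor_at_max=False)
        data, _ = simulate_responses(cfg)
        f_null = fit_person_only(data)
        f_rpcm = fit_rpcm(data)
        lo = np.arange(0, 5)
        caf_null = caf_expected_frequencies(f_null, data, score_range=lo)
        caf_rpcm = caf_expected_frequencies(f_rpcm, data, score_range=lo)
        assert caf_null["expected"].sum() < caf_rpcm["expected"].sum()
        assert caf_rpcm["expected"].sum() <= caf_rpcm["observed"].sum() * 1.5

    def test_rpcm_and_rpcm_r_curves_nearly_coincide(self, study_fits, study_data):
        grid = np.arange(0, 25)
        c1 = caf_expected_frequencies(study_fits["rpcm"], study_data, grid)
        c2 = caf_expected_frequencies(study_fits["rpcm_r"], study_data, grid)
        max_diff = np.abs(c1["expected"] - c2["expected"]).max()
        assert max_diff < 0.02 * study_data.n_obs


class TestItemFit:
    def test_invariant_to_person_order(self, study_fits, study_data):
        fit = study_fits["rpcm"]
        res = item_fit_chisq(fit, study_data)
        perm = np.random.default_rng(1).permutation(study_data.n_persons)
        shuffled = ResponseMatrix(
            scores=study_data.scores[perm],
            radical_levels=study_data.radical_levels,
            incidental_ids=study_data.incidental_ids,
            item_ids=list(study_data.item_ids),
            person_ids=[study_data.person_ids[k] for k in perm],
            max_score=study_data.max_score,
        )
        fit_s = fit_rpcm(shuffled)
        res_s = item_fit_chisq(fit_s, shuffled)
        assert np.allclose(res.chi2, res_s.chi2, atol=1e-6)

    def test_df_and_grouping(self, study_fits, study_data):
        res = item_fit_chisq(study_fits["rpcm"], study_data, n_groups=5)
        assert res.df == 5
        assert np.all(res.chi2 >= 0.0)
        counts = np.bincount(res.group_assignment, minlength=5)
        assert counts.sum() == study_data.n_persons and (counts > 0).all()

    def test_null_calibration_approximate(self):
        # rejection rate at alpha=.05 lands in a loose nominal band when the
        # fitted model is the generating model
        rej, total = 0, 0
        for s in range(20):
            cfg = SimConfig(n_persons=208,
                            item_log_easiness=np.log([10.8, 9.1, 7.1, 9.5, 8.2]),
                            person_sd=0.229, seed=900 + s, censor_at_max=False)
            data, _ = simulate_responses(cfg)
            res = item_fit_chisq(fit_rpcm(data), data)
            rej += (res.p_values < 0.05).sum()
            total += data.n_items
        assert 0.0 <= rej / total <= 0.12

    def test_precondition_errors(self, study_fits, study_data):
        with pytest.raises(ValueError):
            item_fit_chisq(study_fits["rpcm"], study_data, n_groups=1)


class TestDIF:
    def test_group_designs_reduce_to_items_for_single_group(self, study_data):
        from figmem.diagnostics import _dif_designs

        with pytest.raises(ValueError, match="2 groups"):
            _dif_designs(study_data, np.ones(study_data.n_persons, dtype=int))

    def test_null_groups_non_significant(self, study_data, study_fits):
        # labels permuted independently of the data: no DIF by construction
        labels = np.random.default_rng(5).permutation(study_data.groups)
        res = dif_analysis(study_data, group_labels=labels,
                           base_fit=study_fits["rpcm"])
        chi2_int, df_int, p_int = res.lrt_interactions
        chi2_grp, df_grp, p_grp = res.lrt_groups
        assert df_int == 16 and df_grp == 2
        assert p_int > 0.001 and p_grp > 0.001
        inter = res.coef_table[res.coef_table["is_interaction"]]
        assert len(inter) == 16

    def test_detects_injected_dif(self):
        cfg = SimConfig(n_persons=300, item_log_easiness=np.log([9.0, 9.0, 9.0]),
                        person_sd=0.15, seed=13, censor_at_max=False)
        data, _ = simulate_responses(cfg)
        groups = np.repeat([1, 2], 150)
        # make item 3 much harder for group 2
        y = data.scores.copy()
        y[150:, 2] = np.random.default_rng(0).poisson(4.0, 150)
        data = ResponseMatrix(scores=y, radical_levels=data.radical_levels,
                              incidental_ids=data.incidental_ids, groups=groups,
                              max_score=int(y.max()))
        res = dif_analysis(data)
        assert res.lrt_interactions[2] < 0.001
        worst = res.coef_table[res.coef_table["is_interaction"]].nsmallest(1, "p_value")
        assert "group2" in worst.iloc[0]["term"]

    def test_requires_groups(self, study_data):
        bare = ResponseMatrix(scores=study_data.scores,
                              radical_levels=study_data.radical_levels,
                              incidental_ids=study_data.incidental_ids)
        with pytest.raises(ValueError, match="group"):
            dif_analysis(bare)


class TestDescriptives:
    def test_matches_manual_columns(self, study_data):
        table = descriptives(study_data)
        y = study_data.scores
        for i in range(study_data.n_items):
            row = table.iloc[i]
            assert row["mean"] == pytest.approx(y[:, i].mean())
            assert row["sd"] == pytest.approx(y[:, i].std(ddof=1))
            assert row["median"] == pytest.approx(np.median(y[:, i]))
            assert row["min"] == y[:, i].min() and row["max"] == y[:, i].max()
            rest = y.sum(axis=1) - y[:, i]
            assert row["discrimination"] == pytest.approx(
                np.corrcoef(y[:, i], rest)[0, 1]
            )

    def test_constant_column_flagged(self):
        y = np.column_stack([np.full(30, 7), np.random.default_rng(2).poisson(8, 30)])
        data = ResponseMatrix(scores=y, radical_levels=[1, 1], incidental_ids=[1, 2])
        with pytest.warns(UserWarning, match="zero variance"):
            table = descriptives(data)
        assert np.isnan(table.iloc[0]["discrimination"])
        assert table.iloc[0]["sd"] == 0.0 and table.iloc[0]["min"] == table.iloc[0]["max"]


class TestCronbachAlpha:
    def test_duplicated_columns_give_one(self):
        col = np.random.default_rng(3).poisson(9, 100)
        data = ResponseMatrix(scores=np.column_stack([col, col]),
                              radical_levels=[1, 1], incidental_ids=[1, 2])
        alpha, _ = cronbach_alpha(data)
        assert alpha == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(4)
        y = rng.poisson(8, size=(10_000, 6))
        data = ResponseMatrix(scores=np.minimum(y, 20),
                              radical_levels=[1] * 6,
                              incidental_ids=list(range(1, 7)))
        alpha, _ = cronbach_alpha(data)
        assert abs(alpha) < 0.05

    def test_ci_brackets_estimate(self, study_data):
        alpha, (lo, hi) = cronbach_alpha(study_data)
        assert lo < alpha < hi
        assert 0.5 < alpha < 1.0

    def test_errors(self):
        one = ResponseMatrix(scores=np.random.default_rng(0).poisson(5, (10, 1)),
                             radical_levels=[1], incidental_ids=[1])
        with pytest.raises(ValueError):
            cronbach_alpha(one)
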