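"""Analysis stack: scaling, orthogonal polynomials, LM, selection, effect sizes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from srmotion.experiment import DOT_LEVELS
from srmotion.inference import (
    DesignSpec,
    OrthoPoly,
    aicc,
    akaike_weights,
    dichotomize_age,
    evaluate_quartic,
    fit_logistic_glmm,
    fit_threshold_lm,
    marginal_r2,
    model_selection_table,
    orthogonal_poly,
    part_r2,
    peak_location,
    predict_accuracy,
    simulated_residual_ks,
    wald_type3,
    zscale,
)


class TestZscale:
    def test_simple_triplet(self):
        z, c, s = zscale([1.0, 2.0, 3.0])
        assert np.allclose(z, [-1, 0, 1])
        assert (c, s) == (2.0, 1.0)

    def test_output_standardised(self, rng):
        x = rng.normal(3, 7, 200)
        z, _, _ = zscale(x)
        assert z.mean() == pytest.approx(0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1, abs=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            zscale([4.0, 4.0, 4.0])


def gram_schmidt_basis(x, degree):
    """Independent modified Gram-Schmidt oracle for the poly contrast."""
    x = np.asarray(x, dtype=float)
    V = np.column_stack([x**k for k in range(degree + 1)])
    Q = []
    for j in range(degree + 1):
        v = V[:, j].copy()
        for q in Q:
            v -= (q @ v) * q
        Q.append(v / np.linalg.norm(v))
    return np.column_stack(Q[1:])


class TestOrthogonalPoly:
    def test_linear_triplet(self):
        basis, _ = orthogonal_poly([1.0, 2.0, 3.0], 1)
        assert np.allclose(np.abs(basis[:, 0]), [0.70711, 0, 0.70711], atol=1e-5)

    def test_gram_identity_degree_four(self, rng):
        x = rng.uniform(0, 5, 40)
        basis, _ = orthogonal_poly(x, 4)
        gram = basis.T @ basis
        assert np.allclose(gram, np.eye(4), atol=1e-10)
        assert np.allclose(basis.sum(axis=0), 0, atol=1e-10)

    def test_matches_gram_schmidt_on_log_levels(self):
        x = np.log(np.array(DOT_LEVELS, dtype=float))
        basis, _ = orthogonal_poly(x, 2)
        oracle = gram_schmidt_basis(x, 2)
        for j in range(2):
            col, ref = basis[:, j], oracle[:, j]
            sign = np.sign(col @ ref)
            assert np.allclose(col, sign * ref, atol=1e-10)

    def test_prediction_reuses_fitted_basis(self):
        x = np.log(np.array(DOT_LEVELS, dtype=float))
        op = OrthoPoly(x, 3)
        sub = op.transform(x[3:7])
        assert np.allclose(sub, op.transform(x)[3:7], atol=1e-12)

    def test_insufficient_distinct_values(self):
        with pytest.raises(ValueError):
            orthogonal_poly([1.0, 1.0, 2.0], 2)


class TestThresholdLm:
    def _table(self, n, slope, interaction, rng, sd=0.2):
        age = rng.uniform(18, 82, n)
        group = rng.choice([100, 400], n)
        g = np.where(group == 100, 1.0, -1.0)
        ln_thr = 2.8 + slope * (age - 50) / 19 + interaction * (age - 50) / 19 * g
        ln_thr += rng.normal(0, sd, n)
        return pd.DataFrame(
            {"age": age, "group_dots": group, "threshold_pct": np.exp(ln_thr)}
        )

    def test_recovers_slope_and_interaction(self, rng):
        reps = []
        for _ in range(100):
            df = self._table(214, slope=0.3, interaction=0.05, rng=rng)
            fit = fit_threshold_lm(df)
            reps.append([fit.params["age"], fit.params["age:group"]])
        means = np.mean(reps, axis=0)
        # age was drawn uniform(18,82): SD ~ 18.5, so scaled-age slope ~ 0.3*18.5/19
        assert means[0] == pytest.approx(0.3 * 18.5 / 19, abs=0.02)
        assert means[1] == pytest.approx(0.05 * 18.5 / 19, abs=0.02)

    def test_null_interaction_f_is_calibrated(self, rng):
        pvals = []
        for _ in range(200):
            df = self._table(80, slope=0.2, interaction=0.0, rng=rng)
            fit = fit_threshold_lm(df)
            pvals.append(fit.anova.loc[fit.anova.term == "age:group", "p"].iloc[0])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_marginal_means_backtransform(self, rng):
        df = self._table(300, slope=0.0, interaction=0.0, rng=rng, sd=0.05)
        fit = fit_threshold_lm(df)
        for _, row in fit.emmeans.iterrows():
            assert row.emm_dots == pytest.approx(np.exp(row.emm_ln))

    def test_eta_squared_in_unit_interval(self, rng):
        fit = fit_threshold_lm(self._table(100, 0.3, 0.1, rng))
        assert ((fit.anova.partial_eta2 >= 0) & (fit.anova.partial_eta2 <= 1)).all()


class TestAicc:
    def test_direct_formula(self):
        assert aicc(-10.0, 2, 10) == pytest.approx(25.7143, abs=1e-4)

    def test_large_n_limit_is_aic(self):
        assert aicc(-100.0, 5, 10**9) == pytest.approx(210.0, abs=1e-3)

    def test_matches_recomputation(self, rng):
        for _ in range(20):
            ll, K, n = rng.normal(-500, 100), int(rng.integers(2, 12)), int(rng.integers(50, 500))
            assert aicc(ll, K, n) == pytest.approx(
                -2 * ll + 2 * K + 2 * K * (K + 1) / (n - K - 1)
            )

    def test_small_sample_guard(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)


class TestAkaikeWeights:
    def test_equal_models_share_weight(self):
        assert np.allclose(akaike_weights([10.0, 10.0, 10.0, 10.0]), 0.25)

    def test_delta_two(self):
        w = akaike_weights([100.0, 102.0])
        assert np.allclose(w, [0.7311, 0.2689], atol=1e-4)

    def test_weights_sum_to_one(self, rng):
        for _ in range(20):
            w = akaike_weights(rng.uniform(1000, 2000, 5))
            assert w.sum() == pytest.approx(1.0, abs=1e-12)
            assert (w >= 0).all()

    def test_huge_deltas_stay_finite(self):
        w = akaike_weights([0.0, 5000.0])
        assert np.allclose(w, [1.0, 0.0])


@pytest.fixture(scope="module")
def glmm_fits(small_cohort):
    kept, trials = small_cohort["kept"], small_cohort["block2"]
    fits = [
        fit_logistic_glmm(trials, kept, DesignSpec(degree=d), nodes=7,
                          compute_vcov=(d == 4))
        for d in (1, 2, 3, 4)
    ]
    return fits


class TestModelSelection:
    def test_single_fit_table(self, glmm_fits):
        tab = model_selection_table(glmm_fits[:1])
        assert tab.Delta_AICc.iloc[0] == 0.0
        assert tab.AICcWt.iloc[0] == pytest.approx(1.0)

    def test_table_shape_and_invariants(self, glmm_fits):
        tab = model_selection_table(glmm_fits)
        assert list(tab.columns) == ["Model", "K", "AICc", "Delta_AICc", "AICcWt", "Cum_Wt", "LL"]
        assert (tab.AICc.diff().dropna() >= 0).all()
        assert tab.AICcWt.sum() == pytest.approx(1.0, abs=1e-12)
        assert tab.Cum_Wt.is_monotonic_increasing
        assert tab.Cum_Wt.iloc[-1] == pytest.approx(1.0, abs=1e-12)
        assert sorted(tab.K) == [5, 7, 9, 11]

    def test_order_invariance(self, glmm_fits):
        a = model_selection_table(glmm_fits)
        b = model_selection_table(glmm_fits[::-1])
        pd.testing.assert_frame_equal(a, b)

    def test_loglik_monotone_in_degree(self, glmm_fits):
        lls = [f.loglik for f in glmm_fits]
        assert all(b >= a - 1e-4 for a, b in zip(lls, lls[1:]))

    def test_mismatched_data_rejected(self, glmm_fits, small_cohort):
        other = fit_logistic_glmm(
            small_cohort["block2"].iloc[: 280 * 10], small_cohort["kept"],
            DesignSpec(degree=1), nodes=3, compute_vcov=False,
        )
        with pytest.raises(ValueError):
            model_selection_table([glmm_fits[0], other])


class TestWald:
    def test_matches_quadratic_form_oracle(self, glmm_fits):
        fit = glmm_fits[3]
        tab = wald_type3(fit)
        for _, row in tab.iterrows():
            sl = fit.term_slices[row.term]
            b = fit.beta[sl]
            V = fit.vcov[sl, sl]
            assert row.chi2 == pytest.approx(float(b @ np.linalg.inv(V) @ b), rel=1e-8)
            assert row.df == b.size

    def test_single_coefficient_identity(self, glmm_fits):
        fit = glmm_fits[3]
        tab = wald_type3(fit).set_index("term")
        sl = fit.term_slices["age"]
        z2 = (fit.beta[sl][0] / np.sqrt(fit.vcov[sl, sl][0, 0])) ** 2
        assert tab.loc["age", "chi2"] == pytest.approx(z2, rel=1e-8)


class TestMarginalR2:
    def test_zero_for_null_model(self):
        from srmotion.glmm import GlmmFit
        fit = GlmmFit(beta=np.zeros(3), vcov=np.eye(3), sigma_u2=0.5, loglik=0.0,
                      K=4, n_obs=100, converged=True)
        X = np.random.default_rng(0).normal(size=(50, 3))
        assert marginal_r2(fit, X) == 0.0

    def test_balanced_binary_formula(self):
        from srmotion.glmm import GlmmFit
        fit = GlmmFit(beta=np.array([1.0]), vcov=np.eye(1), sigma_u2=0.0, loglik=0.0,
                      K=2, n_obs=100, converged=True)
        X = np.array([[0.5], [-0.5]] * 50)
        assert marginal_r2(fit, X) == pytest.approx(0.25 / (0.25 + np.pi**2 / 3), abs=1e-9)

    def test_matches_first_principles(self, glmm_fits):
        fit = glmm_fits[3]
        X = fit.meta["X"]
        vf = np.var(X @ fit.beta)
        assert marginal_r2(fit) == pytest.approx(vf / (vf + fit.sigma_u2 + np.pi**2 / 3))


def test_part_r2_numerosity_dominates_age(small_cohort):
    kept, trials = small_cohort["kept"], small_cohort["block2"]
    design = DesignSpec(degree=4)
    d_n = part_r2(trials, kept, design, "n_dots", nodes=5)
    d_age = part_r2(trials, kept, design, "age", nodes=5)
    assert d_n > d_age
    assert d_n > 0


class TestPredictionAndPeaks:
    def test_prediction_matches_manual_reconstruction(self, glmm_fits):
        fit = glmm_fits[3]
        grid = np.array([25.0, 83.0, 239.0, 999.0, 1900.0])
        pred = predict_accuracy(fit, 40.0, grid)
        op = fit.meta["poly"]
        basis = op.transform(np.log(grid))
        a = (40.0 - fit.meta["age_center"]) / fit.meta["age_spread"]
        X = np.hstack([np.ones((5, 1)), basis, np.full((5, 1), a), basis * a])
        manual = 1 / (1 + np.exp(-(X @ fit.beta)))
        assert np.allclose(pred, manual, atol=1e-12)

    def test_degree_one_curve_is_monotone(self, glmm_fits):
        fit = glmm_fits[0]
        grid = np.geomspace(20, 2000, 100)
        pred = predict_accuracy(fit, 40.0, grid)
        diffs = np.diff(pred)
        assert (diffs >= -1e-12).all() or (diffs <= 1e-12).all()

    def test_peak_requires_degree_two(self, glmm_fits):
        with pytest.raises(ValueError):
            peak_location(glmm_fits[0], 40.0)

    def test_quartic_grid_peak_matches_derivative_root(self, glmm_fits):
        fit = glmm_fits[3]
        pk = peak_location(fit, 40.0)
        # derivative-root oracle on the link scale, restricted to the range
        op = fit.meta["poly"]
        a = (40.0 - fit.meta["age_center"]) / fit.meta["age_spread"]
        logs = np.linspace(np.log(20), np.log(2000), 400_001)
        basis = op.transform(logs)
        X = np.hstack([np.ones((len(logs), 1)), basis, np.full((len(logs), 1), a), basis * a])
        eta = X @ fit.beta
        assert abs(np.log(pk.peak_n_dots) - logs[np.argmax(eta)]) < 0.01

    def test_extrapolation_warns(self, glmm_fits):
        with pytest.warns(UserWarning):
            predict_accuracy(glmm_fits[3], 40.0, np.array([10.0, 100.0]))


class TestEvaluateQuartic:
    def test_origin_values(self):
        assert evaluate_quartic([0.76, -0.21, -0.35, -0.032, 0.021], 0.0) == 0.76
        assert evaluate_quartic([0.75, -0.5, -0.38, -0.18, 0.031], 0.0) == 0.75

    def test_zero_polynomial(self):
        assert evaluate_quartic([0, 0, 0, 0, 0], 3.7) == 0.0

    def test_horner_equivalence(self, rng):
        c = rng.normal(size=5)
        x = 1.3
        assert evaluate_quartic(c, x) == pytest.approx(np.polyval(c[::-1], x))


class TestDichotomize:
    @pytest.mark.parametrize("age, label", [(35, "younger"), (65, "older"), (50, "older")])
    def test_boundaries(self, age, label):
        assert dichotomize_age([age])[0] == label


class TestResidualKs:
    def test_statistic_in_unit_interval(self, glmm_fits, small_cohort):
        D, p = simulated_residual_ks(
            glmm_fits[3], small_cohort["block2"], small_cohort["kept"],
            n_sim=60, seed=0,
        )
        assert 0 <= D <= 1 and 0 <= p <= 1

    def test_correct_model_not_rejected(self, glmm_fits, small_cohort):
        """Data simulated from the fitted model itself passes the check."""
        rng = np.random.default_rng(8)
        fit = glmm_fits[3]
        kept, trials = small_cohort["kept"], small_cohort["block2"]
        from srmotion.inference import prepare_trials
        from scipy.special import expit
        agg = prepare_trials(trials, kept)
        X = fit.meta["X"]
        pid = agg.participant_id.to_numpy()
        _, gidx = np.unique(pid, return_inverse=True)
        pvals = []
        for _ in range(10):
            u = rng.normal(0, np.sqrt(fit.sigma_u2), gidx.max() + 1)
            ysim = rng.binomial(agg.trials.to_numpy(), expit(X @ fit.beta + u[gidx]))
            sim_trials = agg.assign(successes=ysim)
            rows = []
            for _, r in sim_trials.iterrows():
                rows.append(pd.DataFrame({
                    "participant_id": r.participant_id,
                    "n_dots": r.n_dots,
                    "correct": [True] * int(r.successes) + [False] * int(r.trials - r.successes),
                }))
            flat = pd.concat(rows, ignore_index=True)
            refit = fit_logistic_glmm(flat, kept, DesignSpec(degree=4), nodes=5,
                                      compute_vcov=False)
            _, p = simulated_residual_ks(refit, flat, kept, n_sim=80, seed=rng)
            pvals.append(p)
        assert np.median(pvals) > 0.05

    def test_misspecified_model_detected(self, glmm_fits, small_cohort):
        """A linear fit to strongly curved data yields larger deviations."""
        lin, qua = glmm_fits[0], glmm_fits[3]
        D_lin, _ = simulated_residual_ks(
            lin, small_cohort["block2"], small_cohort["kept"], n_sim=80, seed=1)
        D_qua, _ = simulated_residual_ks(
            qua, small_cohort["block2"], small_cohort["kept"], n_sim=80, seed=1)
        assert D_lin > D_qua


from hypothesis import given, settings, strategies as st


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.lists(st.floats(min_value=0, max_value=1e6, allow_nan=False),
                min_size=1, max_size=8))
def test_akaike_weight_properties_hold_for_any_aicc_list(aiccs):
    w = akaike_weights(aiccs)
    assert w.sum() == pytest.approx(1.0, abs=1e-9)
    assert (w >= 0).all()
    assert w[int(np.argmin(aiccs))] == w.max()
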