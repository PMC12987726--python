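"""dCRT association engine, resamplers, mocks, FDR and survival."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pancansig as ps
from pancansig.associations import (AssociationTask, ConvergenceError,
                                    binarize_activity, bh_fdr,
                                    cph_survival_test, dcrt_pvalue,
                                    fit_nbp_glm, mock_calibration,
                                    prepare_score, resample_target,
                                    run_association, score_z, score_z_batch,
                                    wilks_logistic)
from pancansig.synthetic import gen_covariates


@pytest.fixture(scope="module")
def covariates():
    return gen_covariates(400, seed=9)


class TestBinarize:
    @pytest.mark.parametrize("activity,expected", [
        ([0, 0, 5, 10], [0, 0, 1, 1]),
        ([0, 0, 0], [0, 0, 0]),
        # median 3; the rule is A_i < median, so 3 itself maps to 1
        ([1, 2, 3, 4, 100], [0, 0, 1, 1, 1]),
    ])
    def test_examples(self, activity, expected):
        np.testing.assert_array_equal(binarize_activity(np.array(activity)),
                                      expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            binarize_activity(np.array([]))


class TestCountGlm:
    def test_nb_parameter_recovery(self, covariates):
        rng = np.random.default_rng(3)
        Q = covariates.to_numpy()
        X = rng.binomial(1, 0.4, len(Q)).astype(float)
        mu = np.exp(2.0 + 0.3 * Q[:, 0] + 0.5 * X)
        y = rng.negative_binomial(2.0, 2.0 / (2.0 + mu))
        design = np.column_stack([np.ones(len(Q)), Q, X])
        fit = fit_nbp_glm(y, design)
        assert fit.family == "nb"
        se = np.sqrt(np.diag(fit.result.cov_params()))[-2]
        assert abs(fit.params[-1] - 0.5) < 3 * se

    def test_null_effect_near_zero(self, covariates):
        rng = np.random.default_rng(4)
        Q = covariates.to_numpy()
        mu = np.exp(2.0 + 0.3 * Q[:, 0])
        y = rng.negative_binomial(2.0, 2.0 / (2.0 + mu))
        X = rng.binomial(1, 0.4, len(Q)).astype(float)
        design = np.column_stack([np.ones(len(Q)), Q, X])
        fit = fit_nbp_glm(y, design)
        se = np.sqrt(np.diag(fit.result.cov_params()))[-2]
        assert abs(fit.params[-1]) < 3 * se

    def test_constant_activity_raises(self, covariates):
        design = np.column_stack([np.ones(len(covariates)), covariates.to_numpy()])
        with pytest.raises(ConvergenceError):
            fit_nbp_glm(np.full(len(covariates), 7.0), design)

    def test_singular_design_identified(self, covariates):
        Q = covariates.to_numpy()
        design = np.column_stack([np.ones(len(Q)), Q, Q[:, 0]])  # duplicate column
        with pytest.raises(ValueError, match="singular"):
            fit_nbp_glm(np.arange(len(Q)), design)


class TestScore:
    @pytest.fixture()
    def null_fit(self, covariates):
        rng = np.random.default_rng(5)
        Q = covariates.to_numpy()
        mu = np.exp(2.0 + 0.3 * Q[:, 0])
        y = rng.negative_binomial(2.0, 2.0 / (2.0 + mu))
        design = np.column_stack([np.ones(len(Q)), Q])
        fit = fit_nbp_glm(y, design)
        return prepare_score(fit, y), y, rng

    def test_gradient_matches_finite_difference(self, null_fit):
        """dlogL/dbeta at beta=0 against numeric differentiation of the NB
        log-likelihood with dispersion fixed at the null estimate."""
        fit, y, rng = null_fit
        X = rng.standard_normal(len(y))
        w_resid = fit.score_residual_weights()
        analytic = float(X @ (w_resid * (y - fit.mu)))

        theta = 1.0 / fit.alpha

        def loglik(beta):
            mu = fit.mu * np.exp(beta * X)
            return np.sum(stats.nbinom.logpmf(y, theta, theta / (theta + mu)))

        h = 1e-6
        numeric = (loglik(h) - loglik(-h)) / (2 * h)
        assert analytic == pytest.approx(numeric, rel=1e-4)

    def test_score_sign_matches_residual_covariance(self, null_fit):
        fit, y, rng = null_fit
        for _ in range(5):
            X = rng.standard_normal(len(y))
            z = score_z(fit, X)
            cov = np.cov(X, fit.score_residual_weights() * (y - fit.mu))[0, 1]
            assert np.sign(z) == np.sign(cov)

    def test_collinear_target_degenerate(self, null_fit, covariates):
        fit, _, _ = null_fit
        with pytest.raises(ValueError, match="collinear"):
            score_z(fit, covariates.to_numpy()[:, 0])

    def test_batch_matches_scalar(self, null_fit):
        fit, _, rng = null_fit
        X = rng.standard_normal((fit.mu.size, 7))
        batch = score_z_batch(fit, X)
        singles = [score_z(fit, X[:, j]) for j in range(7)]
        np.testing.assert_allclose(batch, singles, rtol=1e-12)


class TestDcrtPvalue:
    def test_alt_at_null_mean_gives_one(self):
        z = np.array([0.2, -0.1, 0.4, 0.05])
        assert dcrt_pvalue(float(z.mean()), z) == pytest.approx(1.0)

    def test_two_sd_gives_chi2_tail_at_four(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal(1000)
        z_alt = z.mean() + 2 * z.std(ddof=1)
        assert dcrt_pvalue(z_alt, z) == pytest.approx(stats.chi2.sf(4, 1))
        assert dcrt_pvalue(z_alt, z) == pytest.approx(0.0455, abs=2e-4)

    def test_monotone_in_deviation(self):
        z = np.array([0.0, 1.0, -1.0, 0.5])
        devs = [0.1, 0.5, 1.0, 2.0, 5.0]
        ps_ = [dcrt_pvalue(z.mean() + d, z) for d in devs]
        assert all(a > b for a, b in zip(ps_, ps_[1:]))

    def test_degenerate_null_rejected(self):
        with pytest.raises(ValueError):
            dcrt_pvalue(1.0, np.array([0.5, 0.5, 0.5]))


class TestResampling:
    def test_all_zero_target_resamples_zero(self, covariates):
        task = AssociationTask(
            activity=np.arange(len(covariates)), covariates=covariates,
            target=np.zeros(len(covariates)), target_kind="binary_logistic")
        draws = resample_target(task, seed=1)
        assert draws.shape == (len(covariates), 100)
        assert draws.sum() == 0

    def test_intercept_only_rate_preserved(self):
        cov = gen_covariates(10_000, seed=2)
        rng = np.random.default_rng(3)
        target = rng.binomial(1, 0.5, len(cov)).astype(float)
        task = AssociationTask(activity=np.arange(len(cov)), covariates=cov,
                               target=target, target_kind="bernoulli",
                               n_resamples=5)
        draws = resample_target(task, seed=4)
        se = np.sqrt(0.25 / draws.size)
        assert abs(draws.mean() - target.mean()) < 3 * se

    def test_composite_zero_components_resample_zero(self, covariates):
        comp = pd.DataFrame({"germline": np.zeros(len(covariates)),
                             "loh": np.zeros(len(covariates)),
                             "somatic": np.zeros(len(covariates))})
        task = AssociationTask(
            activity=np.arange(len(covariates)), covariates=covariates,
            target=np.zeros(len(covariates)),
            target_kind="inactivation_composite", target_components=comp)
        assert resample_target(task, seed=5).sum() == 0

    def test_composite_draws_capped_at_two(self, covariates):
        rng = np.random.default_rng(6)
        comp = pd.DataFrame({"germline": rng.binomial(1, 0.4, len(covariates)),
                             "loh": rng.binomial(1, 0.5, len(covariates)),
                             "somatic": rng.poisson(1.0, len(covariates))})
        task = AssociationTask(
            activity=np.arange(len(covariates)), covariates=covariates,
            target=np.minimum(2, comp.sum(axis=1)).to_numpy(dtype=float),
            target_kind="inactivation_composite", target_components=comp)
        draws = resample_target(task, seed=7)
        assert set(np.unique(draws)) <= {0.0, 1.0, 2.0}

    def test_poisson_count_target(self, covariates):
        rng = np.random.default_rng(8)
        target = rng.poisson(2.0, len(covariates)).astype(float)
        task = AssociationTask(activity=np.arange(len(covariates)),
                               covariates=covariates, target=target,
                               target_kind="poisson_count", n_resamples=50)
        draws = resample_target(task, seed=9)
        assert abs(draws.mean() - target.mean()) < 0.2


class TestWilks:
    def test_deviance_to_pvalue_convention(self, covariates):
        """A likelihood-ratio statistic of 6.635 corresponds to p = 0.01."""
        assert stats.chi2.sf(6.635, 1) == pytest.approx(0.01, abs=1e-4)
        rng = np.random.default_rng(10)
        B = rng.binomial(1, 0.5, len(covariates))
        X = rng.standard_normal(len(covariates))
        res = wilks_logistic(B, covariates, X)
        assert 0.0 < res.p_wilks <= 1.0

    def test_identical_nested_fits_give_p_one(self, covariates):
        rng = np.random.default_rng(11)
        B = rng.binomial(1, 0.5, len(covariates))
        res = wilks_logistic(B, covariates, np.zeros(len(covariates)))
        assert res.p_wilks == pytest.approx(1.0)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(12)
        cov = gen_covariates(200, seed=13)
        pvals = []
        for _ in range(300):
            B = rng.binomial(1, 0.5, 200)
            X = rng.standard_normal(200)
            pvals.append(wilks_logistic(B, cov, X).p_wilks)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_constant_binary_activity_rejected(self, covariates):
        with pytest.raises(ValueError):
            wilks_logistic(np.zeros(len(covariates)), covariates,
                           np.arange(len(covariates)))


class TestRunAssociation:
    def test_power_under_positive_effect(self, covariates):
        """beta_X = 1 at n=400 is detected by the dCRT."""
        rng = np.random.default_rng(14)
        hits = 0
        for rep in range(10):
            Q = covariates.to_numpy()
            X = rng.binomial(1, 0.3, len(Q)).astype(float)
            mu = np.exp(2.5 + 0.3 * Q[:, 0] + 1.0 * X)
            y = rng.negative_binomial(1.0, 1.0 / (1.0 + mu))
            task = AssociationTask(activity=y, covariates=covariates, target=X,
                                   target_kind="binary_logistic")
            dcrt, _ = run_association(task, seed=100 + rep)
            assert dcrt.beta > 0
            if dcrt.p_dcrt < 0.01:
                hits += 1
        assert hits >= 9

    def test_deterministic_under_seed(self, covariates):
        rng = np.random.default_rng(15)
        y = rng.negative_binomial(1.0, 0.1, len(covariates))
        X = rng.binomial(1, 0.3, len(covariates)).astype(float)
        task = AssociationTask(activity=y, covariates=covariates, target=X,
                               target_kind="binary_logistic")
        d1, l1 = run_association(task, seed=7)
        d2, l2 = run_association(task, seed=7)
        assert d1.p_dcrt == d2.p_dcrt
        np.testing.assert_array_equal(d1.z_null, d2.z_null)
        assert l1.p_wilks == l2.p_wilks

    def test_low_resolution_null_flagged(self, covariates):
        rng = np.random.default_rng(16)
        y = rng.negative_binomial(1.0, 0.1, len(covariates))
        X = rng.binomial(1, 0.5, len(covariates)).astype(float)
        task = AssociationTask(activity=y, covariates=covariates, target=X,
                               target_kind="binary_logistic", n_resamples=2)
        dcrt, _ = run_association(task, seed=8)
        assert dcrt.low_resolution
        with pytest.raises(ValueError):
            AssociationTask(activity=y, covariates=covariates, target=X,
                            target_kind="binary_logistic", n_resamples=1)

    def test_effect_direction_consistency(self, covariates):
        rng = np.random.default_rng(17)
        Q = covariates.to_numpy()
        X = rng.binomial(1, 0.4, len(Q)).astype(float)
        mu = np.exp(2.0 + 1.5 * X)
        y = rng.negative_binomial(2.0, 2.0 / (2.0 + mu))
        task = AssociationTask(activity=y, covariates=covariates, target=X,
                               target_kind="binary_logistic")
        dcrt, _ = run_association(task, seed=9)
        assert np.sign(dcrt.beta) == np.sign(dcrt.z_alt - dcrt.z_null.mean())


class TestMocks:
    @pytest.mark.parametrize("mock_kind", [1, 2, 3])
    def test_dcrt_calibrated_under_mocks(self, mock_kind):
        mc = mock_calibration(mock_kind, n_reps=120, seed=20 + mock_kind,
                              n_samples=150)
        # binomial 95% band around 0.05 at n=120
        se = np.sqrt(0.05 * 0.95 / 120)
        assert mc.fpr_dcrt <= 0.05 + 3 * se
        assert mc.ks_p_dcrt > 0.01
        # naive Wilks p can underflow to 0 under misspecification
        assert np.all((mc.p_wilks >= 0) & (mc.p_wilks <= 1))

    def test_mock2_naive_wilks_inflated_while_dcrt_uniform(self):
        """Heavy-tailed activities: dCRT p-values stay KS-uniform while the
        naive NB/P Wilks p-values are detectably non-uniform and over-reject."""
        mc = mock_calibration(2, n_reps=150, seed=3, n_samples=200)
        assert mc.ks_p_dcrt > 0.01
        assert mc.ks_p_wilks < 0.01
        assert mc.fpr_wilks > mc.fpr_dcrt

    def test_mock3_permutation_preserves_multiset(self):
        """Within-cohort permutation leaves each cohort's target multiset intact
        (checked directly on the permutation primitive)."""
        rng = np.random.default_rng(30)
        values = rng.integers(0, 3, 90)
        cohorts = np.repeat(np.arange(3), 30)
        permuted = values.copy()
        for c in range(3):
            idx = np.flatnonzero(cohorts == c)
            permuted[idx] = values[idx][rng.permutation(len(idx))]
            assert sorted(permuted[idx]) == sorted(values[idx])

    def test_invalid_mock_kind(self):
        with pytest.raises(ValueError):
            mock_calibration(4, n_reps=5, seed=1)


class TestBhFdr:
    def test_no_rejections_at_p_one(self):
        reject, _ = bh_fdr(np.ones(5), q=0.05)
        assert not reject.any()

    def test_single_small_p_rejected(self):
        reject, _ = bh_fdr(np.array([0.005]), q=0.01)
        assert reject.all()

    def test_step_up_thresholds(self):
        """Step-up: the largest i with p_(i) <= i*q/m sets the cut. With
        p = (0.001, 0.008, 0.039, 0.041) at q = 0.05 the 4th threshold 0.05
        exceeds 0.041, so all four are rejected even though 0.039 > 0.0375;
        raising the last p above 0.05 leaves the 0.039 unrejected too."""
        reject, _ = bh_fdr(np.array([0.001, 0.008, 0.039, 0.041]), q=0.05)
        assert reject.tolist() == [True, True, True, True]
        reject, _ = bh_fdr(np.array([0.001, 0.008, 0.039, 0.051]), q=0.05)
        assert reject.tolist() == [True, True, False, False]

    def test_invalid_pvalues(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.0, 0.5]))


class TestSurvival:
    @pytest.fixture(scope="class")
    def survival_data(self):
        rng = np.random.default_rng(40)
        n = 1000
        cov = gen_covariates(n, seed=41)
        activity = rng.negative_binomial(1.0, 0.05, n)
        log_act = np.log1p(activity)
        z = (log_act - log_act.mean()) / log_act.std()
        hazard = np.exp(0.5 * z)
        times = rng.exponential(1.0 / hazard)
        censor = rng.exponential(2.0, n)
        observed = np.minimum(times, censor)
        events = times <= censor
        return activity, cov, observed, events

    def test_coefficient_recovery(self, survival_data):
        activity, cov, times, events = survival_data
        res = cph_survival_test(activity, cov, times, events)
        assert abs(res.coef - 0.5) < 0.15
        assert res.wald_p < 1e-6
        assert res.reportable

    def test_independent_activity_not_significant(self, survival_data):
        _, cov, times, events = survival_data
        rng = np.random.default_rng(42)
        res = cph_survival_test(rng.negative_binomial(1.0, 0.05, len(times)),
                                cov, times, events)
        assert res.wald_p > 0.001

    def test_no_events_rejected(self, survival_data):
        activity, cov, times, _ = survival_data
        with pytest.raises(ValueError):
            cph_survival_test(activity, cov, times, np.zeros(len(times)))
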