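import math

import numpy as np
import pytest

import pemjoint as pj
from pemjoint.estimation import _CohortArrays
from pemjoint.longitudinal import longitudinal_design_matrix
from conftest import override_params, trapezoid_marginal_loglik


class TestQuadratureRule:
    def test_normal_density_integrates_to_one(self):
        for order in (15, 21, 31):
            assert pj.QuadratureRule.from_order(order).normal_identity_error() < 1e-10

    def test_rejects_tiny_orders(self):
        with pytest.raises(pj.ValidationError):
            pj.QuadratureRule.from_order(2)


class TestSubjectMarginal:
    def test_factorizes_when_gamma_is_zero(self, small_cohort, paper_params):
        params = override_params(paper_params, gamma=0.0)
        rule = pj.QuadratureRule.from_order(15)
        for s in small_cohort.subjects:
            joint = pj.subject_marginal_loglik(s, params, rule)
            factored = pj.marginal_loglik_long(
                s, params.longitudinal, params.random_effect
            ) + pj.cond_loglik_rec(s, params.recurrence, 0.0)
            assert joint == pytest.approx(factored, abs=1e-10)

    def test_degenerate_mixing_at_sigma_alpha_zero(self, small_cohort, paper_params):
        params = override_params(paper_params, sigma_alpha=0.0)
        s = small_cohort.subjects[0]
        expected = pj.cond_loglik_long(s, params.longitudinal, 0.0) + pj.cond_loglik_rec(
            s, params.recurrence, 0.0
        )
        assert pj.subject_marginal_loglik(s, params) == pytest.approx(expected, rel=1e-12)

    def test_matches_bruteforce_trapezoid(self, small_cohort, paper_params):
        rule = pj.QuadratureRule.from_order(15)
        for s in small_cohort.subjects[:10]:
            gh = pj.subject_marginal_loglik(s, paper_params, rule)
            oracle = trapezoid_marginal_loglik(s, paper_params)
            assert gh == pytest.approx(oracle, abs=1e-7)

    def test_quadrature_order_convergence(self, small_cohort, paper_params):
        r15 = pj.QuadratureRule.from_order(15)
        r31 = pj.QuadratureRule.from_order(31)
        r9 = pj.QuadratureRule.from_order(9)
        r61_fixed = pj.QuadratureRule.from_order(61, adaptive=False)
        for s in small_cohort.subjects:
            a15 = pj.subject_marginal_loglik(s, paper_params, r15)
            a31 = pj.subject_marginal_loglik(s, paper_params, r31)
            assert a15 == pytest.approx(a31, abs=1e-6)
            # for the fixed-node rule, trim the record so the posterior stays
            # wide relative to the prior-scaled node span
            s2 = pj.SubjectData(s.subject_id, s.covariates, s.observations[:2], s.episodes)
            a9 = pj.subject_marginal_loglik(s2, paper_params, r9)
            a61 = pj.subject_marginal_loglik(s2, paper_params, r61_fixed)
            assert a9 == pytest.approx(a61, abs=1e-6)


class TestJointLoglik:
    def test_additive_over_subjects(self, small_cohort, paper_params):
        two = pj.Cohort(subjects=small_cohort.subjects[:2])
        total = pj.joint_loglik(two, paper_params)
        parts = sum(pj.subject_marginal_loglik(s, paper_params) for s in two.subjects)
        assert total == pytest.approx(parts, rel=1e-12)

    def test_permutation_invariant_to_the_last_bit(self, small_cohort, paper_params):
        forward = pj.joint_loglik(small_cohort, paper_params)
        reversed_cohort = pj.Cohort(subjects=list(reversed(small_cohort.subjects)))
        assert pj.joint_loglik(reversed_cohort, paper_params) == forward

    def test_analytic_gradient_matches_finite_differences(self, small_cohort, paper_params):
        arrays = _CohortArrays(small_cohort, center=True)
        theta = arrays.theta_from_params(paper_params)
        rule = pj.QuadratureRule.from_order(31)
        baseline = paper_params.recurrence.baseline
        _, grad = arrays.loglik_parts(theta, rule, baseline, want_grad=True)
        for j in range(len(theta)):
            h = 1e-6 * (1 + abs(theta[j]))
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            lp, _ = arrays.loglik_parts(tp, rule, baseline, False)
            lm, _ = arrays.loglik_parts(tm, rule, baseline, False)
            fd = (lp.sum() - lm.sum()) / (2 * h)
            assert grad[j] == pytest.approx(fd, rel=5e-6, abs=5e-6)


class TestFitJoint:
    def test_refit_from_optimum_is_a_fixed_point(self, medium_cohort):
        model = pj.JointModel(quad_order=9, compute_se=False).fit(medium_cohort)
        again = pj.JointModel(quad_order=9, compute_se=False).fit(medium_cohort, init=model.params_)
        assert abs(again.loglik_ - model.loglik_) < 1e-6

    def test_deterministic_given_data_and_config(self, medium_cohort):
        a = pj.JointModel(quad_order=9, compute_se=False).fit(medium_cohort)
        b = pj.JointModel(quad_order=9, compute_se=False).fit(medium_cohort)
        np.testing.assert_array_equal(a.result_.values, b.result_.values)

    def test_rejects_degenerate_inputs(self, small_cohort):
        with pytest.raises(pj.ValidationError):
            pj.fit_joint(pj.Cohort(subjects=small_cohort.subjects[:1]))
        no_events = pj.Cohort(subjects=[
            pj.SubjectData(s.subject_id, s.covariates, s.observations,
                           [e for e in s.episodes if not e.delta] or
                           [pj.EpisodeRecord(s.subject_id, 1, s.covariates.follow_up, 0)])
            for s in small_cohort.subjects[:3]
        ])
        for s in no_events.subjects:  # re-index the single censored episode
            s.episodes = [pj.EpisodeRecord(s.subject_id, 1, s.covariates.follow_up, 0)]
        with pytest.raises(pj.ValidationError):
            pj.fit_joint(no_events)

    def test_piecewise_baseline_fit_tracks_increasing_hazard(self, medium_cohort):
        """Data generated under an increasing Weibull baseline should yield
        increasing piecewise rates, with finite SEs for every parameter."""
        model = pj.JointModel(baseline="piecewise_constant", knots=[0.0, 6.0, 18.0],
                              quad_order=9).fit(medium_cohort)
        r = model.result_
        assert r.converged
        rates = [r.values[r.param_names.index(f"piecewise_rate_{j}")] for j in (1, 2, 3)]
        assert rates[0] < rates[1] < rates[2]
        assert np.all(np.isfinite(r.se)) and np.all(r.se > 0)

    def test_sklearn_style_params_round_trip(self):
        model = pj.JointModel(quad_order=9)
        params = model.get_params()
        assert params["quad_order"] == 9
        model.set_params(quad_order=21, adaptive=False)
        assert model.quad_order == 21 and model.adaptive is False
        with pytest.raises(ValueError):
            model.set_params(nonsense=1)

    def test_result_json_round_trip(self, medium_cohort):
        result = pj.JointModel(quad_order=9).fit(medium_cohort).result_
        back = pj.FitResult.from_json(result.to_json())
        np.testing.assert_allclose(back.values, result.values, rtol=1e-15)
        np.testing.assert_allclose(back.se, result.se, rtol=1e-15)
        assert back.loglik == result.loglik
        assert back.param_names == result.param_names

    def test_table_blocks_in_fixed_order(self, medium_cohort):
        result = pj.JointModel(quad_order=9).fit(medium_cohort).result_
        text = result.table2_text()
        i_long = text.index("Longitudinal measures of IgG")
        i_rec = text.index("Recurrent pemphigus event")
        i_gamma = text.index("Association")
        assert i_long < i_rec < i_gamma


class TestStandardErrors:
    def test_beta_ses_match_closed_form_gls(self, medium_cohort):
        """With variances and the recurrence block held fixed, the observed
        information for beta is exactly X' Sigma^{-1} X."""
        lp, re, _ = pj.fit_longitudinal(medium_cohort)
        rec, _ = pj.fit_recurrence_null(medium_cohort)
        fixed = {
            "sigma_e": lp.sigma_e, "sigma_alpha": re.sigma_alpha, "gamma": 0.0,
            "rec_age_std": rec.eta[0], "rec_male": rec.eta[1], "rec_single": rec.eta[2],
            "rec_skin_phenotype": rec.eta[3],
            "weibull_rate": rec.baseline.rate, "weibull_shape": rec.baseline.shape,
        }
        model = pj.JointModel(quad_order=15, fixed=fixed).fit(medium_cohort)
        se_beta = model.se_[:6]

        info = np.zeros((6, 6))
        se2, sa2 = lp.sigma_e**2, re.sigma_alpha**2
        for s in medium_cohort.subjects:
            X = longitudinal_design_matrix(s)
            n = len(s.observations)
            c = sa2 / (se2 + n * sa2)
            sx = X.sum(axis=0)
            info += (X.T @ X - c * np.outer(sx, sx)) / se2
        gls_se = np.sqrt(np.diag(np.linalg.inv(info)))
        np.testing.assert_allclose(se_beta, gls_se, rtol=1e-4)

    def test_step_size_halving_is_stable(self, medium_cohort, paper_params):
        model = pj.JointModel(quad_order=9, compute_se=False).fit(medium_cohort)
        rule = pj.QuadratureRule.from_order(9)
        se_a, _, ok_a = pj.standard_errors(medium_cohort, model.params_, rule, step_scale=1e-4)
        se_b, _, ok_b = pj.standard_errors(medium_cohort, model.params_, rule, step_scale=5e-5)
        assert ok_a and ok_b
        np.testing.assert_allclose(se_a, se_b, rtol=1e-3)


class TestRecurrenceNullOracle:
    def test_matches_lifelines_weibull_aft(self):
        """The frailty-free Weibull gap-time fit agrees with lifelines'
        WeibullAFTFitter after the AFT <-> PH reparameterization."""
        import pandas as pd
        from lifelines import WeibullAFTFitter
        from pemjoint.recurrence import recurrence_design_row

        cohort = pj.simulate_cohort(pj.GeneratorConfig(n_subjects=250, seed=5))
        rows = []
        for s in cohort.subjects:
            z = recurrence_design_row(s.covariates)
            for e in s.episodes:
                rows.append((e.w, e.delta, *z))
        df = pd.DataFrame(rows, columns=["w", "event", "age_std", "male", "single", "skin"])
        aft = WeibullAFTFitter().fit(df, duration_col="w", event_col="event")

        rec, loglik = pj.fit_recurrence_null(cohort)
        shape = rec.baseline.shape
        # AFT scale coefficients: lambda_i = exp(b0 + x'b); PH: b = -eta/shape
        b0 = aft.summary.loc[("lambda_", "Intercept"), "coef"]
        assert math.exp(aft.summary.loc[("rho_", "Intercept"), "coef"]) == pytest.approx(shape, rel=1e-3)
        assert -math.log(rec.baseline.rate) / shape == pytest.approx(b0, rel=1e-3)
        for j, col in enumerate(["age_std", "male", "single", "skin"]):
            b = aft.summary.loc[("lambda_", col), "coef"]
            assert -rec.eta[j] / shape == pytest.approx(b, rel=2e-3, abs=2e-4)
        assert loglik == pytest.approx(aft.log_likelihood_, abs=1e-4)


class TestReportingTransforms:
    @pytest.mark.parametrize(
        "est, se, level, expected",
        [
            (0.106, 0.417, 0.95, (-0.711, 0.923)),
            (0.0, 1.0, 0.95, (-1.96, 1.96)),
            (0.876, 0.274, 0.95, (0.34, 1.41)),
        ],
    )
    def test_wald_ci_rounds_to_published_bounds(self, est, se, level, expected):
        lo, hi = pj.wald_ci(est, se, level)
        decimals = 3 if abs(expected[0]) > 0.4 and expected == (-0.711, 0.923) else 2
        assert round(lo, decimals) == expected[0]
        assert round(hi, decimals) == expected[1]

    def test_wald_ci_domain_errors(self):
        with pytest.raises(pj.ValidationError):
            pj.wald_ci(0.0, 0.0, 0.95)
        with pytest.raises(pj.ValidationError):
            pj.wald_ci(0.0, 1.0, 1.5)

    @pytest.mark.parametrize(
        "coef, expected, ndigits",
        [(0.367, 1.44, 2), (0.0, 1.0, 12), (-0.111, 0.895, 3), (-0.076, 0.927, 3)],
    )
    def test_hazard_ratio(self, coef, expected, ndigits):
        assert round(pj.hazard_ratio(coef), ndigits) == expected

    @pytest.mark.parametrize(
        "coef, expected, ndigits",
        [(0.024, 2.43, 2), (0.0, 0.0, 12), (math.log(2.0), 100.0, 9)],
    )
    def test_percent_change_per_unit(self, coef, expected, ndigits):
        assert round(pj.percent_change_per_unit(coef), ndigits) == expected
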