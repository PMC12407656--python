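"""FIML path models: estimation, Wald tests, mediation, bootstrap, fit indices."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gnurture import pathmodels as pm
from gnurture import scores, simfam


def _mediation_frame(n, a_t=0.2, a_nt=0.2, b=0.3, c_t=0.2, c_nt=0.05,
                     seed=0, sibs=2, missing=None):
    """Data generated exactly from the two-equation mediation model."""
    rng = np.random.default_rng(seed)
    fam = np.repeat(np.arange(int(np.ceil(n / sibs))), sibs)[:n]
    t = rng.standard_normal(n)
    nt = rng.standard_normal(n)
    sex = (rng.random(n) < 0.5).astype(float)
    age = rng.standard_normal(n)
    med = a_t * t + a_nt * nt + 0.1 * sex + 0.05 * age + rng.standard_normal(n)
    out = b * med + c_t * t + c_nt * nt + 0.1 * sex + 0.05 * age + rng.standard_normal(n)
    df = pd.DataFrame(
        {"family_id": fam, "pgs_t_std": t, "pgs_nt_std": nt, "sex": sex,
         "age": age, "mediator": med, "outcome": out}
    )
    if missing:
        for col, frac in missing.items():
            mask = rng.random(n) < frac
            df.loc[mask, col] = np.nan
    return df


MED_SPEC = pm.mediation_spec("mediator", "outcome")


class TestSpec:
    def test_exogenous_detection(self):
        assert MED_SPEC.exogenous == ["pgs_t_std", "pgs_nt_std", "sex", "age"]
        assert MED_SPEC.endogenous == ["mediator", "outcome"]

    def test_non_recursive_rejected(self):
        with pytest.raises(ValueError, match="recursive"):
            pm.PathModelSpec((("a", ("b",)), ("b", ("a",))))

    def test_saturated_equivalence(self):
        assert MED_SPEC.is_saturated_equivalent()
        sub = pm.PathModelSpec(
            (("mediator", ("pgs_t_std", "pgs_nt_std")),
             ("outcome", ("mediator", "pgs_t_std", "pgs_nt_std")))
        )
        assert sub.is_saturated_equivalent()
        holed = pm.PathModelSpec(
            (("mediator", ("pgs_t_std",)),
             ("outcome", ("mediator", "pgs_t_std", "pgs_nt_std")))
        )
        assert not holed.is_saturated_equivalent()


class TestFimlFit:
    def test_complete_data_equals_ols(self):
        """FIML = ML = equation-by-equation OLS under completeness."""
        import statsmodels.api as sm

        df = _mediation_frame(1500, seed=1)
        fit = pm.fiml_fit(MED_SPEC, df)
        assert fit.method == "closed_form"
        X = sm.add_constant(df[["mediator", "pgs_t_std", "pgs_nt_std", "sex", "age"]])
        ols = sm.OLS(df["outcome"], X).fit()
        p = fit.params
        for name, col in (("outcome~mediator", "mediator"),
                          ("outcome~pgs_t_std", "pgs_t_std"),
                          ("outcome~pgs_nt_std", "pgs_nt_std")):
            assert p[name] == pytest.approx(ols.params[col], abs=1e-6)

    def test_optimizer_agrees_with_closed_form(self):
        df = _mediation_frame(400, seed=2)
        a = pm.fiml_fit(MED_SPEC, df)
        b = pm.fiml_fit(MED_SPEC, df, force_optimizer=True)
        assert b.method == "quasi_newton"
        assert b.loglik == pytest.approx(a.loglik, abs=1e-4)
        np.testing.assert_allclose(
            [b.params[k] for k in ("outcome~mediator", "mediator~pgs_t_std")],
            [a.params[k] for k in ("outcome~mediator", "mediator~pgs_t_std")],
            atol=2e-3,
        )

    def test_mcar_recovery(self):
        """30% MCAR missingness in one score: estimates near generative values."""
        df = _mediation_frame(5000, seed=3, missing={"pgs_nt_std": 0.3})
        fit = pm.fiml_fit(MED_SPEC, df)
        assert fit.method == "em_saturated"
        p = fit.params
        assert p["mediator~pgs_t_std"] == pytest.approx(0.2, abs=0.05)
        assert p["mediator~pgs_nt_std"] == pytest.approx(0.2, abs=0.06)
        assert p["outcome~mediator"] == pytest.approx(0.3, abs=0.05)
        assert p["outcome~pgs_nt_std"] == pytest.approx(0.05, abs=0.06)

    def test_fitted_loglik_beats_generative_theta(self):
        df = _mediation_frame(800, seed=4, missing={"mediator": 0.2})
        fit = pm.fiml_fit(MED_SPEC, df)
        truth_theta = fit.theta.copy()
        # perturb toward the generative coefficients
        truth_theta[fit.layout.index["mediator~pgs_t_std"]] = 0.2
        truth_theta[fit.layout.index["outcome~mediator"]] = 0.3
        mu, sigma = pm._implied_moments(fit.spec, fit.layout, truth_theta)
        assert fit.loglik >= fit._pdata.loglik(mu, sigma) - 1e-8

    def test_all_missing_rows_dropped(self):
        df = _mediation_frame(300, seed=5)
        df.loc[:9, ["mediator", "outcome", "pgs_t_std", "pgs_nt_std", "sex", "age"]] = np.nan
        fit = pm.fiml_fit(MED_SPEC, df)
        assert fit.n_dropped == 10
        assert fit.n_used == 290


class TestParentOfOrigin:
    @staticmethod
    def _frame(n_fam, rho_am, seed, eta=0.2):
        params = simfam.PhenoModelParams(rho_am=rho_am, eta_m=eta, eta_f=eta)
        df = simfam.simulate_analysis_table(n_fam, params, seed=seed)
        return scores.residualize_standardize(df, ["mt", "pt", "mnt", "pnt"])

    def test_symmetric_nurture_gives_equal_coefficients(self):
        df = self._frame(6000, 0.0, seed=6)
        fit = pm.fit_parent_of_origin(df, "alc_gday")
        std = fit.standardized_solution()
        assert std["alc_gday~mnt_std"] == pytest.approx(
            std["alc_gday~pnt_std"], abs=0.05
        )
        assert std["alc_gday~mnt_std"] > 0

    def test_no_assortment_zero_cross_parent_covariance(self):
        df = self._frame(3000, 0.0, seed=7)
        fit = pm.fit_parent_of_origin(df, "alc_gday")
        assert abs(fit.params["pt_std~~mt_std"]) < 0.06

    def test_assortment_positive_covariance(self):
        hits = 0
        for seed in range(5):
            df = self._frame(1500, 0.5, seed=20 + seed)
            fit = pm.fit_parent_of_origin(df, "alc_gday")
            hits += fit.params["pt_std~~mt_std"] > 0
        assert hits == 5


class TestWald:
    def test_chi2_to_p_closed_form(self):
        assert stats.chi2.sf(3.84, 1) == pytest.approx(0.050, abs=0.001)

    def test_self_contrast_degenerate(self):
        df = _mediation_frame(300, seed=8)
        fit = pm.fiml_fit(MED_SPEC, df)
        w = pm.wald_equality(fit, "outcome~pgs_t_std", "outcome~pgs_t_std")
        assert w.chi2 == 0.0 and w.degenerate

    def test_symmetric_fit_small_statistic(self):
        df = _mediation_frame(4000, a_t=0.2, a_nt=0.2, c_t=0.1, c_nt=0.1, seed=9)
        fit = pm.fiml_fit(MED_SPEC, df)
        w = pm.wald_equality(fit, "outcome~pgs_t_std", "outcome~pgs_nt_std")
        assert w.p > 0.01

    def test_detects_unequal_coefficients(self):
        df = _mediation_frame(4000, c_t=0.4, c_nt=0.0, seed=10)
        fit = pm.fiml_fit(MED_SPEC, df)
        w = pm.wald_equality(fit, "outcome~pgs_t_std", "outcome~pgs_nt_std")
        assert w.p < 1e-4


class TestMediation:
    def test_identity_total_equals_direct_plus_indirect(self):
        for seed in range(3):
            df = _mediation_frame(500, seed=30 + seed,
                                  missing={"mediator": 0.2} if seed else None)
            med = pm.fit_mediation(df, "mediator", "outcome")
            assert med.total_t == pytest.approx(med.c_t + med.a_t * med.b, abs=1e-12)
            assert med.total_nt == pytest.approx(med.c_nt + med.a_nt * med.b, abs=1e-12)

    def test_zero_b_no_mediation(self):
        df = _mediation_frame(4000, b=0.0, seed=11)
        med = pm.fit_mediation(df, "mediator", "outcome")
        assert med.indirect_t == pytest.approx(0.0, abs=0.02)

    def test_full_mediation_approaches_100_percent(self):
        df = _mediation_frame(8000, a_t=0.4, a_nt=0.4, b=0.4, c_t=0.0, c_nt=0.0,
                              seed=12)
        med = pm.fit_mediation(df, "mediator", "outcome")
        assert med.proportion_mediated_t == pytest.approx(100.0, abs=12.0)

    def test_sign_conflict_flagged(self):
        assert np.isnan(pm.proportion_mediated(-0.1, 0.2))
        assert np.isnan(pm.proportion_mediated(0.1, 0.0))


class TestBootstrap:
    @staticmethod
    def _fitter(d):
        m = pm.fit_mediation(d, "mediator", "outcome")
        return {"ab_t": m.indirect_t}

    def test_deterministic_replicates(self):
        df = _mediation_frame(200, seed=13)
        a = pm.bootstrap_cis(self._fitter, df, b=2, seed=5)
        b = pm.bootstrap_cis(self._fitter, df, b=2, seed=5)
        pd.testing.assert_frame_equal(a.estimates, b.estimates)

    def test_single_family_errors(self):
        df = _mediation_frame(40, seed=14)
        df["family_id"] = 0
        with pytest.raises(ValueError):
            pm.bootstrap_cis(self._fitter, df, b=10, seed=0)

    def test_ci_brackets_point_estimate(self):
        df = _mediation_frame(600, seed=15)
        point = self._fitter(df)["ab_t"]
        res = pm.bootstrap_cis(self._fitter, df, b=80, seed=1)
        lo, hi = res.ci["ab_t"]
        assert lo <= point <= hi

    def test_failure_fraction_guard(self):
        df = _mediation_frame(100, seed=16)

        def bad(_):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="replicates failed"):
            pm.bootstrap_cis(bad, df, b=10, seed=2)


class TestFitIndices:
    def test_saturated_exact_fit_constants(self):
        df = _mediation_frame(500, seed=17)
        fit = pm.fiml_fit(MED_SPEC, df)
        fi = pm.fit_indices(fit)
        assert fi.exact_fit
        assert (fi.chi2, fi.df, fi.rmsea, fi.cfi) == (0.0, 0, 0.0, 1.0)

    def test_restricted_model_positive_chi2_when_misspecified(self):
        # true c_nt path omitted from the model
        df = _mediation_frame(3000, c_nt=0.4, seed=18)
        spec = pm.PathModelSpec(
            (("mediator", ("pgs_t_std", "pgs_nt_std", "sex", "age")),
             ("outcome", ("mediator", "pgs_t_std", "sex", "age")))
        )
        fit = pm.fiml_fit(spec, df)
        fi = pm.fit_indices(fit)
        assert fi.df == 1
        assert fi.chi2 > 10
        assert fi.p < 0.01
        assert 0 <= fi.rmsea and fi.cfi <= 1

    def test_chi2_calibration_under_true_restricted_model(self):
        """LRT p-values roughly uniform when the restricted model is true."""
        spec = pm.PathModelSpec(
            (("mediator", ("pgs_t_std", "pgs_nt_std", "sex", "age")),
             ("outcome", ("mediator", "pgs_t_std", "sex", "age")))
        )
        ps = []
        for seed in range(40):
            df = _mediation_frame(800, c_nt=0.0, seed=200 + seed)
            fit = pm.fiml_fit(spec, df)
            ps.append(pm.fit_indices(fit).p)
        _, ks_p = stats.kstest(ps, "uniform")
        assert ks_p > 0.01
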