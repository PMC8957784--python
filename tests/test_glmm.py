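"""Mixed-effects logistic machinery: oracles, contrasts, VIF, R-squared."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import ssinva
from ssinva.glmm import (
    SIGMA2_LOGISTIC,
    GlmmFit,
    ModelSpec,
    build_design,
    fit_logistic_glmm,
    likelihood_ratio_test,
    model_ladder,
    odds_ratios,
    posthoc_interaction,
    posthoc_pairwise,
    predicted_probabilities,
    r2_nakagawa,
    vif,
)
from ssinva.listener import ListenerProfile, simulate_cohort


def _two_by_two_table():
    """Pooled 2x2 design: successes 8/10 under x=1, 6/10 under x=0.

    Closed-form odds ratio (8/2)/(6/4) = 2.667; split across 2 participants
    so the grouped fitter accepts it.
    """
    rows = []
    for pid in ("A", "B"):
        for x, succ in ((1.0, 4), (0.0, 3)):
            for i in range(5):
                rows.append({"participant_id": pid, "x": x,
                             "outcome": 1 if i < succ else 0})
    return pd.DataFrame(rows)


@pytest.fixture(scope="module")
def loc_obs(small_cohort_module):
    _, obs = small_cohort_module
    return obs[obs.task == "localization"]


@pytest.fixture(scope="module")
def small_cohort_module():
    return simulate_cohort(8, seed=13, runs_per_block=1)


LOC_SPEC = ModelSpec("localization", ("mean_location", "snr", "direction"))


class TestFitting:
    def test_zero_variance_limit_equals_ordinary_logistic(self, loc_obs):
        """With tau pinned at 0 the fit reduces to the plain logistic MLE."""
        import statsmodels.api as sm

        fit = fit_logistic_glmm(loc_obs, LOC_SPEC, var_components="zero")
        glm = sm.GLM(loc_obs["outcome"].to_numpy(float), fit.design.X,
                     family=sm.families.Binomial()).fit()
        assert np.max(np.abs(fit.beta - glm.params)) < 1e-4
        assert fit.tau00 == 0.0

    def test_two_by_two_odds_ratio_oracle(self):
        df = _two_by_two_table()
        fit = fit_logistic_glmm(df, ModelSpec("word", ("x",)), var_components="zero")
        orx = float(np.exp(fit.beta[1]))
        assert orx == pytest.approx((8 / 2) / (6 / 4), rel=1e-3)

    def test_laplace_agrees_with_adaptive_quadrature(self, loc_obs):
        f_lap = fit_logistic_glmm(loc_obs, LOC_SPEC, method="laplace")
        f_agq = fit_logistic_glmm(loc_obs, LOC_SPEC, method="agq", n_quad=21)
        assert np.max(np.abs(f_lap.beta - f_agq.beta)) < 1e-3

    def test_agq_rejected_for_vector_random_effects(self, loc_obs):
        with pytest.raises(ValueError):
            fit_logistic_glmm(loc_obs, ModelSpec("word", ("snr",), random_slope_snr=True),
                              method="agq")

    def test_rank_deficient_design_rejected(self):
        df = _two_by_two_table()
        df["x2"] = df["x"]
        with pytest.raises(np.linalg.LinAlgError):
            fit_logistic_glmm(df, ModelSpec("word", ("x", "x2")), var_components="zero")

    def test_non_binary_outcome_rejected(self):
        df = _two_by_two_table()
        df["outcome"] = df["outcome"] * 2.0
        with pytest.raises(ValueError):
            fit_logistic_glmm(df, ModelSpec("word", ("x",)))

    def test_matches_lme4_glmer_on_small_data(self, loc_obs, tmp_path):
        """Independent cross-check against the R reference implementation."""
        spec = ModelSpec("localization", ("mean_location",))
        fit = fit_logistic_glmm(loc_obs, spec)
        csv = tmp_path / "obs.csv"
        loc_obs.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(f"""
suppressMessages(library(lme4))
d <- read.csv("{csv}")
d$ml <- relevel(factor(d$mean_location_deg), ref = "-75")
m <- glmer(outcome ~ ml + (1 | participant_id), data = d, family = binomial)
cat(fixef(m), as.numeric(VarCorr(m)$participant_id[1]), sep = "\\n")
""")
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True, timeout=300)
        vals = [float(v) for v in out.stdout.split()]
        r_beta, r_tau = np.array(vals[:-1]), vals[-1]
        assert np.max(np.abs(fit.beta - r_beta)) < 0.02
        assert fit.tau00 == pytest.approx(r_tau, abs=0.05)


class TestInference:
    def test_lrt_of_identical_models(self, loc_obs):
        f = fit_logistic_glmm(loc_obs, LOC_SPEC)
        chi2, df, p = likelihood_ratio_test(f, f)
        assert chi2 == 0.0 and df == 0 and p == 1.0

    def test_lrt_arithmetic(self):
        a = _dummy_fit(loglik=-100.0, n_params=3)
        b = _dummy_fit(loglik=-90.0, n_params=8)
        chi2, df, p = likelihood_ratio_test(a, b)
        assert chi2 == pytest.approx(20.0) and df == 5
        from scipy import stats
        assert p == pytest.approx(stats.chi2.sf(20.0, 5))

    def test_deviance_non_increasing_along_ladder(self, loc_obs):
        ladder = model_ladder(loc_obs, ModelSpec("localization", ()),
                              ["mean_location", "snr", "direction"])
        lls = ladder["loglik"].to_numpy()
        assert np.all(np.diff(lls) >= -1e-6)
        assert (ladder["chi2"] >= 0).all()

    def test_odds_ratio_table(self):
        fit = _dummy_fit(beta=np.array([np.log(2.0)]), se=np.array([0.1]),
                         names=("b",))
        tab = odds_ratios(fit)
        assert tab.odds_ratio[0] == pytest.approx(2.0)
        assert tab.ci_low[0] == pytest.approx(2.0 * np.exp(-1.96 * 0.1), rel=1e-3)
        assert tab.ci_high[0] == pytest.approx(2.0 * np.exp(1.96 * 0.1), rel=1e-3)
        zero = _dummy_fit(beta=np.array([0.0]), se=np.array([0.1]), names=("b",))
        t0 = odds_ratios(zero)
        assert t0.odds_ratio[0] == 1.0 and t0.ci_low[0] < 1.0 < t0.ci_high[0]
        assert t0.p[0] == pytest.approx(1.0)


class TestPosthoc:
    @pytest.mark.parametrize("factor,n_pairs", [
        ("mean_location", 15), ("snr", 3), ("direction", 1),
    ])
    def test_contrast_family_sizes(self, loc_obs, factor, n_pairs):
        fit = fit_logistic_glmm(loc_obs, LOC_SPEC)
        tab = posthoc_pairwise(fit, factor)
        assert len(tab) == n_pairs
        # Bonferroni with the family size of that factor
        expected = np.minimum(1.0, n_pairs * tab.p_raw)
        assert np.allclose(tab.p_adjusted, expected)

    def test_azimuth_family_is_21(self, small_cohort_module):
        _, obs = small_cohort_module
        word = obs[obs.task == "word"]
        fit = fit_logistic_glmm(word, ModelSpec("word", ("azimuth", "snr", "group")))
        assert len(posthoc_pairwise(fit, "azimuth")) == 21

    def test_contrast_estimates_are_coefficient_differences(self, loc_obs):
        fit = fit_logistic_glmm(loc_obs, LOC_SPEC)
        tab = posthoc_pairwise(fit, "mean_location").set_index("comparison")
        names = list(fit.design.names)
        b45 = fit.beta[names.index("mean_location[-45.0]")]
        b15 = fit.beta[names.index("mean_location[-15.0]")]
        assert tab.loc["-75.0 vs -45.0", "estimate"] == pytest.approx(-b45)
        assert tab.loc["-45.0 vs -15.0", "estimate"] == pytest.approx(b45 - b15)

    def test_interaction_posthoc_group_within_snr(self, small_cohort_module):
        _, obs = small_cohort_module
        word = obs[obs.task == "word"]
        spec = ModelSpec("word", ("azimuth", "snr", "group"),
                         interactions=(("snr", "group"),))
        fit = fit_logistic_glmm(word, spec)
        tab = posthoc_interaction(fit, "group", "snr")
        assert len(tab) == 3 * 6  # 6 group pairs at each of 3 SNRs
        assert set(tab["snr"]) == {"SRT", "SRT+3", "SRT+6"}


class TestPrediction:
    def test_reference_cell_is_intercept(self, loc_obs):
        fit = fit_logistic_glmm(loc_obs, LOC_SPEC)
        tab = predicted_probabilities(fit, {})
        assert tab.probability[0] == pytest.approx(float(expit(fit.beta[0])))

    def test_probability_monotone_in_level_effect(self, loc_obs):
        fit = fit_logistic_glmm(loc_obs, LOC_SPEC)
        cells = [{"mean_location": ml} for ml in (-75.0, -15.0)]
        tab = predicted_probabilities(fit, cells)
        names = list(fit.design.names)
        b = fit.beta[names.index("mean_location[-15.0]")]
        if b > 0:
            assert tab.probability[1] > tab.probability[0]

    def test_half_probability_at_zero_linear_predictor(self):
        fit = _dummy_fit(beta=np.array([0.0]), se=np.array([0.2]), names=("(Intercept)",))
        tab = predicted_probabilities(fit, {})
        assert tab.probability[0] == pytest.approx(0.5)


class TestVif:
    def test_orthogonal_balanced_design_has_unit_vifs(self, loc_obs):
        tab = vif(loc_obs, LOC_SPEC)
        assert np.allclose(tab.gvif_scaled, 1.0, atol=0.05)

    def test_duplicated_predictor_rejected(self):
        df = _two_by_two_table()
        df["x2"] = df["x"]
        with pytest.raises(np.linalg.LinAlgError):
            vif(df, ModelSpec("word", ("x", "x2")))

    def test_closed_form_for_two_correlated_predictors(self):
        rng = np.random.default_rng(0)
        n = 20_000
        a = rng.standard_normal(n)
        b = 0.9 * a + np.sqrt(1 - 0.81) * rng.standard_normal(n)
        df = pd.DataFrame({"participant_id": ["A", "B"] * (n // 2),
                           "outcome": rng.integers(0, 2, n), "a": a, "b": b})
        tab = vif(df, ModelSpec("word", ("a", "b"))).set_index("term")
        assert tab.loc["a", "gvif"] == pytest.approx(1.0 / (1.0 - 0.81), rel=0.05)


class TestR2AndIcc:
    def test_zero_tau_makes_marginal_equal_conditional(self, loc_obs):
        fit = fit_logistic_glmm(loc_obs, LOC_SPEC, var_components="zero")
        m, c = r2_nakagawa(fit)
        assert m == pytest.approx(c)
        assert fit.icc == 0.0

    def test_null_model_has_zero_marginal_r2(self, loc_obs):
        fit = fit_logistic_glmm(loc_obs, ModelSpec("localization", ()))
        m, _ = r2_nakagawa(fit)
        assert m == pytest.approx(0.0, abs=1e-9)

    def test_r2_recovers_generative_values(self):
        """Simulated-from-model R2 close to the plug-in generative value."""
        template = ListenerProfile(guess_floor_word=0.0, guess_floor_direction=0.0,
                                   loc_direction={"left": 0.0, "right": 0.3})
        _, obs = simulate_cohort(16, profile_template=template, seed=21,
                                 runs_per_block=1)
        loc = obs[obs.task == "localization"]
        fit = fit_logistic_glmm(loc, LOC_SPEC)
        # generative plug-in: same formula with the true coefficients
        eta = (template.loc_intercept
               + loc["mean_location_deg"].map(template.loc_mean_location)
               + loc["snr_condition"].map(template.loc_snr)
               + loc["direction"].map(template.loc_direction))
        vf = float(np.var(eta))
        tau = template.random_intercept_sd_loc ** 2
        m_true = vf / (vf + tau + SIGMA2_LOGISTIC)
        c_true = (vf + tau) / (vf + tau + SIGMA2_LOGISTIC)
        m, c = r2_nakagawa(fit)
        assert m == pytest.approx(m_true, abs=0.03)
        assert c == pytest.approx(c_true, abs=0.03)

    def test_icc_formula(self, loc_obs):
        fit = fit_logistic_glmm(loc_obs, LOC_SPEC)
        assert fit.icc == pytest.approx(fit.tau00 / (fit.tau00 + np.pi**2 / 3))
        assert fit.sigma2 == pytest.approx(3.29, abs=0.01)


def _dummy_fit(loglik=-10.0, n_params=1, beta=None, se=None, names=("(Intercept)",)):
    """Minimal GlmmFit stub for arithmetic-only checks."""
    from ssinva.glmm import Design

    beta = np.zeros(len(names)) if beta is None else beta
    se = np.ones(len(names)) if se is None else se
    design = Design(X=np.ones((1, len(names))), names=tuple(names),
                    term_slices={"(Intercept)": slice(0, 1)})
    return GlmmFit(
        spec=ModelSpec("word", ()), design=design, beta=beta, se=se,
        cov_beta=np.diag(se**2), theta=np.array([0.0]), re_cov=np.zeros((1, 1)),
        loglik=loglik, n_obs=100, n_groups=2, n_params=n_params, converged=True,
        method="laplace", linear_predictor_var=0.0, mean_re_variance=0.0,
    )
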