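"""Mixed-model inference: fitting, LRT reduction, ANOVA, emmeans, power."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from snakegrass.lmm import (
    FULL_TERMS,
    TWO_WAY_TERMS,
    anova_table,
    emmeans_pairwise,
    fit_lmem,
    lrt_reduce,
    omega_squared,
    power_simulation,
    stepwise_reduce,
)
from snakegrass.observers import GroundTruthModel
from tests.conftest import simulate_threshold_table

NO_THREE_WAY = FULL_TERMS[:-1]


@pytest.fixture(scope="module")
def direct_data(default_model):
    """Default ground-truth model measured directly (no staircase)."""
    return simulate_threshold_table(default_model, 12, resid_sd=0.3, seed=21)


@pytest.fixture(scope="module")
def fit_no3way(direct_data):
    return fit_lmem(direct_data, NO_THREE_WAY, method="REML")


class TestFitLmem:
    def test_out_of_range_thresholds_rejected(self, direct_data):
        bad = direct_data.copy()
        bad.loc[0, "threshold"] = 1.0
        with pytest.raises(ValueError):
            fit_lmem(bad, NO_THREE_WAY)

    def test_single_participant_rejected(self, direct_data):
        solo = direct_data[direct_data["participant_id"] == "P00"]
        with pytest.raises(ValueError):
            fit_lmem(solo, NO_THREE_WAY)

    def test_full_model_has_44_fixed_df_beyond_intercept(self, direct_data):
        fit = fit_lmem(direct_data, FULL_TERMS)
        assert fit.n_fixed == 45  # 3*3*5 cells

    def test_zero_participant_sd_recovers_near_zero_variance(self, default_model):
        model = GroundTruthModel.default(participant_sd=0.0)
        data = simulate_threshold_table(model, 12, resid_sd=0.3, seed=3)
        fit = fit_lmem(data, NO_THREE_WAY)
        assert fit.participant_var < 0.01

    def test_parameter_recovery_on_large_cohort(self, default_model):
        """Fixed effects recovered within 2 SEs for >=90% of parameters."""
        data = simulate_threshold_table(default_model, 50, resid_sd=0.3, seed=4)
        fit = fit_lmem(data, NO_THREE_WAY, method="REML")
        # exact coefficients: the generator has no 3-way term, so the
        # no-3-way design reproduces the cell means exactly
        cells = data.groupby(["eccentricity", "spacing", "wiggle"], sort=True)
        import patsy

        grid = cells.size().reset_index()[["eccentricity", "spacing", "wiggle"]]
        from snakegrass.lmm import _formula_rhs

        X = np.asarray(patsy.dmatrix(_formula_rhs(NO_THREE_WAY), grid))
        from snakegrass.geometry import Condition

        eta = np.array(
            [
                default_model.logit_threshold(Condition(r.eccentricity, r.spacing, r.wiggle))
                for r in grid.itertuples()
            ]
        )
        beta_true, *_ = np.linalg.lstsq(X, eta, rcond=None)
        se = np.sqrt(np.diag(fit.fe_cov))
        within = np.abs(fit.fe_params - beta_true) <= 2 * se
        assert within.mean() >= 0.9


class TestLRT:
    def test_three_way_drop_removes_16_parameters(self, direct_data):
        full = fit_lmem(direct_data, FULL_TERMS, "ML")
        red = fit_lmem(direct_data, NO_THREE_WAY, "ML")
        res = lrt_reduce(full, red)
        assert res.df == 16  # (3-1)(3-1)(5-1)

    def test_two_way_drop_degrees_of_freedom(self, direct_data):
        base = fit_lmem(direct_data, NO_THREE_WAY, "ML")
        no_ew = fit_lmem(
            direct_data, tuple(t for t in NO_THREE_WAY if t != "eccentricity:wiggle"), "ML"
        )
        assert lrt_reduce(base, no_ew).df == 4  # (3-1)(3-1)
        no_es = fit_lmem(
            direct_data, tuple(t for t in NO_THREE_WAY if t != "eccentricity:spacing"), "ML"
        )
        assert lrt_reduce(base, no_es).df == 8  # (3-1)(5-1)

    def test_identical_models_give_zero_statistic(self, direct_data):
        fit = fit_lmem(direct_data, NO_THREE_WAY, "ML")
        res = lrt_reduce(fit, fit)
        assert res.chi2 == 0.0 and res.df == 0

    def test_non_nested_or_reml_rejected(self, direct_data):
        a = fit_lmem(direct_data, ("eccentricity", "wiggle"), "ML")
        b = fit_lmem(direct_data, ("eccentricity", "spacing"), "ML")
        with pytest.raises(ValueError):
            lrt_reduce(a, b)
        c = fit_lmem(direct_data, NO_THREE_WAY, "REML")
        with pytest.raises(ValueError):
            lrt_reduce(c, a)

    def test_type_one_error_rate_for_absent_three_way(self, default_model):
        """The default generator has no 3-way term: the LRT should reject at
        about the nominal 5% rate."""
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            data = simulate_threshold_table(default_model, 12, resid_sd=0.3, seed=1000 + rep)
            full = fit_lmem(data, FULL_TERMS, "ML")
            red = fit_lmem(data, NO_THREE_WAY, "ML")
            if lrt_reduce(full, red).p_value <= 0.05:
                hits += 1
        lo, hi = stats.binom.ppf([0.005, 0.995], n_rep, 0.05)
        assert lo <= hits <= hi

    def test_stepwise_drops_three_way_keeps_real_interactions(self, default_model):
        dropped_3way = 0
        kept_2way = 0
        n_rep = 10
        for rep in range(n_rep):
            data = simulate_threshold_table(default_model, 12, resid_sd=0.3, seed=500 + rep)
            final, _ = stepwise_reduce(data)
            if "eccentricity:wiggle:spacing" not in final.terms:
                dropped_3way += 1
            if {"eccentricity:spacing", "eccentricity:wiggle"} <= set(final.terms):
                kept_2way += 1
        assert dropped_3way >= 9
        assert kept_2way >= 9


class TestAgainstLme4:
    def test_loglik_and_lrt_match_lme4(self, direct_data, tmp_path):
        """The ML log-likelihoods and the chi-square difference statistic
        agree with lme4 on a shared dataset."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        from scipy.special import logit

        data = direct_data.copy()
        data["logit_threshold"] = logit(data["threshold"])
        csv = tmp_path / "data.csv"
        data.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            """
            suppressMessages(library(lme4))
            d <- read.csv(commandArgs(trailingOnly=TRUE)[1])
            for (f in c("eccentricity","spacing","wiggle")) d[[f]] <- factor(d[[f]])
            full <- lmer(logit_threshold ~ eccentricity*wiggle*spacing + (1|participant_id),
                         data=d, REML=FALSE)
            red  <- lmer(logit_threshold ~ (eccentricity+wiggle+spacing)^2 + (1|participant_id),
                         data=d, REML=FALSE)
            cat(sprintf("%.6f %.6f\\n", as.numeric(logLik(full)), as.numeric(logLik(red))))
            """
        )
        out = subprocess.run(
            ["Rscript", str(script), str(csv)], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        llf_r, llr_r = (float(x) for x in out.stdout.split())
        full = fit_lmem(direct_data, FULL_TERMS, "ML")
        red = fit_lmem(direct_data, NO_THREE_WAY, "ML")
        assert full.llf == pytest.approx(llf_r, abs=1e-3)
        assert red.llf == pytest.approx(llr_r, abs=1e-3)
        res = lrt_reduce(full, red)
        assert res.chi2 == pytest.approx(2 * (llf_r - llr_r), abs=2e-3)


class TestAnova:
    def test_term_rows_and_numerator_df(self, fit_no3way):
        tbl = anova_table(fit_no3way)
        assert list(tbl["term"]) == list(NO_THREE_WAY)
        df = dict(zip(tbl["term"], tbl["df_num"]))
        assert df == {
            "eccentricity": 2,
            "wiggle": 2,
            "spacing": 4,
            "eccentricity:wiggle": 4,
            "eccentricity:spacing": 8,
            "wiggle:spacing": 8,
        }

    def test_strong_effects_are_significant(self, fit_no3way):
        tbl = anova_table(fit_no3way).set_index("term")
        assert tbl.loc["eccentricity", "p_value"] < 1e-6
        assert tbl.loc["eccentricity:spacing", "p_value"] < 1e-6

    def test_f_near_one_under_null_generator(self):
        null = GroundTruthModel.default(participant_sd=0.3)
        null.ecc[:] = 0
        null.spacing[:] = 0
        null.wiggle[:] = 0
        null.ecc_spacing[:] = 0
        null.ecc_wiggle[:] = 0
        null.spacing_wiggle[:] = 0
        fs = []
        for rep in range(40):
            data = simulate_threshold_table(null, 12, resid_sd=0.3, seed=300 + rep)
            fs.extend(anova_table(fit_lmem(data, NO_THREE_WAY, "REML"))["F"])
        assert 0.75 < np.mean(fs) < 1.25


class TestOmegaSquared:
    def test_null_model_gives_zero(self, direct_data):
        null = fit_lmem(direct_data, (), "REML")
        assert omega_squared(null, null) == pytest.approx(0.0, abs=1e-9)

    def test_near_noiseless_data_approaches_one(self, default_model):
        data = simulate_threshold_table(default_model, 12, resid_sd=0.01, seed=6)
        fit = fit_lmem(data, NO_THREE_WAY, "REML")
        assert omega_squared(fit) > 0.99

    def test_matches_known_variance_ratio(self):
        """Generator with a single eccentricity effect of known variance."""
        model = GroundTruthModel.default(participant_sd=0.3)
        c = 0.4
        model.ecc[:] = np.array([-c, 0.0, c])
        model.spacing[:] = 0
        model.wiggle[:] = 0
        model.ecc_spacing[:] = 0
        model.ecc_wiggle[:] = 0
        model.spacing_wiggle[:] = 0
        sigma_e = 0.3
        v_fixed = (2.0 / 3.0) * c**2
        expected = v_fixed / (v_fixed + sigma_e**2)
        data = simulate_threshold_table(model, 50, resid_sd=sigma_e, seed=7)
        fit = fit_lmem(data, ("eccentricity",), "REML")
        assert omega_squared(fit) == pytest.approx(expected, abs=0.02)


class TestEmmeans:
    def test_ten_spacing_contrasts_per_eccentricity(self, fit_no3way):
        res = emmeans_pairwise(fit_no3way, "spacing", by="eccentricity")
        assert len(res) == 3 * 10  # k(k-1)/2 = 10 per family

    def test_sign_convention_negative_when_increasing(self, fit_no3way):
        """Thresholds rise with spacing in the periphery, so the contrast
        'low spacing minus high spacing' is negative there."""
        res = emmeans_pairwise(fit_no3way, "spacing", by="eccentricity")
        far = [
            r for r in res
            if r.by_level == 15.75 and r.level_a == 0.70 and r.level_b == 3.54
        ]
        assert far[0].estimate < 0
        assert far[0].t_value < 0

    def test_adjusted_p_at_least_unadjusted(self, fit_no3way):
        res = emmeans_pairwise(fit_no3way, "wiggle", by=None)
        for r in res:
            unadj = 2 * stats.t.sf(abs(r.t_value), fit_no3way.ddf)
            assert r.p_adjusted >= unadj - 1e-12

    def test_absent_effect_rejected(self, direct_data):
        fit = fit_lmem(direct_data, ("eccentricity",), "REML")
        with pytest.raises(ValueError):
            emmeans_pairwise(fit, "spacing")


class TestPower:
    def test_shrink_to_zero_gives_alpha_level_power(self, default_model):
        data = simulate_threshold_table(default_model, 12, resid_sd=0.3, seed=8)
        fit = fit_lmem(data, NO_THREE_WAY, method="ML")
        res = power_simulation(
            fit, terms=("eccentricity:wiggle",), shrink=0.0, n_sim=60, rng=9
        )
        assert res[0].power_percent <= 15.0  # ~5% nominal, binomial slack

    def test_large_effects_give_full_power(self, default_model):
        data = simulate_threshold_table(default_model, 12, resid_sd=0.3, seed=10)
        fit = fit_lmem(data, NO_THREE_WAY, method="ML")
        res = power_simulation(
            fit, terms=("eccentricity:spacing",), shrink=0.85, n_sim=15, rng=11
        )
        assert res[0].power_percent >= 90.0

    def test_invalid_n_sim_rejected(self, fit_no3way):
        with pytest.raises(ValueError):
            power_simulation(fit_no3way, n_sim=0)
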