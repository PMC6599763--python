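"""Measurement model and sG×E latent growth curve estimation."""

import numpy as np
import pandas as pd
import pytest

from pcovr_gxe import (
    InformantFactorModel,
    SimulationConfig,
    fit_lgcm_sgxe,
    fit_measurement,
    informant_sensitivity,
    quadratic_robustness,
    simple_slopes,
    simulate_cohort,
)
from pcovr_gxe.growth import LatentGrowthSGxE


def _cohort(seed=0, n=400, **effects):
    cfg = SimulationConfig(
        n_subjects=n, n_snps=30, block_sizes=[15, 15],
        missing_genotype_rate=0.0, seed=seed, **effects,
    )
    _, table, truth = simulate_cohort(cfg)
    table = table.copy()
    table["C1"] = truth.true_score
    return cfg, table, truth


class TestMeasurement:
    def test_noise_free_loadings_recovered(self):
        rng = np.random.default_rng(0)
        lam = np.linspace(0.5, 0.9, 9)
        xi = rng.standard_normal(500)
        xi = (xi - xi.mean()) / xi.std()  # exactly unit-variance factor
        X = xi[:, None] * lam
        fit = fit_measurement(X)
        assert np.abs(fit.loadings - lam).max() < 1e-3
        assert fit.score_reliability > 0.999

    def test_loadings_recovered_at_scale(self):
        cfg = SimulationConfig(n_subjects=2000, n_snps=4, block_sizes=[4], seed=5)
        from pcovr_gxe import simulate_parenting

        ind, factor = simulate_parenting(cfg)
        fit = fit_measurement(ind)
        assert np.abs(fit.loadings - 0.7).max() < 0.05
        # Bartlett scores track the generating factor
        assert np.corrcoef(fit.factor_scores, factor)[0, 1] > 0.9

    def test_single_indicator_unidentified(self):
        with pytest.raises(ValueError, match="indicators"):
            fit_measurement(np.random.default_rng(1).standard_normal((100, 1)))

    def test_fiml_handles_missing_indicators(self):
        cfg = SimulationConfig(n_subjects=800, n_snps=4, block_sizes=[4], seed=6)
        from pcovr_gxe import simulate_parenting

        ind, factor = simulate_parenting(cfg)
        vals = ind.to_numpy().copy()
        rng = np.random.default_rng(6)
        vals[rng.random(vals.shape) < 0.15] = np.nan
        fit = fit_measurement(pd.DataFrame(vals, columns=ind.columns))
        assert fit.converged
        assert np.abs(fit.loadings - 0.7).max() < 0.10
        scores = InformantFactorModel().fit(pd.DataFrame(vals, columns=ind.columns)).transform(
            pd.DataFrame(vals, columns=ind.columns)
        )
        good = ~np.isnan(scores)
        assert np.corrcoef(scores[good], factor[good])[0, 1] > 0.85


class TestLgcmSgxe:
    def test_noise_free_exact_recovery(self):
        cfg, table, truth = _cohort(
            seed=11, effect_intercept_g=0.3, effect_intercept_e=0.2,
            effect_intercept_gxe=0.1, effect_slope_g=-0.1, effect_slope_e=0.05,
            growth_sds=(1e-9, 1e-9), residual_sd_outcome=1e-9,
            parenting_residual_sds=(1e-9,) * 9,
        )
        fit = fit_lgcm_sgxe(table, focal="C1")
        assert fit.coef("intercept", "C1")["b"] == pytest.approx(0.3, abs=1e-6)
        assert fit.coef("intercept", "Parenting")["b"] == pytest.approx(0.2, abs=1e-6)
        assert fit.coef("intercept", "Parenting x C1")["b"] == pytest.approx(0.1, abs=1e-6)
        assert fit.coef("slope", "C1")["b"] == pytest.approx(-0.1, abs=1e-6)
        assert fit.coef("slope", "Parenting")["b"] == pytest.approx(0.05, abs=1e-6)
        assert fit.coef("intercept", "Sex")["b"] == pytest.approx(0.0, abs=1e-6)

    def test_interaction_recovery_small_batch(self):
        bs = []
        for seed in range(12):
            cfg, table, _ = _cohort(
                seed=seed, n=1000, effect_intercept_g=0.25,
                effect_intercept_e=0.15, effect_intercept_gxe=0.10,
            )
            fit = fit_lgcm_sgxe(table, focal="C1")
            bs.append(fit.coef("intercept", "Parenting x C1")["b"])
        assert np.mean(bs) == pytest.approx(0.10, abs=0.02)

    def test_fiml_unbiased_under_mcar_outcomes(self):
        bs = []
        for seed in range(8):
            cfg, table, _ = _cohort(
                seed=100 + seed, n=500, effect_intercept_g=0.25,
                effect_intercept_gxe=0.10, missing_outcome_rate=0.20,
            )
            fit = fit_lgcm_sgxe(table, focal="C1")
            assert fit.converged
            bs.append(fit.coef("intercept", "Parenting x C1")["b"])
        # Monte Carlo error ~ 0.025/sqrt(8)
        assert np.mean(bs) == pytest.approx(0.10, abs=0.035)

    def test_robust_and_model_se_agree_under_normality(self):
        cfg, table, _ = _cohort(seed=21, n=2000, effect_intercept_g=0.25,
                                effect_intercept_e=0.15)
        model = LatentGrowthSGxE(focal="C1").fit(table)
        fit = model.fit_
        merged = fit.coefficients.merge(fit.model_se, on=["equation", "predictor"])
        ratio = merged["se"] / merged["se_model"]
        assert (np.abs(ratio - 1) < 0.10).all()

    def test_standardized_beta_consistent_with_b(self):
        cfg, table, _ = _cohort(seed=22, effect_intercept_g=0.3)
        fit = fit_lgcm_sgxe(table, focal="C1")
        tab = fit.coefficients
        for eq, eta_sd in zip(("intercept", "slope"), fit.eta_sds):
            sub = tab[tab["equation"] == eq].reset_index(drop=True)
            recomputed = sub["b"].to_numpy() * fit.predictor_sds / eta_sd
            assert np.allclose(sub["beta"].to_numpy(), recomputed, atol=1e-10)

    def test_ci_is_b_plus_minus_1p96_se(self):
        cfg, table, _ = _cohort(seed=23)
        fit = fit_lgcm_sgxe(table, focal="C1")
        tab = fit.coefficients
        assert np.allclose(tab["ci_low"], tab["b"] - 1.96 * tab["se"])
        assert np.allclose(tab["ci_high"], tab["b"] + 1.96 * tab["se"])

    def test_rge_reported_near_planted_value(self):
        cfg, table, _ = _cohort(seed=24, n=2000, rge=0.3)
        fit = fit_lgcm_sgxe(table, focal="C1")
        r = fit.rge.set_index("pair").loc["C1 ~ Parenting", "r"]
        # attenuated slightly by factor-score unreliability
        assert r == pytest.approx(0.3, abs=0.07)

    def test_fewer_than_three_waves_rejected(self):
        cfg, table, _ = _cohort(seed=25, n=120)
        with pytest.raises(ValueError, match="waves"):
            fit_lgcm_sgxe(table.drop(columns=["y_w3"]), focal="C1")

    def test_missing_focal_component_rejected(self):
        cfg, table, _ = _cohort(seed=26, n=120)
        with pytest.raises(ValueError, match="focal"):
            fit_lgcm_sgxe(table, focal="C9")


class TestSimpleSlopes:
    def test_flat_model_flat_cells(self):
        cfg, table, _ = _cohort(
            seed=31, growth_means=(3.0, 0.0), growth_sds=(1e-9, 1e-9),
            residual_sd_outcome=1e-9, parenting_residual_sds=(1e-9,) * 9,
        )
        fit = fit_lgcm_sgxe(table, focal="C1")
        traj = simple_slopes(fit)
        assert np.allclose(traj["predicted"], 3.0, atol=1e-6)

    def test_positive_main_and_interaction_orders_cells(self):
        cfg, table, _ = _cohort(
            seed=32, effect_intercept_g=0.3, effect_intercept_e=0.2,
            effect_intercept_gxe=0.15, growth_sds=(1e-9, 1e-9),
            residual_sd_outcome=1e-9, parenting_residual_sds=(1e-9,) * 9,
        )
        fit = fit_lgcm_sgxe(table, focal="C1")
        traj = simple_slopes(fit)
        w1 = traj[traj["wave"] == 1].set_index(["component_level", "parenting_level"])
        assert w1.loc[(1, 1), "predicted"] == w1["predicted"].max()

    def test_dual_risk_pattern_low_g_insensitive(self):
        # positive main effects with interaction equal to environment effect:
        # at G = -1 SD the environment effect cancels (low-risk flat profile)
        cfg, table, _ = _cohort(
            seed=33, n=1500, effect_intercept_g=0.3, effect_intercept_e=0.15,
            effect_intercept_gxe=0.15,
        )
        fit = fit_lgcm_sgxe(table, focal="C1")
        traj = simple_slopes(fit)
        w1 = traj[traj["wave"] == 1].set_index(["component_level", "parenting_level"])
        high_g_spread = w1.loc[(1, 1), "predicted"] - w1.loc[(1, -1), "predicted"]
        low_g_spread = w1.loc[(-1, 1), "predicted"] - w1.loc[(-1, -1), "predicted"]
        assert w1.loc[(1, 1), "predicted"] == w1["predicted"].max()
        assert abs(low_g_spread) < high_g_spread / 2


class TestQuadraticRobustness:
    def test_linear_model_unaffected_by_quadratic_terms(self):
        diffs = []
        for seed in range(6):
            cfg, table, _ = _cohort(
                seed=40 + seed, n=800, effect_intercept_g=0.25,
                effect_intercept_e=0.15, effect_intercept_gxe=0.10,
            )
            out = quadratic_robustness(table, focal="C1")
            b0 = out["base"].coef("intercept", "Parenting x C1")["b"]
            b1 = out["quadratic"].coef("intercept", "Parenting x C1")["b"]
            q = out["quadratic"].coef("intercept", "C1^2")["b"]
            diffs.append(b1 - b0)
            assert abs(q) < 0.08
        assert abs(np.mean(diffs)) < 0.01

    def test_zero_variance_component_rejected(self):
        cfg, table, _ = _cohort(seed=50, n=120)
        table["C1"] = 0.0
        with pytest.raises(ValueError, match="zero-variance"):
            fit_lgcm_sgxe(table, focal="C1", quadratic=True)


class TestInformantSensitivity:
    def test_invariant_signal_gives_similar_interactions(self):
        cfg, table, _ = _cohort(
            seed=60, n=1500, effect_intercept_g=0.25, effect_intercept_e=0.15,
            effect_intercept_gxe=0.10,
        )
        fits = informant_sensitivity(table, focal="C1")
        assert set(fits) == {"self", "mother", "father"}
        bs = [f.coef("intercept", "Parenting x C1")["b"] for f in fits.values()]
        ses = [f.coef("intercept", "Parenting x C1")["se"] for f in fits.values()]
        assert max(bs) - min(bs) < 4 * max(ses)

    def test_identical_indicator_sets_identical_fits(self):
        cfg, table, _ = _cohort(seed=61, n=300, effect_intercept_gxe=0.1)
        # copy self indicators onto the other informants
        for w in (1, 2, 3):
            table[f"par_mother_w{w}"] = table[f"par_self_w{w}"]
            table[f"par_father_w{w}"] = table[f"par_self_w{w}"]
        fits = informant_sensitivity(table, focal="C1")
        b = [f.coef("intercept", "Parenting x C1")["b"] for f in fits.values()]
        assert np.ptp(b) < 1e-8

    def test_noise_informant_inflates_se(self):
        cfg, table, _ = _cohort(seed=62, n=800, effect_intercept_e=0.3)
        rng = np.random.default_rng(62)
        for w in (1, 2, 3):  # father reports pure noise
            table[f"par_father_w{w}"] = rng.standard_normal(len(table))
        fits = informant_sensitivity(table, focal="C1")
        se_self = fits["self"].coef("intercept", "Parenting")["se"]
        se_father = fits["father"].coef("intercept", "Parenting")["se"]
        assert se_father > se_self
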