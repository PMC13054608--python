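"""Mixed-model fitting, selection, contrasts and simple slopes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from freqtagsl import models
from freqtagsl.models import (
    BASE_SNR_MODEL,
    BASE_SNR_STEPS,
    LEARNING_INDEX_MODEL,
    PREFERENCE_LI_MODEL,
    ModelFit,
    ModelSpec,
    RankDeficiencyError,
    compare_models,
    fit_lmm,
    intraclass_correlation,
    marginal_contrasts,
    simple_slopes,
)
from freqtagsl.paradigm import InvalidInputError

GEN = dict(
    Intercept=0.302, T2=0.100, T3=0.002, centred_order=-0.024,
    centred_looking=0.029, t2_block=0.001, t3_block=0.025,
)


def _design(n_subj=18, n_blocks=8, rng=None):
    rng = np.random.default_rng(0) if rng is None else rng
    rows = []
    for i in range(n_subj):
        for tp in ("T1", "T2", "T3"):
            look = rng.uniform(7, 20, n_blocks)
            for b in range(n_blocks):
                rows.append(dict(subject_id=f"s{i}", timepoint=tp,
                                 valid_order=b + 1, looking_s=look[b]))
    df = pd.DataFrame(rows)
    df["centred_order"] = df.valid_order - df.valid_order.mean()
    df["centred_looking"] = df.looking_s - df.looking_s.mean()
    return df


def _outcome(df, noise_sd=0.0, ranef_sd=0.0, rng=None):
    rng = np.random.default_rng(1) if rng is None else rng
    is2 = (df.timepoint == "T2").astype(float)
    is3 = (df.timepoint == "T3").astype(float)
    y = (
        GEN["Intercept"] + GEN["T2"] * is2 + GEN["T3"] * is3
        + GEN["centred_order"] * df.centred_order
        + GEN["centred_looking"] * df.centred_looking
        + GEN["t2_block"] * is2 * df.centred_order
        + GEN["t3_block"] * is3 * df.centred_order
    )
    if ranef_sd:
        b = dict(zip(df.subject_id.unique(),
                     rng.normal(0, ranef_sd, df.subject_id.nunique())))
        y = y + df.subject_id.map(b)
    if noise_sd:
        y = y + rng.normal(0, noise_sd, len(df))
    return y


class TestFitLMM:
    def test_noise_free_exact_recovery(self):
        df = _design()
        df["log_base_snr"] = _outcome(df)
        fit = fit_lmm(BASE_SNR_MODEL, df)
        for name, value in [
            ("Intercept", GEN["Intercept"]), ("T2", GEN["T2"]), ("T3", GEN["T3"]),
            ("centred_order", GEN["centred_order"]),
            ("centred_looking", GEN["centred_looking"]),
            ("T2:centred_order", GEN["t2_block"]),
            ("T3:centred_order", GEN["t3_block"]),
        ]:
            assert fit.params[name] == pytest.approx(value, abs=1e-6)

    def test_wald_ci_halfwidth_is_1p96_se(self, block_table):
        fit = fit_lmm(BASE_SNR_MODEL, block_table)
        np.testing.assert_allclose(
            fit.ci_high - fit.params, 1.96 * fit.se, atol=1e-9
        )
        np.testing.assert_allclose(
            fit.params - fit.ci_low, 1.96 * fit.se, atol=1e-9
        )

    def test_variance_components_and_icc_recovered(self):
        df = _design(n_subj=60, n_blocks=8)
        df["log_base_snr"] = _outcome(df, noise_sd=np.sqrt(0.043),
                                      ranef_sd=np.sqrt(0.013))
        fit = fit_lmm(BASE_SNR_MODEL, df)
        assert fit.var_resid == pytest.approx(0.043, abs=0.01)
        assert fit.var_intercept == pytest.approx(0.013, abs=0.01)
        assert 0.0 <= fit.icc <= 1.0

    def test_centering_invariance(self, block_table):
        fit = fit_lmm(BASE_SNR_MODEL, block_table)
        shifted = block_table.copy()
        shifted["centred_order"] = (
            shifted["valid_order"] + 5.0
            - (shifted["valid_order"] + 5.0).mean()
        )
        fit2 = fit_lmm(BASE_SNR_MODEL, shifted)
        pd.testing.assert_series_equal(fit.params, fit2.params, atol=1e-8, rtol=1e-6)

    def test_rank_deficiency_names_aliased_term(self, block_table):
        df = block_table.copy()
        df["copy_of_order"] = df["centred_order"]
        spec = ModelSpec("aliased", "log_base_snr ~ centred_order + copy_of_order")
        with pytest.raises(RankDeficiencyError, match="copy_of_order"):
            fit_lmm(spec, df)

    def test_degenerate_random_intercept_falls_back_to_ols(self, rng):
        n = 90
        df = pd.DataFrame(
            dict(
                subject_id=np.repeat([f"s{i}" for i in range(30)], 3),
                timepoint=np.tile(["T1", "T2", "T3"], 30),
                learning_index=rng.normal(0, 0.2, n),
            )
        )
        df["preference_score"] = rng.normal(0, 1.0, n)  # no subject structure
        fit = fit_lmm(PREFERENCE_LI_MODEL, df)
        assert fit.method == "OLS" and fit.degenerate_random
        assert fit.icc == 0.0


class TestIntraclassCorrelation:
    def test_reported_variance_components(self):
        assert intraclass_correlation(0.013, 0.043) == pytest.approx(0.232, abs=0.001)

    def test_bounds(self):
        assert intraclass_correlation(0.0, 1.0) == 0.0
        assert intraclass_correlation(1.0, 0.0) == 1.0
        with pytest.raises(InvalidInputError):
            intraclass_correlation(-0.1, 0.1)


class TestCompareModels:
    def test_ladder_selects_model_with_strong_covariates(self, block_table):
        report = compare_models(BASE_SNR_STEPS, block_table)
        assert report.attrs["selected"] == "base_snr"
        assert report.selected.sum() == 1

    def test_pure_noise_covariate_lrt_is_calibrated(self):
        # LRT p for one useless covariate should be ~ Uniform(0, 1)
        pvals = []
        for s in range(120):
            rng = np.random.default_rng(s)
            df = _design(n_subj=10, n_blocks=5, rng=rng)
            df["y"] = _outcome(df, noise_sd=0.2, ranef_sd=0.1, rng=rng)
            df["junk"] = rng.standard_normal(len(df))
            report = compare_models(
                [ModelSpec("m0", "y ~ timepoint"), ModelSpec("m1", "y ~ timepoint + junk")],
                df,
            )
            pvals.append(report.lrt_p.iloc[1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.005

    def test_non_nested_models_rejected(self, block_table):
        with pytest.raises(InvalidInputError):
            compare_models(
                [
                    ModelSpec("a", "log_base_snr ~ centred_order"),
                    ModelSpec("b", "log_base_snr ~ centred_looking"),
                ],
                block_table,
            )


class TestMarginalContrasts:
    def test_zero_timepoint_effects_give_null_contrasts(self):
        df = _design()
        flat = {**GEN, "T2": 0.0, "T3": 0.0, "t2_block": 0.0, "t3_block": 0.0}
        df["log_base_snr"] = (
            flat["Intercept"] + flat["centred_order"] * df.centred_order
            + flat["centred_looking"] * df.centred_looking
        )
        fit = fit_lmm(BASE_SNR_MODEL, df)
        res = marginal_contrasts(fit, adjust="holm")
        assert np.allclose(res.contrasts.estimate, 0.0, atol=1e-8)
        assert (res.contrasts.p_adj > 0.999).all()

    def test_interaction_orders_contrasts_across_grid(self, block_table):
        # the generating T3 x order interaction is positive: the T3 - T1
        # difference must grow from low to high block order
        fit = fit_lmm(BASE_SNR_MODEL, block_table)
        res = marginal_contrasts(fit, adjust="tukey")
        t31 = res.contrasts[res.contrasts.contrast == "T3 - T1"]
        lo, mid, hi = t31.sort_values("order").estimate
        assert lo < mid < hi

    def test_wide_grid_preserves_ordering(self, block_table):
        fit = fit_lmm(BASE_SNR_MODEL, block_table)
        narrow = marginal_contrasts(fit, sd_multipliers=(-1, 0, 1))
        with pytest.warns(UserWarning):
            wide = marginal_contrasts(fit, sd_multipliers=(-2, 0, 2))
        n_mid = narrow.contrasts[narrow.contrasts.order == 0.0]
        w_mid = wide.contrasts[wide.contrasts.order == 0.0]
        pd.testing.assert_frame_equal(n_mid.reset_index(drop=True),
                                      w_mid.reset_index(drop=True))


class TestSimpleSlopes:
    def test_slopes_from_published_coefficients(self):
        fit = ModelFit.from_coefficients(
            PREFERENCE_LI_MODEL,
            {
                "Intercept": -0.070, "learning_index": -0.969,
                "T2": 0.762, "T3": 0.554,
                "learning_index:T2": 2.641, "learning_index:T3": 5.390,
            },
        )
        slopes = simple_slopes(fit).set_index("timepoint")
        assert slopes.loc["T1", "slope"] == pytest.approx(-0.969)
        assert slopes.loc["T2", "slope"] == pytest.approx(1.672)
        assert slopes.loc["T3", "slope"] == pytest.approx(4.421)

    def test_no_interaction_terms_gives_equal_slopes(self, rng):
        n = 120
        df = pd.DataFrame(
            dict(
                subject_id=np.repeat([f"s{i}" for i in range(40)], 3),
                timepoint=np.tile(["T1", "T2", "T3"], 40),
                learning_index=rng.normal(0, 0.2, n),
            )
        )
        df["preference_score"] = (
            0.5 + 2.0 * df.learning_index
        )  # exact, slope equal everywhere
        fit = fit_lmm(PREFERENCE_LI_MODEL, df)
        slopes = simple_slopes(fit)
        assert np.allclose(slopes.slope, 2.0, atol=1e-6)

    def test_missing_interaction_rejected(self, block_table):
        fit = fit_lmm(LEARNING_INDEX_MODEL, block_table)
        with pytest.raises(InvalidInputError):
            simple_slopes(fit)
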