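"""Longitudinal mixed-effects models for block-level entrainment outcomes.

All reported models are random-intercept LMMs fit by REML (ML refits for
likelihood-ratio comparisons), with treatment coding and T1 as the
reference timepoint.  Wald 95% CIs are b +/- 1.96*SE.  t statistics are
referenced to a Student t with residual degrees of freedom
(n_obs - k_fixed); with ~480 residual df this agrees with
finite-sample-corrected approximations to reported precision.
When the random-intercept variance of the brain-behaviour model
estimates to zero the model is refit by OLS and flagged, which leaves
the fixed effects essentially unchanged while avoiding an
overparameterized fit.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .paradigm import InvalidInputError

WALD_Z = 1.96
TIMEPOINTS = ("T1", "T2", "T3")


def intraclass_correlation(var_intercept: float, var_resid: float) -> float:
    """ICC of a random-intercept model: between-subject share of variance."""
    if var_intercept < 0 or var_resid < 0:
        raise InvalidInputError("variance components must be non-negative")
    total = var_intercept + var_resid
    return var_intercept / total if total > 0 else 0.0


class RankDeficiencyError(ValueError):
    """Raised when the fixed-effects design matrix is rank deficient."""


@dataclass(frozen=True)
class ModelSpec:
    """One model equation: outcome, fixed effects, random intercept."""

    name: str
    formula: str
    group: str | None = "subject_id"          # None: no random intercept
    ols_fallback_on_degenerate: bool = False  # refit OLS if intercept var ~ 0

    @property
    def outcome(self) -> str:
        return self.formula.split("~")[0].strip()


BASE_SNR_MODEL = ModelSpec(
    name="base_snr",
    formula="log_base_snr ~ timepoint * centred_order + centred_looking",
)
DOUBLET_SNR_MODEL = ModelSpec(
    name="doublet_snr",
    formula="log_doublet_snr ~ timepoint * centred_order + centred_looking",
)
LEARNING_INDEX_MODEL = ModelSpec(
    name="learning_index",
    formula="learning_index ~ timepoint + centred_order",
)
PREFERENCE_TIMEPOINT_MODEL = ModelSpec(
    name="preference_timepoint",
    formula="preference_score ~ timepoint",
)
PREFERENCE_LI_MODEL = ModelSpec(
    name="preference_learning",
    formula="preference_score ~ learning_index * timepoint",
    ols_fallback_on_degenerate=True,
)
TRIAL_LOOKING_MODEL = ModelSpec(
    name="trial_looking",
    formula="looking_s ~ trial_type * timepoint",
)

#: stepwise ladders used by the selection procedure
BASE_SNR_STEPS = (
    ModelSpec("base_snr_0", "log_base_snr ~ timepoint"),
    ModelSpec("base_snr_1", "log_base_snr ~ timepoint + centred_order"),
    ModelSpec("base_snr_2", "log_base_snr ~ timepoint * centred_order"),
    BASE_SNR_MODEL,
)
LEARNING_INDEX_STEPS = (
    ModelSpec("learning_index_0", "learning_index ~ timepoint"),
    LEARNING_INDEX_MODEL,
    ModelSpec("learning_index_2", "learning_index ~ timepoint * centred_order"),
)


@dataclass
class ModelFit:
    """Coefficients, Wald CIs, variance components and fit statistics."""

    spec: ModelSpec
    method: str                  # "REML" | "ML" | "OLS"
    params: pd.Series
    se: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    df_resid: int
    var_intercept: float
    var_resid: float
    icc: float
    llf: float
    aic: float
    n_obs: int
    n_groups: int
    degenerate_random: bool
    cov_params: pd.DataFrame = field(repr=False)
    data: pd.DataFrame = field(repr=False)

    @classmethod
    def from_coefficients(
        cls,
        spec: ModelSpec,
        params: dict[str, float],
        cov: pd.DataFrame | None = None,
        df_resid: int = 10**6,
    ) -> "ModelFit":
        """A fit object from externally given coefficients.

        Useful for evaluating derived quantities (simple slopes, marginal
        means) from published coefficient tables; SEs are zero unless a
        covariance is supplied.
        """
        p = pd.Series(params, dtype=float)
        if cov is None:
            cov = pd.DataFrame(0.0, index=p.index, columns=p.index)
        se = pd.Series(np.sqrt(np.diag(cov)), index=p.index)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (p / se).fillna(0.0)
        return cls(
            spec=spec, method="external", params=p, se=se, tvalues=t,
            pvalues=pd.Series(1.0, index=p.index),
            ci_low=p - WALD_Z * se, ci_high=p + WALD_Z * se,
            df_resid=df_resid, var_intercept=0.0, var_resid=0.0, icc=0.0,
            llf=float("nan"), aic=float("nan"), n_obs=0, n_groups=0,
            degenerate_random=False, cov_params=cov, data=pd.DataFrame(),
        )

    @property
    def sd_intercept(self) -> float:
        return float(np.sqrt(self.var_intercept))

    @property
    def sd_resid(self) -> float:
        return float(np.sqrt(self.var_resid))

    def summary_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.params, "se": self.se,
                "ci_low": self.ci_low, "ci_high": self.ci_high,
                "t": self.tvalues, "p": self.pvalues,
            }
        )

    def report(self) -> dict:
        return {
            "model": self.spec.name,
            "equation": self.spec.formula,
            "method": self.method,
            "df_convention": "residual (n_obs - k_fixed)",
            "fixed_effects": {
                name: {
                    "estimate": float(self.params[name]),
                    "se": float(self.se[name]),
                    "ci": [float(self.ci_low[name]), float(self.ci_high[name])],
                    "t": float(self.tvalues[name]),
                    "p": float(self.pvalues[name]),
                }
                for name in self.params.index
            },
            "random_effects": {
                "intercept_variance": self.var_intercept,
                "intercept_sd": self.sd_intercept,
                "residual_variance": self.var_resid,
                "residual_sd": self.sd_resid,
                "degenerate": self.degenerate_random,
            },
            "icc": self.icc,
            "log_likelihood": self.llf,
            "aic": self.aic,
            "n_obs": self.n_obs,
            "n_participants": self.n_groups,
        }


def _tidy_name(name: str) -> str:
    """Map patsy coefficient names to field-standard labels."""
    name = re.sub(r"timepoint\[T\.(T\d)\]", r"\1", name)
    name = re.sub(r"trial_type\[T\.([a-z]+)\]", r"\1", name)
    return name


def _check_rank(exog: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        _, r = np.linalg.qr(exog)
        aliased = [names[i] for i in np.flatnonzero(np.abs(np.diag(r)) < 1e-10)]
        raise RankDeficiencyError(
            f"design is rank deficient (rank {rank} < {exog.shape[1]}); "
            f"aliased term(s): {', '.join(_tidy_name(n) for n in aliased)}"
        )


def fit_lmm(spec: ModelSpec, data: pd.DataFrame, reml: bool = True) -> ModelFit:
    """Fit one random-intercept LMM (or plain OLS for group-free specs).

    Returns a :class:`ModelFit` with Wald CIs (b +/- 1.96 SE), t tests on
    residual df, variance components, ICC, log-likelihood and AIC.  If
    the spec allows it and the intercept variance collapses to ~0, the
    model is refit by OLS and ``degenerate_random`` is set.
    """
    df = data.copy()
    if "timepoint" in df:
        df["timepoint"] = pd.Categorical(df["timepoint"], categories=TIMEPOINTS)
        df["timepoint"] = df["timepoint"].cat.remove_unused_categories()

    if spec.group is None:
        return _fit_ols(spec, df, degenerate=False)

    model = smf.mixedlm(spec.formula, df, groups=df[spec.group])
    _check_rank(model.exog, model.exog_names)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=reml)
        var_int = float(np.asarray(res.cov_re)[0, 0])
        var_resid = float(res.scale)
        if spec.ols_fallback_on_degenerate and var_int <= 1e-8 * max(var_resid, 1e-12):
            return _fit_ols(spec, df, degenerate=True)
        bse_fe = res.bse_fe.to_numpy()
        cov_arr = np.asarray(res.cov_params())

    k = len(res.fe_params)
    names = [_tidy_name(n) for n in res.fe_params.index]
    params = pd.Series(res.fe_params.to_numpy(), index=names)
    se = pd.Series(bse_fe, index=names)
    tvals = params / se
    df_resid = int(res.nobs - k)
    pvals = pd.Series(2 * stats.t.sf(np.abs(tvals), df_resid), index=names)
    cov = pd.DataFrame(cov_arr[:k, :k], index=names, columns=names)
    icc = intraclass_correlation(var_int, var_resid)
    # MixedLMResults does not define AIC; use -2 llf + 2 * n_parameters
    aic = -2.0 * res.llf + 2.0 * (k + 2)
    return ModelFit(
        spec=spec, method="REML" if reml else "ML",
        params=params, se=se, tvalues=tvals, pvalues=pvals,
        ci_low=params - WALD_Z * se, ci_high=params + WALD_Z * se,
        df_resid=df_resid, var_intercept=var_int, var_resid=var_resid,
        icc=float(icc), llf=float(res.llf), aic=float(aic),
        n_obs=int(res.nobs), n_groups=df[spec.group].nunique(),
        degenerate_random=False, cov_params=cov, data=df,
    )


def _fit_ols(spec: ModelSpec, df: pd.DataFrame, degenerate: bool) -> ModelFit:
    model = smf.ols(spec.formula, df)
    _check_rank(model.exog, model.exog_names)
    res = model.fit()
    names = [_tidy_name(n) for n in res.params.index]
    params = pd.Series(res.params.to_numpy(), index=names)
    se = pd.Series(res.bse.to_numpy(), index=names)
    tvals = params / se
    pvals = pd.Series(2 * stats.t.sf(np.abs(tvals), res.df_resid), index=names)
    cov = pd.DataFrame(np.asarray(res.cov_params()), index=names, columns=names)
    n_groups = df[spec.group].nunique() if spec.group and spec.group in df else 0
    return ModelFit(
        spec=spec, method="OLS",
        params=params, se=se, tvalues=tvals, pvalues=pvals,
        ci_low=params - WALD_Z * se, ci_high=params + WALD_Z * se,
        df_resid=int(res.df_resid), var_intercept=0.0,
        var_resid=float(res.mse_resid), icc=0.0,
        llf=float(res.llf), aic=float(res.aic),
        n_obs=int(res.nobs), n_groups=n_groups,
        degenerate_random=degenerate, cov_params=cov, data=df,
    )


def compare_models(
    specs: Sequence[ModelSpec],
    data: pd.DataFrame,
    alpha: float = 0.05,
    aic_improvement: float = -2.0,
) -> pd.DataFrame:
    """Stepwise selection over a nested ladder of model specs.

    Models are refit by ML; each step is compared with the current best
    by likelihood-ratio test and change in AIC, and is adopted when
    LRT p < alpha or delta-AIC < `aic_improvement`.  The report carries
    `selected` flags; ``df.attrs['selected']`` names the winner.
    """
    if len(specs) < 2:
        raise InvalidInputError("need at least two models to compare")
    fits = [fit_lmm(s, data, reml=False) for s in specs]
    for prev, cur in zip(fits, fits[1:]):
        if not set(prev.params.index) <= set(cur.params.index):
            raise InvalidInputError(
                f"models {prev.spec.name!r} and {cur.spec.name!r} are not nested"
            )
    rows = [
        dict(model=fits[0].spec.name, k=len(fits[0].params), llf=fits[0].llf,
             aic=fits[0].aic, chi2=np.nan, ddf=np.nan, lrt_p=np.nan, delta_aic=np.nan)
    ]
    best = 0
    for i, fit in enumerate(fits[1:], start=1):
        ref = fits[best]
        chi2 = 2.0 * (fit.llf - ref.llf)
        ddf = len(fit.params) - len(ref.params)
        p = float(stats.chi2.sf(max(chi2, 0.0), ddf)) if ddf > 0 else 1.0
        d_aic = fit.aic - ref.aic
        rows.append(
            dict(model=fit.spec.name, k=len(fit.params), llf=fit.llf, aic=fit.aic,
                 chi2=chi2, ddf=ddf, lrt_p=p, delta_aic=d_aic)
        )
        if p < alpha or d_aic < aic_improvement:
            best = i
    out = pd.DataFrame(rows)
    out["selected"] = [i == best for i in range(len(fits))]
    out.attrs["selected"] = fits[best].spec.name
    return out


def _effect_row(fit: ModelFit, timepoint: str, order: float = 0.0,
                looking: float = 0.0, li: float | None = None) -> pd.Series:
    """Linear-combination vector for a model-implied mean."""
    c = pd.Series(0.0, index=fit.params.index)
    c["Intercept"] = 1.0
    for tp in ("T2", "T3"):
        if timepoint == tp and tp in c.index:
            c[tp] = 1.0
    if "centred_order" in c.index:
        c["centred_order"] = order
        for tp in ("T2", "T3"):
            key = f"{tp}:centred_order"
            if timepoint == tp and key in c.index:
                c[key] = order
    if "centred_looking" in c.index:
        c["centred_looking"] = looking
    if li is not None and "learning_index" in c.index:
        c["learning_index"] = li
        for tp in ("T2", "T3"):
            key = f"learning_index:{tp}"
            if timepoint == tp and key in c.index:
                c[key] = li
    return c


def _lincomb(fit: ModelFit, c: pd.Series) -> tuple[float, float]:
    est = float(c @ fit.params)
    var = float(c @ fit.cov_params @ c)
    return est, float(np.sqrt(max(var, 0.0)))


def _t_and_p(est: float, se: float, df: int) -> tuple[float, float]:
    # an SE at numerical zero means a deterministic (noise-free) fit
    if se <= 1e-10:
        return 0.0, 1.0
    t = est / se
    return t, float(2 * stats.t.sf(abs(t), df))


def _adjust(pvals: np.ndarray, tvals: np.ndarray, df: int, method: str,
            n_groups: int) -> np.ndarray:
    if method == "holm":
        return multipletests(pvals, method="holm")[1]
    if method == "tukey":
        q = np.abs(tvals) * np.sqrt(2.0)
        return stats.studentized_range.sf(q, n_groups, df)
    raise InvalidInputError(f"unknown adjustment {method!r}")


@dataclass(frozen=True)
class ContrastResult:
    marginal_means: pd.DataFrame
    contrasts: pd.DataFrame
    adjust: str
    grid: tuple[float, ...]


def marginal_contrasts(
    fit: ModelFit,
    sd_multipliers: Sequence[float] = (-1.0, 0.0, 1.0),
    adjust: str = "holm",
) -> ContrastResult:
    """Timepoint contrasts at representative block-order values.

    Marginal means are estimated at `sd_multipliers` x SD(block order)
    around its (centred) mean, with other covariates at zero; all
    pairwise timepoint differences are tested within each grid point and
    adjusted with Holm or Tukey.
    """
    if not any(tp in fit.params.index for tp in ("T2", "T3")):
        raise InvalidInputError("fitted model has no timepoint term")
    sd = float(fit.data["centred_order"].std(ddof=1)) if "centred_order" in fit.data else 0.0
    grid = tuple(float(m) * sd for m in sd_multipliers)
    obs_range = (
        (fit.data["centred_order"].min(), fit.data["centred_order"].max())
        if "centred_order" in fit.data else (0.0, 0.0)
    )
    timepoints = [tp for tp in TIMEPOINTS if tp == "T1" or tp in fit.params.index]

    means, contrasts = [], []
    for g in grid:
        if not obs_range[0] <= g <= obs_range[1]:
            warnings.warn(f"grid value {g:.3f} outside observed block-order range", stacklevel=2)
        rows = {tp: _effect_row(fit, tp, order=g) for tp in timepoints}
        for tp, c in rows.items():
            est, se = _lincomb(fit, c)
            means.append(dict(order=g, timepoint=tp, estimate=est, se=se))
        block = []
        for i, a in enumerate(timepoints):
            for b in timepoints[i + 1:]:
                diff = rows[b] - rows[a]
                est, se = _lincomb(fit, diff)
                t, p = _t_and_p(est, se, fit.df_resid)
                block.append(dict(order=g, contrast=f"{b} - {a}", estimate=est,
                                  se=se, t=t, p=p))
        bl = pd.DataFrame(block)
        bl["p_adj"] = _adjust(bl["p"].to_numpy(), bl["t"].to_numpy(),
                              fit.df_resid, adjust, len(timepoints))
        contrasts.append(bl)
    return ContrastResult(
        marginal_means=pd.DataFrame(means),
        contrasts=pd.concat(contrasts, ignore_index=True),
        adjust=adjust, grid=grid,
    )


def simple_slopes(fit: ModelFit, adjust: str = "tukey") -> pd.DataFrame:
    """Per-timepoint slopes of preference on the learning index.

    slope(T1) = b_LI; slope(Tk) = b_LI + b_{LI:Tk}.  SEs come from the
    coefficient covariance; pairwise slope differences are
    Tukey-adjusted.  The pairwise table is in ``df.attrs['pairwise']``.
    """
    if "learning_index" not in fit.params.index:
        raise InvalidInputError("model has no learning-index term")
    if not any(f"learning_index:{tp}" in fit.params.index for tp in ("T2", "T3")):
        raise InvalidInputError("model has no learning-index x timepoint interaction")

    vecs = {}
    for tp in TIMEPOINTS:
        c = pd.Series(0.0, index=fit.params.index)
        c["learning_index"] = 1.0
        key = f"learning_index:{tp}"
        if key in c.index:
            c[key] = 1.0
        vecs[tp] = c
    rows = []
    for tp, c in vecs.items():
        est, se = _lincomb(fit, c)
        t, p = _t_and_p(est, se, fit.df_resid)
        rows.append(dict(timepoint=tp, slope=est, se=se,
                         ci_low=est - WALD_Z * se, ci_high=est + WALD_Z * se,
                         t=t, p=p))
    out = pd.DataFrame(rows)

    pairs = []
    tps = list(vecs)
    for i, a in enumerate(tps):
        for b in tps[i + 1:]:
            est, se = _lincomb(fit, vecs[b] - vecs[a])
            t, p = _t_and_p(est, se, fit.df_resid)
            pairs.append(dict(contrast=f"{b} - {a}", estimate=est, se=se, t=t, p=p))
    pw = pd.DataFrame(pairs)
    pw["p_adj"] = _adjust(pw["p"].to_numpy(), pw["t"].to_numpy(),
                          fit.df_resid, adjust, len(tps))
    out.attrs["pairwise"] = pw
    return out
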