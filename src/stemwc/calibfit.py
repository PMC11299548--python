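"""Re-derive sqrt(epsilon) -> VWC calibrations from segment experiments.

A calibration experiment yields one row per wood segment: gravimetric VWC
against sqrt(epsilon), inside a species/individual hierarchy. This module
fits

* a pooled ordinary-least-squares line (the TTC form),
* per-species lines plus the interaction-vs-main-effects ANOVA,
* a linear mixed model with random intercepts for species and for
  individuals nested in species (optionally a species-mean wood-density
  covariate), with marginal/conditional R2 by variance partition,
* the one-slope calibration (OSC): first-order differencing within a
  configurable unit followed by through-origin regression of
  delta-VWC on delta-sqrt(epsilon),

and the shared fit metrics (R2, RMSE, MAE, RAE).

Mixed models are estimated with statsmodels MixedLM: REML by default for
variance components, maximum likelihood for likelihood-ratio comparisons.
"""

from __future__ import annotations

import warnings
from collections import namedtuple
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import LinearCalibration, ABSOLUTE, RELATIVE_ONLY
from .exceptions import (
    ConvergenceError,
    DataQualityWarning,
    MetricsError,
    NestingError,
    OrderingError,
    RankError,
)

#: canonical segment-table columns (see io.read_segment_table)
SEGMENT_COLUMNS = (
    "species", "individual", "segment", "sample", "treatment", "order_index",
    "sqrt_epsilon", "vwc", "temperature", "sensor_id", "wood_density",
)

#: sanity band on gravimetric VWC; wider than physical to admit measurement
#: error while still rejecting unit mistakes (e.g. percent instead of m3 m-3)
VWC_SANITY_BAND = (-0.05, 1.5)

TREATMENTS = ("fresh", "wet-up", "dry-down")

#: default first-order-differencing unit: one individual's trajectory
#: through a single treatment, ordered by order_index
DEFAULT_DIFFERENCING_UNIT = ("species", "individual", "treatment")

Metrics = namedtuple("Metrics", ["r2", "rmse", "mae", "rae"])


def fit_metrics(observed: Sequence[float], predicted: Sequence[float]) -> Metrics:
    """R2, RMSE, MAE and relative absolute error of predictions.

    RAE is the total absolute error over the total absolute deviation of
    the observations from their mean, so predicting the mean everywhere
    gives RAE = 1 (and R2 = 0).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise MetricsError("observed and predicted must have equal length")
    if obs.size < 2:
        raise MetricsError("need at least 2 observations")
    err = obs - pred
    dev = obs - obs.mean()
    sst = float(np.sum(dev**2))
    sad = float(np.sum(np.abs(dev)))
    if sst == 0.0:
        raise MetricsError("zero total sum of squares; metrics undefined")
    return Metrics(
        r2=float(1.0 - np.sum(err**2) / sst),
        rmse=float(np.sqrt(np.mean(err**2))),
        mae=float(np.mean(np.abs(err))),
        rae=float(np.sum(np.abs(err)) / sad),
    )


@dataclass(frozen=True)
class FitResult:
    """A fitted linear calibration with uncertainty and in-sample metrics."""

    slope: float
    intercept: Optional[float]
    slope_se: float
    intercept_se: Optional[float]
    slope_ci: Tuple[float, float]
    intercept_ci: Optional[Tuple[float, float]]
    n: int
    r2: float
    rmse: float
    mae: float
    rae: float
    label: str = ""

    def __post_init__(self):
        if self.n < 3:
            raise RankError("fit needs at least 3 records")
        lo, hi = self.slope_ci
        if not lo <= self.slope <= hi:
            raise RankError("slope CI does not contain the slope")

    def as_calibration(self, label: Optional[str] = None) -> LinearCalibration:
        mode = ABSOLUTE if self.intercept is not None else RELATIVE_ONLY
        return LinearCalibration(
            slope=self.slope,
            intercept=self.intercept,
            slope_ci=self.slope_ci,
            intercept_ci=self.intercept_ci,
            label=label if label is not None else self.label,
            mode=mode,
        )


def _check_predictor(x: np.ndarray):
    if np.ptp(x) == 0.0:
        raise RankError("degenerate predictor: sqrt_epsilon has zero variance")


def fit_pooled_calibration(
    records: pd.DataFrame,
    x_col: str = "sqrt_epsilon",
    y_col: str = "vwc",
    label: str = "pooled OLS",
) -> FitResult:
    """Ordinary least squares of VWC on sqrt(epsilon), pooled over species."""
    import statsmodels.api as sm

    df = records.dropna(subset=[x_col, y_col])
    if len(df) < 3:
        raise RankError(f"need >= 3 records, got {len(df)}")
    x = df[x_col].to_numpy(dtype=float)
    y = df[y_col].to_numpy(dtype=float)
    _check_predictor(x)
    res = sm.OLS(y, sm.add_constant(x)).fit()
    ci = res.conf_int()
    m = fit_metrics(y, res.fittedvalues)
    return FitResult(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        slope_se=float(res.bse[1]),
        intercept_se=float(res.bse[0]),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        intercept_ci=(float(ci[0][0]), float(ci[0][1])),
        n=int(res.nobs),
        r2=m.r2, rmse=m.rmse, mae=m.mae, rae=m.rae,
        label=label,
    )


@dataclass(frozen=True)
class SpeciesModelsResult:
    """Per-species lines plus the species/interaction ANOVA."""

    per_species: Dict[str, FitResult]
    anova: Optional[pd.DataFrame]          # type-I ANOVA of the interaction model
    comparison: Optional[pd.DataFrame]     # main-effects vs interaction model
    f_sqrt_eps: Optional[float] = None
    f_species: Optional[float] = None
    f_interaction: Optional[float] = None
    p_sqrt_eps: Optional[float] = None
    p_species: Optional[float] = None
    p_interaction: Optional[float] = None
    pooled_fallback: bool = False


def fit_species_models(
    records: pd.DataFrame,
    x_col: str = "sqrt_epsilon",
    y_col: str = "vwc",
    species_col: str = "species",
) -> SpeciesModelsResult:
    """Species-specific lines and the interaction-vs-main-effects comparison.

    Fits ``vwc ~ sqrt_eps * species`` and reports type-I F statistics for
    the common slope, the species intercepts and the species-by-slope
    interaction, plus the goodness-of-fit comparison between the
    interaction and main-effects models. With a single species the pooled
    fit is returned with a notice.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = records.dropna(subset=[x_col, y_col, species_col]).copy()
    species = df[species_col].unique()
    per_species = {
        str(sp): fit_pooled_calibration(
            df[df[species_col] == sp], x_col=x_col, y_col=y_col, label=f"species {sp}"
        )
        for sp in species
        if (df[species_col] == sp).sum() >= 3
    }
    if len(species) < 2:
        warnings.warn(
            "single species in input; falling back to pooled fit",
            DataQualityWarning,
            stacklevel=2,
        )
        pooled = fit_pooled_calibration(df, x_col=x_col, y_col=y_col)
        return SpeciesModelsResult(
            per_species=per_species or {str(species[0]): pooled},
            anova=None, comparison=None, pooled_fallback=True,
        )
    data = df.rename(columns={x_col: "_x", y_col: "_y", species_col: "_sp"})
    slope_only = smf.ols("_y ~ _x", data=data).fit()
    main = smf.ols("_y ~ _x + C(_sp)", data=data).fit()
    inter = smf.ols("_y ~ _x + C(_sp) + _x:C(_sp)", data=data).fit()
    # sequential (type-I) sums of squares in the order slope -> species
    # intercepts -> interaction, against the full-model residual MS
    # (patsy would otherwise reorder the categorical ahead of the slope)
    sst = float(np.sum((data["_y"] - data["_y"].mean()) ** 2))
    ss = {
        "_x": sst - float(slope_only.ssr),
        "C(_sp)": float(slope_only.ssr - main.ssr),
        "_x:C(_sp)": float(main.ssr - inter.ssr),
    }
    dfs = {
        "_x": 1.0,
        "C(_sp)": float(len(species) - 1),
        "_x:C(_sp)": float(len(species) - 1),
    }
    mse = float(inter.ssr / inter.df_resid)
    rows = {
        term: {
            "df": dfs[term],
            "sum_sq": ss[term],
            "mean_sq": ss[term] / dfs[term],
            "F": ss[term] / dfs[term] / mse,
            "PR(>F)": float(stats.f.sf(ss[term] / dfs[term] / mse,
                                       dfs[term], inter.df_resid)),
        }
        for term in ("_x", "C(_sp)", "_x:C(_sp)")
    }
    rows["Residual"] = {"df": float(inter.df_resid), "sum_sq": float(inter.ssr),
                        "mean_sq": mse, "F": np.nan, "PR(>F)": np.nan}
    aov = pd.DataFrame(rows).T[["df", "sum_sq", "mean_sq", "F", "PR(>F)"]]
    comparison = anova_lm(main, inter)
    return SpeciesModelsResult(
        per_species=per_species,
        anova=aov,
        comparison=comparison,
        f_sqrt_eps=float(aov.loc["_x", "F"]),
        f_species=float(aov.loc["C(_sp)", "F"]),
        f_interaction=float(aov.loc["_x:C(_sp)", "F"]),
        p_sqrt_eps=float(aov.loc["_x", "PR(>F)"]),
        p_species=float(aov.loc["C(_sp)", "PR(>F)"]),
        p_interaction=float(aov.loc["_x:C(_sp)", "PR(>F)"]),
    )


@dataclass(frozen=True)
class MixedFitResult:
    """Fixed effects, variance components and diagnostics of the mixed model."""

    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    wood_density_coef: Optional[float]
    wood_density_se: Optional[float]
    var_species: float
    var_individual: float
    var_residual: float
    loglik: float
    r2_marginal: float
    r2_conditional: float
    n: int
    n_params: int
    method: str                       # "reml" | "ml"
    random_structure: Tuple[str, ...]  # subset of ("species", "individual")
    fixed_spec: str
    converged: bool = True

    def __post_init__(self):
        for v in (self.var_species, self.var_individual, self.var_residual):
            if v < 0:
                raise RankError("variance components must be non-negative")
        if not (self.r2_marginal <= self.r2_conditional + 1e-12
                and self.r2_conditional <= 1 + 1e-12):
            raise RankError("require r2_marginal <= r2_conditional <= 1")


def _uid(df: pd.DataFrame) -> pd.Series:
    return df["species"].astype(str) + ":" + df["individual"].astype(str)


def _species_mean_wd(df: pd.DataFrame) -> pd.Series:
    return df.groupby("species")["wood_density"].transform("mean")


def fit_mixed_calibration(
    records: pd.DataFrame,
    include_wood_density: bool = False,
    reml: bool = True,
    random_effects: Tuple[str, ...] = ("species", "individual"),
) -> MixedFitResult:
    """Mixed model: vwc ~ sqrt_eps (+ species-mean wood density).

    Random intercepts per ``random_effects``: "species" and/or
    "individual" (nested in species). Marginal and conditional R2 follow
    the variance-partition definition: fixed-effect variance over total,
    and fixed-plus-random over total.

    With a single species and single individual the hierarchy is
    degenerate; the model reduces to OLS (zero variance components, ML
    log-likelihood of the OLS fit).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if not set(random_effects) <= {"species", "individual"}:
        raise ValueError(f"unknown random effects {random_effects}")
    df = records.dropna(subset=["sqrt_epsilon", "vwc", "species", "individual"]).copy()
    df["_uid"] = _uid(df)
    fixed_spec = "vwc ~ sqrt_epsilon"
    if include_wood_density:
        df["species_mean_wd"] = _species_mean_wd(df)
        fixed_spec += " + species_mean_wd"
    method = "reml" if reml else "ml"

    n_species = df["species"].nunique()
    n_uid = df["_uid"].nunique()
    if (n_species == 1 and n_uid == 1) or not random_effects:
        return _degenerate_mixed(df, fixed_spec, include_wood_density, method)

    if random_effects == ("species", "individual"):
        model = smf.mixedlm(
            fixed_spec, df, groups=df["species"], re_formula="1",
            vc_formula={"individual": "0 + C(_uid)"},
        )
    elif random_effects == ("species",):
        model = smf.mixedlm(fixed_spec, df, groups=df["species"], re_formula="1")
    elif random_effects == ("individual",):
        model = smf.mixedlm(fixed_spec, df, groups=df["_uid"], re_formula="1")
    else:
        raise ValueError(f"unsupported random_effects {random_effects}")

    res = None
    last_exc = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for opt in ("lbfgs", "cg", "powell"):
            try:
                cand = model.fit(reml=reml, method=opt, maxiter=2000)
            except Exception as exc:  # noqa: BLE001 - optimizer backends vary
                last_exc = exc
                continue
            if np.isfinite(cand.llf):
                res = cand
                if cand.converged:
                    break
    if res is None:
        raise ConvergenceError(
            "mixed-model estimation failed", diagnostics={"error": repr(last_exc)}
        )

    var_species = float(res.cov_re.iloc[0, 0]) if "species" in random_effects and random_effects != ("individual",) else 0.0
    if random_effects == ("individual",):
        var_individual = float(res.cov_re.iloc[0, 0])
    elif "individual" in random_effects:
        var_individual = float(res.vcomp[0])
    else:
        var_individual = 0.0
    var_resid = float(res.scale)

    fe = res.fe_params
    exog = model.exog
    var_fixed = float(np.var(exog @ np.asarray(fe)))
    total = var_fixed + var_species + var_individual + var_resid
    r2m = var_fixed / total
    r2c = (var_fixed + var_species + var_individual) / total

    wd_coef = wd_se = None
    if include_wood_density:
        wd_coef = float(fe["species_mean_wd"])
        wd_se = float(res.bse_fe["species_mean_wd"])
    n_var_params = len(random_effects)
    return MixedFitResult(
        slope=float(fe["sqrt_epsilon"]),
        slope_se=float(res.bse_fe["sqrt_epsilon"]),
        intercept=float(fe["Intercept"]),
        intercept_se=float(res.bse_fe["Intercept"]),
        wood_density_coef=wd_coef,
        wood_density_se=wd_se,
        var_species=max(var_species, 0.0),
        var_individual=max(var_individual, 0.0),
        var_residual=var_resid,
        loglik=float(res.llf),
        r2_marginal=float(r2m),
        r2_conditional=float(r2c),
        n=int(res.nobs),
        n_params=int(len(fe) + n_var_params + 1),
        method=method,
        random_structure=tuple(random_effects),
        fixed_spec=fixed_spec,
        converged=bool(res.converged),
    )


def _degenerate_mixed(
    df: pd.DataFrame, fixed_spec: str, include_wood_density: bool, method: str
) -> MixedFitResult:
    """Single-group hierarchy: variance components vanish; OLS is exact."""
    import statsmodels.formula.api as smf

    res = smf.ols(fixed_spec, df).fit()
    var_fixed = float(np.var(res.fittedvalues))
    var_resid = float(np.mean(res.resid**2))
    total = var_fixed + var_resid
    wd_coef = wd_se = None
    if include_wood_density and "species_mean_wd" in res.params.index:
        wd_coef = float(res.params["species_mean_wd"])
        wd_se = float(res.bse["species_mean_wd"])
    return MixedFitResult(
        slope=float(res.params["sqrt_epsilon"]),
        slope_se=float(res.bse["sqrt_epsilon"]),
        intercept=float(res.params["Intercept"]),
        intercept_se=float(res.bse["Intercept"]),
        wood_density_coef=wd_coef,
        wood_density_se=wd_se,
        var_species=0.0,
        var_individual=0.0,
        var_residual=var_resid,
        loglik=float(res.llf),
        r2_marginal=var_fixed / total,
        r2_conditional=var_fixed / total,
        n=int(res.nobs),
        n_params=int(len(res.params) + 1),
        method=method,
        random_structure=(),
        fixed_spec=fixed_spec,
        converged=True,
    )


def mixed_loglik_zero_variance(records: pd.DataFrame, eps: float = 1e-12) -> float:
    """Mixed-model ML log-likelihood at (numerically) zero variance components.

    Builds the full hierarchical model and evaluates its profiled
    likelihood with both random-intercept variances pinned at ``eps``
    (the boundary limit; exactly zero makes the random-effect covariance
    singular) and the fixed effects at their OLS estimates; equals the
    pooled OLS log-likelihood up to numerical error. Exposed for
    verification of the boundary behaviour of the hierarchy.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.regression.mixed_linear_model import MixedLMParams

    df = records.dropna(subset=["sqrt_epsilon", "vwc", "species", "individual"]).copy()
    df["_uid"] = _uid(df)
    model = smf.mixedlm(
        "vwc ~ sqrt_epsilon", df, groups=df["species"], re_formula="1",
        vc_formula={"individual": "0 + C(_uid)"},
    )
    ols = smf.ols("vwc ~ sqrt_epsilon", df).fit()
    params = MixedLMParams.from_components(
        fe_params=np.asarray(ols.params),
        cov_re=np.full((1, 1), eps),
        vcomp=np.full(1, eps),
    )
    model.reml = False
    # loglike() expects fit()-time attributes; set them for a standalone call
    if not hasattr(model, "cov_pen"):
        model.cov_pen = None
    if not hasattr(model, "_cov_sing"):
        model._cov_sing = 0
    return float(model.loglike(params, profile_fe=False))


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio test of nested mixed models."""

    statistic: float
    df: int
    p_value: float
    null_mixture_flag: bool


def lrt_random_effect(
    full: MixedFitResult, reduced: MixedFitResult, boundary_mixture: bool = False
) -> LRTResult:
    """LRT of random-effect structure: 2*(llf_full - llf_reduced), clamped at 0.

    Both fits must be by maximum likelihood with identical fixed effects,
    and the reduced random structure strictly nested in the full one.
    ``boundary_mixture=True`` uses the 50:50 chi2 mixture reference
    appropriate when a variance component sits on the boundary of its
    parameter space (flagged in the result); the default is the plain
    chi2 on the parameter-count difference.
    """
    if full.fixed_spec != reduced.fixed_spec:
        raise NestingError("fixed-effect specifications differ; models not nested")
    if not set(reduced.random_structure) < set(full.random_structure):
        raise NestingError(
            f"reduced random structure {reduced.random_structure} is not strictly "
            f"nested in {full.random_structure}"
        )
    if full.method != "ml" or reduced.method != "ml":
        raise NestingError("LRT requires maximum-likelihood fits (reml=False)")
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    df = full.n_params - reduced.n_params
    if df < 1:
        raise NestingError("full model has no extra parameters")
    if boundary_mixture:
        # 0.5*chi2(df) + 0.5*chi2(df-1), with chi2(0) a point mass at zero
        upper = stats.chi2.sf(stat, df)
        lower = stats.chi2.sf(stat, df - 1) if df > 1 else float(stat <= 0.0)
        p = 0.5 * (upper + lower)
    else:
        p = stats.chi2.sf(stat, df)
    if stat == 0.0:
        p = 1.0
    return LRTResult(
        statistic=float(stat), df=int(df), p_value=float(p),
        null_mixture_flag=bool(boundary_mixture),
    )


def first_order_difference(
    records: pd.DataFrame,
    unit_cols: Tuple[str, ...] = DEFAULT_DIFFERENCING_UNIT,
    order_col: str = "order_index",
    x_col: str = "sqrt_epsilon",
    y_col: str = "vwc",
) -> pd.DataFrame:
    """Consecutive differences of (vwc, sqrt_eps) within each differencing unit.

    Each unit (default: one individual's wet-up or dry-down sequence) is
    sorted by ``order_col``; consecutive rows are differenced, so a unit
    with n rows contributes n-1 pairs and single-row units contribute
    nothing. Differences never cross unit boundaries. Duplicated order
    indices within a unit raise :class:`OrderingError`.
    """
    cols = list(unit_cols)
    out_frames = []
    for key, grp in records.groupby(cols, sort=True, dropna=False):
        if grp[order_col].duplicated().any():
            raise OrderingError(
                f"duplicate {order_col} within differencing unit {key!r}"
            )
        grp = grp.sort_values(order_col)
        if len(grp) < 2:
            continue
        d = pd.DataFrame({
            "delta_vwc": np.diff(grp[y_col].to_numpy(dtype=float)),
            "delta_sqrt_epsilon": np.diff(grp[x_col].to_numpy(dtype=float)),
        })
        key_tuple = key if isinstance(key, tuple) else (key,)
        for c, v in zip(cols, key_tuple):
            d[c] = v
        out_frames.append(d)
    if not out_frames:
        return pd.DataFrame(columns=["delta_vwc", "delta_sqrt_epsilon", *cols])
    return pd.concat(out_frames, ignore_index=True)[
        ["delta_vwc", "delta_sqrt_epsilon", *cols]
    ]


def osc_closed_form_slope(diffs: pd.DataFrame) -> float:
    """Through-origin OLS slope in closed form: sum(dy*dx)/sum(dx^2)."""
    dx = diffs["delta_sqrt_epsilon"].to_numpy(dtype=float)
    dy = diffs["delta_vwc"].to_numpy(dtype=float)
    denom = float(np.sum(dx**2))
    if denom == 0.0:
        raise RankError("all delta sqrt_epsilon are zero")
    return float(np.sum(dy * dx) / denom)


def fit_osc(
    diffs: pd.DataFrame,
    include_intercept: bool = False,
    label: str = "one-slope calibration (fitted)",
) -> FitResult:
    """One-slope calibration: regression of delta-VWC on delta-sqrt(eps).

    Through the origin by default — differencing is performed precisely to
    remove unit intercepts — with an intercept-included fit available as a
    diagnostic. The resulting calibration is relative-only.
    """
    import statsmodels.api as sm

    if len(diffs) < 3:
        raise RankError(f"need >= 3 differenced pairs, got {len(diffs)}")
    dx = diffs["delta_sqrt_epsilon"].to_numpy(dtype=float)
    dy = diffs["delta_vwc"].to_numpy(dtype=float)
    if np.all(dx == 0.0):
        raise RankError("all delta sqrt_epsilon are zero")
    X = sm.add_constant(dx) if include_intercept else dx[:, None]
    res = sm.OLS(dy, X).fit()
    ci = res.conf_int()
    i_slope = 1 if include_intercept else 0
    m = fit_metrics(dy, res.fittedvalues)
    return FitResult(
        slope=float(res.params[i_slope]),
        intercept=float(res.params[0]) if include_intercept else None,
        slope_se=float(res.bse[i_slope]),
        intercept_se=float(res.bse[0]) if include_intercept else None,
        slope_ci=(float(ci[i_slope][0]), float(ci[i_slope][1])),
        intercept_ci=((float(ci[0][0]), float(ci[0][1]))
                      if include_intercept else None),
        n=int(res.nobs),
        r2=m.r2, rmse=m.rmse, mae=m.mae, rae=m.rae,
        label=label,
    )
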