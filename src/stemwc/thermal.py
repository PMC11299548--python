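"""Temperature sensitivity of the FDR signal and its correction.

The dielectric permittivity of water decreases with temperature, so a
capacitance sensor in a medium of constant water content reads a slowly
falling water content as the medium warms. Over the 15-27 degC range the
effect is well described by a straight line in temperature; the shipped
registry carries the water-bucket coefficient -0.000974 m3 m-3 per degC
(default) and the wood-block coefficient -0.000950 (diagnostic).

Correction subtracts the artefact relative to a reference temperature
(default 25 degC):  wc_corrected(t) = wc(t) - slope_wc*(T(t) - T_ref).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError, DomainError, SpanError, StemWCError

DEFAULT_REFERENCE_TEMPERATURE = 25.0
WATER_DENSITY_KG_M3 = 1000.0

#: sanity band on plausible sensor temperatures, degC
TEMPERATURE_SANITY_BAND = (-20.0, 60.0)


@dataclass(frozen=True)
class TemperatureModel:
    """Linear sensitivity of the sensor signal to temperature.

    ``slope_wc`` is in sensor water-content units (m3 m-3) per degC and is
    expected to be negative; ``slope_sqrt_eps`` (per degC), when present,
    is the same artefact expressed on the sqrt(epsilon) scale.
    """

    slope_wc: float
    slope_wc_se: Optional[float] = None
    slope_wc_ci: Optional[Tuple[float, float]] = None
    intercept: Optional[float] = None
    r2: Optional[float] = None
    slope_sqrt_eps: Optional[float] = None
    slope_sqrt_eps_se: Optional[float] = None
    reference_temperature: float = DEFAULT_REFERENCE_TEMPERATURE
    n: Optional[int] = None
    label: str = ""

    def __post_init__(self):
        if not np.isfinite(self.slope_wc):
            raise ConfigError("slope_wc must be finite")
        if not np.isfinite(self.reference_temperature):
            raise ConfigError("reference_temperature must be finite")
        if self.slope_wc_ci is not None:
            lo, hi = self.slope_wc_ci
            if not lo <= self.slope_wc <= hi:
                raise ConfigError("slope_wc_ci does not contain slope_wc")


def fit_temperature_model(
    records: pd.DataFrame,
    wc_col: str = "sensor_wc",
    temp_col: str = "temperature",
    sqrt_eps_col: str = "sqrt_epsilon",
    reference_temperature: float = DEFAULT_REFERENCE_TEMPERATURE,
    min_span: float = 2.0,
    label: str = "fitted",
) -> TemperatureModel:
    """OLS of sensor-reported water content (and sqrt(eps) if present) on temperature.

    Requires at least 10 records spanning at least ``min_span`` degC.
    """
    import statsmodels.api as sm

    df = records.dropna(subset=[wc_col, temp_col])
    if len(df) < 10:
        raise SpanError(f"need >= 10 records, got {len(df)}")
    t = df[temp_col].to_numpy(dtype=float)
    span = np.ptp(t)
    if span < min_span:
        raise SpanError(
            f"temperature span {span:.3g} degC below required {min_span} degC"
        )
    X = sm.add_constant(t)
    res = sm.OLS(df[wc_col].to_numpy(dtype=float), X).fit()
    ci = res.conf_int()
    kwargs = dict(
        slope_wc=float(res.params[1]),
        slope_wc_se=float(res.bse[1]),
        slope_wc_ci=(float(ci[1][0]), float(ci[1][1])),
        intercept=float(res.params[0]),
        r2=float(res.rsquared),
        reference_temperature=reference_temperature,
        n=int(res.nobs),
        label=label,
    )
    if sqrt_eps_col in df.columns and df[sqrt_eps_col].notna().all():
        res_e = sm.OLS(df[sqrt_eps_col].to_numpy(dtype=float), X).fit()
        kwargs["slope_sqrt_eps"] = float(res_e.params[1])
        kwargs["slope_sqrt_eps_se"] = float(res_e.bse[1])
    return TemperatureModel(**kwargs)


def temperature_correct(
    series: pd.DataFrame,
    model: TemperatureModel,
    reference_temperature: Optional[float] = None,
    wc_col: str = "sensor_wc",
    temp_col: str = "temperature",
    out_col: str = "sensor_wc_corrected",
) -> Tuple[pd.DataFrame, dict]:
    """Remove the linear temperature artefact from a water-content series.

    Returns the corrected frame (new column ``out_col``) and a summary dict
    carrying the model label, reference temperature and count of rows with
    missing temperature (propagated as NaN, never filled).
    """
    t_ref = model.reference_temperature if reference_temperature is None else reference_temperature
    out = series.copy()
    temp = out[temp_col].to_numpy(dtype=float)
    missing = int(np.isnan(temp).sum())
    out[out_col] = out[wc_col] - model.slope_wc * (temp - t_ref)
    summary = {
        "model": model.label or "<unnamed>",
        "slope_wc": model.slope_wc,
        "reference_temperature": t_ref,
        "n_missing_temperature": missing,
    }
    return out, summary


def bias_table(
    model: TemperatureModel,
    delta_ts: Sequence[float],
    water_density: float = WATER_DENSITY_KG_M3,
) -> pd.DataFrame:
    """Artefactual water-content bias per temperature difference.

    ``bias(dT) = |slope_wc| * dT * water_density`` in kg m-3. With the
    shipped water-bucket coefficient, a day-night difference of 5 degC
    yields 4.87 kg m-3.
    """
    dts = np.asarray(list(delta_ts), dtype=float)
    if np.any(dts < 0):
        raise DomainError("temperature differences must be >= 0")
    bias = np.abs(model.slope_wc) * dts * water_density
    return pd.DataFrame({"delta_t_degC": dts, "bias_kg_m3": bias})


@dataclass(frozen=True)
class SlopeComparison:
    """Two-sample z comparison of temperature slopes."""

    difference: float
    se_difference: float
    z: float
    p_value: float


def compare_slopes(model_a: TemperatureModel, model_b: TemperatureModel) -> SlopeComparison:
    """z-style test of slope equality between two temperature models."""
    if model_a.slope_wc_se is None or model_b.slope_wc_se is None:
        raise StemWCError("both models must carry slope standard errors")
    diff = model_a.slope_wc - model_b.slope_wc
    se = float(np.hypot(model_a.slope_wc_se, model_b.slope_wc_se))
    if se == 0.0:
        z = 0.0 if diff == 0.0 else np.inf * np.sign(diff)
    else:
        z = diff / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return SlopeComparison(difference=float(diff), se_difference=se, z=float(z), p_value=p)


def correction_consistency_ratio(model: TemperatureModel, calibration) -> float:
    """Diagnostic: ratio of the sqrt(eps)-route correction to the WC-route one.

    A calibration slope ``s`` maps the sqrt(eps)-scale artefact to
    ``s * slope_sqrt_eps`` m3 m-3 per degC; this returns that quantity over
    ``slope_wc``. The two routes need not agree (they sit in different unit
    systems); the ratio is reported, never asserted.
    """
    if model.slope_sqrt_eps is None:
        raise StemWCError("model carries no sqrt(epsilon) slope")
    return float(calibration.slope * model.slope_sqrt_eps / model.slope_wc)
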