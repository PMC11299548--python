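"""Field logger time series: raw counts to temperature-adjusted delta-StWC.

The pipeline order is fixed and logged in the output metadata:

    raw -> epsilon -> sqrt(epsilon) -> calibration -> temperature
    correction -> delta-StWC against a baseline

delta-StWC is expressed in kg of water per m3 of wood (water density
1000 kg m-3). Gaps are recorded, never filled; missing values propagate
row-wise and are excluded from aggregates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .calibration import (
    LinearCalibration,
    apply_calibration,
)
from .dielectrics import PolynomialTransform, raw_to_permittivity
from .exceptions import (
    BaselineError,
    CalibrationModeError,
    DataQualityWarning,
    LabellingError,
    OrderingError,
    WindowError,
)
from .thermal import TemperatureModel, WATER_DENSITY_KG_M3


@dataclass
class LoggerSeries:
    """A timestamped field sensor series plus processing metadata.

    ``data`` holds at least a ``timestamp`` column (strictly increasing)
    and typically ``raw``, ``factory_wc`` and ``temperature``; processing
    adds ``epsilon``, ``sqrt_epsilon``, ``vwc``, ``vwc_adjusted``,
    ``delta_stwc_unadjusted`` and ``delta_stwc`` (kg m-3). Cadence gaps
    found at construction are recorded in ``metadata['gaps']``.
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        ts = pd.to_datetime(self.data["timestamp"])
        diffs = ts.diff().dropna()
        if (diffs <= pd.Timedelta(0)).any():
            offenders = ts[diffs.index[diffs <= pd.Timedelta(0)]].tolist()
            raise OrderingError(
                f"timestamps not strictly increasing at {offenders[:5]}"
            )
        self.data = self.data.copy()
        self.data["timestamp"] = ts
        if len(diffs) and "gaps" not in self.metadata:
            cadence = diffs.mode().iloc[0]
            gap_idx = diffs[diffs > cadence].index
            self.metadata["cadence"] = str(cadence)
            self.metadata["gaps"] = [
                str(ts.loc[i - 1]) for i in gap_idx
            ]

    def __len__(self) -> int:
        return len(self.data)


BaselineSpec = Union[str, Tuple[str, str]]


def _baseline_value(df: pd.DataFrame, col: str, baseline: BaselineSpec) -> float:
    series = df[col]
    if isinstance(baseline, str) and baseline == "first":
        valid = series.dropna()
        if valid.empty:
            raise BaselineError("no valid sample for a 'first' baseline")
        return float(valid.iloc[0])
    start, stop = baseline
    mask = (df["timestamp"] >= pd.Timestamp(start)) & (df["timestamp"] <= pd.Timestamp(stop))
    window = series[mask].dropna()
    if window.empty:
        raise BaselineError(f"empty baseline window ({start}, {stop})")
    return float(window.mean())


def process_series(
    series: LoggerSeries,
    transform: Optional[PolynomialTransform],
    calibration: LinearCalibration,
    temperature_model: Optional[TemperatureModel] = None,
    reference_temperature: Optional[float] = None,
    baseline: BaselineSpec = "first",
    correction_level: str = "wc",
    water_density: float = WATER_DENSITY_KG_M3,
) -> LoggerSeries:
    """Run the full pipeline on a logger series.

    With an absolute calibration, ``vwc`` is absolute water content; with a
    relative-only calibration the slope-only signal ``slope*sqrt(eps)`` is
    carried (its offset is arbitrary and removed by the baseline), so a
    baseline specification is mandatory. ``correction_level`` chooses where
    the temperature artefact is removed: ``"wc"`` (default; the shipped
    water-bucket coefficient is in sensor water-content units) or
    ``"sqrt_eps"`` (corrects sqrt(epsilon) before calibrating, for users
    who consider the artefact a permittivity effect).
    """
    df = series.data.copy()
    meta = dict(series.metadata)
    steps = []

    if transform is not None:
        ps = raw_to_permittivity(df["raw"].to_numpy(dtype=float), transform)
        df["epsilon"] = ps.epsilon
        df["sqrt_epsilon"] = ps.sqrt_epsilon
        steps.append(f"raw->epsilon [{transform.name}]")
    elif "sqrt_epsilon" not in df.columns:
        raise CalibrationModeError(
            "no transform given and no sqrt_epsilon column present"
        )

    sqrt_eps = df["sqrt_epsilon"].to_numpy(dtype=float)
    temp = (df["temperature"].to_numpy(dtype=float)
            if "temperature" in df.columns else None)
    if temperature_model is not None and temp is None:
        raise CalibrationModeError("temperature correction requires a temperature column")

    if temperature_model is not None:
        t_ref = (temperature_model.reference_temperature
                 if reference_temperature is None else reference_temperature)
    else:
        t_ref = reference_temperature

    if correction_level not in ("wc", "sqrt_eps"):
        raise ValueError(f"unknown correction_level {correction_level!r}")

    if calibration.is_absolute:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vwc = apply_calibration(sqrt_eps, calibration)
        steps.append(f"calibration [{calibration.label or 'absolute'}]")
    else:
        if baseline is None:
            raise CalibrationModeError(
                "relative-only calibration requires a baseline specification"
            )
        vwc = calibration.slope * sqrt_eps
        steps.append(f"relative calibration [{calibration.label or 'slope-only'}]")
    df["vwc"] = vwc

    if temperature_model is not None:
        if correction_level == "wc":
            adj = vwc - temperature_model.slope_wc * (temp - t_ref)
            steps.append(
                f"temperature correction on WC [{temperature_model.label}], "
                f"T_ref={t_ref}"
            )
        else:
            if temperature_model.slope_sqrt_eps is None:
                raise CalibrationModeError(
                    "sqrt_eps-level correction requires slope_sqrt_eps"
                )
            se_adj = sqrt_eps - temperature_model.slope_sqrt_eps * (temp - t_ref)
            if calibration.is_absolute:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    adj = apply_calibration(np.clip(se_adj, 0, None), calibration)
            else:
                adj = calibration.slope * se_adj
            steps.append(
                f"temperature correction on sqrt_eps [{temperature_model.label}], "
                f"T_ref={t_ref}"
            )
    else:
        adj = vwc.copy() if isinstance(vwc, np.ndarray) else vwc
    df["vwc_adjusted"] = adj

    base_unadj = _baseline_value(df, "vwc", baseline)
    base_adj = _baseline_value(df, "vwc_adjusted", baseline)
    df["delta_stwc_unadjusted"] = (df["vwc"] - base_unadj) * water_density
    df["delta_stwc"] = (df["vwc_adjusted"] - base_adj) * water_density
    steps.append(f"delta-StWC vs baseline {baseline!r} (x{water_density:g} kg m-3)")

    meta.update({
        "pipeline": steps,
        "baseline_spec": baseline,
        "baseline_vwc": base_unadj,
        "baseline_vwc_adjusted": base_adj,
        "reference_temperature": t_ref,
        "temperature_model": (temperature_model.label if temperature_model else None),
        "n_missing_temperature": (int(np.isnan(temp).sum()) if temp is not None else 0),
        "water_density": water_density,
    })
    return LoggerSeries(data=df, metadata=meta)


@dataclass(frozen=True)
class DiurnalCycle:
    """Time-of-day bin means with dispersion and peak-to-trough amplitude."""

    bins: pd.DataFrame          # columns: time_of_day, mean, sd, n
    peak_to_trough: float
    value_col: str


def diurnal_cycle(
    series: LoggerSeries,
    value_col: str = "delta_stwc",
    bin_minutes: Optional[float] = None,
    window: Optional[Tuple[str, str]] = None,
) -> DiurnalCycle:
    """Mean value per time-of-day bin over a window of at least 2 full days.

    ``peak_to_trough`` is max(bin mean) - min(bin mean): for a pure daily
    sinusoid of peak-to-trough A it recovers A (bin-averaging attenuation
    is negligible at logger cadences).
    """
    df = series.data
    if window is not None:
        start, stop = window
        df = df[(df["timestamp"] >= pd.Timestamp(start))
                & (df["timestamp"] <= pd.Timestamp(stop))]
    if df.empty or (df["timestamp"].iloc[-1] - df["timestamp"].iloc[0]
                    < pd.Timedelta(days=2)):
        raise WindowError("diurnal cycle needs >= 2 full days of data")
    if bin_minutes is None:
        bin_minutes = (df["timestamp"].diff().dropna().mode().iloc[0]
                       / pd.Timedelta(minutes=1))
    minutes = (df["timestamp"].dt.hour * 60 + df["timestamp"].dt.minute
               + df["timestamp"].dt.second / 60.0)
    tod_bin = (minutes // bin_minutes) * bin_minutes
    grouped = df.assign(_bin=tod_bin).groupby("_bin")[value_col]
    bins = grouped.agg(mean="mean", sd="std", n="count").reset_index()
    bins = bins.rename(columns={"_bin": "time_of_day_minutes"})
    amp = float(bins["mean"].max() - bins["mean"].min())
    return DiurnalCycle(bins=bins, peak_to_trough=amp, value_col=value_col)


PeriodSpec = Union[str, pd.Series, Sequence, Callable[[pd.Timestamp], str]]


def seasonal_aggregate(series: LoggerSeries, period_spec: PeriodSpec) -> pd.DataFrame:
    """Per-period means of adjusted/unadjusted delta-StWC and temperature stats.

    ``period_spec`` labels every timestamp: a column name in the data, a
    label sequence aligned with the rows, or a callable mapping a
    timestamp to a label. Unlabelled rows raise; declared-but-empty
    periods (unused categoricals) are omitted with a warning.
    """
    df = series.data
    if isinstance(period_spec, str):
        if period_spec not in df.columns:
            raise LabellingError(f"no column {period_spec!r} in series")
        labels = df[period_spec]
    elif callable(period_spec):
        labels = df["timestamp"].map(period_spec)
    else:
        if len(period_spec) != len(df):
            raise LabellingError(f"{len(period_spec)} labels for {len(df)} rows")
        if isinstance(period_spec, pd.Series):
            labels = period_spec.reset_index(drop=True).set_axis(df.index)
        else:
            labels = pd.Series(list(period_spec), index=df.index)
    if labels.isna().any():
        n_bad = int(labels.isna().sum())
        raise LabellingError(f"{n_bad} timestamps left unlabelled by period_spec")
    if isinstance(labels.dtype, pd.CategoricalDtype):
        unused = set(labels.cat.categories) - set(labels.unique())
        if unused:
            warnings.warn(
                f"periods with no rows omitted from output: {sorted(unused)}",
                DataQualityWarning,
                stacklevel=2,
            )
    agg_cols = {}
    for col, out in (("delta_stwc", "delta_stwc_adjusted_mean"),
                     ("delta_stwc_unadjusted", "delta_stwc_unadjusted_mean")):
        if col in df.columns:
            agg_cols[out] = (col, "mean")
    if "temperature" in df.columns:
        agg_cols.update(
            temperature_mean=("temperature", "mean"),
            temperature_min=("temperature", "min"),
            temperature_max=("temperature", "max"),
        )
    agg_cols["n"] = ("timestamp", "count")
    out = df.assign(_period=labels.values).groupby("_period", observed=True).agg(**agg_cols)
    out.index.name = "period"
    return out
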