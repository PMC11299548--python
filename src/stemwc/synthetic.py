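"""Synthetic inputs with the statistical structure the analyses assume.

Three generators emulate the three experiment types:

* :func:`generate_calibration_experiment` — the wet-up/dry-down segment
  experiment: a common sqrt(epsilon) slope, species and
  individual-within-species random intercepts, residual noise on the
  gravimetric VWC (the regression response).
* :func:`generate_bucket_experiment` — a temperature ramp with a linear
  artefact on the sensor-reported water content (the water-bucket /
  wood-block design).
* :func:`generate_field_series` — a field logger series: sinusoidal
  diurnal temperature, optional true water-content dynamics, the linear
  temperature artefact, and raw counts obtained by inverting the
  configured transform so the full pipeline can run end to end.

Every generator takes a mandatory seed, is byte-deterministic given its
config, and returns the generating truth alongside the data so recovery
tests can state their expectations in closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .calibration import LinearCalibration, invert_calibration
from .dielectrics import PolynomialTransform, invert_transform
from .exceptions import ConfigError
from .fieldseries import LoggerSeries

MINUTES_PER_DAY = 1440.0


def _rng(seed) -> np.random.Generator:
    if seed is None:
        raise ConfigError("seed is mandatory for synthetic generators")
    return np.random.default_rng(seed)


# --------------------------------------------------------------------------
# calibration experiment


@dataclass(frozen=True)
class CalibGenConfig:
    """Design of a synthetic segment calibration experiment.

    Defaults mirror the real design: 8 species x 3 individuals x ~11
    segments (n = 264), common slope 0.2227 and mean intercept -0.396,
    species/individual intercept spreads 0.03/0.02 and residual noise
    0.05, all on the VWC scale. Roughly a third of each individual's
    segments rehydrate (wet-up), the rest dry down.
    """

    seed: int = None
    n_species: int = 8
    n_individuals_per_species: int = 3
    n_segments_per_individual: int = 11
    true_slope: float = 0.2227
    mean_intercept: float = -0.396
    sd_species_intercept: float = 0.03
    sd_individual_intercept: float = 0.02
    sd_residual: float = 0.05
    wet_up_fraction: float = 1 / 3
    #: trajectory (start, end) VWC per treatment; exponential approach
    dry_down_trajectory: Tuple[float, float] = (0.40, 0.05)
    wet_up_trajectory: Tuple[float, float] = (0.40, 0.60)
    trajectory_timescale: float = 0.5   # e-folding as fraction of sequence length
    wood_density_range: Tuple[float, float] = (0.22, 0.84)
    sd_wood_density: float = 0.03
    temperature: float = 25.0
    n_sensors: int = 10

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if min(self.n_species, self.n_individuals_per_species,
               self.n_segments_per_individual) < 1:
            raise ConfigError("design counts must be >= 1")
        for sd in (self.sd_species_intercept, self.sd_individual_intercept,
                   self.sd_residual, self.sd_wood_density):
            if sd < 0:
                raise ConfigError("standard deviations must be >= 0")
        if not 0 <= self.wet_up_fraction <= 1:
            raise ConfigError("wet_up_fraction must lie in [0, 1]")


def _trajectory(start: float, end: float, k: np.ndarray, tau: float) -> np.ndarray:
    """Exponential approach from start toward end over order index k (1-based)."""
    return end + (start - end) * np.exp(-(k - 1) / tau)


def generate_calibration_experiment(
    config: CalibGenConfig,
) -> Tuple[pd.DataFrame, Dict]:
    """Segment records plus the generating truth.

    sqrt(epsilon) is obtained by inverting each segment's *effective* line
    (common slope, intercept shifted by its species and individual
    offsets) at the segment's noiseless trajectory VWC; residual noise is
    then added to the recorded VWC, matching the fitted model's error
    structure.
    """
    rng = _rng(config.seed)
    rows = []
    species_offsets: Dict[str, float] = {}
    individual_offsets: Dict[str, float] = {}
    n_seg = config.n_segments_per_individual
    n_wet = int(round(config.wet_up_fraction * n_seg))
    tau = max(config.trajectory_timescale * n_seg, 1e-9)
    sensor_ids = [f"S{i + 1:02d}" for i in range(config.n_sensors)]

    for s in range(config.n_species):
        sp = f"sp{s + 1:02d}"
        b_s = rng.normal(0.0, config.sd_species_intercept)
        species_offsets[sp] = b_s
        wd_mean = rng.uniform(*config.wood_density_range)
        for i in range(config.n_individuals_per_species):
            ind = f"{sp}-i{i + 1}"
            b_si = rng.normal(0.0, config.sd_individual_intercept)
            individual_offsets[ind] = b_si
            intercept_eff = config.mean_intercept + b_s + b_si
            treatments = (["wet-up"] * n_wet) + (["dry-down"] * (n_seg - n_wet))
            order_counter = {"wet-up": 0, "dry-down": 0, "fresh": 0}
            for j, treatment in enumerate(treatments):
                order_counter[treatment] += 1
                k = order_counter[treatment]
                if treatment == "wet-up":
                    true_vwc = _trajectory(*config.wet_up_trajectory, np.array(k), tau)
                else:
                    true_vwc = _trajectory(*config.dry_down_trajectory, np.array(k), tau)
                true_vwc = float(true_vwc)
                sqrt_eps = (true_vwc - intercept_eff) / config.true_slope
                vwc_obs = true_vwc + rng.normal(0.0, config.sd_residual)
                rows.append({
                    "species": sp,
                    "individual": ind,
                    "segment": f"{ind}-g{j + 1}",
                    "sample": f"{ind}|{treatment}",
                    "treatment": treatment,
                    "order_index": k,
                    "sqrt_epsilon": sqrt_eps,
                    "vwc": vwc_obs,
                    "true_vwc": true_vwc,
                    "temperature": config.temperature,
                    "sensor_id": sensor_ids[int(rng.integers(0, config.n_sensors))],
                    "wood_density": wd_mean + rng.normal(0.0, config.sd_wood_density),
                })
    records = pd.DataFrame(rows)
    truth = {
        "true_slope": config.true_slope,
        "mean_intercept": config.mean_intercept,
        "species_offsets": species_offsets,
        "individual_offsets": individual_offsets,
        "sd_residual": config.sd_residual,
        "config": asdict(config),
    }
    return records, truth


# --------------------------------------------------------------------------
# temperature-ramp (bucket / wood-block) experiment


@dataclass(frozen=True)
class ThermalGenConfig:
    """A warming ramp logged at fixed cadence.

    Defaults reproduce the water-bucket design: 15 -> 27 degC over 2 days
    at 5-min cadence (577 records, both endpoints included) with the
    published artefact slope on the sensor water content.
    """

    seed: int = None
    true_slope_wc: float = -0.000974
    t_start: float = 15.0
    t_end: float = 27.0
    duration_days: float = 2.0
    cadence_minutes: float = 5.0
    noise_sd: float = 1e-4
    base_wc: float = 1.0
    reference_temperature: float = 25.0
    true_slope_sqrt_eps: Optional[float] = None
    base_sqrt_eps: float = 9.0
    ramp: str = "linear"   # or "logistic"

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if self.cadence_minutes <= 0:
            raise ConfigError("cadence must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.ramp not in ("linear", "logistic"):
            raise ConfigError(f"unknown ramp {self.ramp!r}")


def generate_bucket_experiment(
    config: ThermalGenConfig,
) -> Tuple[pd.DataFrame, Dict]:
    """Temperature-experiment records plus the generating truth."""
    rng = _rng(config.seed)
    n = int(round(config.duration_days * MINUTES_PER_DAY / config.cadence_minutes)) + 1
    frac = np.linspace(0.0, 1.0, n)
    if config.ramp == "linear":
        temp = config.t_start + (config.t_end - config.t_start) * frac
    else:
        z = 10.0 * (frac - 0.5)
        temp = config.t_start + (config.t_end - config.t_start) / (1.0 + np.exp(-z))
    timestamps = pd.date_range(
        "2023-01-01", periods=n, freq=pd.Timedelta(minutes=config.cadence_minutes)
    )
    wc = (config.base_wc
          + config.true_slope_wc * (temp - config.reference_temperature)
          + rng.normal(0.0, config.noise_sd, size=n))
    df = pd.DataFrame({"timestamp": timestamps, "temperature": temp, "sensor_wc": wc})
    if config.true_slope_sqrt_eps is not None:
        df["sqrt_epsilon"] = (
            config.base_sqrt_eps
            + config.true_slope_sqrt_eps * (temp - config.reference_temperature)
            + rng.normal(0.0, config.noise_sd, size=n)
        )
    truth = {
        "true_slope_wc": config.true_slope_wc,
        "true_slope_sqrt_eps": config.true_slope_sqrt_eps,
        "base_wc": config.base_wc,
        "reference_temperature": config.reference_temperature,
        "config": asdict(config),
    }
    return df, truth


# --------------------------------------------------------------------------
# field logger series


@dataclass(frozen=True)
class FieldGenConfig:
    """A field logger deployment at fixed cadence.

    Amplitude fields are peak-to-trough. Default: 10 days at 15-min
    cadence, diurnal temperature swing 5 degC around a 25 degC mean
    (tropical understorey scale), no true water-content dynamics, and the
    water-bucket artefact slope — the configuration under which any
    diurnal signal in the unadjusted series is purely artefactual.
    """

    seed: int = None
    n_days: int = 10
    cadence_minutes: float = 15.0
    temp_mean: float = 25.0
    temp_diurnal_range: float = 5.0      # peak-to-trough, degC
    wc_base: float = 0.45
    wc_diurnal_range: float = 0.0        # peak-to-trough, m3 m-3 (true dynamics)
    wc_seasonal_drift: float = 0.0       # m3 m-3 per day, linear
    artefact_slope: float = -0.000974    # m3 m-3 per degC
    noise_sd: float = 0.0
    reference_temperature: float = 25.0
    start: str = "2023-06-01"

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if self.cadence_minutes <= 0:
            raise ConfigError("cadence must be positive")
        if self.temp_diurnal_range < 0 or self.wc_diurnal_range < 0:
            raise ConfigError("amplitudes must be >= 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


def generate_field_series(
    config: FieldGenConfig,
    transform: Optional[PolynomialTransform] = None,
    calibration: Optional[LinearCalibration] = None,
) -> Tuple[LoggerSeries, Dict]:
    """A logger series (timestamp, raw, factory_wc, temperature) plus truth.

    The sensed water content is the true dynamics plus the linear
    temperature artefact plus noise; raw counts are produced by mapping
    the sensed signal back through the calibration and inverting the
    transform, so processing the series with the same transform and
    calibration reproduces the sensed signal to numerical precision.
    Temperature peaks at 14:00, true water content troughs at the same
    hour (midday depletion).
    """
    from .registry import default_registry

    reg = default_registry()
    transform = transform if transform is not None else reg.transform("teros12")
    calibration = calibration if calibration is not None else reg.calibrations["TTC"]

    rng = _rng(config.seed)
    n = int(round(config.n_days * MINUTES_PER_DAY / config.cadence_minutes))
    timestamps = pd.date_range(
        config.start, periods=n, freq=pd.Timedelta(minutes=config.cadence_minutes)
    )
    hours = (timestamps - timestamps[0]) / pd.Timedelta(hours=1)
    hours = np.asarray(hours, dtype=float) + timestamps[0].hour
    phase = 2.0 * np.pi * (hours - 8.0) / 24.0    # sin peaks at 14:00
    temp = config.temp_mean + 0.5 * config.temp_diurnal_range * np.sin(phase)
    days = hours / 24.0
    true_wc = (config.wc_base
               - 0.5 * config.wc_diurnal_range * np.sin(phase)
               + config.wc_seasonal_drift * days)
    sensed_wc = (true_wc
                 + config.artefact_slope * (temp - config.reference_temperature)
                 + rng.normal(0.0, config.noise_sd, size=n))
    sqrt_eps = invert_calibration(sensed_wc, calibration)
    raw = invert_transform(sqrt_eps, transform)
    df = pd.DataFrame({
        "timestamp": timestamps,
        "raw": raw,
        "factory_wc": sensed_wc,
        "temperature": temp,
    })
    series = LoggerSeries(
        data=df,
        metadata={
            "source": "synthetic",
            "transform": transform.name,
            "calibration": calibration.label,
            "cadence_minutes": config.cadence_minutes,
        },
    )
    truth = {
        "true_wc": true_wc,
        "sensed_wc": sensed_wc,
        "artefact_slope": config.artefact_slope,
        "reference_temperature": config.reference_temperature,
        "config": asdict(config),
    }
    return series, truth
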