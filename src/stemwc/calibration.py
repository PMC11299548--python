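"""Linear sqrt(epsilon) -> volumetric water content calibrations.

Two published calibrations ship with the package registry:

* **TTC** (tropical tree calibration): ``theta = 0.2227*sqrt(eps) - 0.396``,
  an absolute calibration pooled over tropical dicot trees and arborescent
  palms.
* **OSC** (one-slope calibration): slope 0.2254 estimated on first-order
  differenced data. It carries no intercept and therefore supports only
  *relative* water-content changes; absolute application is refused.

Also here: the gravimetric reference quantities (volumetric water content
from fresh/dry mass and fresh volume, and wood density) used to build
calibration datasets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple, Union

import numpy as np

from .exceptions import (
    CalibrationModeError,
    ConfigError,
    DegenerateCalibrationError,
    DomainError,
    NegativeVWCWarning,
)

ArrayLike = Union[float, np.ndarray]

ABSOLUTE = "absolute"
RELATIVE_ONLY = "relative-only"


@dataclass(frozen=True)
class LinearCalibration:
    """A slope/intercept pair mapping sqrt(epsilon) to VWC (m3 m-3).

    The intercept is stored *signed*: the TTC line ``0.2227*sqrt(eps) - 0.396``
    is stored as ``intercept=-0.396`` and applied as ``slope*x + intercept``.
    ``mode="relative-only"`` marks slope-only calibrations (no intercept);
    these refuse absolute application.
    """

    slope: float
    intercept: Optional[float] = None
    slope_ci: Optional[Tuple[float, float]] = None
    intercept_ci: Optional[Tuple[float, float]] = None
    label: str = ""
    mode: str = ABSOLUTE

    def __post_init__(self):
        if self.mode not in (ABSOLUTE, RELATIVE_ONLY):
            raise ConfigError(f"unknown calibration mode {self.mode!r}")
        if self.mode == ABSOLUTE and self.intercept is None:
            raise ConfigError("absolute calibration requires an intercept")
        if self.mode == RELATIVE_ONLY and self.intercept is not None:
            raise ConfigError("relative-only calibration must not carry an intercept")
        if self.slope_ci is not None:
            lo, hi = self.slope_ci
            if not lo <= self.slope <= hi:
                raise ConfigError("slope_ci does not contain the slope")
        if self.intercept_ci is not None and self.intercept is not None:
            lo, hi = self.intercept_ci
            if not lo <= self.intercept <= hi:
                raise ConfigError("intercept_ci does not contain the intercept")

    @property
    def is_absolute(self) -> bool:
        return self.mode == ABSOLUTE


def apply_calibration(sqrt_epsilon: ArrayLike, cal: LinearCalibration) -> ArrayLike:
    """VWC = slope*sqrt(eps) + intercept.

    Negative results are returned unclipped but flagged with a
    :class:`NegativeVWCWarning` — dry-end extrapolation is diagnostic of
    sensor faults or out-of-domain wood.
    """
    if not cal.is_absolute:
        raise CalibrationModeError(
            f"calibration {cal.label or '<unnamed>'} is relative-only; "
            "absolute VWC is undefined"
        )
    x = np.asarray(sqrt_epsilon, dtype=float)
    if np.any(x < 0):
        raise DomainError("sqrt_epsilon must be non-negative")
    vwc = cal.slope * x + cal.intercept
    if np.any(np.asarray(vwc) < 0):
        warnings.warn(
            f"calibration {cal.label or '<unnamed>'} predicted negative VWC",
            NegativeVWCWarning,
            stacklevel=2,
        )
    return float(vwc) if x.ndim == 0 else vwc


def invert_calibration(vwc: ArrayLike, cal: LinearCalibration) -> ArrayLike:
    """sqrt(epsilon) that the calibration maps to the given VWC."""
    if not cal.is_absolute:
        raise CalibrationModeError("cannot invert a relative-only calibration")
    if cal.slope == 0:
        raise DegenerateCalibrationError("zero-slope calibration is not invertible")
    v = np.asarray(vwc, dtype=float)
    x = (v - cal.intercept) / cal.slope
    return float(x) if v.ndim == 0 else x


def relative_wc_change(delta_sqrt_epsilon: ArrayLike, cal: LinearCalibration) -> ArrayLike:
    """Change in VWC implied by a change in sqrt(epsilon): slope * delta.

    Works for relative-only calibrations (the OSC's purpose); the
    intercept is ignored by construction.
    """
    d = np.asarray(delta_sqrt_epsilon, dtype=float)
    out = cal.slope * d
    return float(out) if d.ndim == 0 else out


def gravimetric_vwc(
    fresh_mass: ArrayLike,
    dry_mass: ArrayLike,
    fresh_volume: ArrayLike,
    water_density: float = 1.0,
) -> ArrayLike:
    """Gravimetric volumetric water content (m3_water m-3_wood).

    ``((fresh_mass - dry_mass) / water_density) / fresh_volume`` with masses
    in g, volume in cm3 and water density in g cm-3 (default 1.0).
    A dry mass exceeding the fresh mass signals a scale or logging fault;
    the negative value is returned with a warning rather than hidden.
    """
    mf = np.asarray(fresh_mass, dtype=float)
    md = np.asarray(dry_mass, dtype=float)
    vf = np.asarray(fresh_volume, dtype=float)
    if np.any(vf <= 0):
        raise DomainError("fresh_volume must be positive")
    if np.any(mf < 0) or np.any(md < 0):
        raise DomainError("masses must be non-negative")
    if np.any(md > mf):
        warnings.warn(
            "dry mass exceeds fresh mass; negative VWC returned (check scales)",
            NegativeVWCWarning,
            stacklevel=2,
        )
    out = ((mf - md) / water_density) / vf
    return float(out) if out.ndim == 0 else out


def wood_density(dry_mass: ArrayLike, fresh_volume: ArrayLike) -> ArrayLike:
    """Wood density: oven-dry mass over fresh volume (g cm-3)."""
    md = np.asarray(dry_mass, dtype=float)
    vf = np.asarray(fresh_volume, dtype=float)
    if np.any(vf <= 0):
        raise DomainError("fresh_volume must be positive")
    out = md / vf
    return float(out) if out.ndim == 0 else out


class CalibrationRegistry:
    """Named set of :class:`LinearCalibration` entries."""

    def __init__(self, entries: Optional[dict] = None):
        self._entries: dict = dict(entries or {})

    def __getitem__(self, name: str) -> LinearCalibration:
        try:
            return self._entries[name]
        except KeyError:
            raise KeyError(
                f"unknown calibration {name!r}; available: {sorted(self._entries)}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def __iter__(self):
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def names(self):
        return sorted(self._entries)

    def add(self, name: str, cal: LinearCalibration):
        self._entries[name] = cal

    def items(self):
        return self._entries.items()
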