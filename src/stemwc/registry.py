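"""Registry of transforms, calibrations and temperature models.

Loaded from a plain-text YAML file; the packaged default carries the
Teros 11/12 manual transform, the TTC/OSC calibrations and both
temperature-experiment coefficients. User registries with the same
schema can be loaded from any path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Dict, Optional, Union

import yaml

from .calibration import CalibrationRegistry, LinearCalibration
from .dielectrics import PolynomialTransform
from .exceptions import ConfigError
from .thermal import TemperatureModel


@dataclass
class Registry:
    transforms: Dict[str, PolynomialTransform] = field(default_factory=dict)
    calibrations: CalibrationRegistry = field(default_factory=CalibrationRegistry)
    temperature_models: Dict[str, TemperatureModel] = field(default_factory=dict)
    source: str = ""

    def transform(self, name: str) -> PolynomialTransform:
        try:
            return self.transforms[name]
        except KeyError:
            raise KeyError(
                f"unknown transform {name!r}; available: {sorted(self.transforms)}"
            ) from None

    def temperature_model(self, name: str) -> TemperatureModel:
        try:
            return self.temperature_models[name]
        except KeyError:
            raise KeyError(
                f"unknown temperature model {name!r}; "
                f"available: {sorted(self.temperature_models)}"
            ) from None


def _as_tuple(value):
    return None if value is None else tuple(float(v) for v in value)


def load_registry(path: Union[str, Path]) -> Registry:
    """Parse a registry YAML file into typed objects (validated on load)."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    reg = Registry(source=str(path))
    for name, spec in (doc.get("transforms") or {}).items():
        try:
            reg.transforms[name] = PolynomialTransform(
                name=name,
                coefficients=tuple(spec["coefficients"]),
                post_square=bool(spec.get("post_square", False)),
                valid_range=_as_tuple(spec.get("valid_range")),
            )
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"bad transform entry {name!r}: {exc}") from exc
    for name, spec in (doc.get("calibrations") or {}).items():
        try:
            reg.calibrations.add(
                name,
                LinearCalibration(
                    slope=float(spec["slope"]),
                    intercept=(None if spec.get("intercept") is None
                               else float(spec["intercept"])),
                    slope_ci=_as_tuple(spec.get("slope_ci")),
                    intercept_ci=_as_tuple(spec.get("intercept_ci")),
                    label=str(spec.get("label", name)),
                    mode=str(spec.get("mode", "absolute")),
                ),
            )
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"bad calibration entry {name!r}: {exc}") from exc
    for name, spec in (doc.get("temperature_models") or {}).items():
        try:
            reg.temperature_models[name] = TemperatureModel(
                slope_wc=float(spec["slope_wc"]),
                slope_wc_se=(None if spec.get("slope_wc_se") is None
                             else float(spec["slope_wc_se"])),
                slope_wc_ci=_as_tuple(spec.get("slope_wc_ci")),
                r2=(None if spec.get("r2") is None else float(spec["r2"])),
                slope_sqrt_eps=(None if spec.get("slope_sqrt_eps") is None
                                else float(spec["slope_sqrt_eps"])),
                reference_temperature=float(spec.get("reference_temperature", 25.0)),
                n=(None if spec.get("n") is None else int(spec["n"])),
                label=str(spec.get("label", name)),
            )
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"bad temperature model entry {name!r}: {exc}") from exc
    return reg


@lru_cache(maxsize=1)
def default_registry() -> Registry:
    """The packaged registry (TTC, OSC, meta slope; bucket/block temperature models)."""
    with resources.as_file(
        resources.files("stemwc.data").joinpath("default_registry.yaml")
    ) as p:
        return load_registry(p)
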