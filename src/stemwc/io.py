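"""CSV input/output and toolkit configuration.

CSV is the sole tabular interchange format (comma delimiter, "." decimal
point regardless of locale). Segment tables use the canonical header of
:data:`stemwc.calibfit.SEGMENT_COLUMNS`; foreign headers are mapped with
a ``column_map`` of ``{canonical_name: file_column_name}``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .calibfit import SEGMENT_COLUMNS, VWC_SANITY_BAND
from .exceptions import DataQualityWarning, OrderingError, SchemaError
from .fieldseries import LoggerSeries

SEGMENT_REQUIRED = ("species", "individual", "sqrt_epsilon", "vwc")
LOGGER_REQUIRED = ("timestamp",)

#: reject the input outright when more than this fraction of rows fails
MAX_INVALID_FRACTION = 0.10


def _remap(df: pd.DataFrame, column_map: Optional[Dict[str, str]]) -> pd.DataFrame:
    if not column_map:
        return df
    rename = {src: canon for canon, src in column_map.items() if src in df.columns}
    return df.rename(columns=rename)


def read_segment_table(
    path: Union[str, Path], column_map: Optional[Dict[str, str]] = None
) -> pd.DataFrame:
    """Read and validate a segment calibration table.

    Row-level failures (non-finite sqrt(epsilon), VWC outside the sanity
    band) are reported with their file line numbers; the offending rows
    are dropped with a warning, unless more than 10% of rows fail, in
    which case the whole file is rejected — a VWC column in percent, for
    example, fails the band everywhere and aborts with a clear message.
    """
    df = pd.read_csv(path)
    df = _remap(df, column_map)
    missing = [c for c in SEGMENT_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    lo, hi = VWC_SANITY_BAND
    vwc = pd.to_numeric(df["vwc"], errors="coerce")
    se = pd.to_numeric(df["sqrt_epsilon"], errors="coerce")
    bad = (~np.isfinite(vwc)) | (vwc < lo) | (vwc > hi) | (~np.isfinite(se)) | (se < 0)
    if bad.any():
        # +2: header line plus 1-based numbering
        lines = (df.index[bad] + 2).tolist()
        frac = bad.mean()
        msg = (f"{path}: {int(bad.sum())} invalid rows "
               f"(vwc outside {VWC_SANITY_BAND} or bad sqrt_epsilon) "
               f"at file lines {lines[:20]}")
        if frac > MAX_INVALID_FRACTION:
            raise SchemaError(msg + f"; {frac:.0%} invalid, aborting")
        warnings.warn(msg + "; rows dropped", DataQualityWarning, stacklevel=2)
        df = df[~bad]
    df = df.copy()
    df["vwc"] = pd.to_numeric(df["vwc"])
    df["sqrt_epsilon"] = pd.to_numeric(df["sqrt_epsilon"])
    if "order_index" in df.columns:
        df["order_index"] = pd.to_numeric(df["order_index"]).astype(int)
    return df.reset_index(drop=True)


def write_segment_table(df: pd.DataFrame, path: Union[str, Path]):
    cols = [c for c in SEGMENT_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, index=False)


def read_logger_csv(
    path: Union[str, Path], column_map: Optional[Dict[str, str]] = None
) -> LoggerSeries:
    """Read a logger CSV export into a :class:`LoggerSeries`.

    Timestamps must be strictly increasing; duplicated or out-of-order
    stamps raise :class:`OrderingError` listing the offenders. Cadence
    gaps are recorded in the series metadata (never filled).
    """
    df = pd.read_csv(path)
    df = _remap(df, column_map)
    missing = [c for c in LOGGER_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    series = LoggerSeries(data=df, metadata={"source": str(path)})
    if series.metadata.get("gaps"):
        warnings.warn(
            f"{path}: {len(series.metadata['gaps'])} cadence gap(s) recorded "
            "in metadata",
            DataQualityWarning,
            stacklevel=2,
        )
    return series


def write_logger_csv(series: LoggerSeries, path: Union[str, Path]):
    series.data.to_csv(path, index=False)


@dataclass
class ToolkitConfig:
    """Top-level processing configuration; round-trips through YAML."""

    transform: str = "teros12"
    calibration: str = "TTC"
    temperature_model: str = "water-bucket"
    reference_temperature: float = 25.0
    column_map: Dict[str, str] = field(default_factory=dict)
    output_dir: str = "."
    verbosity: int = 1

    def validate(self, registry) -> "ToolkitConfig":
        if self.transform not in registry.transforms:
            raise SchemaError(f"unknown transform {self.transform!r} in config")
        if self.calibration not in registry.calibrations:
            raise SchemaError(f"unknown calibration {self.calibration!r} in config")
        if self.temperature_model not in registry.temperature_models:
            raise SchemaError(
                f"unknown temperature model {self.temperature_model!r} in config"
            )
        return self

    def to_yaml(self, path: Union[str, Path]):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "ToolkitConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise SchemaError(f"unknown config keys {sorted(unknown)}")
        return cls(**doc)
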