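"""Raw sensor counts to dielectric permittivity.

Capacitance (FDR) sensors report raw counts; the manufacturer supplies a
polynomial transform from counts to relative dielectric permittivity
``epsilon``. Because the relation between epsilon and water content is
nonlinear, calibrations regress on ``sqrt(epsilon)`` instead, which is
close to linear in volumetric water content for porous media.

The transform itself is configuration, not science: coefficients are read
from the registry (see :mod:`stemwc.registry`), shipped with the
manufacturer-manual default for the Teros 11/12, and validated numerically
for monotonicity and positivity over their declared raw-count range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .exceptions import ConfigError, DomainError, RangeError, TransformDomainError

ArrayLike = Union[float, np.ndarray]

_GRID_N = 2001


@dataclass(frozen=True)
class PermittivitySample:
    """Relative dielectric permittivity and its square root.

    Both fields are dimensionless; ``sqrt_epsilon**2 == epsilon`` holds to
    1e-12 relative tolerance by construction.
    """

    epsilon: ArrayLike
    sqrt_epsilon: ArrayLike

    def __post_init__(self):
        eps = np.asarray(self.epsilon, dtype=float)
        sq = np.asarray(self.sqrt_epsilon, dtype=float)
        if not np.allclose(sq**2, eps, rtol=1e-12, atol=0.0):
            raise ConfigError("sqrt_epsilon**2 does not equal epsilon")


@dataclass(frozen=True)
class PolynomialTransform:
    """Polynomial map from raw counts to permittivity.

    Parameters
    ----------
    coefficients
        Polynomial coefficients, lowest order first.
    post_square
        If True, epsilon is the *square* of the polynomial output (the
        convention of the Teros 11/12 manual, whose polynomial yields
        ``sqrt(epsilon)`` directly).
    valid_range
        Inclusive raw-count range over which the transform is declared
        valid. If None, the widest contiguous range over which the
        transform is strictly increasing with positive epsilon is found
        numerically on a grid at construction time.
    """

    name: str = "unnamed"
    coefficients: tuple = (0.0, 1.0)
    post_square: bool = False
    valid_range: tuple = None
    search_window: tuple = field(default=(-1e4, 1e5), repr=False)

    def __post_init__(self):
        coefs = tuple(float(c) for c in self.coefficients)
        if len(coefs) < 1:
            raise ConfigError("transform needs at least one coefficient")
        object.__setattr__(self, "coefficients", coefs)
        if self.valid_range is None:
            object.__setattr__(self, "valid_range", self._auto_range())
        lo, hi = (float(v) for v in self.valid_range)
        if not lo < hi:
            raise ConfigError(f"invalid raw range ({lo}, {hi}) for transform {self.name!r}")
        object.__setattr__(self, "valid_range", (lo, hi))
        self._validate_on_grid()

    # epsilon = p(raw)**2 is increasing iff p > 0 and p' > 0; without the
    # post-square, the same pair of conditions enforces epsilon > 0 too.
    def _admissible(self, raw: np.ndarray) -> np.ndarray:
        p = self._poly(raw)
        dp = np.polynomial.polynomial.polyval(
            raw, np.polynomial.polynomial.polyder(self.coefficients)
        )
        return (p > 0.0) & (dp > 0.0)

    def _auto_range(self) -> tuple:
        grid = np.linspace(self.search_window[0], self.search_window[1], 200001)
        ok = self._admissible(grid)
        if not ok.any():
            raise ConfigError(
                f"transform {self.name!r} has no monotone positive region in "
                f"{self.search_window}"
            )
        # widest contiguous run of admissible grid points
        edges = np.flatnonzero(np.diff(np.concatenate(([0], ok.view(np.int8), [0]))))
        starts, stops = edges[::2], edges[1::2]
        best = np.argmax(stops - starts)
        return (float(grid[starts[best]]), float(grid[stops[best] - 1]))

    def _validate_on_grid(self):
        grid = np.linspace(self.valid_range[0], self.valid_range[1], _GRID_N)
        if not self._admissible(grid).all():
            raise ConfigError(
                f"transform {self.name!r} is not strictly increasing with "
                f"positive epsilon over raw range {self.valid_range}"
            )

    def _poly(self, raw: ArrayLike) -> ArrayLike:
        return np.polynomial.polynomial.polyval(raw, self.coefficients)

    def epsilon(self, raw: ArrayLike) -> ArrayLike:
        """Evaluate epsilon at raw counts without range checking."""
        p = self._poly(raw)
        return p**2 if self.post_square else p


def raw_to_permittivity(raw: ArrayLike, transform: PolynomialTransform) -> PermittivitySample:
    """Convert raw sensor counts to permittivity.

    Raises
    ------
    RangeError
        If any raw value lies outside the transform's valid range; the
        message names the first offending value.
    TransformDomainError
        If the transform yields non-positive epsilon.
    """
    arr = np.asarray(raw, dtype=float)
    lo, hi = transform.valid_range
    bad = (arr < lo) | (arr > hi) | ~np.isfinite(arr)
    if bad.any():
        offender = arr[np.atleast_1d(bad)][0] if arr.ndim else float(arr)
        raise RangeError(
            f"raw value {offender!r} outside valid range ({lo}, {hi}) "
            f"of transform {transform.name!r}"
        )
    eps = transform.epsilon(arr)
    if np.any(np.asarray(eps) <= 0.0):
        raise TransformDomainError(
            f"transform {transform.name!r} produced non-positive epsilon"
        )
    sqrt_eps = np.sqrt(eps)
    if arr.ndim == 0:
        return PermittivitySample(float(eps), float(sqrt_eps))
    return PermittivitySample(eps, sqrt_eps)


def sqrt_transform(epsilon: ArrayLike) -> ArrayLike:
    """Non-negative square root of permittivity; negative input is a domain error."""
    arr = np.asarray(epsilon, dtype=float)
    if np.any(arr < 0.0):
        raise DomainError("epsilon must be non-negative")
    out = np.sqrt(arr)
    return float(out) if arr.ndim == 0 else out


def invert_transform(
    sqrt_epsilon: ArrayLike, transform: PolynomialTransform, xtol: float = 1e-12
) -> ArrayLike:
    """Raw counts producing the given sqrt(epsilon); numeric bisection.

    Used by the synthetic field-series generator to emit raw counts that
    round-trip through :func:`raw_to_permittivity`.
    """
    from scipy.optimize import brentq

    lo, hi = transform.valid_range
    arr = np.atleast_1d(np.asarray(sqrt_epsilon, dtype=float))
    if transform.post_square:
        def f(raw, target):
            return transform._poly(raw) - target
    else:
        def f(raw, target):
            return transform._poly(raw) - target**2

    out = np.empty_like(arr)
    for i, target in enumerate(arr):
        if f(lo, target) > 0 or f(hi, target) < 0:
            raise DomainError(
                f"sqrt_epsilon={target} not reachable within raw range ({lo}, {hi})"
            )
        out[i] = brentq(f, lo, hi, args=(target,), xtol=xtol)
    if np.asarray(sqrt_epsilon).ndim == 0:
        return float(out[0])
    return out


def identity_transform() -> PolynomialTransform:
    """Identity raw->epsilon transform over positive counts (for testing/bypass)."""
    return PolynomialTransform(
        name="identity", coefficients=(0.0, 1.0), post_square=False,
        valid_range=(1e-9, 1e6),
    )
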