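"""Magnitude-domain random transformations.

Four label-preserving distortions of a single ``(T, S)`` window that change
amplitudes while leaving the time axis alone: additive Gaussian jitter,
elementwise cosine "rotation" (the field's name — not a rotation matrix),
multiplicative scaling, and magnitude warping by a smooth random curve.

Multichannel conventions: jitter and rotation draw independently per
element; magnitude warping draws one independent spline per channel;
scaling applies a single factor to the whole window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ParameterError
from .spline import SplineCurve

__all__ = [
    "JitterParams",
    "RotationParams",
    "ScalingParams",
    "MagnitudeWarpParams",
    "jitter",
    "rotate",
    "scale",
    "magnitude_warp",
]


@dataclass(frozen=True)
class JitterParams:
    """Gaussian noise mean and standard deviation (sensor units)."""

    mu: float = 0.0
    sigma: float = 0.03

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ParameterError(f"jitter sigma must be >= 0; got {self.sigma}")


@dataclass(frozen=True)
class RotationParams:
    """No numeric parameter; angles are drawn uniformly from [0, 2*pi)."""


@dataclass(frozen=True)
class ScalingParams:
    """Multiplicative factor alpha.

    ``alpha`` may be a nonzero number (applied as-is) or the string
    ``"random"``, in which case a factor is drawn from ``N(1, 0.1^2)``
    truncated away from zero.
    """

    alpha: float | str = 0.1

    def __post_init__(self) -> None:
        if self.alpha != "random" and float(self.alpha) == 0.0:
            raise ParameterError("scaling alpha must be nonzero")


@dataclass(frozen=True)
class MagnitudeWarpParams:
    """Number of interior knots and the knot-height distribution N(mu, sigma^2)."""

    knots: int = 4
    mu: float = 1.0
    sigma: float = 0.2

    def __post_init__(self) -> None:
        if self.knots < 1:
            raise ParameterError(f"need at least 1 knot; got {self.knots}")
        if self.sigma < 0:
            raise ParameterError(f"sigma must be >= 0; got {self.sigma}")


def _check_window(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ParameterError(f"window must be 2-D (T, S); got shape {x.shape}")
    return x


def jitter(x: np.ndarray, params: JitterParams, rng: np.random.Generator) -> np.ndarray:
    """Add i.i.d. Gaussian noise ``N(mu, sigma^2)`` to every element."""
    x = _check_window(x)
    return x + rng.normal(params.mu, params.sigma, size=x.shape)


def rotate(x: np.ndarray, params: RotationParams, rng: np.random.Generator) -> np.ndarray:
    """Multiply each element by cos(theta), theta ~ U(0, 2*pi) per element.

    Elementwise magnitude never increases: |x'_ij| <= |x_ij|.
    """
    x = _check_window(x)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=x.shape)
    return x * np.cos(theta)


def scale(
    x: np.ndarray, params: ScalingParams, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Multiply the whole window by one factor alpha (exactly linear)."""
    x = _check_window(x)
    if params.alpha == "random":
        if rng is None:
            raise ParameterError("random scaling requires an rng")
        alpha = 0.0
        while abs(alpha) < 1e-3:  # truncate away from zero
            alpha = rng.normal(1.0, 0.1)
    else:
        alpha = float(params.alpha)
    return alpha * x


def magnitude_warp(
    x: np.ndarray, params: MagnitudeWarpParams, rng: np.random.Generator
) -> np.ndarray:
    """Multiply each channel by an independent smooth random curve.

    The curve is a cubic spline through ``knots`` interior knots plus the two
    endpoints, evenly spaced over ``[0, T-1]``, heights ~ ``N(mu, sigma^2)``.
    With ``sigma = 0`` and ``mu = 1`` this is the identity.
    """
    x = _check_window(x)
    t, s = x.shape
    if t < 2:
        raise ParameterError("magnitude warping needs T >= 2")
    timesteps = np.arange(t)
    out = np.empty_like(x)
    for j in range(s):
        curve = SplineCurve.random(params.knots, t, params.mu, params.sigma, rng)
        out[:, j] = curve(timesteps) * x[:, j]
    return out
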