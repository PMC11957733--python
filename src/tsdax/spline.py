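"""Smooth knot-based curves used by magnitude and time warping.

Both warps draw knot heights from a normal distribution and interpolate a
cubic spline through them; the spline evaluated at every timestep gives a
per-timestep multiplier (magnitude warp) or speed (time warp).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = ["SplineCurve"]


@dataclass(frozen=True)
class SplineCurve:
    """Cubic spline through knots spanning the time axis, endpoints included.

    Evaluation at a knot position returns the knot height exactly
    (interpolation, not approximation); a curve whose knots are all 1
    evaluates to 1 everywhere.
    """

    knot_positions: np.ndarray
    knot_values: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.knot_positions, dtype=float)
        val = np.asarray(self.knot_values, dtype=float)
        if pos.ndim != 1 or pos.shape != val.shape:
            raise ValueError("knot positions and values must be 1-D and equal length")
        if len(pos) < 3:
            raise ValueError("need at least 3 knots (one interior + endpoints)")
        if not np.all(np.diff(pos) > 0):
            raise ValueError("knot positions must be strictly increasing")
        object.__setattr__(self, "knot_positions", pos)
        object.__setattr__(self, "knot_values", val)
        object.__setattr__(self, "_spline", CubicSpline(pos, val))

    def __call__(self, t: np.ndarray | float) -> np.ndarray:
        return self._spline(t)

    @classmethod
    def random(
        cls,
        n_interior_knots: int,
        length: int,
        mu: float,
        sigma: float,
        rng: np.random.Generator,
    ) -> "SplineCurve":
        """Curve over ``[0, length-1]`` with ``n_interior_knots + 2`` evenly
        spaced knots whose heights are drawn i.i.d. from ``N(mu, sigma^2)``."""
        if n_interior_knots < 1:
            raise ValueError("need at least one interior knot")
        positions = np.linspace(0.0, float(length - 1), n_interior_knots + 2)
        values = rng.normal(mu, sigma, size=n_interior_knots + 2)
        return cls(positions, values)
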