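"""Time-domain random transformations.

Distortions of the time axis of a ``(T, S)`` window: slicing (crop and
stretch back), segment permutation, smooth time warping, and window warping
(local stretch/contraction).  All four preserve the window shape ``(T, S)``.

Time-axis warps are shared across channels to preserve inter-channel
synchrony — the sensors are co-recorded, so a warp that moved channels
independently would decorrelate them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ParameterError
from .spline import SplineCurve

__all__ = [
    "SliceParams",
    "PermutationParams",
    "TimeWarpParams",
    "WindowWarpParams",
    "slice_resample",
    "permute",
    "time_warp",
    "window_warp",
]


@dataclass(frozen=True)
class SliceParams:
    """Fraction of the window kept before stretching back to length T."""

    keep_fraction: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 < self.keep_fraction <= 1.0:
            raise ParameterError(f"keep_fraction must be in (0, 1]; got {self.keep_fraction}")

    def window_length(self, t: int) -> int:
        w = int(round(self.keep_fraction * t))
        if w < 2:
            raise ParameterError(f"slice of {self.keep_fraction} x T={t} is shorter than 2")
        return min(w, t)


@dataclass(frozen=True)
class PermutationParams:
    """Number of contiguous segments whose order is shuffled."""

    n_segments: int = 5

    def __post_init__(self) -> None:
        if self.n_segments < 1:
            raise ParameterError(f"n_segments must be >= 1; got {self.n_segments}")


@dataclass(frozen=True)
class TimeWarpParams:
    """Interior knot count and knot-height distribution of the speed curve."""

    knots: int = 4
    mu: float = 1.0
    sigma: float = 0.2
    max_retries: int = 16

    def __post_init__(self) -> None:
        if self.knots < 1:
            raise ParameterError(f"need at least 1 knot; got {self.knots}")
        if self.sigma < 0:
            raise ParameterError(f"sigma must be >= 0; got {self.sigma}")


@dataclass(frozen=True)
class WindowWarpParams:
    """Length fraction of the two warped windows and their factors.

    Two random non-overlapping equal-length subsequences are picked; one is
    stretched, the other contracted, by the two factors (default {2, 1/2}).
    """

    window_fraction: float = 0.1
    factors: tuple[float, float] = (0.5, 2.0)

    def __post_init__(self) -> None:
        if not 0.0 < self.window_fraction < 0.5:
            raise ParameterError(
                f"window_fraction must be in (0, 0.5); got {self.window_fraction}"
            )


def _check_window(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ParameterError(f"window must be 2-D (T, S); got shape {x.shape}")
    return x


def _resample(x: np.ndarray, length: int) -> np.ndarray:
    """Linear resampling of a (t, S) block to ``length`` timesteps."""
    t = x.shape[0]
    if t == length:
        return x.copy()
    if t == 1:
        return np.repeat(x, length, axis=0)
    src = np.linspace(0.0, 1.0, t)
    dst = np.linspace(0.0, 1.0, length)
    return np.column_stack([np.interp(dst, src, x[:, j]) for j in range(x.shape[1])])


def slice_resample(
    x: np.ndarray, params: SliceParams, rng: np.random.Generator
) -> np.ndarray:
    """Crop a random contiguous segment and stretch it back to length T.

    The segment ``[zeta, zeta + w)`` with ``zeta ~ U{0 .. T-w}`` is linearly
    interpolated to T timesteps, so per-channel output values stay within
    the segment's min/max.
    """
    x = _check_window(x)
    t = x.shape[0]
    w = params.window_length(t)
    zeta = int(rng.integers(0, t - w + 1))
    return _resample(x[zeta : zeta + w], t)


def segment_bounds(t: int, n_segments: int) -> list[tuple[int, int]]:
    """Half-open bounds of ``n_segments`` near-equal contiguous segments.

    The first ``T mod n_segments`` segments get one extra timestep.
    """
    base, extra = divmod(t, n_segments)
    bounds, start = [], 0
    for k in range(n_segments):
        stop = start + base + (1 if k < extra else 0)
        bounds.append((start, stop))
        start = stop
    return bounds


def permute(
    x: np.ndarray, params: PermutationParams, rng: np.random.Generator
) -> np.ndarray:
    """Shuffle the order of contiguous time segments.

    The window is cut into ``n_segments`` near-equal slices which are
    re-concatenated in a uniformly drawn order; the multiset of rows is
    conserved.
    """
    x = _check_window(x)
    t = x.shape[0]
    if params.n_segments > t:
        raise ParameterError(f"n_segments={params.n_segments} exceeds T={t}")
    bounds = segment_bounds(t, params.n_segments)
    order = rng.permutation(params.n_segments)
    return np.concatenate([x[bounds[k][0] : bounds[k][1]] for k in order], axis=0)


def time_warp(
    x: np.ndarray, params: TimeWarpParams, rng: np.random.Generator
) -> np.ndarray:
    """Resample the window along a smooth random warp of the time axis.

    A spline speed curve with knot heights ~ ``N(mu, sigma^2)`` is evaluated
    at every timestep; its cumulative sum, rescaled to span ``[0, T-1]``,
    gives a strictly increasing warp ``tau`` with pinned endpoints.  The
    output is the input linearly interpolated at ``tau``; one shared warp is
    applied to all channels.  If the spline dips non-positive the knots are
    resampled (bounded retries), then an error is raised.
    """
    x = _check_window(x)
    t = x.shape[0]
    if t < 2:
        raise ParameterError("time warping needs T >= 2")
    timesteps = np.arange(t, dtype=float)
    for _ in range(params.max_retries):
        curve = SplineCurve.random(params.knots, t, params.mu, params.sigma, rng)
        speeds = curve(timesteps)
        if np.all(speeds > 0):
            break
    else:
        raise ParameterError(
            "speed curve stayed non-positive after "
            f"{params.max_retries} retries (mu={params.mu}, sigma={params.sigma})"
        )
    cumulative = np.cumsum(speeds)
    cumulative -= cumulative[0]
    tau = cumulative / cumulative[-1] * (t - 1)
    return np.column_stack([np.interp(tau, timesteps, x[:, j]) for j in range(x.shape[1])])


def window_warp(
    x: np.ndarray, params: WindowWarpParams, rng: np.random.Generator
) -> np.ndarray:
    """Stretch one random subsequence and contract another, keeping length T.

    Two non-overlapping equal-length subsequences are drawn; one is
    stretched by the larger factor, the other contracted by the smaller
    (both via linear interpolation).  The concatenation is linearly
    resampled back to T timesteps so the output matches the input size.
    """
    x = _check_window(x)
    t = x.shape[0]
    length = int(round(params.window_fraction * t))
    if length < 2:
        raise ParameterError(f"window of {params.window_fraction} x T={t} is shorter than 2")
    if 2 * length > t:
        raise ParameterError("two non-overlapping windows do not fit")
    # Draw two disjoint start positions: first window anywhere that leaves
    # room for the second, second strictly after the first.
    start_a = int(rng.integers(0, t - 2 * length + 1))
    start_b = int(rng.integers(start_a + length, t - length + 1))
    lo, hi = sorted(params.factors)
    if bool(rng.integers(0, 2)):
        factor_a, factor_b = hi, lo
    else:
        factor_a, factor_b = lo, hi
    pieces = [
        x[:start_a],
        _resample(x[start_a : start_a + length], max(2, int(round(factor_a * length)))),
        x[start_a + length : start_b],
        _resample(x[start_b : start_b + length], max(2, int(round(factor_b * length)))),
        x[start_b + length :],
    ]
    warped = np.concatenate([p for p in pieces if p.shape[0]], axis=0)
    return _resample(warped, t)
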