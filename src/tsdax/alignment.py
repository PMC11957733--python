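"""Dynamic time warping and the variants used by pattern mixing.

Plain DTW under the symmetric step pattern, ShapeDTW (DTW on local
subsequence descriptors), and suboptimal DTW (DTW constrained to pass
through a prescribed matching point, as used by SPAWNER).

Local cost is the squared Euclidean distance across channels.  Dynamic-
programming ties are broken deterministically, preferring the diagonal
step, then the step consuming a timestep of the first sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "StepPattern",
    "SYMMETRIC",
    "WarpPath",
    "dtw",
    "shape_dtw",
    "suboptimal_dtw",
    "shape_descriptors",
    "ShapeDescriptorParams",
]


@dataclass(frozen=True)
class StepPattern:
    """Allowed alignment steps and their weights.

    The default is the symmetric pattern: diagonal, vertical, and
    horizontal unit-weight steps with no slope limit or global band.
    """

    steps: tuple[tuple[int, int], ...] = ((1, 1), (1, 0), (0, 1))
    weights: tuple[float, ...] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if len(self.steps) != len(self.weights):
            raise ValueError("steps and weights must be equal length")
        for di, dj in self.steps:
            if di < 0 or dj < 0 or (di == 0 and dj == 0):
                raise ValueError(f"step {(di, dj)} does not advance")


SYMMETRIC = StepPattern()


@dataclass(frozen=True)
class ShapeDescriptorParams:
    """Raw local-subsequence descriptor of odd length, edge-padded."""

    descriptor_len: int = 5

    def __post_init__(self) -> None:
        if self.descriptor_len < 1 or self.descriptor_len % 2 == 0:
            raise ValueError(f"descriptor_len must be odd and >= 1; got {self.descriptor_len}")


@dataclass(frozen=True)
class WarpPath:
    """Monotone alignment between two sequences.

    ``pairs`` is the ordered list of 0-based index pairs from ``(0, 0)`` to
    ``(T_a - 1, T_b - 1)``; ``cost`` is the nonnegative total alignment cost.
    """

    pairs: tuple[tuple[int, int], ...]
    cost: float

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("empty warp path")
        if self.pairs[0] != (0, 0):
            raise ValueError(f"path must start at (0, 0); got {self.pairs[0]}")
        for (i0, j0), (i1, j1) in zip(self.pairs, self.pairs[1:]):
            if (i1 - i0, j1 - j0) not in {(1, 0), (0, 1), (1, 1)}:
                raise ValueError(f"illegal step {(i0, j0)} -> {(i1, j1)}")
        if self.cost < 0:
            raise ValueError(f"negative alignment cost {self.cost}")

    @property
    def a_indices(self) -> np.ndarray:
        return np.array([i for i, _ in self.pairs])

    @property
    def b_indices(self) -> np.ndarray:
        return np.array([j for _, j in self.pairs])


def _as_sequence(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2 or x.shape[0] == 0:
        raise ValueError(f"sequence must be non-empty (T, S); got shape {x.shape}")
    return x


def local_cost_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean costs between timesteps of a and b."""
    a, b = _as_sequence(a), _as_sequence(b)
    if a.shape[1] != b.shape[1]:
        raise ValueError(f"channel mismatch: {a.shape[1]} vs {b.shape[1]}")
    return cdist(a, b, metric="sqeuclidean")


def _dtw_from_costs(local: np.ndarray, step: StepPattern) -> WarpPath:
    ta, tb = local.shape
    acc = np.full((ta, tb), np.inf)
    # step index taken to reach each cell, -1 at the origin
    choice = np.full((ta, tb), -1, dtype=np.int8)
    acc[0, 0] = local[0, 0]
    for i in range(ta):
        for j in range(tb):
            if i == 0 and j == 0:
                continue
            best, best_k = np.inf, -1
            for k, ((di, dj), w) in enumerate(zip(step.steps, step.weights)):
                pi, pj = i - di, j - dj
                if pi < 0 or pj < 0:
                    continue
                cand = acc[pi, pj] + w * local[i, j]
                if cand < best:  # strict: earlier (diagonal-first) step wins ties
                    best, best_k = cand, k
            acc[i, j] = best
            choice[i, j] = best_k

    pairs = [(ta - 1, tb - 1)]
    i, j = ta - 1, tb - 1
    while (i, j) != (0, 0):
        di, dj = step.steps[choice[i, j]]
        i, j = i - di, j - dj
        pairs.append((i, j))
    pairs.reverse()
    return WarpPath(tuple(pairs), float(acc[ta - 1, tb - 1]))


def dtw(a: np.ndarray, b: np.ndarray, step: StepPattern = SYMMETRIC) -> WarpPath:
    """Minimal-cost monotone alignment of two sequences.

    ``dtw(x, x)`` has zero cost along the diagonal; under the symmetric
    step pattern the cost is symmetric in its arguments.
    """
    return _dtw_from_costs(local_cost_matrix(a, b), step)


def shape_descriptors(x: np.ndarray, desc: ShapeDescriptorParams) -> np.ndarray:
    """Replace each timestep by its flattened local subsequence.

    The subsequence of ``descriptor_len`` timesteps centered at t is taken
    with edge replication, then flattened across channels, giving a
    ``(T, descriptor_len * S)`` sequence.  Length-1 descriptors reproduce
    the input.
    """
    x = _as_sequence(x)
    half = desc.descriptor_len // 2
    padded = np.pad(x, ((half, half), (0, 0)), mode="edge")
    t = x.shape[0]
    return np.stack([padded[i : i + desc.descriptor_len].ravel() for i in range(t)])


def shape_dtw(
    a: np.ndarray,
    b: np.ndarray,
    step: StepPattern = SYMMETRIC,
    desc: ShapeDescriptorParams = ShapeDescriptorParams(),
) -> WarpPath:
    """DTW on local-subsequence descriptors; path indices refer to the
    original timesteps.  With ``descriptor_len = 1`` this is plain DTW."""
    da, db = shape_descriptors(_as_sequence(a), desc), shape_descriptors(_as_sequence(b), desc)
    return _dtw_from_costs(local_cost_matrix(da, db), step)


def suboptimal_dtw(
    a: np.ndarray,
    b: np.ndarray,
    step: StepPattern = SYMMETRIC,
    forced: tuple[int, int] = (0, 0),
) -> WarpPath:
    """Minimal-cost alignment constrained to pass through ``forced``.

    Computed as DTW on the prefix rectangle up to the forced cell
    concatenated with DTW on the suffix rectangle from it; the forced
    cell's local cost is counted once.  The constrained cost is >= the
    unconstrained DTW cost, with equality when the forced cell lies on an
    optimal path (e.g. the corners).
    """
    a, b = _as_sequence(a), _as_sequence(b)
    i_star, j_star = forced
    if not (0 <= i_star < a.shape[0] and 0 <= j_star < b.shape[0]):
        raise ValueError(f"forced point {forced} out of range for lengths "
                         f"{(a.shape[0], b.shape[0])}")
    local = local_cost_matrix(a, b)
    head = _dtw_from_costs(local[: i_star + 1, : j_star + 1], step)
    tail = _dtw_from_costs(local[i_star:, j_star:], step)
    tail_pairs = [(i + i_star, j + j_star) for i, j in tail.pairs[1:]]
    # the forced cell's local cost appears in both sub-alignments (as the
    # head's terminal cell and the tail's origin); remove one copy.
    cost = head.cost + tail.cost - float(local[i_star, j_star])
    return WarpPath(tuple(list(head.pairs) + tail_pairs), max(cost, 0.0))
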