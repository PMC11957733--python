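"""Pattern-mixing augmenters: SMOTE, guided warping (RGW/DGW), SPAWNER.

Unlike the random transformations, these methods combine two (or more)
same-class windows: SMOTE interpolates a window toward a near neighbour,
guided warping re-times a window onto the time base of a reference
("teacher") window found by DTW or ShapeDTW, and SPAWNER averages two
windows after aligning them with a suboptimal DTW forced through a random
matching point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .alignment import (
    SYMMETRIC,
    ShapeDescriptorParams,
    StepPattern,
    WarpPath,
    dtw,
    shape_dtw,
    suboptimal_dtw,
)
from .core import LabeledWindowSet, ParameterError

__all__ = [
    "SmoteParams",
    "GuidedWarpParams",
    "SpawnerParams",
    "smote",
    "random_guided_warp",
    "discriminative_guided_warp",
    "spawner",
    "warp_values_onto_reference",
]


@dataclass(frozen=True)
class SmoteParams:
    """Number of nearest same-class neighbours to interpolate toward."""

    k_neighbors: int = 5

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ParameterError(f"k_neighbors must be >= 1; got {self.k_neighbors}")


@dataclass(frozen=True)
class GuidedWarpParams:
    """Guided-warping variant and its discriminative-selection knobs."""

    variant: str = "rgw"
    bootstrap_size: int = 5
    descriptor: ShapeDescriptorParams = field(default_factory=ShapeDescriptorParams)

    def __post_init__(self) -> None:
        if self.variant not in ("rgw", "dgw"):
            raise ParameterError(f"variant must be 'rgw' or 'dgw'; got {self.variant!r}")
        if self.variant == "dgw" and self.bootstrap_size < 2:
            raise ParameterError("dgw bootstrap_size must be >= 2")


@dataclass(frozen=True)
class SpawnerParams:
    """Mixing weight mu in [0, 1] and additive noise sd sigma >= 0."""

    mu: float = 0.5
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu <= 1.0:
            raise ParameterError(f"mu must be in [0, 1]; got {self.mu}")
        if self.sigma < 0:
            raise ParameterError(f"sigma must be >= 0; got {self.sigma}")


def _check_window(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ParameterError(f"window must be 2-D (T, S); got shape {x.shape}")
    return x


def smote(
    x: np.ndarray,
    same_class_pool: LabeledWindowSet,
    params: SmoteParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Interpolate toward one of the k nearest same-class neighbours.

    Distances are Euclidean on flattened windows; the neighbour is drawn
    uniformly among the k nearest and the output is
    ``x + lambda * (x_nn - x)`` with ``lambda ~ U(0, 1)``, so every element
    lies between x and its neighbour.
    """
    x = _check_window(x)
    if same_class_pool.n_windows == 0:
        raise ParameterError("SMOTE needs a non-empty same-class pool")
    flat = same_class_pool.data.reshape(same_class_pool.n_windows, -1)
    dist = np.linalg.norm(flat - x.ravel(), axis=1)
    k = min(params.k_neighbors, len(dist))
    nearest = np.argsort(dist, kind="stable")[:k]
    neighbour = same_class_pool.data[int(rng.choice(nearest))]
    lam = rng.uniform(0.0, 1.0)
    return x + lam * (neighbour - x)


def warp_values_onto_reference(x: np.ndarray, reference: np.ndarray, path: WarpPath) -> np.ndarray:
    """Place x's values on the reference's time base along an alignment.

    For each reference index j, the x values aligned to j are averaged;
    the resulting length-``T_ref`` series is linearly resampled to x's
    length T.  A diagonal self-alignment reproduces x exactly.
    """
    x, reference = _check_window(x), _check_window(reference)
    t_ref = reference.shape[0]
    sums = np.zeros((t_ref, x.shape[1]))
    counts = np.zeros(t_ref)
    for i, j in path.pairs:
        sums[j] += x[i]
        counts[j] += 1
    values = sums / counts[:, None]
    t = x.shape[0]
    if t_ref == t:
        resampled = values
    else:
        src = np.linspace(0.0, 1.0, t_ref)
        dst = np.linspace(0.0, 1.0, t)
        resampled = np.column_stack(
            [np.interp(dst, src, values[:, j]) for j in range(values.shape[1])]
        )
    return resampled


def random_guided_warp(
    x: np.ndarray,
    same_class_pool: LabeledWindowSet,
    step: StepPattern = SYMMETRIC,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Warp x onto a uniformly drawn same-class reference via DTW."""
    x = _check_window(x)
    if same_class_pool.n_windows == 0:
        raise ParameterError("guided warping needs a non-empty same-class pool")
    if rng is None:
        rng = np.random.default_rng()
    reference = same_class_pool.data[int(rng.integers(0, same_class_pool.n_windows))]
    path = dtw(x, reference, step)
    return warp_values_onto_reference(x, reference, path)


def _teacher_scores(
    positives: np.ndarray,
    negatives: np.ndarray,
    step: StepPattern,
    desc: ShapeDescriptorParams,
) -> np.ndarray:
    """Discriminative score per positive candidate: mean ShapeDTW distance
    to the negatives minus mean ShapeDTW distance to the other positives."""
    n_pos = len(positives)
    scores = np.empty(n_pos)
    for p in range(n_pos):
        to_neg = np.mean([shape_dtw(positives[p], neg, step, desc).cost for neg in negatives])
        others = [q for q in range(n_pos) if q != p]
        to_pos = (
            np.mean([shape_dtw(positives[p], positives[q], step, desc).cost for q in others])
            if others
            else 0.0
        )
        scores[p] = to_neg - to_pos
    return scores


def discriminative_guided_warp(
    x: np.ndarray,
    label: int,
    train_pool: LabeledWindowSet,
    params: GuidedWarpParams,
    rng: np.random.Generator,
    step: StepPattern = SYMMETRIC,
) -> np.ndarray:
    """Warp x onto a discriminatively chosen teacher via ShapeDTW.

    A bootstrap subset of the training pool is drawn; candidates sharing
    x's label are scored by how far (in ShapeDTW cost) they sit from the
    subset's other-class windows relative to their own class, and the
    highest-scoring candidate becomes the teacher.  If the subset contains
    no other-class (or no same-class) window the method falls back to RGW
    on the full same-class pool, with a warning.
    """
    x = _check_window(x)
    n = train_pool.n_windows
    if n == 0:
        raise ParameterError("guided warping needs a non-empty training pool")
    size = min(params.bootstrap_size, n)
    subset = np.sort(rng.choice(n, size=size, replace=False))
    sub_labels = train_pool.labels[subset]
    pos_idx = subset[sub_labels == label]
    neg_idx = subset[sub_labels != label]
    if len(pos_idx) == 0 or len(neg_idx) == 0:
        warnings.warn(
            "DGW bootstrap subset lacks a positive or negative window; "
            "falling back to random guided warping",
            stacklevel=2,
        )
        pool = train_pool.subset(np.flatnonzero(train_pool.labels == label))
        return random_guided_warp(x, pool, step, rng)
    positives = train_pool.data[pos_idx]
    negatives = train_pool.data[neg_idx]
    scores = _teacher_scores(positives, negatives, step, params.descriptor)
    teacher = positives[int(np.argmax(scores))]  # ties -> lowest pool index
    path = shape_dtw(x, teacher, step, params.descriptor)
    return warp_values_onto_reference(x, teacher, path)


def spawner(
    x1: np.ndarray,
    x2: np.ndarray,
    params: SpawnerParams,
    rng: np.random.Generator,
    step: StepPattern = SYMMETRIC,
    label1: int | None = None,
    label2: int | None = None,
) -> np.ndarray:
    """Average two same-class windows along a suboptimal-DTW alignment.

    A matching point is drawn uniformly from the interior timesteps and the
    alignment is forced through it; the aligned sequences are mixed as
    ``mu * x1 + (1 - mu) * x2``, resampled back to length T, and Gaussian
    noise with sd ``sigma`` is added.  With identical inputs and
    ``sigma = 0`` the output equals the input.
    """
    x1, x2 = _check_window(x1), _check_window(x2)
    if x1.shape != x2.shape:
        raise ParameterError(f"SPAWNER needs equal shapes; got {x1.shape} vs {x2.shape}")
    if label1 is not None and label2 is not None and label1 != label2:
        raise ParameterError(f"SPAWNER partners must share a label; got {label1} vs {label2}")
    t = x1.shape[0]
    t_star = int(rng.integers(1, t - 1)) if t > 2 else 0
    path = suboptimal_dtw(x1, x2, step, forced=(t_star, t_star))
    aligned1 = x1[path.a_indices]
    aligned2 = x2[path.b_indices]
    mixed = params.mu * aligned1 + (1.0 - params.mu) * aligned2
    if mixed.shape[0] != t:
        src = np.linspace(0.0, 1.0, mixed.shape[0])
        dst = np.linspace(0.0, 1.0, t)
        mixed = np.column_stack(
            [np.interp(dst, src, mixed[:, j]) for j in range(mixed.shape[1])]
        )
    if params.sigma > 0:
        mixed = mixed + rng.normal(0.0, params.sigma, size=mixed.shape)
    return mixed
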