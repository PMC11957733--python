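"""The augmentation-method registry.

Maps each method name to its family, its published default parameters,
and an adapter with the uniform signature

    fn(x, label, train_set, source_index, params_dict, rng) -> window

so the strategy engine can drive every method the same way.  Random
transformations ignore the training set; pattern-mixing methods draw
references/partners from the same-class windows of the training set,
excluding the source window itself.  The conditional GAN is registered as
family ``"gm"`` and is handled by the engine (train once, then sample).

SMOTE is registered for completeness but excluded from the default
benchmark set: on raw sensor windows it tends to interpolate patterns
into implausible intermediate shapes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from . import pattern_mixing as pm
from . import rt_magnitude as rtm
from . import rt_time as rtt
from .core import LabeledWindowSet, ParameterError

__all__ = ["MethodSpec", "REGISTRY", "DEFAULT_BENCHMARK_METHODS", "get_method", "apply_method"]


@dataclass(frozen=True)
class MethodSpec:
    name: str
    family: str  # "rt" | "pm" | "gm"
    defaults: dict
    fn: Callable | None  # None for generative methods (engine-managed)


def _same_class_pool(train: LabeledWindowSet, label: int, exclude: int | None) -> LabeledWindowSet:
    idx = np.flatnonzero(train.labels == label)
    if exclude is not None:
        idx = idx[idx != exclude]
    if len(idx) == 0:
        raise ParameterError(f"no other window of class {label} available as reference")
    return train.subset(idx)


def _jitter(x, label, train, src, params, rng):
    return rtm.jitter(x, rtm.JitterParams(**params), rng)


def _rotation(x, label, train, src, params, rng):
    return rtm.rotate(x, rtm.RotationParams(**params), rng)


def _scaling(x, label, train, src, params, rng):
    return rtm.scale(x, rtm.ScalingParams(**params), rng)


def _magnitude_warp(x, label, train, src, params, rng):
    return rtm.magnitude_warp(x, rtm.MagnitudeWarpParams(**params), rng)


def _slicing(x, label, train, src, params, rng):
    return rtt.slice_resample(x, rtt.SliceParams(**params), rng)


def _permutation(x, label, train, src, params, rng):
    return rtt.permute(x, rtt.PermutationParams(**params), rng)


def _time_warp(x, label, train, src, params, rng):
    return rtt.time_warp(x, rtt.TimeWarpParams(**params), rng)


def _window_warp(x, label, train, src, params, rng):
    p = dict(params)
    if "factors" in p:
        p["factors"] = tuple(p["factors"])
    return rtt.window_warp(x, rtt.WindowWarpParams(**p), rng)


def _rgw(x, label, train, src, params, rng):
    pool = _same_class_pool(train, label, src)
    return pm.random_guided_warp(x, pool, rng=rng)


def _dgw(x, label, train, src, params, rng):
    gwp = pm.GuidedWarpParams(variant="dgw", **params)
    return pm.discriminative_guided_warp(x, label, train, gwp, rng)


def _spawner(x, label, train, src, params, rng):
    pool = _same_class_pool(train, label, src)
    partner = pool.data[int(rng.integers(0, pool.n_windows))]
    return pm.spawner(x, partner, pm.SpawnerParams(**params), rng)


def _smote(x, label, train, src, params, rng):
    pool = _same_class_pool(train, label, src)
    return pm.smote(x, pool, pm.SmoteParams(**params), rng)


#: All registered methods with their published default parameters.
REGISTRY: dict[str, MethodSpec] = {
    "jitter": MethodSpec("jitter", "rt", {"mu": 0.0, "sigma": 0.03}, _jitter),
    "rotation": MethodSpec("rotation", "rt", {}, _rotation),
    "scaling": MethodSpec("scaling", "rt", {"alpha": 0.1}, _scaling),
    "magnitude_warp": MethodSpec(
        "magnitude_warp", "rt", {"knots": 4, "mu": 1.0, "sigma": 0.2}, _magnitude_warp
    ),
    "slicing": MethodSpec("slicing", "rt", {"keep_fraction": 0.9}, _slicing),
    "time_warp": MethodSpec(
        "time_warp", "rt", {"knots": 4, "mu": 1.0, "sigma": 0.2}, _time_warp
    ),
    "window_warp": MethodSpec(
        "window_warp", "rt", {"window_fraction": 0.1, "factors": (0.5, 2.0)}, _window_warp
    ),
    "permutation": MethodSpec("permutation", "rt", {"n_segments": 5}, _permutation),
    "rgw": MethodSpec("rgw", "pm", {}, _rgw),
    "dgw": MethodSpec("dgw", "pm", {"bootstrap_size": 5}, _dgw),
    "spawner": MethodSpec("spawner", "pm", {"mu": 0.5, "sigma": 0.0}, _spawner),
    "smote": MethodSpec("smote", "pm", {"k_neighbors": 5}, _smote),
    "cgan": MethodSpec("cgan", "gm", {}, None),
}

#: The benchmark set: every registered method except SMOTE and the cGAN
#: (the cGAN joins benchmarks explicitly; it needs a training pass).
DEFAULT_BENCHMARK_METHODS: tuple[str, ...] = (
    "jitter",
    "rotation",
    "scaling",
    "magnitude_warp",
    "slicing",
    "time_warp",
    "window_warp",
    "permutation",
    "rgw",
    "dgw",
    "spawner",
)


def get_method(name: str) -> MethodSpec:
    try:
        return REGISTRY[name]
    except KeyError:
        raise ParameterError(
            f"unknown method {name!r}; registered: {sorted(REGISTRY)}"
        ) from None


def apply_method(
    name: str,
    x: np.ndarray,
    label: int,
    train: LabeledWindowSet,
    source_index: int | None,
    rng: np.random.Generator,
    params: dict | None = None,
) -> np.ndarray:
    """Augment one window by a registered (non-generative) method."""
    spec = get_method(name)
    if spec.fn is None:
        raise ParameterError(f"method {name!r} is generative; use the strategy engine")
    merged = {**spec.defaults, **(params or {})}
    return spec.fn(x, label, train, source_index, merged, rng)
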