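"""Augmentation strategy engine and benchmarking harness.

The augmentation factor ``n`` fixes how many synthetic windows are added:

* **balanced** mode adds ``round(n * m)`` windows, ``m`` the training-set
  size, drawing source windows uniformly with replacement across classes;
* **imbalanced** mode augments only the non-majority classes, each by
  factor ``n`` of its own count, capped so that no class ever exceeds the
  majority count.  The largest useful integer factor is
  ``n_max = floor(N_majority / N_minority)``.

The benchmark harness sweeps (method, factor) cells over a
cross-validation scheme, augments the training portion only, evaluates on
untouched real windows, and aggregates macro-F1 over folds and repeats.
Classifiers are pluggable through a fit/predict contract; two cheap
reference classifiers (nearest centroid on flattened windows, 1-NN under
DTW distance) are shipped so the harness runs at desk scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .alignment import dtw
from .core import (
    PROVENANCE_ORIGINAL,
    PROVENANCE_SYNTHETIC,
    LabeledWindowSet,
    ParameterError,
    RandomStream,
)
from .generative import CganConfig, generate as cgan_generate, train_cgan
from .registry import DEFAULT_BENCHMARK_METHODS, apply_method, get_method
from .stats import MetricReport, classification_metrics

__all__ = [
    "AugmentationPlan",
    "FactorGrid",
    "FoldScheme",
    "BenchmarkResult",
    "NearestCentroidClassifier",
    "OneNNDtwClassifier",
    "round_half_away",
    "compute_nmax",
    "augment_balanced",
    "augment_imbalanced",
    "augment",
    "run_benchmark",
]


def round_half_away(value: float) -> int:
    """Round half away from zero (so n=0.5, m=1 adds one window, not zero)."""
    return int(math.floor(abs(value) + 0.5)) * (1 if value >= 0 else -1)


@dataclass(frozen=True)
class AugmentationPlan:
    """Method + parameters + factor n + balanced/imbalanced mode + seed."""

    method: str
    factor: float
    mode: str = "balanced"
    params: dict = field(default_factory=dict)
    seed: int = 0
    cgan_config: CganConfig | None = None

    def __post_init__(self) -> None:
        get_method(self.method)  # raises on unknown method
        if self.factor <= 0:
            raise ParameterError(f"factor must be > 0; got {self.factor}")
        if self.mode not in ("balanced", "imbalanced"):
            raise ParameterError(f"mode must be balanced|imbalanced; got {self.mode!r}")


@dataclass(frozen=True)
class FactorGrid:
    """Grid of augmentation factors, optionally capped for imbalanced data."""

    factors: tuple[float, ...]
    mode: str = "balanced"

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.factors):
            raise ParameterError("all factors must be > 0")

    @classmethod
    def balanced_default(cls) -> "FactorGrid":
        return cls((0.2, 0.4, 0.6, 0.8, 1.0, 2.0, 3.0, 4.0), "balanced")

    @classmethod
    def imbalanced_default(cls, n_max: int) -> "FactorGrid":
        """Fractional factors up to 1, then integers 2..n_max."""
        fractional = (0.2, 0.4, 0.6, 0.8, 1.0)
        integers = tuple(float(v) for v in range(2, n_max + 1))
        return cls(fractional + integers, "imbalanced")


def compute_nmax(class_counts: dict[int, int] | Sequence[int]) -> int:
    """Largest integer n with ``n * N_minority <= N_majority``."""
    counts = list(class_counts.values()) if isinstance(class_counts, dict) else list(class_counts)
    if len(counts) < 2:
        raise ParameterError("need at least 2 classes")
    if min(counts) <= 0:
        raise ParameterError("every class must have a positive count")
    return max(counts) // min(counts)


# -- augmentation ------------------------------------------------------------


def _synthesize(
    train: LabeledWindowSet,
    source_indices: np.ndarray,
    plan: AugmentationPlan,
    stream: RandomStream,
) -> LabeledWindowSet:
    """One synthetic window per source index, labels copied from sources."""
    if get_method(plan.method).family == "gm":
        cfg = plan.cgan_config or CganConfig(seed=plan.seed)
        gen = train_cgan(train, cfg)
        return cgan_generate(
            gen, train.labels[source_indices], stream.substream(plan.method, "cgan-generate")
        )
    windows = np.empty((len(source_indices), train.n_timesteps, train.n_channels))
    for row, src in enumerate(source_indices):
        src = int(src)
        rng = stream.substream(plan.method, row)
        windows[row] = apply_method(
            plan.method, train.data[src], int(train.labels[src]), train, src, rng, plan.params
        )
    return LabeledWindowSet(
        data=windows,
        labels=train.labels[source_indices],
        provenance=np.full(len(source_indices), PROVENANCE_SYNTHETIC, dtype=np.uint8),
    )


def augment_balanced(train: LabeledWindowSet, plan: AugmentationPlan) -> LabeledWindowSet:
    """Add ``round(n * m)`` synthetic windows from uniformly drawn sources."""
    stream = RandomStream(plan.seed)
    m = train.n_windows
    n_syn = round_half_away(plan.factor * m)
    sources = stream.substream("sources").integers(0, m, size=n_syn)
    synthetic = _synthesize(train, sources, plan, stream)
    return LabeledWindowSet.concatenate([train, synthetic])


def augment_imbalanced(train: LabeledWindowSet, plan: AugmentationPlan) -> LabeledWindowSet:
    """Augment every non-majority class by factor n of its own count.

    The synthetic count per class is capped so no class exceeds the
    majority count after augmentation; the majority class is untouched.
    """
    counts = train.class_counts()
    if len(counts) < 2:
        raise ParameterError("imbalanced augmentation needs >= 2 classes")
    majority_label = max(counts, key=lambda k: (counts[k], -k))
    majority_count = counts[majority_label]
    stream = RandomStream(plan.seed)
    sources: list[np.ndarray] = []
    for label, count in sorted(counts.items()):
        if label == majority_label:
            continue
        n_syn = min(round_half_away(plan.factor * count), majority_count - count)
        if n_syn <= 0:
            continue
        class_idx = np.flatnonzero(train.labels == label)
        rng = stream.substream("sources", label)
        sources.append(class_idx[rng.integers(0, len(class_idx), size=n_syn)])
    if not sources:
        return LabeledWindowSet.concatenate([train])
    synthetic = _synthesize(train, np.concatenate(sources), plan, stream)
    return LabeledWindowSet.concatenate([train, synthetic])


def augment(train: LabeledWindowSet, plan: AugmentationPlan) -> LabeledWindowSet:
    """Dispatch on the plan's balanced/imbalanced mode."""
    if plan.mode == "balanced":
        return augment_balanced(train, plan)
    return augment_imbalanced(train, plan)


# -- cross-validation schemes ------------------------------------------------


@dataclass(frozen=True)
class FoldScheme:
    """Cross-validation scheme: fixed split, stratified k-fold, or LOSO."""

    kind: str = "stratified_kfold"
    k: int = 5
    test_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.kind not in ("fixed_split", "stratified_kfold", "loso"):
            raise ParameterError(f"unknown scheme kind {self.kind!r}")
        if self.kind == "stratified_kfold" and self.k < 2:
            raise ParameterError("stratified k-fold needs k >= 2")

    def folds(
        self, data: LabeledWindowSet, seed: int
    ) -> Iterator[tuple[np.ndarray, np.ndarray]]:
        indices = np.arange(data.n_windows)
        if self.kind == "fixed_split":
            train_idx, test_idx = train_test_split(
                indices,
                test_size=self.test_fraction,
                random_state=seed,
                stratify=data.labels,
            )
            yield np.sort(train_idx), np.sort(test_idx)
        elif self.kind == "stratified_kfold":
            splitter = StratifiedKFold(n_splits=self.k, shuffle=True, random_state=seed)
            for train_idx, test_idx in splitter.split(indices, data.labels):
                yield train_idx, test_idx
        else:  # loso: every subject is a test fold exactly once
            if data.groups is None:
                raise ParameterError("LOSO requires subject groups")
            for subject in np.unique(data.groups):
                mask = data.groups == subject
                yield indices[~mask], indices[mask]


# -- reference classifiers ---------------------------------------------------


class NearestCentroidClassifier:
    """Nearest class centroid on flattened windows (deterministic)."""

    def fit(self, train: LabeledWindowSet) -> "NearestCentroidClassifier":
        flat = train.data.reshape(train.n_windows, -1)
        self.classes_ = np.unique(train.labels)
        self.centroids_ = np.stack(
            [flat[train.labels == k].mean(axis=0) for k in self.classes_]
        )
        return self

    def predict(self, data: np.ndarray) -> np.ndarray:
        flat = data.reshape(data.shape[0], -1)
        dist = np.linalg.norm(flat[:, None, :] - self.centroids_[None, :, :], axis=2)
        return self.classes_[np.argmin(dist, axis=1)]


class OneNNDtwClassifier:
    """1-nearest-neighbour under DTW alignment cost (quadratic; keep small)."""

    def fit(self, train: LabeledWindowSet) -> "OneNNDtwClassifier":
        self.train_ = train
        return self

    def predict(self, data: np.ndarray) -> np.ndarray:
        out = np.empty(data.shape[0], dtype=np.int64)
        for i, window in enumerate(data):
            costs = [dtw(window, ref).cost for ref in self.train_.data]
            out[i] = self.train_.labels[int(np.argmin(costs))]
        return out


# -- benchmark harness -------------------------------------------------------


@dataclass
class BenchmarkResult:
    """Per-cell metric table with tidy accessors.

    ``table`` has one row per (method, factor, repeat, fold) plus the
    unaugmented baseline rows (method "baseline", factor 0), with columns
    accuracy, af1, per-class F1 (JSON), and a status flag ("ok"/"failed").
    """

    table: pd.DataFrame

    def mean_af1(self) -> pd.DataFrame:
        ok = self.table[self.table["status"] == "ok"]
        return ok.pivot_table(index="method", columns="factor", values="af1", aggfunc="mean")

    def baseline_af1(self) -> float:
        rows = self.table[(self.table["method"] == "baseline") & (self.table["status"] == "ok")]
        return float(rows["af1"].mean())

    def best_af1(self) -> pd.Series:
        """Best mean AF1 over factors, per method."""
        return self.mean_af1().max(axis=1)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False)
        return path


def run_benchmark(
    data: LabeledWindowSet,
    methods: Sequence[str] = DEFAULT_BENCHMARK_METHODS,
    grid: FactorGrid | None = None,
    scheme: FoldScheme | None = None,
    classifier_factory: Callable[[], object] = NearestCentroidClassifier,
    repeats: int = 5,
    seed: int = 0,
    method_params: dict[str, dict] | None = None,
    cgan_config: CganConfig | None = None,
) -> BenchmarkResult:
    """Sweep (method, factor) cells over repeated cross-validation.

    For every fold, only the training portion is augmented; evaluation is
    always on untouched real windows (synthetic windows never enter a test
    fold).  A cell whose augmentation or fit raises is marked failed and
    the sweep continues.  Default ``repeats=5`` mirrors common repeated
    five-fold practice.
    """
    grid = grid or FactorGrid.balanced_default()
    scheme = scheme or FoldScheme()
    method_params = method_params or {}
    stream = RandomStream(seed)
    rows = []

    for repeat in range(repeats):
        fold_seed = int(stream.substream("folds", repeat).integers(0, 2**31 - 1))
        for fold, (train_idx, test_idx) in enumerate(scheme.folds(data, fold_seed)):
            train = data.subset(train_idx)
            test = data.subset(test_idx)
            assert np.all(test.provenance == PROVENANCE_ORIGINAL), "synthetic test window"

            def evaluate(train_set: LabeledWindowSet) -> MetricReport:
                clf = classifier_factory()
                clf.fit(train_set)
                predictions = clf.predict(test.data)
                return classification_metrics(test.labels, predictions, c=data.n_classes)

            base = evaluate(train)
            rows.append(_row("baseline", 0.0, repeat, fold, base, "ok"))

            for method in methods:
                for factor in grid.factors:
                    plan = AugmentationPlan(
                        method=method,
                        factor=factor,
                        mode=grid.mode,
                        params=method_params.get(method, {}),
                        seed=int(
                            stream.substream("plan", repeat, fold, method).integers(0, 2**31 - 1)
                        ),
                        cgan_config=cgan_config,
                    )
                    try:
                        augmented = augment(train, plan)
                        report = evaluate(augmented)
                    except Exception:
                        rows.append(_row(method, factor, repeat, fold, None, "failed"))
                        continue
                    rows.append(_row(method, factor, repeat, fold, report, "ok"))

    return BenchmarkResult(table=pd.DataFrame(rows))


def _row(method, factor, repeat, fold, report: MetricReport | None, status: str) -> dict:
    return {
        "method": method,
        "factor": factor,
        "repeat": repeat,
        "fold": fold,
        "accuracy": report.accuracy if report else np.nan,
        "af1": report.af1 if report else np.nan,
        "per_class_f1": json.dumps(report.f1.tolist()) if report else "[]",
        "status": status,
    }
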