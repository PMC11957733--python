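"""Core containers, deterministic randomness, and window-set I/O.

The universal currency of the package is the :class:`LabeledWindowSet`: a
dense tensor of ``N`` pre-segmented sensor windows, each ``T`` timesteps by
``S`` channels, with an integer class label per window, optional subject
(group) IDs for subject-wise cross-validation, and a provenance flag that
distinguishes original recordings from synthetic windows produced by an
augmenter.

Windows are pre-segmented by the caller; the toolkit never re-windows.
Internally all time indices are 0-based with half-open slices.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PROVENANCE_ORIGINAL",
    "PROVENANCE_SYNTHETIC",
    "WindowSetError",
    "ParameterError",
    "LabeledWindowSet",
    "RandomStream",
    "read_window_set",
    "write_window_set",
]

PROVENANCE_ORIGINAL: int = 0
PROVENANCE_SYNTHETIC: int = 1

#: Column order of the long-format CSV carrier.
CSV_COLUMNS = ("window_id", "time_index", "channel", "value", "label", "group")


class WindowSetError(ValueError):
    """Raised when a window set (or a file claiming to be one) is invalid."""


class ParameterError(ValueError):
    """Raised when an augmenter receives out-of-range parameters."""


@dataclass
class LabeledWindowSet:
    """Labeled, windowed, multichannel time-series data.

    Parameters
    ----------
    data
        Real tensor of shape ``(N, T, S)``; arbitrary sensor units.
    labels
        Integer class index per window, each in ``0..c-1``.
    groups
        Optional integer subject ID per window (length ``N``).
    provenance
        Per-window flag, ``PROVENANCE_ORIGINAL`` or ``PROVENANCE_SYNTHETIC``.
        Defaults to all-original.
    """

    data: np.ndarray
    labels: np.ndarray
    groups: np.ndarray | None = None
    provenance: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.groups is not None:
            self.groups = np.asarray(self.groups, dtype=np.int64)
        if self.provenance is None:
            self.provenance = np.full(len(self.labels), PROVENANCE_ORIGINAL, dtype=np.uint8)
        else:
            self.provenance = np.asarray(self.provenance, dtype=np.uint8)
        self.validate()

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        if self.data.ndim != 3:
            raise WindowSetError(f"data must be (N, T, S); got shape {self.data.shape}")
        n, t, s = self.data.shape
        if t < 2 or s < 1:
            raise WindowSetError(f"need T >= 2 and S >= 1; got T={t}, S={s}")
        if not np.all(np.isfinite(self.data)):
            raise WindowSetError("data contains non-finite values")
        if self.labels.shape != (n,):
            raise WindowSetError(f"labels must have length N={n}; got {self.labels.shape}")
        if n and self.labels.min() < 0:
            raise WindowSetError("labels must be non-negative class indices")
        if self.groups is not None and self.groups.shape != (n,):
            raise WindowSetError(f"groups must have length N={n}; got {self.groups.shape}")
        if self.provenance.shape != (n,):
            raise WindowSetError(f"provenance must have length N={n}")

    # -- basic descriptors --------------------------------------------------

    @property
    def n_windows(self) -> int:
        return self.data.shape[0]

    @property
    def n_timesteps(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    @property
    def n_classes(self) -> int:
        """Class count ``c``; labels are assumed to span ``0..c-1``."""
        return int(self.labels.max()) + 1 if self.n_windows else 0

    def class_counts(self) -> dict[int, int]:
        values, counts = np.unique(self.labels, return_counts=True)
        return {int(v): int(c) for v, c in zip(values, counts)}

    def __len__(self) -> int:
        return self.n_windows

    # -- assembly -----------------------------------------------------------

    def subset(self, index: Sequence[int] | np.ndarray) -> "LabeledWindowSet":
        index = np.asarray(index)
        return LabeledWindowSet(
            data=self.data[index],
            labels=self.labels[index],
            groups=None if self.groups is None else self.groups[index],
            provenance=self.provenance[index],
        )

    @staticmethod
    def concatenate(sets: Iterable["LabeledWindowSet"]) -> "LabeledWindowSet":
        sets = list(sets)
        if not sets:
            raise WindowSetError("cannot concatenate zero window sets")
        shapes = {(s.n_timesteps, s.n_channels) for s in sets}
        if len(shapes) != 1:
            raise WindowSetError(f"incompatible (T, S) shapes: {sorted(shapes)}")
        groups = None
        if all(s.groups is not None for s in sets):
            groups = np.concatenate([s.groups for s in sets])
        return LabeledWindowSet(
            data=np.concatenate([s.data for s in sets]),
            labels=np.concatenate([s.labels for s in sets]),
            groups=groups,
            provenance=np.concatenate([s.provenance for s in sets]),
        )

    def equals(self, other: "LabeledWindowSet") -> bool:
        same_groups = (self.groups is None) == (other.groups is None) and (
            self.groups is None or np.array_equal(self.groups, other.groups)
        )
        return (
            np.array_equal(self.data, other.data)
            and np.array_equal(self.labels, other.labels)
            and np.array_equal(self.provenance, other.provenance)
            and same_groups
        )


class RandomStream:
    """Seeded random-number source with derivable, independent substreams.

    A single integer seed reproduces every draw in the toolkit bit-for-bit.
    Substreams are keyed by arbitrary strings/ints (e.g. method name and
    window index) through a :class:`numpy.random.SeedSequence` spawn key, so
    augmenting window 7 never perturbs the noise drawn for window 8.
    """

    def __init__(self, seed: int):
        self.seed = int(seed)
        self._root = np.random.default_rng(np.random.SeedSequence(self.seed))

    @property
    def rng(self) -> np.random.Generator:
        """The root generator (stateful; use substreams for per-item draws)."""
        return self._root

    def substream(self, *keys: int | str) -> np.random.Generator:
        """A fresh generator deterministically derived from ``(seed, *keys)``."""
        spawn_key = tuple(
            zlib.crc32(k.encode()) if isinstance(k, str) else int(k) & 0xFFFFFFFF
            for k in keys
        )
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=spawn_key))


# ---------------------------------------------------------------------------
# File I/O.  NPZ is the canonical binary carrier; the CSV dialect is fixed
# (comma separator, header row, UTF-8, long format).
# ---------------------------------------------------------------------------


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".npz":
        return "npz"
    if suffix == ".csv":
        return "csv"
    raise WindowSetError(f"cannot infer format from {path.name!r}; pass format=")


def write_window_set(window_set: LabeledWindowSet, path: str | Path, format: str | None = None) -> Path:
    """Write a window set to ``path`` as NPZ or long-format CSV.

    The round trip ``read_window_set(write_window_set(x))`` reproduces ``x``
    exactly for both carriers (CSV serialises floats at full precision).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "npz":
        arrays = {
            "data": window_set.data,
            "labels": window_set.labels,
            "provenance": window_set.provenance,
        }
        if window_set.groups is not None:
            arrays["groups"] = window_set.groups
        np.savez(path, **arrays)
    elif fmt == "csv":
        if window_set.n_windows == 0:
            raise WindowSetError("empty sets cannot be carried by CSV; use NPZ")
        n, t, s = window_set.data.shape
        win = np.repeat(np.arange(n), t * s)
        time = np.tile(np.repeat(np.arange(t), s), n)
        chan = np.tile(np.arange(s), n * t)
        frame = pd.DataFrame(
            {
                "window_id": win,
                "time_index": time,
                "channel": chan,
                "value": window_set.data.ravel(),
                "label": np.repeat(window_set.labels, t * s),
                "group": np.repeat(
                    window_set.groups if window_set.groups is not None else np.full(n, -1),
                    t * s,
                ),
                "provenance": np.repeat(window_set.provenance, t * s),
            }
        )
        frame.to_csv(path, index=False)
    else:
        raise WindowSetError(f"unknown format {fmt!r}")
    return path


def read_window_set(path: str | Path, format: str | None = None) -> LabeledWindowSet:
    """Read a window set from an NPZ bundle or a long-format CSV file.

    CSV windows must be dense: every ``(time_index, channel)`` pair in
    ``[0, T) x [0, S)`` present exactly once per window, with one consistent
    ``T`` across windows.  Ragged or gappy windows raise a
    :class:`WindowSetError` naming the offending ``window_id``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "npz":
        with np.load(path) as bundle:
            return LabeledWindowSet(
                data=bundle["data"],
                labels=bundle["labels"],
                groups=bundle["groups"] if "groups" in bundle.files else None,
                provenance=bundle["provenance"] if "provenance" in bundle.files else None,
            )
    if fmt != "csv":
        raise WindowSetError(f"unknown format {fmt!r}")

    frame = pd.read_csv(path, float_precision="round_trip")
    missing = set(CSV_COLUMNS[:5]) - set(frame.columns)
    if missing:
        raise WindowSetError(f"CSV missing required columns: {sorted(missing)}")
    if frame.empty:
        raise WindowSetError("CSV contains no rows")
    if frame["value"].isna().any():
        raise WindowSetError("CSV contains NaN values")

    window_ids = frame["window_id"].unique()
    channels = np.sort(frame["channel"].unique())
    s = len(channels)
    t = int(frame["time_index"].max()) + 1

    data = np.empty((len(window_ids), t, s), dtype=float)
    labels = np.empty(len(window_ids), dtype=np.int64)
    groups = np.empty(len(window_ids), dtype=np.int64)
    provenance = np.zeros(len(window_ids), dtype=np.uint8)
    has_prov = "provenance" in frame.columns
    has_group = "group" in frame.columns

    for row, (wid, block) in enumerate(frame.groupby("window_id", sort=True)):
        expected = t * s
        if len(block) != expected:
            raise WindowSetError(
                f"window_id {wid}: expected {expected} rows (T={t} x S={s}), got {len(block)}"
            )
        pivot = block.pivot(index="time_index", columns="channel", values="value")
        if pivot.shape != (t, s) or not np.array_equal(pivot.index.to_numpy(), np.arange(t)):
            raise WindowSetError(f"window_id {wid}: time indices are not dense 0..{t - 1}")
        data[row] = pivot.to_numpy()
        labels[row] = block["label"].iloc[0]
        groups[row] = block["group"].iloc[0] if has_group else -1
        if has_prov:
            provenance[row] = block["provenance"].iloc[0]

    return LabeledWindowSet(
        data=data,
        labels=labels,
        groups=None if (not has_group or np.all(groups == -1)) else groups,
        provenance=provenance,
    )
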