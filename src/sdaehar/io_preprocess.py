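"""Loading, windowing and scaling of raw multi-sensor recordings.

A recording is a set of per-sensor time-series matrices sharing one clock and
carrying a single activity label.  The pipeline cuts each recording into
fixed-length sliding windows, flattens every window to a row vector (one row
per window, ``w * n_axes`` columns), pools windows across recordings and
min-max scales each column with extrema learned from the *training* partition
only.  Test data is scaled with the training extrema and may leave [0, 1];
it is deliberately not clipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

__all__ = [
    "SensorSpec",
    "RawRecording",
    "WindowConfig",
    "ScalerParams",
    "SampleMatrix",
    "SchemaError",
    "FormatError",
    "axis_names",
    "load_recording",
    "load_uci_har",
    "segment_windows",
    "flatten_windows",
    "unflatten_windows",
    "windows_to_samples",
    "fit_minmax",
    "apply_minmax",
    "split_train_test",
    "save_samples",
    "load_samples",
]


class SchemaError(ValueError):
    """A file's columns do not match the declared sensor schema."""


class FormatError(ValueError):
    """A file is structurally malformed (ragged rows, non-numeric cells)."""


@dataclass(frozen=True)
class SensorSpec:
    """One physical sensor: a short name, its axis count and sampling rate."""

    name: str
    n_axes: int
    sampling_rate: float

    def __post_init__(self) -> None:
        if self.n_axes < 1:
            raise ValueError(f"n_axes must be >= 1, got {self.n_axes}")
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")

    @property
    def columns(self) -> list[str]:
        return [f"{self.name}_{a}" for a in axis_names(self.n_axes)]


def axis_names(n_axes: int) -> list[str]:
    """Column suffixes for an ``n_axes``-axis sensor: x, y, z then a3, a4, ..."""
    letters = ["x", "y", "z"]
    return [letters[i] if i < 3 else f"a{i}" for i in range(n_axes)]


@dataclass
class RawRecording:
    """Aligned per-sensor sample matrices of shape (T, n_axes) with one label."""

    data: dict[str, np.ndarray]
    label: str
    subject_id: str | None = None

    def __post_init__(self) -> None:
        lengths = {k: v.shape[0] for k, v in self.data.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"sensor matrices differ in length: {lengths}")
        for k, v in self.data.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"sensor {k!r} contains non-finite values")

    @property
    def n_samples(self) -> int:
        return next(iter(self.data.values())).shape[0]


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window geometry: length ``window_len`` and stride, in samples."""

    window_len: int
    stride: int

    def __post_init__(self) -> None:
        if not 1 <= self.stride <= self.window_len:
            raise ValueError(
                f"require 1 <= stride <= window_len, got stride={self.stride}, "
                f"window_len={self.window_len}"
            )


@dataclass
class ScalerParams:
    """Per-column training extrema, one (min, max) array pair per sensor."""

    col_min: dict[str, np.ndarray]
    col_max: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for k in self.col_min:
            if np.any(self.col_max[k] < self.col_min[k]):
                raise ValueError(f"sensor {k!r}: max < min in scaler params")


@dataclass
class SampleMatrix:
    """Flattened windowed samples: per-sensor (N, w*n_axes) matrices + labels."""

    data: dict[str, np.ndarray]
    labels: np.ndarray
    schema: Sequence[SensorSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        rows = {k: v.shape[0] for k, v in self.data.items()}
        if len(set(rows.values())) > 1:
            raise ValueError(f"row counts differ across sensors: {rows}")
        n = next(iter(rows.values())) if rows else 0
        if len(self.labels) != n:
            raise ValueError(f"{len(self.labels)} labels for {n} rows")

    @property
    def n_samples(self) -> int:
        return len(self.labels)

    def stacked(self) -> np.ndarray:
        """All sensors concatenated column-wise, in schema (or dict) order."""
        order = [s.name for s in self.schema] if self.schema else list(self.data)
        return np.hstack([self.data[name] for name in order])


def load_recording(
    path: str | Path, schema: Sequence[SensorSpec], label_column: str = "label"
) -> RawRecording:
    """Read one CSV recording (one row per timestamp, ``<sensor>_<axis>`` columns).

    The file must contain every column implied by ``schema`` plus a label
    column holding a single activity class for the whole recording.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # ragged rows and friends
        raise FormatError(f"{path}: {exc}") from exc
    missing = [c for s in schema for c in s.columns if c not in df.columns]
    if label_column not in df.columns:
        missing.append(label_column)
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    labels = df[label_column].unique()
    if len(labels) != 1:
        raise FormatError(f"{path}: expected one label per recording, got {labels}")
    data = {}
    for s in schema:
        mat = df[s.columns].to_numpy(dtype=float)
        if not np.all(np.isfinite(mat)):
            raise FormatError(f"{path}: non-finite values in sensor {s.name!r}")
        data[s.name] = mat
    return RawRecording(data=data, label=str(labels[0]), subject_id=None)


#: The nine fixed-width signal files of the public smartphone HAR layout.
_UCI_SIGNALS = [
    ("total_acc", ["x", "y", "z"]),
    ("body_acc", ["x", "y", "z"]),
    ("body_gyro", ["x", "y", "z"]),
]


def load_uci_har(root: str | Path, split: str = "train") -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Read one split of the public smartphone activity dataset layout.

    Expects ``<root>/<split>/Inertial Signals/<signal>_<axis>_<split>.txt``
    (whitespace-delimited, 128 columns: pre-cut windows) and
    ``<root>/<split>/y_<split>.txt`` (1-based integer classes).

    Returns ``(windows, labels)`` where ``windows`` maps each of the three
    sensor groups to an (N, 128, 3) tensor.
    """
    root = Path(root)
    sig_dir = root / split / "Inertial Signals"
    windows: dict[str, np.ndarray] = {}
    for sensor, axes in _UCI_SIGNALS:
        mats = []
        for ax in axes:
            f = sig_dir / f"{sensor}_{ax}_{split}.txt"
            if not f.exists():
                raise SchemaError(f"missing signal file {f}")
            mats.append(np.loadtxt(f))
        tensor = np.stack([np.atleast_2d(m) for m in mats], axis=2)
        windows[sensor] = tensor
    labels = np.loadtxt(root / split / f"y_{split}.txt", dtype=int)
    labels = np.atleast_1d(labels)
    n = {k: v.shape[0] for k, v in windows.items()}
    if len(set(n.values())) > 1 or next(iter(n.values())) != len(labels):
        raise FormatError(f"row-count mismatch across signal files/labels: {n}, {len(labels)}")
    return windows, labels


def segment_windows(rec: RawRecording, cfg: WindowConfig) -> dict[str, np.ndarray]:
    """Cut one recording into sliding windows per sensor.

    Windows start at 0 and advance by ``stride``; a window is emitted iff it
    fits entirely (start + window_len <= T), giving floor((T-w)/s) + 1
    windows.  Returns sensor name -> (n_windows, w, n_axes) tensor.
    """
    w, s = cfg.window_len, cfg.stride
    T = rec.n_samples
    if T < w:
        warnings.warn(
            f"recording of length {T} shorter than window {w}; no windows emitted",
            stacklevel=2,
        )
        return {k: np.empty((0, w, v.shape[1])) for k, v in rec.data.items()}
    starts = range(0, T - w + 1, s)
    return {
        k: np.stack([v[st : st + w] for st in starts], axis=0)
        for k, v in rec.data.items()
    }


def flatten_windows(windows: np.ndarray) -> np.ndarray:
    """Flatten an (N, w, d) window tensor to (N, w*d) row-major."""
    if windows.ndim != 3:
        raise ValueError(f"expected (N, w, d) tensor, got shape {windows.shape}")
    n = windows.shape[0]
    return windows.reshape(n, -1)


def unflatten_windows(flat: np.ndarray, window_len: int, n_axes: int) -> np.ndarray:
    """Inverse of :func:`flatten_windows`."""
    return flat.reshape(flat.shape[0], window_len, n_axes)


def windows_to_samples(
    recordings: Sequence[RawRecording],
    cfg: WindowConfig,
    schema: Sequence[SensorSpec],
) -> SampleMatrix:
    """Segment every recording, flatten, and pool into one SampleMatrix.

    Windows never span two recordings; each window inherits its recording's
    label.
    """
    per_sensor: dict[str, list[np.ndarray]] = {s.name: [] for s in schema}
    labels: list[str] = []
    for rec in recordings:
        wins = segment_windows(rec, cfg)
        n = next(iter(wins.values())).shape[0]
        for s in schema:
            per_sensor[s.name].append(flatten_windows(wins[s.name]))
        labels.extend([rec.label] * n)
    data = {
        name: np.vstack(mats) if mats else np.empty((0, cfg.window_len))
        for name, mats in per_sensor.items()
    }
    return SampleMatrix(data=data, labels=np.asarray(labels), schema=list(schema))


def fit_minmax(train: SampleMatrix) -> ScalerParams:
    """Learn per-column extrema from the training samples only."""
    if train.n_samples < 1:
        raise ValueError("cannot fit scaler on an empty sample matrix")
    return ScalerParams(
        col_min={k: v.min(axis=0) for k, v in train.data.items()},
        col_max={k: v.max(axis=0) for k, v in train.data.items()},
    )


def apply_minmax(x: SampleMatrix, p: ScalerParams) -> SampleMatrix:
    """Scale each column to (v - min) / (max - min) using the stored extrema.

    Training data maps into [0, 1]; unseen data may fall outside and is kept
    as-is.  Columns that were constant in training map to 0.
    """
    out = {}
    for k, v in x.data.items():
        lo, hi = p.col_min[k], p.col_max[k]
        if v.shape[1] != lo.shape[0]:
            raise ValueError(
                f"sensor {k!r}: {v.shape[1]} columns vs scaler of width {lo.shape[0]}"
            )
        span = hi - lo
        safe = np.where(span == 0, 1.0, span)
        scaled = (v - lo) / safe
        out[k] = np.where(span == 0, 0.0, scaled)
    return SampleMatrix(data=out, labels=x.labels.copy(), schema=list(x.schema))


def split_train_test(
    samples: SampleMatrix, test_fraction: float = 0.3, seed: int = 0
) -> tuple[SampleMatrix, SampleMatrix]:
    """Stratified random train/test partition of the pooled windows."""
    if not 0 < test_fraction < 1:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    idx = np.arange(samples.n_samples)
    tr, te = train_test_split(
        idx,
        test_size=test_fraction,
        random_state=seed,
        stratify=samples.labels,
        shuffle=True,
    )

    def take(ix: np.ndarray) -> SampleMatrix:
        return SampleMatrix(
            data={k: v[ix] for k, v in samples.data.items()},
            labels=samples.labels[ix],
            schema=list(samples.schema),
        )

    return take(np.sort(tr)), take(np.sort(te))


def save_samples(path: str | Path, samples: SampleMatrix, scaler: ScalerParams | None = None) -> None:
    """Persist a SampleMatrix (and optionally its scaler) to HDF5."""
    with h5py.File(path, "w") as f:
        g = f.create_group("sensors")
        for s in samples.schema:
            ds = g.create_dataset(s.name, data=samples.data[s.name])
            ds.attrs["n_axes"] = s.n_axes
            ds.attrs["sampling_rate"] = s.sampling_rate
        f.create_dataset("labels", data=np.asarray(samples.labels, dtype="S"))
        f.attrs["sensor_order"] = [s.name for s in samples.schema]
        if scaler is not None:
            sg = f.create_group("scaler")
            for k in scaler.col_min:
                sg.create_dataset(f"{k}/min", data=scaler.col_min[k])
                sg.create_dataset(f"{k}/max", data=scaler.col_max[k])


def load_samples(path: str | Path) -> tuple[SampleMatrix, ScalerParams | None]:
    """Inverse of :func:`save_samples`."""
    with h5py.File(path, "r") as f:
        order = [str(n) for n in f.attrs["sensor_order"]]
        schema = [
            SensorSpec(
                name=n,
                n_axes=int(f["sensors"][n].attrs["n_axes"]),
                sampling_rate=float(f["sensors"][n].attrs["sampling_rate"]),
            )
            for n in order
        ]
        data = {n: f["sensors"][n][...] for n in order}
        labels = np.array([b.decode() for b in f["labels"][...]])
        scaler = None
        if "scaler" in f:
            scaler = ScalerParams(
                col_min={n: f["scaler"][n]["min"][...] for n in order},
                col_max={n: f["scaler"][n]["max"][...] for n in order},
            )
    return SampleMatrix(data=data, labels=labels, schema=schema), scaler
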