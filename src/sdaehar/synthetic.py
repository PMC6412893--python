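"""Synthetic labelled inertial-sensor recordings for desk-scale testing.

Emulates the statistical structure the recognition pipeline relies on,
without any biomechanical realism:

* static postures — a constant gravity vector in the accelerometer frame
  plus i.i.d. Gaussian noise (the orientation distinguishes stand/sit/lie);
* periodic locomotion — a class-specific gait fundamental with a few
  harmonics on the accelerometer and phase-shifted harmonics on the
  gyroscope (walking vs. stair ascent/descent differ in fundamental
  frequency and harmonic amplitudes);
* a slowly rotating constant magnetic field on the magnetometer;
* monotone barometric drift for vertical-transport classes (pressure falls
  while ascending).

All randomness flows from one seed through per-recording child generators,
so a dataset is reproducible recording-by-recording.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_preprocess import RawRecording, SensorSpec

__all__ = [
    "ActivityModel",
    "SimConfig",
    "default_activity_models",
    "default_schema",
    "generate_recording",
    "generate_dataset",
    "write_dataset_csv",
]

GRAVITY = 9.81  # m/s^2
BASE_PRESSURE = 101325.0  # Pa
BASE_FIELD = np.array([20.0, 5.0, -40.0])  # uT, arbitrary fixed reference field


@dataclass(frozen=True)
class ActivityModel:
    """Signal model for one activity class.

    ``harmonics`` maps a sensor name to an (n_harmonics, n_axes) amplitude
    array for sinusoids at multiples of ``gait_freq``; ``noise_sigma`` maps
    sensor names to Gaussian noise scales (a missing entry means the
    default for that sensor).
    """

    name: str
    gravity: tuple[float, float, float] = (0.0, 0.0, 1.0)
    gait_freq: float = 0.0
    harmonics: Mapping[str, np.ndarray] = field(default_factory=dict)
    pressure_drift: float = 0.0  # Pa/s
    noise_sigma: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = np.asarray(self.gravity, dtype=float)
        if not np.isclose(np.linalg.norm(g), 1.0, atol=1e-6):
            raise ValueError(f"gravity orientation must be a unit vector, got {g}")
        if self.gait_freq < 0:
            raise ValueError("gait frequency must be >= 0")
        if any(s < 0 for s in self.noise_sigma.values()):
            raise ValueError("noise sigma must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Dataset-level generation settings."""

    sampling_rate: float = 50.0  # Hz
    duration: float = 10.0  # seconds per recording
    recordings_per_class: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0 or self.duration <= 0:
            raise ValueError("sampling_rate and duration must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate * self.duration))


#: default per-sensor noise scales: low-noise consumer-grade IMU at rest
_DEFAULT_SIGMA = {"acc": 0.05, "gyro": 0.02, "mag": 0.1, "pressure": 1.0}


def default_schema(include_pressure: bool = False, sampling_rate: float = 50.0) -> list[SensorSpec]:
    """Accelerometer + gyroscope + magnetometer (+ optional barometer)."""
    schema = [
        SensorSpec("acc", 3, sampling_rate),
        SensorSpec("gyro", 3, sampling_rate),
        SensorSpec("mag", 3, sampling_rate),
    ]
    if include_pressure:
        schema.append(SensorSpec("pressure", 1, sampling_rate))
    return schema


def _h(acc_amps: Sequence[Sequence[float]], gyro_scale: float = 0.5) -> dict[str, np.ndarray]:
    acc = np.asarray(acc_amps, dtype=float)
    return {"acc": acc, "gyro": gyro_scale * acc}


def default_activity_models(
    include_vertical_transport: bool = False,
    noise_scale: float = 1.0,
) -> list[ActivityModel]:
    """Six posture/locomotion classes, optionally plus elevator classes.

    Three static postures differ in gravity orientation; three gait classes
    differ in fundamental frequency and harmonic pattern.  ``noise_scale``
    multiplies every sensor's default noise sigma.
    """
    sigma = {k: v * noise_scale for k, v in _DEFAULT_SIGMA.items()}
    s32 = np.sqrt(3.0) / 2.0
    models = [
        ActivityModel("STANDING", gravity=(0.0, 0.0, 1.0), noise_sigma=sigma),
        ActivityModel("SITTING", gravity=(0.0, 0.5, s32), noise_sigma=sigma),
        ActivityModel("LAYING", gravity=(1.0, 0.0, 0.0), noise_sigma=sigma),
        ActivityModel(
            "WALKING",
            gravity=(0.0, 0.0, 1.0),
            gait_freq=1.8,
            harmonics=_h([[0.8, 0.5, 1.6], [0.3, 0.2, 0.7]]),
            noise_sigma=sigma,
        ),
        ActivityModel(
            "WALKING_UP",
            gravity=(0.0, 0.1, np.sqrt(0.99)),
            gait_freq=1.4,
            harmonics=_h([[1.2, 0.4, 1.1], [0.5, 0.3, 0.4], [0.2, 0.1, 0.2]]),
            noise_sigma=sigma,
        ),
        ActivityModel(
            "WALKING_DOWN",
            gravity=(0.0, -0.1, np.sqrt(0.99)),
            gait_freq=2.3,
            harmonics=_h([[1.5, 0.9, 2.0], [0.2, 0.5, 0.9]]),
            noise_sigma=sigma,
        ),
    ]
    if include_vertical_transport:
        models += [
            ActivityModel(
                "ELEVATOR_UP",
                gravity=(0.0, 0.0, 1.0),
                pressure_drift=-12.0,
                noise_sigma=sigma,
            ),
            ActivityModel(
                "ELEVATOR_DOWN",
                gravity=(0.0, 0.0, 1.0),
                pressure_drift=12.0,
                noise_sigma=sigma,
            ),
        ]
    return models


def _noise(rng: np.random.Generator, sigma: float, shape) -> np.ndarray:
    return rng.normal(0.0, sigma, size=shape) if sigma > 0 else np.zeros(shape)


def generate_recording(
    model: ActivityModel,
    cfg: SimConfig,
    rng: np.random.Generator,
    schema: Sequence[SensorSpec] | None = None,
    subject_id: str | None = None,
) -> RawRecording:
    """Simulate one labelled recording under the given activity model."""
    if schema is None:
        schema = default_schema(include_pressure=model.pressure_drift != 0.0,
                                sampling_rate=cfg.sampling_rate)
    n = cfg.n_samples
    t = np.arange(n) / cfg.sampling_rate
    sig = {**_DEFAULT_SIGMA, **dict(model.noise_sigma)}
    g = np.asarray(model.gravity)

    def harmonics_for(sensor: str, phase_shift: float) -> np.ndarray:
        amps = model.harmonics.get(sensor)
        out = np.zeros((n, 3))
        if amps is None or model.gait_freq == 0.0:
            return out
        amps = np.atleast_2d(np.asarray(amps, dtype=float))
        for h_i in range(amps.shape[0]):
            freq = model.gait_freq * (h_i + 1)
            for ax in range(min(3, amps.shape[1])):
                phase = phase_shift + ax * 2 * np.pi / 3 + h_i * np.pi / 4
                out[:, ax] += amps[h_i, ax] * np.sin(2 * np.pi * freq * t + phase)
        return out

    data: dict[str, np.ndarray] = {}
    for spec in schema:
        if spec.name == "acc":
            base = GRAVITY * g[None, :] + harmonics_for("acc", 0.0)
            data["acc"] = base + _noise(rng, sig["acc"], (n, 3))
        elif spec.name == "gyro":
            base = harmonics_for("gyro", np.pi / 2)
            data["gyro"] = base + _noise(rng, sig["gyro"], (n, 3))
        elif spec.name == "mag":
            # heading wanders slowly: rotate the reference field about z
            theta = 2 * np.pi * 0.01 * t + rng.uniform(0, 2 * np.pi)
            c, s = np.cos(theta), np.sin(theta)
            fx, fy, fz = BASE_FIELD
            base = np.stack([c * fx - s * fy, s * fx + c * fy, np.full(n, fz)], axis=1)
            data["mag"] = base + _noise(rng, sig["mag"], (n, 3))
        elif spec.name == "pressure":
            base = BASE_PRESSURE + model.pressure_drift * t
            data["pressure"] = (base + _noise(rng, sig["pressure"], n))[:, None]
        else:
            raise ValueError(f"no signal model for sensor {spec.name!r}")
    return RawRecording(data=data, label=model.name, subject_id=subject_id)


def generate_dataset(
    cfg: SimConfig,
    models: Sequence[ActivityModel] | None = None,
    schema: Sequence[SensorSpec] | None = None,
) -> tuple[list[RawRecording], pd.DataFrame]:
    """Balanced synthetic dataset: ``recordings_per_class`` per model.

    Returns the recordings plus a manifest (one row per recording with its
    class and the child-seed used), deterministic under ``cfg.seed``.
    """
    if models is None:
        models = default_activity_models()
    if schema is None:
        include_pre = any(m.pressure_drift != 0.0 for m in models)
        schema = default_schema(include_pressure=include_pre, sampling_rate=cfg.sampling_rate)
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(len(models) * cfg.recordings_per_class)
    recordings: list[RawRecording] = []
    rows = []
    i = 0
    for model in models:
        for r in range(cfg.recordings_per_class):
            rng = np.random.default_rng(children[i])
            rec = generate_recording(model, cfg, rng, schema=schema,
                                     subject_id=f"sim{r:03d}")
            recordings.append(rec)
            rows.append({"index": i, "label": model.name, "recording": r})
            i += 1
    return recordings, pd.DataFrame(rows)


def write_dataset_csv(
    recordings: Sequence[RawRecording],
    out_dir: str | Path,
    schema: Sequence[SensorSpec],
    manifest: pd.DataFrame | None = None,
) -> list[Path]:
    """Write one CSV per recording (plus manifest.csv) in the loader's layout."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    header = [c for s in schema for c in s.columns] + ["label"]
    for i, rec in enumerate(recordings):
        path = out_dir / f"recording_{i:04d}.csv"
        mat = np.hstack([rec.data[s.name] for s in schema])
        with open(path, "w", newline="") as f:
            writer = csv.writer(f)
            writer.writerow(header)
            for row in mat:
                writer.writerow([f"{v:.6f}" for v in row] + [rec.label])
        paths.append(path)
    if manifest is not None:
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return paths
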