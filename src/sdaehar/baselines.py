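"""In-package comparison methods.

Two reference classifiers accompany the main SDAE + boosted-tree pipeline:

* **single SDAE** — the pretrained per-sensor encoder stacks with a softmax
  output layer on top of the concatenated encodings, trained end-to-end by
  gradient descent on the categorical cross-entropy (gradients flow into the
  encoder weights as well);
* **hand-crafted features + gradient-boosted trees** — a classical feature
  table per window (gravity-axis decomposition statistics, modulus-series
  statistics with spectral and autocorrelation terms, inter-axis Pearson
  correlations, and barometric change/spread features) fed to a boosted-tree
  backend (xgboost by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .boost_kfold import GBDTParams, _encode_labels, _quiet_predict, fit_gbdt_backend
from .io_preprocess import SampleMatrix, SensorSpec, unflatten_windows
from .sdae import EncoderStack, TrainingDivergenceError, _Adam, encode_layer

__all__ = [
    "SoftmaxHead",
    "SingleSDAEClassifier",
    "SoftmaxTrainConfig",
    "train_single_sdae_classifier",
    "gravity_decompose",
    "extract_handcrafted_features",
    "handcrafted_feature_matrix",
    "train_handcrafted_gbdt",
    "HandcraftedGBDTClassifier",
]


# --------------------------------------------------------------------------
# single SDAE with a softmax head
# --------------------------------------------------------------------------

@dataclass
class SoftmaxHead:
    """Affine map from concatenated encoder output to class scores."""

    w: np.ndarray  # (D, M)
    b: np.ndarray  # (M,)

    def probabilities(self, feats: np.ndarray) -> np.ndarray:
        z = feats @ self.w + self.b
        z = z - z.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)


@dataclass(frozen=True)
class SoftmaxTrainConfig:
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    fine_tune_encoder: bool = True
    seed: int = 0


@dataclass
class SingleSDAEClassifier:
    """Per-sensor encoder stacks + softmax head, predicting hard labels."""

    stacks: dict[str, EncoderStack]
    head: SoftmaxHead
    classes: np.ndarray
    loss_history: list[float] = field(default_factory=list)

    def _features(self, samples: SampleMatrix) -> np.ndarray:
        blocks = []
        for name, stack in self.stacks.items():
            h = samples.data[name]
            for p in stack.layers:
                h = encode_layer(h, p)
            blocks.append(h)
        return np.hstack(blocks)

    def predict_proba(self, samples: SampleMatrix) -> np.ndarray:
        return self.head.probabilities(self._features(samples))

    def predict(self, samples: SampleMatrix) -> np.ndarray:
        return self.classes[np.argmax(self.predict_proba(samples), axis=1)]


def train_single_sdae_classifier(
    stacks: Mapping[str, EncoderStack],
    samples: SampleMatrix,
    y: Sequence,
    cfg: SoftmaxTrainConfig | None = None,
) -> SingleSDAEClassifier:
    """Supervised training of the softmax head over pretrained encoders.

    Cross-entropy loss, mini-batch Adam; with ``fine_tune_encoder`` the
    encoder weights of every stack receive gradients too.  Zero epochs
    leaves the randomly initialised head untouched.
    """
    import copy

    cfg = cfg or SoftmaxTrainConfig()
    stacks = {k: copy.deepcopy(v) for k, v in stacks.items()}
    y_enc, classes = _encode_labels(np.asarray(y))
    m_classes = len(classes)
    rng = np.random.default_rng(cfg.seed)
    d_feat = sum(s.feature_dim for s in stacks.values())
    lim = np.sqrt(6.0 / (d_feat + m_classes))
    head = SoftmaxHead(
        w=rng.uniform(-lim, lim, size=(d_feat, m_classes)),
        b=np.zeros(m_classes),
    )
    params: list[np.ndarray] = [head.w, head.b]
    if cfg.fine_tune_encoder:
        for stack in stacks.values():
            for p in stack.layers:
                params.extend([p.w_enc, p.b_enc])
    opt = _Adam(params, cfg.learning_rate)
    names = list(stacks)
    n = samples.n_samples
    onehot = np.eye(m_classes)[y_enc]
    history: list[float] = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses, weights = [], []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            # forward: keep every activation for backprop
            acts: dict[str, list[np.ndarray]] = {}
            blocks = []
            for name in names:
                h = samples.data[name][idx]
                layer_acts = [h]
                for p in stacks[name].layers:
                    h = encode_layer(h, p)
                    layer_acts.append(h)
                acts[name] = layer_acts
                blocks.append(h)
            feats = np.hstack(blocks)
            probs = head.probabilities(feats)
            eps = 1e-12
            loss = float(-np.mean(np.log(probs[np.arange(len(idx)), y_enc[idx]] + eps)))
            if not np.isfinite(loss):
                raise TrainingDivergenceError("non-finite cross-entropy loss")
            dz = (probs - onehot[idx]) / len(idx)
            grads: list[np.ndarray] = [feats.T @ dz, dz.sum(axis=0)]
            dfeat = dz @ head.w.T
            if cfg.fine_tune_encoder:
                col = 0
                for name in names:
                    stack = stacks[name]
                    width = stack.feature_dim
                    d = dfeat[:, col : col + width]
                    col += width
                    layer_acts = acts[name]
                    layer_grads: list[np.ndarray] = []
                    for li in range(len(stack.layers) - 1, -1, -1):
                        out = layer_acts[li + 1]
                        inp = layer_acts[li]
                        dzl = d * out * (1 - out)
                        layer_grads[:0] = [inp.T @ dzl, dzl.sum(axis=0)]
                        d = dzl @ stack.layers[li].w_enc.T
                    grads.extend(layer_grads)
            opt.step(grads)
            losses.append(loss)
            weights.append(len(idx))
        history.append(float(np.average(losses, weights=weights)))
    return SingleSDAEClassifier(
        stacks=dict(stacks), head=head, classes=classes, loss_history=history
    )


# --------------------------------------------------------------------------
# hand-crafted features
# --------------------------------------------------------------------------

def gravity_decompose(acc_window: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a 3-axis accelerometer window into vertical/horizontal series.

    The gravity direction is estimated as the unit window-mean vector;
    vertical is the signed projection onto it and horizontal the magnitude
    of the residual.  A near-zero mean falls back to the device z-axis.
    """
    acc_window = np.asarray(acc_window, dtype=float)
    if acc_window.ndim != 2 or acc_window.shape[1] != 3:
        raise ValueError(f"expected a (w, 3) window, got {acc_window.shape}")
    g = acc_window.mean(axis=0)
    norm = np.linalg.norm(g)
    if norm < 1e-8:
        warnings.warn("near-zero mean acceleration; using device z-axis as vertical",
                      stacklevel=2)
        u = np.array([0.0, 0.0, 1.0])
    else:
        u = g / norm
    vertical = acc_window @ u
    residual = acc_window - np.outer(vertical, u)
    horizontal = np.linalg.norm(residual, axis=1)
    return vertical, horizontal


def _basic_stats(x: np.ndarray, prefix: str) -> dict[str, float]:
    """mean/variance/std/median/min/max/range and the three quartiles."""
    q1, q2, q3 = np.percentile(x, [25, 50, 75])
    return {
        f"{prefix}_mean": float(np.mean(x)),
        f"{prefix}_var": float(np.var(x)),        # population normalisation
        f"{prefix}_std": float(np.std(x)),
        f"{prefix}_median": float(np.median(x)),
        f"{prefix}_min": float(np.min(x)),
        f"{prefix}_max": float(np.max(x)),
        f"{prefix}_range": float(np.max(x) - np.min(x)),
        f"{prefix}_q1": float(q1),
        f"{prefix}_q2": float(q2),
        f"{prefix}_q3": float(q3),
    }


def _lag1_autocorr(x: np.ndarray) -> float:
    if np.std(x[:-1]) == 0 or np.std(x[1:]) == 0:
        return 0.0
    return float(np.corrcoef(x[:-1], x[1:])[0, 1])


def _modulus_stats(x: np.ndarray, prefix: str, dt: float) -> dict[str, float]:
    """Extended statistics for a modulus series: basic stats plus shape,
    energy, integral, autocorrelation and low-frequency spectral terms."""
    out = _basic_stats(x, prefix)
    if np.std(x) == 0:  # degenerate constant series: moments defined as 0
        kurt, skew = 0.0, 0.0
    else:
        kurt = sstats.kurtosis(x)  # Fisher definition, population moments
        skew = sstats.skew(x)
    out[f"{prefix}_kurtosis"] = float(np.nan_to_num(kurt))
    out[f"{prefix}_skewness"] = float(np.nan_to_num(skew))
    out[f"{prefix}_rms"] = float(np.sqrt(np.mean(x**2)))
    integral = np.concatenate([[0.0], np.cumsum((x[1:] + x[:-1]) / 2.0 * dt)])
    out[f"{prefix}_integral"] = float(integral[-1])
    dbl = np.concatenate([[0.0], np.cumsum((integral[1:] + integral[:-1]) / 2.0 * dt)])
    out[f"{prefix}_double_integral"] = float(dbl[-1])
    out[f"{prefix}_autocorr1"] = _lag1_autocorr(x)
    mags = np.abs(np.fft.rfft(x))
    for i in range(1, 8):  # 7 lowest non-DC coefficients
        out[f"{prefix}_fft{i}"] = float(mags[i]) if i < len(mags) else 0.0
    return out


def _pairwise_pearson(win: np.ndarray, prefix: str) -> dict[str, float]:
    names = ["xy", "xz", "yz"]
    pairs = [(0, 1), (0, 2), (1, 2)]
    out = {}
    for nm, (a, b) in zip(names, pairs):
        if np.std(win[:, a]) == 0 or np.std(win[:, b]) == 0:
            r = 0.0
        else:
            r = float(np.corrcoef(win[:, a], win[:, b])[0, 1])
        out[f"{prefix}_corr_{nm}"] = r
    return out


def _pressure_features(series: np.ndarray, sampling_rate: float) -> dict[str, float]:
    """Change value and spread of the barometric series over 6 s and 10 s
    trailing sub-windows (the whole series if shorter, with a warning)."""
    out = {}
    for span in (6.0, 10.0):
        need = int(round(span * sampling_rate))
        if need > len(series):
            warnings.warn(
                f"pressure buffer shorter than {span:g} s; using the full series",
                stacklevel=3,
            )
            sub = series
        else:
            sub = series[-need:]
        out[f"pressure_{span:g}s_change"] = float(sub[-1] - sub[0])
        out[f"pressure_{span:g}s_std"] = float(np.std(sub))
    return out


def extract_handcrafted_features(
    window: Mapping[str, np.ndarray],
    schema: Sequence[SensorSpec],
    pressure_buffer: np.ndarray | None = None,
) -> dict[str, float]:
    """Classical feature table for one multi-sensor window.

    ``window`` maps sensor names to (w, n_axes) matrices.  The barometric
    features may use a longer trailing buffer than the classification
    window when ``pressure_buffer`` is given.
    """
    by_name = {s.name: s for s in schema}
    feats: dict[str, float] = {}
    if "acc" in by_name and "acc" in window:
        vert, horiz = gravity_decompose(window["acc"])
        feats.update(_basic_stats(vert, "acc_vertical"))
        feats.update(_basic_stats(horiz, "acc_horizontal"))
    elif "acc" in by_name:
        warnings.warn("accelerometer missing from window; gravity cluster omitted",
                      stacklevel=2)
    for name in ("acc", "gyro", "mag"):
        if name not in by_name:
            continue
        if name not in window:
            warnings.warn(f"sensor {name!r} missing from window; cluster omitted",
                          stacklevel=2)
            continue
        spec = by_name[name]
        win = np.asarray(window[name], dtype=float)
        modulus = np.linalg.norm(win, axis=1)
        feats.update(_modulus_stats(modulus, f"{name}_mod", dt=1.0 / spec.sampling_rate))
        if spec.n_axes == 3:
            feats.update(_pairwise_pearson(win, name))
    if "pressure" in by_name:
        if pressure_buffer is not None:
            series = np.asarray(pressure_buffer, dtype=float).ravel()
        elif "pressure" in window:
            series = np.asarray(window["pressure"], dtype=float).ravel()
        else:
            series = None
            warnings.warn("pressure missing from window; barometric cluster omitted",
                          stacklevel=2)
        if series is not None:
            feats.update(_pressure_features(series, by_name["pressure"].sampling_rate))
    return feats


def handcrafted_feature_matrix(
    samples: SampleMatrix, window_len: int
) -> pd.DataFrame:
    """Apply :func:`extract_handcrafted_features` to every flattened window."""
    by_name = {s.name: s for s in samples.schema}
    rows = []
    for i in range(samples.n_samples):
        window = {
            name: unflatten_windows(mat[i : i + 1], window_len, by_name[name].n_axes)[0]
            for name, mat in samples.data.items()
        }
        rows.append(extract_handcrafted_features(window, samples.schema))
    return pd.DataFrame(rows)


@dataclass
class HandcraftedGBDTClassifier:
    model: object
    classes: np.ndarray
    feature_names: list[str]
    window_len: int

    def predict(self, samples: SampleMatrix) -> np.ndarray:
        feats = handcrafted_feature_matrix(samples, self.window_len)
        codes = _quiet_predict(self.model, feats[self.feature_names].to_numpy())
        return self.classes[codes]


def train_handcrafted_gbdt(
    samples: SampleMatrix,
    window_len: int,
    params: GBDTParams | None = None,
) -> HandcraftedGBDTClassifier:
    """Fit a boosted-tree model on the classical feature table."""
    params = params or GBDTParams(backend="xgboost")
    feats = handcrafted_feature_matrix(samples, window_len)
    y_enc, classes = _encode_labels(samples.labels)
    model = fit_gbdt_backend(feats.to_numpy(), y_enc, params)
    return HandcraftedGBDTClassifier(
        model=model,
        classes=classes,
        feature_names=list(feats.columns),
        window_len=window_len,
    )
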