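"""Per-sensor stacked denoising autoencoders (SDAE).

Each sensor's flattened, min-max-scaled windows feed an independent stack of
denoising autoencoder layers.  A single layer corrupts its input by Bernoulli
zero-masking at rate ``dropout``, encodes with a sigmoid affine map, decodes
with another sigmoid affine map, and is trained to minimise the mean squared
reconstruction error against the *clean* input.  Layers are pretrained
greedily — layer l+1 trains on the clean encodings of layer l — then the
unrolled encoder/decoder chain is fine-tuned end-to-end on the same
unsupervised reconstruction objective.  Inference composes the encoders only,
with no corruption, and the per-sensor features are concatenated in fixed
sensor order into the final feature matrix.

Everything here is plain numpy: sigmoid activations (inputs live in [0, 1]
after min-max scaling, so a (0, 1)-valued decoder output is the natural
reconstruction range), mini-batch gradients and Adam updates.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

__all__ = [
    "SDAEConfig",
    "LayerParams",
    "EncoderStack",
    "FeatureMatrix",
    "TrainingDivergenceError",
    "corrupt_input",
    "encode_layer",
    "decode_layer",
    "pretrain_layer",
    "build_stack",
    "fine_tune_stack",
    "extract_features",
    "concat_sensor_features",
    "save_stack",
    "load_stack",
]


class TrainingDivergenceError(RuntimeError):
    """Raised when the reconstruction loss becomes non-finite."""


@dataclass(frozen=True)
class SDAEConfig:
    """Hyperparameters for one sensor's stack.

    ``n_hidden`` lists the encoder widths from bottom to top; ``dropout`` is
    the Bernoulli input-corruption probability used during training only.
    ``epochs`` is the per-layer pretraining budget; ``fine_tune_epochs``
    defaults to the same value.
    """

    n_hidden: tuple[int, ...]
    dropout: float = 0.4
    batch_size: int = 32
    epochs: int = 2
    fine_tune_epochs: int | None = None
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_hidden", tuple(int(w) for w in self.n_hidden))
        if len(self.n_hidden) < 1:
            raise ValueError("need at least one hidden layer")
        if any(w < 1 for w in self.n_hidden):
            raise ValueError(f"layer widths must be >= 1, got {self.n_hidden}")
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError(f"dropout must be in [0, 1], got {self.dropout}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    @property
    def n_layer(self) -> int:
        return len(self.n_hidden)

    @property
    def effective_fine_tune_epochs(self) -> int:
        return self.epochs if self.fine_tune_epochs is None else self.fine_tune_epochs


@dataclass
class LayerParams:
    """One denoising autoencoder layer: encode and decode affine maps."""

    w_enc: np.ndarray  # (d_in, d_hidden)
    b_enc: np.ndarray  # (d_hidden,)
    w_dec: np.ndarray  # (d_hidden, d_in)
    b_dec: np.ndarray  # (d_in,)

    @property
    def input_dim(self) -> int:
        return self.w_enc.shape[0]

    @property
    def hidden_dim(self) -> int:
        return self.w_enc.shape[1]


@dataclass
class EncoderStack:
    """Ordered trained layers for one sensor plus its config and loss traces."""

    layers: list[LayerParams]
    config: SDAEConfig
    pretrain_losses: list[list[float]] = field(default_factory=list)
    fine_tune_losses: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("an encoder stack needs at least one layer")
        for lo, hi in zip(self.layers, self.layers[1:]):
            if hi.input_dim != lo.hidden_dim:
                raise ValueError(
                    f"layer chaining broken: {lo.hidden_dim} -> {hi.input_dim}"
                )

    @property
    def feature_dim(self) -> int:
        return self.layers[-1].hidden_dim


@dataclass
class FeatureMatrix:
    """Concatenated learned features across sensors, with labels."""

    features: np.ndarray  # (N, sum of top widths)
    labels: np.ndarray
    sensor_widths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.features.shape[0] != len(self.labels):
            raise ValueError("feature rows and labels disagree")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def corrupt_input(x: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Zero each coordinate independently with probability ``rate``."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"corruption rate must be in [0, 1], got {rate}")
    if rate == 0.0:
        return x.copy()
    mask = rng.random(x.shape) >= rate
    return x * mask


def encode_layer(x: np.ndarray, p: LayerParams) -> np.ndarray:
    """sigmoid(x W_enc + b_enc); accepts a vector or an (N, d_in) matrix."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != p.input_dim:
        raise ValueError(f"input width {x.shape[-1]} != layer input dim {p.input_dim}")
    return _sigmoid(x @ p.w_enc + p.b_enc)


def decode_layer(h: np.ndarray, p: LayerParams) -> np.ndarray:
    """sigmoid(h W_dec + b_dec); accepts a vector or an (N, d_hidden) matrix."""
    h = np.asarray(h, dtype=float)
    if h.shape[-1] != p.hidden_dim:
        raise ValueError(f"hidden width {h.shape[-1]} != layer hidden dim {p.hidden_dim}")
    return _sigmoid(h @ p.w_dec + p.b_dec)


def init_layer(d_in: int, d_hidden: int, rng: np.random.Generator) -> LayerParams:
    """Scaled-uniform (fan-in + fan-out) initialisation, zero biases."""
    lim_e = np.sqrt(6.0 / (d_in + d_hidden))
    return LayerParams(
        w_enc=rng.uniform(-lim_e, lim_e, size=(d_in, d_hidden)),
        b_enc=np.zeros(d_hidden),
        w_dec=rng.uniform(-lim_e, lim_e, size=(d_hidden, d_in)),
        b_dec=np.zeros(d_in),
    )


class _Adam:
    """Adam updates over a flat list of parameter arrays (in place)."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def pretrain_layer(
    data: np.ndarray,
    cfg: SDAEConfig,
    layer_index: int,
    rng: np.random.Generator | None = None,
    params: LayerParams | None = None,
) -> tuple[LayerParams, list[float]]:
    """Train one denoising autoencoder layer on ``data`` (rows = samples).

    Minimises mean ||decode(encode(corrupt(x))) - x||^2 over mini-batches
    (mean over both samples and coordinates).  Returns the trained layer and
    the per-epoch mean training loss (length == cfg.epochs; zero epochs
    leaves the initialisation untouched).
    """
    data = np.asarray(data, dtype=float)
    if rng is None:
        rng = np.random.default_rng((cfg.seed, layer_index))
    d_in = data.shape[1]
    d_hid = cfg.n_hidden[layer_index]
    if params is None:
        params = init_layer(d_in, d_hid, rng)
    opt = _Adam([params.w_enc, params.b_enc, params.w_dec, params.b_dec], cfg.learning_rate)
    history: list[float] = []
    for _ in range(cfg.epochs):
        losses, weights = [], []
        for idx in _batches(data.shape[0], cfg.batch_size, rng):
            x = data[idx]
            n = corrupt_input(x, cfg.dropout, rng)
            h = encode_layer(n, params)
            r = decode_layer(h, params)
            diff = r - x
            loss = float(np.mean(diff * diff))
            if not np.isfinite(loss):
                raise TrainingDivergenceError(
                    f"non-finite reconstruction loss at layer {layer_index}"
                )
            # backprop: loss = mean(diff^2) over batch*features
            dr = 2.0 * diff / diff.size
            dz2 = dr * r * (1 - r)
            g_wdec = h.T @ dz2
            g_bdec = dz2.sum(axis=0)
            dh = dz2 @ params.w_dec.T
            dz1 = dh * h * (1 - h)
            g_wenc = n.T @ dz1
            g_benc = dz1.sum(axis=0)
            opt.step([g_wenc, g_benc, g_wdec, g_bdec])
            losses.append(loss)
            weights.append(len(idx))
        history.append(float(np.average(losses, weights=weights)))
    return params, history


def build_stack(train: np.ndarray, cfg: SDAEConfig) -> EncoderStack:
    """Greedy layer-wise pretraining of a full stack for one sensor.

    Layer l+1 is trained on the *clean* (uncorrupted) encodings of layer l;
    corruption is re-applied inside each layer's own pretraining.
    """
    rng = np.random.default_rng(cfg.seed)
    current = np.asarray(train, dtype=float)
    layers: list[LayerParams] = []
    histories: list[list[float]] = []
    for li in range(cfg.n_layer):
        params, hist = pretrain_layer(current, cfg, li, rng=rng)
        layers.append(params)
        histories.append(hist)
        current = encode_layer(current, params)
    return EncoderStack(layers=layers, config=cfg, pretrain_losses=histories)


def _unrolled_forward(
    x: np.ndarray, layers: list[LayerParams]
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Encoders bottom-up then decoders top-down; returns (encodings, decodings)."""
    encs = [x]
    for p in layers:
        encs.append(encode_layer(encs[-1], p))
    decs = [encs[-1]]
    for p in reversed(layers):
        decs.append(decode_layer(decs[-1], p))
    return encs, decs


def unrolled_reconstruction_loss(stack: EncoderStack, x: np.ndarray) -> float:
    """Mean squared error of the full encode-then-decode chain on clean input."""
    _, decs = _unrolled_forward(np.asarray(x, dtype=float), stack.layers)
    diff = decs[-1] - x
    return float(np.mean(diff * diff))


def fine_tune_stack(stack: EncoderStack, train: np.ndarray, cfg: SDAEConfig | None = None) -> EncoderStack:
    """Unsupervised end-to-end fine-tuning of the unrolled encoder/decoder.

    The corrupted input passes through every encoder then every decoder in
    reverse; all affine maps are updated jointly against the clean-input MSE.
    Returns a new stack; the input stack is not modified.
    """
    cfg = stack.config if cfg is None else cfg
    stack = copy.deepcopy(stack)
    train = np.asarray(train, dtype=float)
    rng = np.random.default_rng((cfg.seed, cfg.n_layer, 977))  # distinct stream from pretraining
    flat: list[np.ndarray] = []
    for p in stack.layers:
        flat.extend([p.w_enc, p.b_enc, p.w_dec, p.b_dec])
    opt = _Adam(flat, cfg.learning_rate)
    L = len(stack.layers)
    history: list[float] = []
    for _ in range(cfg.effective_fine_tune_epochs):
        losses, weights = [], []
        for idx in _batches(train.shape[0], cfg.batch_size, rng):
            x = train[idx]
            noised = corrupt_input(x, cfg.dropout, rng)
            encs, decs = _unrolled_forward(noised, stack.layers)
            diff = decs[-1] - x
            loss = float(np.mean(diff * diff))
            if not np.isfinite(loss):
                raise TrainingDivergenceError("non-finite loss during fine-tuning")
            grads = [np.zeros_like(a) for a in flat]
            # decoder chain runs layers top-down: decs[L-step] is the output of
            # stack.layers[step]'s decoder, fed by decs[L-step-1]
            d = 2.0 * diff / diff.size
            for step in range(L):
                layer = stack.layers[step]
                out = decs[L - step]
                inp = decs[L - step - 1]
                dz = d * out * (1 - out)
                gi = 4 * step
                grads[gi + 2] += inp.T @ dz
                grads[gi + 3] += dz.sum(axis=0)
                d = dz @ layer.w_dec.T
            for step in range(L - 1, -1, -1):
                layer = stack.layers[step]
                out = encs[step + 1]
                inp = encs[step]
                dz = d * out * (1 - out)
                gi = 4 * step
                grads[gi + 0] += inp.T @ dz
                grads[gi + 1] += dz.sum(axis=0)
                d = dz @ layer.w_enc.T
            opt.step(grads)
            losses.append(loss)
            weights.append(len(idx))
        history.append(float(np.average(losses, weights=weights)))
    stack.fine_tune_losses = history
    return stack


def extract_features(stack: EncoderStack, x: np.ndarray) -> np.ndarray:
    """Compose all encoders with no corruption; output width = top layer width."""
    x = np.asarray(x, dtype=float)
    h = x
    for p in stack.layers:
        h = encode_layer(h, p)
    return h


def concat_sensor_features(
    per_sensor: Sequence[np.ndarray] | dict[str, np.ndarray],
    labels: np.ndarray | None = None,
) -> FeatureMatrix:
    """Column-wise concatenation of per-sensor feature blocks, in given order."""
    if isinstance(per_sensor, dict):
        names = list(per_sensor)
        mats = [per_sensor[n] for n in names]
    else:
        mats = list(per_sensor)
        names = [f"sensor{i}" for i in range(len(mats))]
    if not mats:
        raise ValueError("no feature blocks given")
    rows = {m.shape[0] for m in mats}
    if len(rows) > 1:
        raise ValueError(f"row counts differ across sensors: {sorted(rows)}")
    feats = np.hstack(mats)
    if labels is None:
        labels = np.arange(feats.shape[0])
    return FeatureMatrix(
        features=feats,
        labels=np.asarray(labels),
        sensor_widths={n: m.shape[1] for n, m in zip(names, mats)},
    )


def save_stack(path: str | Path, stacks: dict[str, EncoderStack]) -> None:
    """Persist per-sensor stacks to HDF5 (one group per sensor)."""
    with h5py.File(path, "w") as f:
        f.attrs["sensor_order"] = list(stacks)
        for name, stack in stacks.items():
            g = f.create_group(name)
            cfg = stack.config
            g.attrs.update(
                n_hidden=list(cfg.n_hidden),
                dropout=cfg.dropout,
                batch_size=cfg.batch_size,
                epochs=cfg.epochs,
                fine_tune_epochs=cfg.effective_fine_tune_epochs,
                learning_rate=cfg.learning_rate,
                seed=cfg.seed,
            )
            for i, p in enumerate(stack.layers):
                lg = g.create_group(f"layer{i}")
                lg.create_dataset("w_enc", data=p.w_enc)
                lg.create_dataset("b_enc", data=p.b_enc)
                lg.create_dataset("w_dec", data=p.w_dec)
                lg.create_dataset("b_dec", data=p.b_dec)


def load_stack(path: str | Path) -> dict[str, EncoderStack]:
    """Inverse of :func:`save_stack`."""
    out: dict[str, EncoderStack] = {}
    with h5py.File(path, "r") as f:
        for name in f.attrs["sensor_order"]:
            g = f[name]
            cfg = SDAEConfig(
                n_hidden=tuple(int(w) for w in g.attrs["n_hidden"]),
                dropout=float(g.attrs["dropout"]),
                batch_size=int(g.attrs["batch_size"]),
                epochs=int(g.attrs["epochs"]),
                fine_tune_epochs=int(g.attrs["fine_tune_epochs"]),
                learning_rate=float(g.attrs["learning_rate"]),
                seed=int(g.attrs["seed"]),
            )
            layers = []
            for i in range(cfg.n_layer):
                lg = g[f"layer{i}"]
                layers.append(
                    LayerParams(
                        w_enc=lg["w_enc"][...],
                        b_enc=lg["b_enc"][...],
                        w_dec=lg["w_dec"][...],
                        b_dec=lg["b_dec"][...],
                    )
                )
            out[str(name)] = EncoderStack(layers=layers, config=cfg)
    return out
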