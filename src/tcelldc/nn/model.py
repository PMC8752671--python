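"""CNN-LSTM video classifier: construction, training, prediction, persistence.

Architecture: four blocks of time-distributed convolutions (two 3x3 convs
per block except the last, which has one), each block closed by batch
normalization and 2x2 max pooling with 1x1 stride; per-frame features are
flattened and fed to an LSTM whose final state passes through a dense
layer into a 2-unit softmax.  Trained with RMSprop and 2-class
cross-entropy (the "binary cross-entropy over softmax" formulation), with
an L2 penalty on the LSTM input kernel.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np

from ..errors import (
    InputShapeError,
    LayerNotFoundError,
    TrainingDivergedError,
)
from ..params import TrainConfig
from .layers import LSTM, BatchNorm, Conv2D, Dense, Flatten, Layer, MaxPool2D, ReLU

__all__ = ["ModelSpec", "CNNLSTM", "build_model", "train_model", "predict_proba",
           "save_model", "load_model"]


@dataclass(frozen=True)
class ModelSpec:
    """Hyperparameters of the CNN-LSTM.

    Defaults reproduce the published architecture for 20-frame 101x101
    3-channel videos.  ``input_shape`` is (frames, height, width, channels).
    """

    input_shape: Tuple[int, int, int, int] = (20, 101, 101, 3)
    conv_blocks: Tuple[Tuple[int, ...], ...] = ((8, 4), (16, 8), (32, 16), (64,))
    kernel: int = 3
    pool_size: int = 2
    pool_stride: int = 1
    bn_momentum: float = 0.9
    lstm_units: int = 100
    lstm_dropout: float = 0.2
    lstm_recurrent_dropout: float = 0.2
    lstm_l2: float = 0.01
    dense_units: int = 100
    output_units: int = 2
    learning_rate: float = 1e-4
    rmsprop_rho: float = 0.9
    rmsprop_eps: float = 1e-7
    epochs: int = 20
    init_seed: int = 0

    def __post_init__(self):
        if any(n <= 0 for block in self.conv_blocks for n in block):
            raise ValueError("filter counts must be positive")
        if self.output_units < 2:
            raise ValueError("softmax head needs >= 2 units")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        d = json.loads(text)
        d["input_shape"] = tuple(d["input_shape"])
        d["conv_blocks"] = tuple(tuple(b) for b in d["conv_blocks"])
        return cls(**d)

    @property
    def penultimate_conv1(self) -> str:
        """Name of the first conv of the penultimate conv block (Grad-CAM target)."""
        return f"block{len(self.conv_blocks) - 1}_conv1"


class CNNLSTM:
    """The assembled network.  Use :func:`build_model` to construct."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.init_seed)
        t, h, w, c = spec.input_shape
        self.conv_layers: List[Layer] = []
        c_in = c
        for bi, block in enumerate(spec.conv_blocks, start=1):
            for ci, filters in enumerate(block, start=1):
                self.conv_layers.append(
                    Conv2D(f"block{bi}_conv{ci}", c_in, filters, rng, spec.kernel)
                )
                self.conv_layers.append(ReLU(f"block{bi}_relu{ci}"))
                c_in = filters
            self.conv_layers.append(
                BatchNorm(f"block{bi}_bn", c_in, momentum=spec.bn_momentum)
            )
            pool = MaxPool2D(f"block{bi}_pool", spec.pool_size, spec.pool_stride)
            self.conv_layers.append(pool)
            h, w = pool.out_hw(h, w)
        self.feature_hw = (h, w, c_in)
        d_feat = h * w * c_in
        self.flatten = Flatten("flatten")
        self.lstm = LSTM(
            "lstm",
            d_feat,
            spec.lstm_units,
            rng,
            dropout=spec.lstm_dropout,
            recurrent_dropout=spec.lstm_recurrent_dropout,
            l2=spec.lstm_l2,
        )
        self.dense = Dense("dense", spec.lstm_units, spec.dense_units, rng, "relu")
        self.head = Dense("head", spec.dense_units, spec.output_units, rng)
        self.all_layers: List[Layer] = (
            self.conv_layers + [self.flatten, self.lstm, self.dense, self.head]
        )
        self._opt_cache: Dict[str, np.ndarray] = {}

    # -- introspection -----------------------------------------------------
    def layer(self, name: str) -> Layer:
        for lay in self.all_layers:
            if lay.name == name:
                return lay
        raise LayerNotFoundError(f"no layer named {name!r}")

    def layer_param_counts(self) -> Dict[str, int]:
        return {l.name: l.n_params() for l in self.all_layers if l.params}

    def count_params(self) -> int:
        return sum(self.layer_param_counts().values())

    # -- forward / backward ------------------------------------------------
    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 5 or x.shape[1:] != tuple(self.spec.input_shape):
            raise InputShapeError(
                f"expected (batch, {', '.join(map(str, self.spec.input_shape))}), "
                f"got {x.shape}"
            )

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a (batch, T, H, W, C) float array."""
        self._check_input(x)
        b, t = x.shape[:2]
        z = x.reshape((b * t,) + x.shape[2:]).astype(np.float32)
        for lay in self.conv_layers:
            z = lay.forward(z, train)
        z = self.flatten.forward(z, train)
        z = z.reshape(b, t, -1)
        z = self.lstm.forward(z, train)
        z = self.dense.forward(z, train)
        return self.head.forward(z, train)

    def backward_from_logits(self, dlogits: np.ndarray) -> np.ndarray:
        """Backpropagate a gradient w.r.t. the logits; returns d/d(input)."""
        g = self.dense.backward(self.head.backward(dlogits))
        g = self.lstm.backward(g)
        b, t, d = g.shape
        g = self.flatten.backward(g.reshape(b * t, d))
        for lay in reversed(self.conv_layers):
            g = lay.backward(g)
        return g.reshape((b, t) + g.shape[1:])

    def predict_proba(self, x: np.ndarray, batch_size: int = 16) -> np.ndarray:
        """Per-video probability of the cognate class (index 1)."""
        probs = []
        for lo in range(0, len(x), batch_size):
            logits = self.forward_logits(x[lo : lo + batch_size], train=False)
            probs.append(_softmax(logits)[:, 1])
        return np.concatenate(probs)

    # -- optimization ------------------------------------------------------
    def _reg_loss_and_grads(self) -> float:
        """Keras-style l2: penalty = l2 * sum(W**2) on the LSTM input kernel."""
        l2 = self.spec.lstm_l2
        if l2 <= 0:
            return 0.0
        w = self.lstm.params["W"]
        self.lstm.grads["W"] = self.lstm.grads["W"] + 2.0 * l2 * w
        return float(l2 * np.sum(w.astype(np.float64) ** 2))

    def rmsprop_step(self) -> None:
        s = self.spec
        for lay in self.all_layers:
            for k, g in lay.grads.items():
                key = f"{lay.name}/{k}"
                cache = self._opt_cache.get(key)
                if cache is None:
                    cache = np.zeros_like(lay.params[k])
                cache = s.rmsprop_rho * cache + (1.0 - s.rmsprop_rho) * g * g
                self._opt_cache[key] = cache
                lay.params[k] -= (
                    s.learning_rate * g / (np.sqrt(cache) + s.rmsprop_eps)
                ).astype(np.float32)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def build_model(spec: ModelSpec | None = None) -> CNNLSTM:
    """Construct an untrained CNN-LSTM from a spec (defaults = published)."""
    return CNNLSTM(spec or ModelSpec())


def _ce_loss_and_dlogits(logits, y):
    p = _softmax(logits)
    n = len(y)
    eps = 1e-12
    loss = float(-np.mean(np.log(p[np.arange(n), y] + eps)))
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, (dlogits / n).astype(np.float32)


def _evaluate(model: CNNLSTM, x, y, batch_size=16):
    losses, hits, total = [], 0, 0
    for lo in range(0, len(x), batch_size):
        xb, yb = x[lo : lo + batch_size], y[lo : lo + batch_size]
        logits = model.forward_logits(xb, train=False)
        loss, _ = _ce_loss_and_dlogits(logits, yb)
        losses.append(loss * len(yb))
        hits += int((logits.argmax(axis=1) == yb).sum())
        total += len(yb)
    return float(np.sum(losses) / total), hits / total


def _shift_batch(xb: np.ndarray, shifts: np.ndarray) -> np.ndarray:
    """Shift whole videos by integer (dx, dy), zero-filling vacated pixels."""
    out = np.zeros_like(xb)
    h, w = xb.shape[2], xb.shape[3]
    for i, (dx, dy) in enumerate(shifts):
        src_r = slice(max(0, -dy), min(h, h - dy))
        dst_r = slice(max(0, dy), min(h, h + dy))
        src_c = slice(max(0, -dx), min(w, w - dx))
        dst_c = slice(max(0, dx), min(w, w + dx))
        out[i, :, dst_r, dst_c, :] = xb[i, :, src_r, src_c, :]
    return out


def train_model(
    model: CNNLSTM,
    train: Tuple[np.ndarray, np.ndarray],
    val: Tuple[np.ndarray, np.ndarray],
    cfg: TrainConfig | None = None,
) -> Tuple[CNNLSTM, Dict[str, list]]:
    """Train in place; returns the model and a per-epoch history.

    History keys: loss, acc, val_loss, val_acc.  The training loss/accuracy
    are running means over the epoch's batches (data loss plus the L2
    penalty).  All randomness (shuffling, augmentation shifts, dropout)
    derives from ``cfg.seed``.
    """
    cfg = cfg or TrainConfig()
    x_tr, y_tr = train
    x_va, y_va = val
    if len(x_tr) == 0 or len(x_va) == 0:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    model.lstm.rng = rng
    history: Dict[str, list] = {"loss": [], "acc": [], "val_loss": [], "val_acc": []}
    n = len(x_tr)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        ep_loss, ep_hits = 0.0, 0
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            xb = x_tr[idx].astype(np.float32)
            yb = y_tr[idx]
            if cfg.augment and cfg.shift_augment_max > 0:
                shifts = rng.integers(
                    -cfg.shift_augment_max, cfg.shift_augment_max + 1, (len(idx), 2)
                )
                xb = _shift_batch(xb, shifts)
            logits = model.forward_logits(xb, train=True)
            loss, dlogits = _ce_loss_and_dlogits(logits, yb)
            if not np.all(np.isfinite(logits)):
                raise TrainingDivergedError(
                    f"non-finite logits at epoch {epoch}, "
                    f"batch {lo // cfg.batch_size}"
                )
            model.backward_from_logits(dlogits)
            loss += model._reg_loss_and_grads()
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, batch {lo // cfg.batch_size}: "
                    f"loss={loss}, logit range=({logits.min()}, {logits.max()})"
                )
            model.rmsprop_step()
            ep_loss += loss * len(idx)
            ep_hits += int((logits.argmax(axis=1) == yb).sum())
        val_loss, val_acc = _evaluate(model, x_va, y_va, cfg.batch_size)
        history["loss"].append(ep_loss / n)
        history["acc"].append(ep_hits / n)
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
    return model, history


def predict_proba(model: CNNLSTM, x: np.ndarray) -> np.ndarray:
    """Cognate-class probability for each video in ``x``."""
    return model.predict_proba(x)


def save_model(model: CNNLSTM, path: str | Path) -> None:
    """Serialize spec, weights, batch-norm statistics and optimizer cache."""
    arrays = {}
    for lay in model.all_layers:
        for k, v in lay.params.items():
            arrays[f"param/{lay.name}/{k}"] = v
        if isinstance(lay, BatchNorm):
            arrays[f"stat/{lay.name}/running_mean"] = lay.running_mean
            arrays[f"stat/{lay.name}/running_var"] = lay.running_var
    for k, v in model._opt_cache.items():
        arrays[f"opt/{k}"] = v
    np.savez(path, spec=np.frombuffer(model.spec.to_json().encode(), dtype=np.uint8), **arrays)


def load_model(path: str | Path) -> CNNLSTM:
    """Rebuild a model saved by :func:`save_model`; predictions are bit-identical."""
    with np.load(path) as data:
        spec = ModelSpec.from_json(bytes(data["spec"]).decode())
        model = CNNLSTM(spec)
        for lay in model.all_layers:
            for k in lay.params:
                lay.params[k] = data[f"param/{lay.name}/{k}"].copy()
            if isinstance(lay, BatchNorm):
                lay.running_mean = data[f"stat/{lay.name}/running_mean"].copy()
                lay.running_var = data[f"stat/{lay.name}/running_var"].copy()
        for key in data.files:
            if key.startswith("opt/"):
                model._opt_cache[key[4:]] = data[key].copy()
    return model
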