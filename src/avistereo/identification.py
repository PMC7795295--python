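"""Bird / non-bird identification network and evaluation metrics.

The classifier is a compact convolutional network operating on the
100 x 100 x 3 crops produced by the detector:

    conv(32, 3x3) + ReLU -> maxpool(2x2)
    conv(32, 3x3) + ReLU -> maxpool(2x2)
    dense(128) + ReLU -> dense(2) + softmax

trained with two-class cross-entropy under Adam.  It is implemented
directly in numpy (im2col + GEMM for the convolutions), which keeps the
package dependency-light and the arithmetic fully deterministic under a
seed.  Label 1 means *bird*.

Evaluation uses the standard confusion-matrix ratios: precision, recall,
F1, specificity and accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CnnConfig",
    "ConfusionCounts",
    "MetricsReport",
    "BirdCnn",
    "build_model",
    "train_model",
    "classify_crop",
    "confusion_counts",
    "compute_metrics",
]


@dataclass(frozen=True)
class CnnConfig:
    """Architecture and training hyper-parameters.

    Defaults follow the deployed configuration: 32/32 convolutional
    filters, 128 fully-connected neurons, 3x3 kernels, 2x2 max pooling,
    Adam with epsilon 1e-7 and learning rate 1e-5, 50 epochs, 10%
    validation split.  Small synthetic runs typically shorten the
    schedule and raise the learning rate (see ``fit`` arguments).
    """

    lc1: int = 32
    lc2: int = 32
    lfc1: int = 128
    n_classes: int = 2
    kernel: int = 3
    pool: int = 2
    learning_rate: float = 1e-5
    adam_epsilon: float = 1e-7
    epochs: int = 50
    validation_split: float = 0.1
    batch_size: int = 64
    input_size: int = 100
    input_channels: int = 3

    def __post_init__(self) -> None:
        for attr in ("lc1", "lc2", "lfc1", "n_classes", "kernel", "pool"):
            if getattr(self, attr) < 1:
                raise ValueError(f"CnnConfig.{attr} must be >= 1")
        if not 0 < self.validation_split < 1:
            raise ValueError("validation_split must be in (0, 1)")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    precision: float
    recall: float
    f1: float
    specificity: float
    accuracy: float


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Confusion counts with label 1 = bird (positive class)."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
    )


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Precision, recall, F1, specificity and accuracy from counts.

    A ratio whose denominator is zero is reported as ``nan``; all-zero
    counts raise, since no metric is then defined.
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    precision = ratio(c.tp, c.tp + c.fp)
    recall = ratio(c.tp, c.tp + c.fn)
    f1 = ratio(2 * c.tp, 2 * c.tp + c.fn + c.fp)
    specificity = ratio(c.tn, c.tn + c.fp)
    accuracy = ratio(c.tp + c.tn, c.total)
    return MetricsReport(precision, recall, f1, specificity, accuracy)


# ---------------------------------------------------------------------------
# numpy CNN internals

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, H, W, C) -> (N * oh * ow, k * k * C) patch matrix (valid conv)."""
    n, h, w, c = x.shape
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
    # win: (N, oh, ow, C, k, k) -> (N, oh, ow, k, k, C)
    win = win.transpose(0, 1, 2, 4, 5, 3)
    oh, ow = h - k + 1, w - k + 1
    return np.ascontiguousarray(win).reshape(n * oh * ow, k * k * c)


def _conv_forward(x, w, b, k):
    n, h, wd, c = x.shape
    oh, ow = h - k + 1, wd - k + 1
    cols = _im2col(x, k)
    out = cols @ w + b
    return out.reshape(n, oh, ow, -1), cols


def _conv_backward_params(cols, dout):
    f = dout.shape[-1]
    dflat = dout.reshape(-1, f)
    return cols.T @ dflat, dflat.sum(axis=0)


def _conv_backward_input(dout, w, k, in_shape):
    """Full correlation of dout with the flipped kernel, via im2col."""
    n, h, wd, c = in_shape
    f = w.shape[1]
    pad = k - 1
    dpad = np.pad(dout, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    cols = _im2col(dpad, k)  # (N*h*wd, k*k*F)
    # rearrange w (k*k*C, F) -> flipped (k*k*F, C)
    w4 = w.reshape(k, k, c, f)[::-1, ::-1]  # spatial flip
    wmat = w4.transpose(0, 1, 3, 2).reshape(k * k * f, c)
    dx = cols @ wmat
    return dx.reshape(n, h, wd, c)


def _pool_forward(x, p):
    n, h, w, c = x.shape
    oh, ow = h // p, w // p
    xv = x[:, : oh * p, : ow * p, :].reshape(n, oh, p, ow, p, c)
    out = xv.max(axis=(2, 4))
    return out, xv


def _pool_backward(dout, xv, out, p, in_shape):
    # gradient split evenly among tied maxima (a valid subgradient,
    # deterministic, and much cheaper than argmax bookkeeping)
    n, h, w, c = in_shape
    oh, ow = h // p, w // p
    mask = xv == out[:, :, None, :, None, :]
    counts = mask.sum(axis=(2, 4), keepdims=True)
    dxv = mask * (dout[:, :, None, :, None, :] / counts)
    dx = np.zeros(in_shape, dtype=dout.dtype)
    dx[:, : oh * p, : ow * p, :] = dxv.reshape(n, oh * p, ow * p, c)
    return dx


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class BirdCnn:
    """The crop classifier.  Build with :func:`build_model` or directly."""

    def __init__(self, cfg: CnnConfig | None = None, seed: int = 0):
        self.cfg = cfg or CnnConfig()
        self.seed = seed
        self._init_weights(np.random.default_rng(seed))
        self._adam_state = None

    # -- weights ----------------------------------------------------------
    def _init_weights(self, rng: np.random.Generator) -> None:
        cfg = self.cfg
        k, p = cfg.kernel, cfg.pool
        s = cfg.input_size
        c0 = cfg.input_channels
        s1 = (s - k + 1) // p            # after conv1+pool1
        s2 = (s1 - k + 1) // p           # after conv2+pool2
        self._flat = s2 * s2 * cfg.lc2
        self._shapes = (s, s1, s2)

        def he(shape, fan_in):
            return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(
                np.float32
            )

        self.params = {
            "w1": he((k * k * c0, cfg.lc1), k * k * c0),
            "b1": np.zeros(cfg.lc1, dtype=np.float32),
            "w2": he((k * k * cfg.lc1, cfg.lc2), k * k * cfg.lc1),
            "b2": np.zeros(cfg.lc2, dtype=np.float32),
            "w3": he((self._flat, cfg.lfc1), self._flat),
            "b3": np.zeros(cfg.lfc1, dtype=np.float32),
            "w4": he((cfg.lfc1, cfg.n_classes), cfg.lfc1),
            "b4": np.zeros(cfg.n_classes, dtype=np.float32),
        }

    @property
    def n_parameters(self) -> int:
        return sum(v.size for v in self.params.values())

    # -- forward / backward ------------------------------------------------
    def _prepare(self, x: np.ndarray) -> np.ndarray:
        cfg = self.cfg
        x = np.asarray(x)
        if x.ndim == 3:
            x = x[None]
        expected = (cfg.input_size, cfg.input_size, cfg.input_channels)
        if x.ndim != 4 or x.shape[1:] != expected:
            raise ValueError(f"expected crops of shape {expected}, got {x.shape[1:]}")
        if x.dtype == np.uint8 or x.max() > 1.5:
            x = x.astype(np.float32) / 255.0
        return np.ascontiguousarray(x, dtype=np.float32)

    def _forward(self, x: np.ndarray, need_cache: bool):
        p = self.params
        k, pool = self.cfg.kernel, self.cfg.pool
        z1, cols1 = _conv_forward(x, p["w1"], p["b1"], k)
        a1 = np.maximum(z1, 0)
        m1, xv1 = _pool_forward(a1, pool)
        z2, cols2 = _conv_forward(m1, p["w2"], p["b2"], k)
        a2 = np.maximum(z2, 0)
        m2, xv2 = _pool_forward(a2, pool)
        flat = m2.reshape(len(x), -1)
        z3 = flat @ p["w3"] + p["b3"]
        a3 = np.maximum(z3, 0)
        z4 = a3 @ p["w4"] + p["b4"]
        probs = _softmax(z4)
        cache = None
        if need_cache:
            cache = (x, cols1, z1, a1.shape, m1, xv1, cols2, z2, a2.shape,
                     m2, xv2, flat, z3, a3)
        return probs, cache

    def _backward(self, probs, y_onehot, cache):
        (x, cols1, z1, a1shape, m1, xv1, cols2, z2, a2shape,
         m2, xv2, flat, z3, a3) = cache
        p = self.params
        k, pool = self.cfg.kernel, self.cfg.pool
        n = len(x)
        g = {}
        dz4 = (probs - y_onehot).astype(np.float32) / n
        g["w4"] = a3.T @ dz4
        g["b4"] = dz4.sum(axis=0)
        da3 = dz4 @ p["w4"].T
        dz3 = da3 * (z3 > 0)
        g["w3"] = flat.T @ dz3
        g["b3"] = dz3.sum(axis=0)
        dflat = dz3 @ p["w3"].T
        dm2 = dflat.reshape(m2.shape)
        da2 = _pool_backward(dm2, xv2, m2, pool, a2shape)
        dz2 = da2 * (z2 > 0)
        g["w2"], g["b2"] = _conv_backward_params(cols2, dz2)
        dm1 = _conv_backward_input(dz2, p["w2"], k, m1.shape)
        da1 = _pool_backward(dm1, xv1, m1, pool, a1shape)
        dz1 = da1 * (z1 > 0)
        g["w1"], g["b1"] = _conv_backward_params(cols1, dz1)
        return g

    # -- training ----------------------------------------------------------
    def fit(
        self,
        crops: np.ndarray,
        labels: np.ndarray,
        epochs: int | None = None,
        learning_rate: float | None = None,
        seed: int | None = None,
        validation_split: float | None = None,
    ) -> pd.DataFrame:
        """Train on labelled crops; returns a per-epoch history frame
        with columns loss / accuracy / val_loss / val_accuracy.

        Deterministic under a fixed ``seed`` (shuffling and the
        validation split both derive from it).
        """
        cfg = self.cfg
        epochs = cfg.epochs if epochs is None else epochs
        lr = cfg.learning_rate if learning_rate is None else learning_rate
        vsplit = cfg.validation_split if validation_split is None else validation_split
        labels = np.asarray(labels).astype(int)
        if len(np.unique(labels)) < 2:
            raise ValueError("training data must contain at least two classes")
        x = self._prepare(crops)
        rng = np.random.default_rng(self.seed if seed is None else seed)

        n = len(x)
        perm = rng.permutation(n)
        n_val = max(1, int(round(n * vsplit)))
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        xt, yt = x[tr_idx], labels[tr_idx]
        xv, yv = x[val_idx], labels[val_idx]

        if self._adam_state is None:
            self._adam_state = {
                key: (np.zeros_like(v), np.zeros_like(v))
                for key, v in self.params.items()
            }
        beta1, beta2 = 0.9, 0.999
        step = 0
        eye = np.eye(cfg.n_classes, dtype=np.float32)
        history = []
        for _ in range(int(epochs)):
            order = rng.permutation(len(xt))
            losses, correct = [], 0
            for start in range(0, len(xt), cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb, yb = xt[idx], yt[idx]
                probs, cache = self._forward(xb, need_cache=True)
                losses.append(
                    float(-np.log(np.clip(probs[np.arange(len(yb)), yb], 1e-12, 1)).mean())
                    * len(yb)
                )
                correct += int((probs.argmax(axis=1) == yb).sum())
                grads = self._backward(probs, eye[yb], cache)
                step += 1
                for key, grad in grads.items():
                    m, v = self._adam_state[key]
                    m *= beta1
                    m += (1 - beta1) * grad
                    v *= beta2
                    v += (1 - beta2) * grad * grad
                    mhat = m / (1 - beta1**step)
                    vhat = v / (1 - beta2**step)
                    self.params[key] -= lr * mhat / (np.sqrt(vhat) + cfg.adam_epsilon)
            vloss, vacc = self._evaluate(xv, yv)
            history.append(
                {
                    "loss": sum(losses) / len(xt),
                    "accuracy": correct / len(xt),
                    "val_loss": vloss,
                    "val_accuracy": vacc,
                }
            )
        return pd.DataFrame(history)

    def _evaluate(self, x, y, batch: int = 64) -> tuple[float, float]:
        loss, correct = 0.0, 0
        for start in range(0, len(x), batch):
            probs, _ = self._forward(x[start : start + batch], need_cache=False)
            yb = y[start : start + batch]
            loss += float(
                -np.log(np.clip(probs[np.arange(len(yb)), yb], 1e-12, 1)).sum()
            )
            correct += int((probs.argmax(axis=1) == yb).sum())
        return loss / len(x), correct / len(x)

    # -- inference ---------------------------------------------------------
    def predict_proba(self, crops: np.ndarray, batch: int = 64) -> np.ndarray:
        x = self._prepare(crops)
        out = []
        for start in range(0, len(x), batch):
            probs, _ = self._forward(x[start : start + batch], need_cache=False)
            out.append(probs)
        return np.concatenate(out)

    def predict(self, crops: np.ndarray) -> np.ndarray:
        return self.predict_proba(crops).argmax(axis=1)

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        meta = {f"cfg_{k}": v for k, v in vars(self.cfg).items()}
        np.savez(path, seed=self.seed, **meta, **self.params)

    @classmethod
    def load(cls, path) -> "BirdCnn":
        data = np.load(path)
        cfg_kwargs = {}
        for key in data.files:
            if key.startswith("cfg_"):
                val = data[key].item()
                cfg_kwargs[key[4:]] = val
        model = cls(CnnConfig(**cfg_kwargs), seed=int(data["seed"]))
        for key in model.params:
            model.params[key] = data[key].astype(np.float32)
        return model


def build_model(cfg: CnnConfig | None = None, seed: int = 0) -> BirdCnn:
    return BirdCnn(cfg, seed=seed)


def train_model(model: BirdCnn, crops, labels, **kwargs) -> pd.DataFrame:
    return model.fit(crops, labels, **kwargs)


def classify_crop(model: BirdCnn, crop: np.ndarray) -> float:
    """Probability that a single 100x100x3 crop is a bird."""
    return float(model.predict_proba(crop)[0, 1])
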