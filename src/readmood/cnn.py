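"""The proposed compact CNN for log-Mel segment classification.

Architecture: four convolution blocks (3x3 kernels, 16/32/64/32 channels,
ReLU, 2x2 max-pooling), then flatten -> dense 128 -> dense 64 (ReLU, 0.5
dropout after each) -> dense 1 with a sigmoid, trained with Adam at 1e-3
on binary cross-entropy, batch size 32, up to 20 epochs with early
stopping on validation accuracy and best-weight restoration.

Two pooling-stride conventions are supported: ``halve`` (stride (2, 2) on
both axes, the default — a 64x200 input shrinks to 4x12 maps) and
``literal`` (stride (1, 2): stride 1 on the mel axis, 2 on time).

The implementation is pure NumPy with activations kept channels-last
(batch, mel, time, channel): same-padded convolutions run as a single
GEMM over stacked kernel shifts, the input gradient as the transposed
GEMM scattered back through the same shifts, and the optimizer is a
standard Adam.  Inference is deterministic (dropout inactive); training
is reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .spectro import LogMelSegment

__all__ = [
    "CnnArchitecture",
    "TrainConfig",
    "SmallCnn",
    "build_cnn",
    "train_cnn",
    "predict_segments",
    "segments_to_array",
    "standardize_segments",
]


@dataclass(frozen=True)
class CnnArchitecture:
    input_shape: tuple[int, int] = (64, 200)      # (mel bands, frames)
    conv_channels: tuple[int, ...] = (16, 32, 64, 32)
    kernel: int = 3
    pool_window: tuple[int, int] = (2, 2)
    pool_stride_mode: str = "halve"               # "halve" or "literal"
    dense_units: tuple[int, ...] = (128, 64)
    dropout: float = 0.5

    def __post_init__(self) -> None:
        if self.pool_stride_mode not in ("halve", "literal"):
            raise ValueError("pool_stride_mode must be 'halve' or 'literal'")
        if not (0.0 <= self.dropout <= 1.0):
            raise ValueError("dropout must lie in [0, 1]")

    @property
    def pool_stride(self) -> tuple[int, int]:
        return (2, 2) if self.pool_stride_mode == "halve" else (1, 2)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 1e-3
    patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


def _pooled_size(n: int, window: int, stride: int) -> int:
    return (n - window) // stride + 1


def _shifts(k: int):
    return [(i, j) for i in range(k) for j in range(k)]


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """Channels-last (B,H,W,C) -> (B*H*W, k*k*C), same padding.

    Built by stacking the k*k shifted views of the padded input, so each
    copy runs along long contiguous (time, channel) runs and the final
    reshape is free.
    """
    b, h, w, c = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    cols = np.empty((b, h, w, k * k, c), dtype=np.float32)
    for s, (i, j) in enumerate(_shifts(k)):
        cols[:, :, :, s, :] = xp[:, i:i + h, j:j + w, :]
    return cols.reshape(b * h * w, k * k * c)


class SmallCnn:
    """Weights, forward/backward passes and Adam state for the CNN."""

    def __init__(self, arch: CnnArchitecture, seed: int = 0) -> None:
        self.arch = arch
        rng = np.random.default_rng(seed)
        h, w = arch.input_shape
        k = arch.kernel
        sh, sw = arch.pool_stride
        ph, pw = arch.pool_window
        self.params: dict[str, np.ndarray] = {}
        self._conv_in: list[int] = []
        c_in = 1
        for i, c_out in enumerate(arch.conv_channels):
            fan_in = c_in * k * k
            self.params[f"Wc{i}"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in),
                size=(fan_in, c_out)).astype(np.float32)
            self.params[f"bc{i}"] = np.zeros(c_out, dtype=np.float32)
            self._conv_in.append(c_in)
            c_in = c_out
            h, w = _pooled_size(h, ph, sh), _pooled_size(w, pw, sw)
            if h < 1 or w < 1:
                raise ValueError("pooled feature map collapsed below 1x1")
        self.flat_dim = h * w * c_in
        d_in = self.flat_dim
        for j, d_out in enumerate(arch.dense_units):
            self.params[f"Wd{j}"] = rng.normal(
                0.0, np.sqrt(2.0 / d_in),
                size=(d_in, d_out)).astype(np.float32)
            self.params[f"bd{j}"] = np.zeros(d_out, dtype=np.float32)
            d_in = d_out
        self.params["Wout"] = rng.normal(
            0.0, np.sqrt(1.0 / d_in), size=(d_in, 1)).astype(np.float32)
        self.params["bout"] = np.zeros(1, dtype=np.float32)
        self._adam_m = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self._adam_v = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self._adam_t = 0

    # ---------------------------------------------------------------- info
    def parameter_count(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def layer_summary(self) -> list[tuple[str, tuple, int]]:
        return [(name, tuple(v.shape), int(v.size))
                for name, v in self.params.items()]

    # ------------------------------------------------------------- pooling
    def _pool(self, x: np.ndarray):
        """Max pool on (B,H,W,C); returns output plus backward context."""
        ph, pw = self.arch.pool_window
        sh, sw = self.arch.pool_stride
        b, h, w, c = x.shape
        if (sh, sw) == (ph, pw) == (2, 2):
            h2, w2 = h // 2, w // 2
            r = x[:, :h2 * 2, :w2 * 2, :].reshape(b, h2, 2, w2, 2, c)
            top, bot = r[:, :, 0], r[:, :, 1]          # (b,h2,w2,2,c)
            ah = bot > top                             # row offset per column
            m1 = np.maximum(top, bot)
            left, right = m1[:, :, :, 0], m1[:, :, :, 1]
            aw = right > left                          # winning column
            out = np.maximum(left, right)
            ah_sel = np.where(aw, ah[:, :, :, 1], ah[:, :, :, 0])
            return out, ("fast", ah_sel, aw, x.shape)
        wins = sliding_window_view(x, (ph, pw), axis=(1, 2))[:, ::sh, ::sw]
        b, ho, wo, c = wins.shape[:4]
        flat = wins.reshape(b, ho, wo, c, ph * pw)
        arg = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        return np.ascontiguousarray(out), ("slow", arg, None, x.shape)

    def _pool_backward(self, dy: np.ndarray, ctx) -> np.ndarray:
        ph, pw = self.arch.pool_window
        sh, sw = self.arch.pool_stride
        kind, a, a2, x_shape = ctx
        b, h, w, c = x_shape
        dx = np.zeros(b * h * w * c, dtype=dy.dtype)
        if kind == "fast":
            bo, h2, w2, co = dy.shape
            bi, hi, wi, ci = np.indices((bo, h2, w2, co), sparse=True)
            rows = hi * 2 + a                          # a: bool row offsets
            cols = wi * 2 + a2                         # a2: bool col offsets
            idx = (((bi * h + rows) * w + cols) * c + ci).ravel()
            dx[idx] = dy.ravel()                      # windows disjoint
        else:
            bo, ho, wo, co = dy.shape
            bi, hi, wi, ci = np.indices((bo, ho, wo, co), sparse=True)
            rows = hi * sh + a // pw
            cols = wi * sw + a % pw
            idx = (((bi * h + rows) * w + cols) * c + ci).ravel()
            np.add.at(dx, idx, dy.ravel())            # windows may overlap
        return dx.reshape(x_shape)

    # ------------------------------------------------------------- forward
    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None):
        """Logits for a (B, H, W, 1) float32 batch; caches for backward."""
        arch = self.arch
        k = arch.kernel
        cache: dict = {"cols": [], "relu": [], "pool": [],
                       "drop": [], "dense_in": []}
        out = x.astype(np.float32, copy=False)
        for i in range(len(arch.conv_channels)):
            b, h, w, _ = out.shape
            cols = _im2col(out, k)
            z = cols @ self.params[f"Wc{i}"] + self.params[f"bc{i}"]
            z = z.reshape(b, h, w, -1)
            mask = z > 0
            out = z * mask
            out, ctx = self._pool(out)
            cache["cols"].append(cols)
            cache["relu"].append(mask)
            cache["pool"].append(ctx)
        b = out.shape[0]
        out = out.reshape(b, -1)
        for j in range(len(arch.dense_units)):
            cache["dense_in"].append(out)
            z = out @ self.params[f"Wd{j}"] + self.params[f"bd{j}"]
            mask = z > 0
            out = z * mask
            cache["relu"].append(mask)
            if train and arch.dropout > 0:
                keep = 1.0 - arch.dropout
                drop = ((rng.random(out.shape) < keep)
                        .astype(np.float32) / np.float32(keep))
                out = out * drop
                cache["drop"].append(drop)
            else:
                cache["drop"].append(None)
        cache["dense_in"].append(out)
        logits = (out @ self.params["Wout"] + self.params["bout"])[:, 0]
        return logits, cache

    def predict_proba(self, x: np.ndarray,
                      batch_size: int = 16) -> np.ndarray:
        probs = []
        for lo in range(0, len(x), batch_size):
            logits, _ = self.forward(x[lo:lo + batch_size], train=False)
            probs.append(1.0 / (1.0 + np.exp(-logits)))
        return np.concatenate(probs) if probs else np.empty(0)

    # ------------------------------------------------------------ backward
    def backward(self, dlogits: np.ndarray, cache: dict
                 ) -> dict[str, np.ndarray]:
        arch = self.arch
        k = arch.kernel
        p = k // 2
        grads: dict[str, np.ndarray] = {}
        d = dlogits[:, None].astype(np.float32)
        out_in = cache["dense_in"][-1]
        grads["Wout"] = out_in.T @ d
        grads["bout"] = d.sum(axis=0)
        d = d @ self.params["Wout"].T
        n_dense = len(arch.dense_units)
        n_conv = len(arch.conv_channels)
        for j in reversed(range(n_dense)):
            if cache["drop"][j] is not None:
                d = d * cache["drop"][j]
            d = d * cache["relu"][n_conv + j]
            x_in = cache["dense_in"][j]
            grads[f"Wd{j}"] = x_in.T @ d
            grads[f"bd{j}"] = d.sum(axis=0)
            d = d @ self.params[f"Wd{j}"].T
        for i in reversed(range(n_conv)):
            ctx = cache["pool"][i]
            if i == n_conv - 1:
                # undo the flatten: back to the pooled map's (B,H2,W2,C)
                b, h, w, _ = ctx[3]
                ph, pw = arch.pool_window
                sh, sw = arch.pool_stride
                d = d.reshape(b, _pooled_size(h, ph, sh),
                              _pooled_size(w, pw, sw), -1)
            d = self._pool_backward(d, ctx)
            d = d * cache["relu"][i]
            b, h, w, c = d.shape
            d_flat = d.reshape(b * h * w, c)
            grads[f"Wc{i}"] = cache["cols"][i].T @ d_flat
            grads[f"bc{i}"] = d_flat.sum(axis=0)
            if i > 0:
                # input gradient: transposed conv as one GEMM plus
                # scatter-adds of the k*k shift blocks
                c_in = self._conv_in[i]
                g = (d_flat @ self.params[f"Wc{i}"].T).reshape(
                    b, h, w, k * k, c_in)
                dxp = np.zeros((b, h + 2 * p, w + 2 * p, c_in),
                               dtype=np.float32)
                for s, (si, sj) in enumerate(_shifts(k)):
                    dxp[:, si:si + h, sj:sj + w, :] += g[:, :, :, s, :]
                d = dxp[:, p:p + h, p:p + w, :]
        return grads

    # ------------------------------------------------------------- updates
    def adam_step(self, grads: dict[str, np.ndarray],
                  lr: float = 1e-3, beta1: float = 0.9,
                  beta2: float = 0.999, eps: float = 1e-8) -> None:
        self._adam_t += 1
        t = self._adam_t
        for name, g in grads.items():
            m = self._adam_m[name]
            v = self._adam_v[name]
            m += (1 - beta1) * (g - m)
            v += (1 - beta2) * (g * g - v)
            mhat = m / (1 - beta1 ** t)
            vhat = v / (1 - beta2 ** t)
            self.params[name] -= (lr * mhat /
                                  (np.sqrt(vhat) + eps)).astype(np.float32)

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k_: v.copy() for k_, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        self.params = {k_: v.copy() for k_, v in params.items()}


def build_cnn(arch: CnnArchitecture = CnnArchitecture(),
              seed: int = 0) -> SmallCnn:
    """Instantiate the CNN with He-initialized weights."""
    return SmallCnn(arch, seed=seed)


def save_checkpoint(model: SmallCnn, directory) -> None:
    """Write architecture JSON + weight arrays to ``directory``."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "architecture.json", "w") as fh:
        json.dump(asdict(model.arch), fh, indent=2)
    np.savez(directory / "weights.npz", **model.params)


def load_checkpoint(directory) -> SmallCnn:
    """Rebuild a model from :func:`save_checkpoint` output."""
    import json
    from pathlib import Path

    directory = Path(directory)
    with open(directory / "architecture.json") as fh:
        raw = json.load(fh)
    arch = CnnArchitecture(
        input_shape=tuple(raw["input_shape"]),
        conv_channels=tuple(raw["conv_channels"]),
        kernel=raw["kernel"],
        pool_window=tuple(raw["pool_window"]),
        pool_stride_mode=raw["pool_stride_mode"],
        dense_units=tuple(raw["dense_units"]),
        dropout=raw["dropout"])
    model = SmallCnn(arch, seed=0)
    with np.load(directory / "weights.npz") as data:
        model.set_params({k: data[k] for k in data.files})
    return model


def standardize_segments(x: np.ndarray) -> np.ndarray:
    """Per-segment z-score, applied identically at train and inference."""
    x = x.astype(np.float32, copy=True)
    flat = x.reshape(len(x), -1)
    mean = flat.mean(axis=1, keepdims=True)
    std = flat.std(axis=1, keepdims=True)
    flat -= mean
    flat /= std + 1e-6
    return x


def segments_to_array(segments: list[LogMelSegment]
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Stack segments into a standardized (N, H, W, 1) batch plus labels."""
    x = np.stack([s.values for s in segments]).astype(np.float32)
    x = standardize_segments(x)[:, :, :, None]
    y = np.array([s.label for s in segments], dtype=np.float32)
    return x, y


def _bce_and_grad(logits: np.ndarray, y: np.ndarray):
    loss = float(np.mean(np.logaddexp(0.0, logits) - y * logits))
    probs = 1.0 / (1.0 + np.exp(-logits))
    return loss, (probs - y) / len(y)


def train_cnn(model: SmallCnn,
              train_x: np.ndarray, train_y: np.ndarray,
              val_x: np.ndarray, val_y: np.ndarray,
              config: TrainConfig = TrainConfig()) -> dict:
    """Minibatch Adam training with early stopping on validation accuracy.

    Returns a history dict with per-epoch train loss/accuracy and
    validation accuracy; the model is left holding the best-validation
    weights.  Raises on a single-class training set.
    """
    classes = np.unique(train_y)
    if len(classes) < 2:
        raise ValueError("training data must contain both classes")
    rng = np.random.default_rng(config.seed)
    history = {"train_loss": [], "train_acc": [], "val_acc": []}
    best_acc, best_params, bad = -np.inf, model.copy_params(), 0
    n = len(train_x)
    for _epoch in range(config.epochs):
        perm = rng.permutation(n)
        losses, correct = [], 0
        for lo in range(0, n, config.batch_size):
            idx = perm[lo:lo + config.batch_size]
            xb, yb = train_x[idx], train_y[idx]
            logits, cache = model.forward(xb, train=True, rng=rng)
            loss, dlogits = _bce_and_grad(logits, yb)
            grads = model.backward(dlogits, cache)
            model.adam_step(grads, lr=config.learning_rate)
            losses.append(loss * len(idx))
            correct += int(np.sum((logits > 0) == (yb > 0.5)))
        val_probs = model.predict_proba(val_x)
        val_acc = float(np.mean((val_probs >= 0.5) == (val_y > 0.5)))
        history["train_loss"].append(sum(losses) / n)
        history["train_acc"].append(correct / n)
        history["val_acc"].append(val_acc)
        if val_acc > best_acc:
            best_acc, best_params, bad = val_acc, model.copy_params(), 0
        else:
            bad += 1
            if bad >= config.patience:
                break
    model.set_params(best_params)
    return history


def predict_segments(model: SmallCnn,
                     segments: list[LogMelSegment]) -> np.ndarray:
    """Per-segment probabilities, deterministic and order-preserving."""
    if not segments:
        return np.empty(0)
    expected = model.arch.input_shape
    for s in segments:
        if s.values.shape != expected:
            raise ValueError("segment shape does not match the architecture")
    x, _ = segments_to_array(segments)
    return model.predict_proba(x)
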