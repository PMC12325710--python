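"""Fourier-domain classification network implemented in numpy.

Each spectral block takes the 2-D Fourier transform of the feature map,
applies a learnable per-frequency complex scaling, transforms back, passes
through a GELU nonlinearity and a 1x1 convolutional channel-mixing layer,
then halves the spatial resolution. A global-average-pooling head reduces
the final feature map to an n_classes logit vector.

Gradients are derived analytically (the spectral layer's adjoint is again a
Fourier multiply) and validated against finite differences in the test
suite, so the whole model trains on CPU without an autograd framework.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.special import erf

from ..errors import InvalidConfigError, ShapeError

_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


def gelu(x: np.ndarray) -> np.ndarray:
    return 0.5 * x * (1.0 + erf(x * _INV_SQRT2))


def gelu_grad(x: np.ndarray) -> np.ndarray:
    phi = _INV_SQRT2PI * np.exp(-0.5 * x * x)
    return 0.5 * (1.0 + erf(x * _INV_SQRT2)) + x * phi


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass(frozen=True)
class ClassifierConfig:
    n_classes: int = 4
    input_size: int = 512
    in_channels: int = 15
    n_fourier_blocks: int = 3
    widths: tuple[int, ...] = (32, 64, 64)
    stem_pool: bool = True
    block_pool: bool = True
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.n_classes not in (2, 4):
            raise InvalidConfigError("n_classes must be 2 or 4")
        if len(self.widths) != self.n_fourier_blocks:
            raise InvalidConfigError("widths must list one entry per block")
        if self.input_size < 4:
            raise InvalidConfigError("input_size too small")
        res = self.input_size // (2 if self.stem_pool else 1)
        for _ in range(self.n_fourier_blocks):
            if res < 2:
                raise InvalidConfigError("too many blocks for this input size")
            if self.block_pool:
                res //= 2

    def to_dict(self) -> dict:
        return {"n_classes": self.n_classes, "input_size": self.input_size,
                "in_channels": self.in_channels,
                "n_fourier_blocks": self.n_fourier_blocks,
                "widths": list(self.widths), "stem_pool": self.stem_pool,
                "block_pool": self.block_pool, "seed": self.seed,
                "dtype": self.dtype}

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifierConfig":
        d = dict(d)
        d["widths"] = tuple(d["widths"])
        return cls(**d)


@dataclass
class Prediction:
    """Class-probability vector with its argmax score and confidence."""

    probabilities: np.ndarray
    score: int
    ci: float

    @classmethod
    def from_probabilities(cls, probs: np.ndarray) -> "Prediction":
        probs = np.asarray(probs, dtype=np.float64)
        # np.argmax resolves ties to the lowest index, as documented
        return cls(probabilities=probs, score=int(np.argmax(probs)),
                   ci=float(probs.max()))


def spectral_forward(x: np.ndarray, A: np.ndarray, B: np.ndarray):
    """y = Re(ifft2(M * fft2(x))) with M = A + iB applied per frequency."""
    X = np.fft.fft2(x, axes=(-2, -1))
    M = A + 1j * B
    y = np.real(np.fft.ifft2(M[None] * X, axes=(-2, -1)))
    return y.astype(x.dtype, copy=False), (X, M)


def spectral_backward(g: np.ndarray, cache):
    """Adjoint of the spectral layer.

    With G = ifft2(g): dL/dM = conj(sum_b G_b * X_b) split into (dA, dB),
    and dL/dx = Re(fft2(G * M)).
    """
    X, M = cache
    G = np.fft.ifft2(g, axes=(-2, -1))
    GX = (G * X).sum(axis=0)
    dA = np.real(GX)
    dB = -np.imag(GX)
    gx = np.real(np.fft.fft2(G * M[None], axes=(-2, -1)))
    return gx.astype(g.dtype, copy=False), dA.astype(g.dtype), dB.astype(g.dtype)


def conv1x1_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    y = np.einsum("oc,bchw->bohw", W, x, optimize=True) + b[None, :, None, None]
    return y, x


def conv1x1_backward(g: np.ndarray, x: np.ndarray, W: np.ndarray):
    dW = np.einsum("bohw,bchw->oc", g, x, optimize=True)
    db = g.sum(axis=(0, 2, 3))
    dx = np.einsum("oc,bohw->bchw", W, g, optimize=True)
    return dx, dW, db


def avgpool2_forward(x: np.ndarray) -> np.ndarray:
    b, c, h, w = x.shape
    return x.reshape(b, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


def avgpool2_backward(g: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25


class FourierClassifier:
    """Spectral-block classifier with a GAP + linear head."""

    def __init__(self, config: ClassifierConfig) -> None:
        self.config = config
        self.dtype = np.dtype(config.dtype)
        # input standardization, fitted from the training data
        self.norm_mean = 0.0
        self.norm_std = 1.0
        rng = np.random.default_rng(config.seed)
        p: dict[str, np.ndarray] = {}

        widths = config.widths
        res = config.input_size // (2 if config.stem_pool else 1)
        p["stem_w"] = (rng.standard_normal((widths[0], config.in_channels))
                       * np.sqrt(2.0 / config.in_channels))
        p["stem_b"] = np.zeros(widths[0])
        self.block_res: list[int] = []
        for i in range(config.n_fourier_blocks):
            c_in = widths[i]
            c_out = widths[i + 1] if i + 1 < len(widths) else widths[i]
            self.block_res.append(res)
            p[f"A{i}"] = 1.0 + 0.02 * rng.standard_normal((c_in, res, res))
            p[f"B{i}"] = 0.02 * rng.standard_normal((c_in, res, res))
            p[f"conv{i}_w"] = (rng.standard_normal((c_out, c_in))
                               * np.sqrt(2.0 / c_in))
            p[f"conv{i}_b"] = np.zeros(c_out)
            if config.block_pool:
                res //= 2
        c_last = widths[-1]
        p["head_w"] = rng.standard_normal((config.n_classes, c_last)) * 0.01
        p["head_b"] = np.zeros(config.n_classes)
        self.params = {k: v.astype(self.dtype) for k, v in p.items()}

    # ------------------------------------------------------------------ #

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        if x.ndim == 3:
            x = x[None]
        s = self.config.input_size
        if x.ndim != 4 or x.shape[1] != self.config.in_channels \
                or x.shape[2] != s or x.shape[3] != s:
            raise ShapeError(
                f"expected input (B, {self.config.in_channels}, {s}, {s}), "
                f"got {x.shape}")
        return x.astype(self.dtype, copy=False)

    def forward(self, x: np.ndarray, keep_cache: bool = False):
        x = self._check_input(x)
        if self.norm_mean != 0.0 or self.norm_std != 1.0:
            x = (x - self.dtype.type(self.norm_mean)) \
                / self.dtype.type(self.norm_std)
        p = self.params
        cfg = self.config
        cache: dict = {"x0": x}

        h, _ = conv1x1_forward(x, p["stem_w"], p["stem_b"])
        if cfg.stem_pool:
            h = avgpool2_forward(h)
        cache["stem_out"] = h

        for i in range(cfg.n_fourier_blocks):
            y, sp_cache = spectral_forward(h, p[f"A{i}"], p[f"B{i}"])
            a = gelu(y)
            m, _ = conv1x1_forward(a, p[f"conv{i}_w"], p[f"conv{i}_b"])
            if cfg.block_pool:
                out = avgpool2_forward(m)
            else:
                out = m
            if keep_cache:
                cache[f"block{i}"] = (h, sp_cache, y, a)
            h = out

        b, c, hh, ww = h.shape
        feat = h.mean(axis=(2, 3))
        logits = feat @ p["head_w"].T + p["head_b"][None]
        if keep_cache:
            cache["pre_gap"] = h
            cache["feat"] = feat
        return logits, cache

    def predict_proba(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        x = self._check_input(x)
        out = []
        for i in range(0, len(x), batch_size):
            logits, _ = self.forward(x[i:i + batch_size])
            out.append(softmax(logits))
        return np.concatenate(out, axis=0)

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        """Mean cross-entropy loss and gradients for one batch."""
        logits, cache = self.forward(x, keep_cache=True)
        n = len(logits)
        probs = softmax(logits.astype(np.float64))
        eps = 1e-12
        loss = float(-np.log(probs[np.arange(n), y] + eps).mean())

        p = self.params
        cfg = self.config
        grads = {k: np.zeros_like(v) for k, v in p.items()}

        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits = (dlogits / n).astype(self.dtype)

        feat = cache["feat"]
        grads["head_w"] = dlogits.T @ feat
        grads["head_b"] = dlogits.sum(axis=0)
        dfeat = dlogits @ p["head_w"]

        h = cache["pre_gap"]
        bb, cc, hh, ww = h.shape
        g = (dfeat[:, :, None, None] / (hh * ww)) * np.ones_like(h)

        for i in reversed(range(cfg.n_fourier_blocks)):
            h_in, sp_cache, y_sp, a = cache[f"block{i}"]
            if cfg.block_pool:
                g = avgpool2_backward(g)
            g, dW, db = conv1x1_backward(g, a, p[f"conv{i}_w"])
            grads[f"conv{i}_w"] = dW
            grads[f"conv{i}_b"] = db
            g = g * gelu_grad(y_sp).astype(self.dtype)
            g, dA, dB = spectral_backward(g, sp_cache)
            grads[f"A{i}"] = dA
            grads[f"B{i}"] = dB

        if cfg.stem_pool:
            g = avgpool2_backward(g)
        _, dW, db = conv1x1_backward(g, cache["x0"], p["stem_w"])
        grads["stem_w"] = dW
        grads["stem_b"] = db
        return loss, grads

    # ------------------------------------------------------------------ #

    def fit_normalization(self, x: np.ndarray) -> None:
        """Record dataset mean/std applied to inputs at the model boundary."""
        sample = np.asarray(x[: min(len(x), 256)])
        if sample.dtype == np.uint8:
            sample = sample.astype(np.float64) / 255.0
        self.norm_mean = float(sample.mean())
        self.norm_std = float(max(sample.std(), 1e-6))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path, __config__=json.dumps(self.config.to_dict()),
                 __norm__=np.array([self.norm_mean, self.norm_std]),
                 **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "FourierClassifier":
        with np.load(Path(path), allow_pickle=False) as data:
            config = ClassifierConfig.from_dict(
                json.loads(str(data["__config__"])))
            model = cls(config)
            for k in model.params:
                model.params[k] = data[k]
            if "__norm__" in data:
                model.norm_mean, model.norm_std = map(float, data["__norm__"])
        return model


def predict_with_ci(model: FourierClassifier, stack) -> Prediction:
    """Classify one stack: probability vector, argmax score, CI = max prob."""
    from ..stacks import PatchStack  # local import to avoid a cycle

    if isinstance(stack, PatchStack):
        x = stack.as_channels()
    else:
        x = np.asarray(stack)
    probs = model.predict_proba(x[None] if x.ndim == 3 else x)[0]
    return Prediction.from_probabilities(probs)
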