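"""Minimal seeded neural-network core for 16 x 100 ERP trials.

A compact convolutional ERP decoder implemented directly in numpy with
hand-written backpropagation, so the whole pipeline runs on one CPU with no
deep-learning framework:

* feature extractor: per-channel temporal convolution (kernel 1 x 25) ->
  spatial convolution collapsing the 16 channels -> ELU -> average pooling
  -> dense 64-unit embedding;
* two heads of identical shape (hidden 32 -> 2-way softmax): a category
  classifier and a domain discriminator.  The discriminator couples to the
  extractor through a gradient-reversal layer.

Losses are *summed* (not batch-averaged) cross-entropies; the learning rate
absorbs the scale.  Inputs are z-scored per trial before the first
convolution, which removes inter-subject amplitude scale and leaves the
waveform shape to discriminate on.

Everything here is deterministic given the initialization generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EPS_PROB = 1e-12  # clamp for log-probabilities


def elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(x))


def elu_grad(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, 1.0, np.exp(np.minimum(x, 0.0)))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def one_hot(labels: np.ndarray, n_classes: int = 2) -> np.ndarray:
    out = np.zeros((labels.shape[0], n_classes))
    out[np.arange(labels.shape[0]), labels.astype(int)] = 1.0
    return out


def cross_entropy_sum(probs: np.ndarray, labels: np.ndarray) -> float:
    """Summed cross-entropy -sum_k log p_k[label_k], with epsilon clamp."""
    p = np.clip(probs[np.arange(len(labels)), labels.astype(int)], EPS_PROB, 1.0)
    return float(-np.log(p).sum())


@dataclass
class Arch:
    """Architecture hyperparameters (sizes are config-exposed)."""

    n_channels: int = 16
    n_samples: int = 100
    n_temporal: int = 8
    kernel: int = 25
    n_spatial: int = 8
    pool: int = 8
    embed: int = 64
    hidden: int = 32

    @property
    def conv_out(self) -> int:
        return self.n_samples - self.kernel + 1

    @property
    def n_frames(self) -> int:
        return self.conv_out // self.pool

    @property
    def flat(self) -> int:
        return self.n_spatial * self.n_frames


def init_params(arch: Arch, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """He-style initialization of all parameters from one generator."""

    def he(shape, fan_in):
        return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)

    a = arch
    p = {
        "W1": he((a.n_temporal, a.kernel), a.kernel),
        "b1": np.zeros(a.n_temporal),
        "W2": he((a.n_spatial, a.n_temporal, a.n_channels), a.n_temporal * a.n_channels),
        "b2": np.zeros(a.n_spatial),
        "W3": he((a.flat, a.embed), a.flat),
        "b3": np.zeros(a.embed),
    }
    for head in ("clf", "dom"):
        p[f"{head}_W1"] = he((a.embed, a.hidden), a.embed)
        p[f"{head}_b1"] = np.zeros(a.hidden)
        p[f"{head}_W2"] = he((a.hidden, 2), a.hidden)
        p[f"{head}_b2"] = np.zeros(2)
    return p


def normalize_input(x: np.ndarray) -> np.ndarray:
    """Per-trial z-score over all channels and samples."""
    mu = x.mean(axis=(1, 2), keepdims=True)
    sd = x.std(axis=(1, 2), keepdims=True)
    return (x - mu) / (sd + 1e-6)


def feature_forward(params: dict, arch: Arch, x: np.ndarray) -> tuple[np.ndarray, dict]:
    """Extractor forward pass.  Returns (features (m, embed), cache)."""
    a = arch
    xn = normalize_input(np.asarray(x, dtype=np.float64))
    # (m, C, T') windows of length kernel
    xc = np.lib.stride_tricks.sliding_window_view(xn, a.kernel, axis=2)
    h1 = np.einsum("mcts,fs->mfct", xc, params["W1"]) + params["b1"][None, :, None, None]
    h2 = np.einsum("mfct,gfc->mgt", h1, params["W2"]) + params["b2"][None, :, None]
    a2 = elu(h2)
    tp = a.n_frames * a.pool
    pooled = a2[:, :, :tp].reshape(x.shape[0], a.n_spatial, a.n_frames, a.pool).mean(axis=3)
    z = pooled.reshape(x.shape[0], a.flat)
    h3 = z @ params["W3"] + params["b3"]
    f = elu(h3)
    cache = {"xc": xc, "h1": h1, "h2": h2, "z": z, "h3": h3}
    return f, cache


def feature_backward(
    params: dict, arch: Arch, cache: dict, df: np.ndarray
) -> dict[str, np.ndarray]:
    """Gradients of all extractor parameters given d(loss)/d(features)."""
    a = arch
    m = df.shape[0]
    dh3 = df * elu_grad(cache["h3"])
    g = {
        "W3": cache["z"].T @ dh3,
        "b3": dh3.sum(axis=0),
    }
    dz = dh3 @ params["W3"].T
    dpooled = dz.reshape(m, a.n_spatial, a.n_frames)
    da2 = np.zeros_like(cache["h2"])
    tp = a.n_frames * a.pool
    da2[:, :, :tp] = np.repeat(dpooled / a.pool, a.pool, axis=2)
    dh2 = da2 * elu_grad(cache["h2"])
    g["W2"] = np.einsum("mgt,mfct->gfc", dh2, cache["h1"])
    g["b2"] = dh2.sum(axis=(0, 2))
    dh1 = np.einsum("mgt,gfc->mfct", dh2, params["W2"])
    g["W1"] = np.einsum("mfct,mcts->fs", dh1, cache["xc"])
    g["b1"] = dh1.sum(axis=(0, 2, 3))
    return g


def head_forward(
    params: dict, head: str, f: np.ndarray
) -> tuple[np.ndarray, dict]:
    """Hidden-layer + softmax head.  Returns (probs (m, 2), cache)."""
    h = f @ params[f"{head}_W1"] + params[f"{head}_b1"]
    act = elu(h)
    logits = act @ params[f"{head}_W2"] + params[f"{head}_b2"]
    probs = softmax(logits)
    return probs, {"f": f, "h": h, "act": act}


def head_backward(
    params: dict, head: str, cache: dict, dlogits: np.ndarray
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Head gradients and d(loss)/d(features)."""
    g = {
        f"{head}_W2": cache["act"].T @ dlogits,
        f"{head}_b2": dlogits.sum(axis=0),
    }
    dact = dlogits @ params[f"{head}_W2"].T
    dh = dact * elu_grad(cache["h"])
    g[f"{head}_W1"] = cache["f"].T @ dh
    g[f"{head}_b1"] = dh.sum(axis=0)
    df = dh @ params[f"{head}_W1"].T
    return g, df


@dataclass
class Adam:
    """Adam optimizer over a parameter dict."""

    lr: float = 3e-4
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    t: int = 0
    m: dict = field(default_factory=dict)
    v: dict = field(default_factory=dict)

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k, gk in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(params[k])
                self.v[k] = np.zeros_like(params[k])
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * gk
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * gk**2
            mhat = self.m[k] / (1 - self.beta1**self.t)
            vhat = self.v[k] / (1 - self.beta2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def accumulate(*grad_dicts: dict) -> dict:
    """Sum gradient dicts key-wise."""
    out: dict[str, np.ndarray] = {}
    for g in grad_dicts:
        for k, v in g.items():
            out[k] = out.get(k, 0) + v
    return out
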