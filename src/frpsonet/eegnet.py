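"""Compact convolutional network for EEG (EEGNet-8,2) in pure NumPy.

The network serves one purpose here: its *first* block — 8 temporal
filters of length 64 followed by 2 depthwise spatial filters per
temporal filter over the 19 electrodes — is a bank of learned
frequency-specific spatial filters whose post-ELU activation
(16 feature channels x 128 time instances, taken *before* average
pooling so the temporal resolution is intact) feeds the augmented
covariance pooling stage.  The full three-block classifier is trained
end-to-end only to obtain that block.

Everything is hand-implemented with explicit forward/backward passes:
FFT-based 1-D convolutions, batch normalization, ELU, average pooling,
dropout, and an Adam optimizer with class-weighted cross-entropy,
max-norm constraints on the depthwise spatial and dense kernels, and
validation-loss early stopping with best-weight restoration.
Computation is float32; all randomness (init, batch order, dropout)
flows from one seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .spdnet import class_weights  # shared loss weighting

__all__ = [
    "ConvNetConfig",
    "TrainConfig",
    "class_weights",
    "build_eegnet",
    "train_convnet",
    "extract_feature_maps",
    "EEGNet",
    "EEGNetFeatureExtractor",
]

_BN_EPS = 1e-3


@dataclass(frozen=True)
class ConvNetConfig:
    """EEGNet-8,2 architecture settings.

    ``n_temporal_filters`` (F1) kernels of ``temporal_kernel`` samples,
    ``depth_multiplier`` (S1) spatial filters per temporal filter; the
    block-1 tap therefore has D = F1 * S1 feature channels and N = T
    time instances.
    """

    n_temporal_filters: int = 8
    temporal_kernel: int = 64
    depth_multiplier: int = 2
    n_channels: int = 19
    n_samples: int = 128
    n_classes: int = 2
    dropout_p: float = 0.25
    pool1: int = 4
    pool2: int = 8
    sep_kernel: int = 16      # block-2 depthwise temporal kernel
    bn_momentum: float = 0.9  # running-statistics update rate

    def __post_init__(self) -> None:
        for name in ("n_temporal_filters", "temporal_kernel", "depth_multiplier",
                     "n_channels", "n_samples", "n_classes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")
        if self.n_samples < self.temporal_kernel:
            raise ValueError("n_samples must be >= temporal_kernel")

    @property
    def n_feature_channels(self) -> int:
        return self.n_temporal_filters * self.depth_multiplier


@dataclass(frozen=True)
class TrainConfig:
    """Adam + class-weighted cross-entropy training settings."""

    lr: float = 1e-3
    max_epochs: int = 100
    val_fraction: float = 0.2
    batch_size: int = 64
    class_weighted: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")


# --------------------------------------------------------------------------
# 1-D convolution primitives (correlation convention, FFT-based)


def _corr_valid(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """out[.., t] = sum_j x[.., t+j] * w[.., j] along the last axis."""
    return fftconvolve(x, np.flip(w, axis=-1), mode="valid", axes=-1)


def _conv_full(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    return fftconvolve(x, w, mode="full", axes=-1)


def _pad_same(x: np.ndarray, k: int) -> np.ndarray:
    left = (k - 1) // 2
    pads = [(0, 0)] * (x.ndim - 1) + [(left, k - 1 - left)]
    return np.pad(x, pads)


def _unpad_grad(dxp: np.ndarray, k: int, n: int) -> np.ndarray:
    left = (k - 1) // 2
    return dxp[..., left:left + n]


# --------------------------------------------------------------------------
# Layer helpers


def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def _elu_backward(dy: np.ndarray, y: np.ndarray, x: np.ndarray) -> np.ndarray:
    return dy * np.where(x > 0, 1.0, y + 1.0)


class _BatchNorm:
    """Per-feature-channel batch normalization (channel axis = 1)."""

    def __init__(self, n_ch: int, momentum: float):
        self.gamma = np.ones(n_ch, dtype=np.float32)
        self.beta = np.zeros(n_ch, dtype=np.float32)
        self.running_mean = np.zeros(n_ch, dtype=np.float32)
        self.running_var = np.ones(n_ch, dtype=np.float32)
        self.momentum = momentum

    def _shape(self, x: np.ndarray) -> tuple:
        return (1, -1) + (1,) * (x.ndim - 2)

    def forward(self, x: np.ndarray, train: bool):
        s = self._shape(x)
        axes = tuple(i for i in range(x.ndim) if i != 1)
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mu
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (x - mu.reshape(s)) * inv.reshape(s)
        y = self.gamma.reshape(s) * xhat + self.beta.reshape(s)
        cache = (xhat, inv, axes, s)
        return y.astype(np.float32), cache

    def backward(self, dy: np.ndarray, cache):
        xhat, inv, axes, s = cache
        dgamma = (dy * xhat).sum(axis=axes)
        dbeta = dy.sum(axis=axes)
        dxhat = dy * self.gamma.reshape(s)
        mean_dxhat = dxhat.mean(axis=axes).reshape(s)
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=axes).reshape(s)
        dx = inv.reshape(s) * (dxhat - mean_dxhat - xhat * mean_dxhat_xhat)
        return dx.astype(np.float32), dgamma.astype(np.float32), dbeta.astype(np.float32)


def _avgpool(x: np.ndarray, p: int) -> np.ndarray:
    b, c, t = x.shape
    return x.reshape(b, c, t // p, p).mean(axis=-1)


def _avgpool_backward(dy: np.ndarray, p: int) -> np.ndarray:
    return np.repeat(dy, p, axis=-1) / p


# --------------------------------------------------------------------------
# Model


class EEGNet:
    """Three-block EEGNet-8,2 with named activation taps.

    Parameters are NumPy float32 arrays; :meth:`forward` supports
    training mode (batch statistics, dropout) and inference mode
    (running statistics, dropout off), and can stop at the block-1 or
    block-2 post-ELU, pre-pooling tap.
    """

    def __init__(self, cfg: ConvNetConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        c = cfg

        def glorot(shape, fan_in, fan_out):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-limit, limit, size=shape).astype(np.float32)

        f1, k, s1 = c.n_temporal_filters, c.temporal_kernel, c.depth_multiplier
        d = c.n_feature_channels
        t1 = c.n_samples // c.pool1
        t2 = t1 // c.pool2
        self.params = {
            "Wt": glorot((f1, k), k, k * f1),
            "Ws": glorot((f1, s1, c.n_channels), c.n_channels, s1),
            "Wd": glorot((d, c.sep_kernel), c.sep_kernel, c.sep_kernel),
            "Wp": glorot((d, d), d, d),
            "A": glorot((d * t2, c.n_classes), d * t2, c.n_classes),
            "b": np.zeros(c.n_classes, dtype=np.float32),
        }
        self.bn1 = _BatchNorm(f1, c.bn_momentum)
        self.bn2 = _BatchNorm(d, c.bn_momentum)
        self.bn3 = _BatchNorm(d, c.bn_momentum)

    # -- forward -----------------------------------------------------------

    def forward(self, X: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None, tap: str | None = None):
        """Run the network; returns (output, cache).

        ``tap='block1'`` or ``'block2'`` stops at the corresponding
        post-ELU, pre-pooling activation (feature channels x time).
        """
        c = self.cfg
        p = self.params
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 3 or X.shape[1] != c.n_channels or X.shape[2] != c.n_samples:
            raise ValueError(
                f"expected trials of shape (n, {c.n_channels}, {c.n_samples}), got {X.shape}")
        cache: dict = {}
        # Block 1: temporal conv (same padding) -> BN -> depthwise spatial -> BN -> ELU
        Xp = _pad_same(X, c.temporal_kernel)
        cache["Xp"] = Xp
        h = _corr_valid(Xp[:, None, :, :], p["Wt"][None, :, None, :])
        h = h.astype(np.float32)                               # (B, F1, C, T)
        h, cache["bn1"] = self.bn1.forward(h, train)
        cache["h1"] = h
        a = np.einsum("bfct,fsc->bfst", h, p["Ws"], optimize=True)
        b_, f1, s1, t = a.shape
        a = a.reshape(b_, f1 * s1, t)                          # (B, D, T)
        a, cache["bn2"] = self.bn2.forward(a, train)
        cache["pre_elu1"] = a
        a1 = _elu(a).astype(np.float32)
        cache["elu1"] = a1
        if tap == "block1":
            return a1, cache
        # pooling + dropout
        q = _avgpool(a1, c.pool1)                              # (B, D, T1)
        q, cache["drop1"] = self._dropout(q, train, rng)
        cache["q1"] = q
        # Block 2: depthwise temporal -> pointwise -> BN -> ELU
        qp = _pad_same(q, c.sep_kernel)
        cache["qp"] = qp
        g = _corr_valid(qp, p["Wd"][None, :, :]).astype(np.float32)  # (B, D, T1)
        cache["g"] = g
        u = np.einsum("bdt,ed->bet", g, p["Wp"], optimize=True)
        u, cache["bn3"] = self.bn3.forward(u, train)
        cache["pre_elu2"] = u
        a2 = _elu(u).astype(np.float32)
        cache["elu2"] = a2
        if tap == "block2":
            return a2, cache
        r = _avgpool(a2, c.pool2)                              # (B, D, T2)
        r, cache["drop2"] = self._dropout(r, train, rng)
        v = r.reshape(r.shape[0], -1)
        cache["v"] = v
        z = v @ p["A"] + p["b"]
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        probs = e / e.sum(axis=1, keepdims=True)
        return probs, cache

    def _dropout(self, x, train, rng):
        pdrop = self.cfg.dropout_p
        if not train or pdrop == 0.0:
            return x, None
        if rng is None:
            raise ValueError("training-mode dropout needs a random generator")
        mask = (rng.random(x.shape) >= pdrop).astype(np.float32) / (1.0 - pdrop)
        return x * mask, mask

    # -- backward ----------------------------------------------------------

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray, w: np.ndarray,
                       rng: np.random.Generator):
        """Class-weighted cross-entropy and gradients for one minibatch."""
        probs, cache = self.forward(X, train=True, rng=rng)
        c, p = self.cfg, self.params
        n = len(y)
        y = np.asarray(y, dtype=int)
        logp = np.log(np.clip(probs[np.arange(n), y], 1e-12, None))
        loss = float(np.mean(-w[y] * logp))

        onehot = np.zeros_like(probs)
        onehot[np.arange(n), y] = 1.0
        dz = ((probs - onehot) * w[y][:, None] / n).astype(np.float32)
        grads = {"A": cache["v"].T @ dz, "b": dz.sum(axis=0)}
        dv = dz @ p["A"].T
        t2 = c.n_samples // c.pool1 // c.pool2
        dr = dv.reshape(-1, c.n_feature_channels, t2)
        if cache["drop2"] is not None:
            dr = dr * cache["drop2"]
        da2 = _avgpool_backward(dr, c.pool2)
        du = _elu_backward(da2, cache["elu2"], cache["pre_elu2"])
        du, grads["bn3_g"], grads["bn3_b"] = self.bn3.backward(du, cache["bn3"])
        grads["Wp"] = np.einsum("bet,bdt->ed", du, cache["g"], optimize=True)
        dg = np.einsum("bet,ed->bdt", du, p["Wp"], optimize=True)
        # depthwise temporal conv backward: dWd[d, j] = sum_t qp[d, t+j] dg[d, t]
        grads["Wd"] = _corr_valid(cache["qp"], dg).sum(axis=0)
        dqp = _conv_full(dg, p["Wd"][None, :, :])
        dq = _unpad_grad(dqp, c.sep_kernel, cache["q1"].shape[-1]).astype(np.float32)
        if cache["drop1"] is not None:
            dq = dq * cache["drop1"]
        da1 = _avgpool_backward(dq, c.pool1)
        da = _elu_backward(da1, cache["elu1"], cache["pre_elu1"])
        da, grads["bn2_g"], grads["bn2_b"] = self.bn2.backward(da, cache["bn2"])
        da = da.reshape(-1, c.n_temporal_filters, c.depth_multiplier, c.n_samples)
        grads["Ws"] = np.einsum("bfst,bfct->fsc", da, cache["h1"], optimize=True)
        dh = np.einsum("bfst,fsc->bfct", da, p["Ws"], optimize=True)
        dh, grads["bn1_g"], grads["bn1_b"] = self.bn1.backward(dh, cache["bn1"])
        # temporal conv backward: dWt[f, j] = sum_{b,c,t} Xp[b, c, t+j] dh[b, f, c, t]
        grads["Wt"] = _corr_valid(cache["Xp"][:, None, :, :], dh).sum(axis=(0, 2))
        return loss, grads

    # -- inference helpers -------------------------------------------------

    def predict_proba(self, X: np.ndarray, chunk: int = 256) -> np.ndarray:
        out = [self.forward(X[i:i + chunk])[0] for i in range(0, len(X), chunk)]
        return np.concatenate(out, axis=0)

    def feature_maps(self, X: np.ndarray, tap: str = "block1",
                     chunk: int = 256) -> np.ndarray:
        """Post-ELU, pre-pooling activation maps, (n, D, N), inference mode."""
        if tap not in ("block1", "block2"):
            raise ValueError(f"unknown tap {tap!r}")
        out = [self.forward(X[i:i + chunk], tap=tap)[0]
               for i in range(0, len(X), chunk)]
        return np.concatenate(out, axis=0).astype(float)

    def state(self) -> dict:
        return {
            "params": copy.deepcopy(self.params),
            "bn": [copy.deepcopy((bn.gamma, bn.beta, bn.running_mean, bn.running_var))
                   for bn in (self.bn1, self.bn2, self.bn3)],
        }

    def load_state(self, state: dict) -> None:
        self.params = copy.deepcopy(state["params"])
        for bn, (g, b, rm, rv) in zip((self.bn1, self.bn2, self.bn3), state["bn"]):
            bn.gamma, bn.beta = g.copy(), b.copy()
            bn.running_mean, bn.running_var = rm.copy(), rv.copy()


def build_eegnet(cfg: ConvNetConfig | None = None, seed: int = 0) -> EEGNet:
    """Construct an EEGNet-8,2 with seeded initialization."""
    return EEGNet(cfg or ConvNetConfig(), seed=seed)


# --------------------------------------------------------------------------
# Training


class _Adam:
    def __init__(self, keys, lr):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-7
        self.m = {k: 0.0 for k in keys}
        self.v = {k: 0.0 for k in keys}
        self.t = 0

    def step(self, params, grads, bns):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        targets = dict(params)
        targets.update({"bn1_g": bns[0].gamma, "bn1_b": bns[0].beta,
                        "bn2_g": bns[1].gamma, "bn2_b": bns[1].beta,
                        "bn3_g": bns[2].gamma, "bn3_b": bns[2].beta})
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            update = self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
            targets[k] -= update.astype(np.float32)


def _apply_maxnorm(params: dict) -> None:
    # depthwise spatial kernels: unit max-norm over the electrode axis
    norms = np.linalg.norm(params["Ws"], axis=2, keepdims=True)
    np.divide(params["Ws"], np.maximum(norms, 1.0), out=params["Ws"])
    # dense kernel: max-norm 0.25 per output unit
    norms = np.linalg.norm(params["A"], axis=0, keepdims=True)
    scale = np.maximum(norms / 0.25, 1.0)
    np.divide(params["A"], scale, out=params["A"])


@dataclass
class ConvTrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1


def train_convnet(
    model: EEGNet,
    trainset: tuple[np.ndarray, np.ndarray],
    valset: tuple[np.ndarray, np.ndarray],
    tcfg: TrainConfig | None = None,
) -> tuple[EEGNet, ConvTrainHistory]:
    """Train the full EEGNet end-to-end; restore minimum-validation-loss weights."""
    tcfg = tcfg or TrainConfig()
    Xt, yt = np.asarray(trainset[0], np.float32), np.asarray(trainset[1], int)
    Xv, yv = np.asarray(valset[0], np.float32), np.asarray(valset[1], int)
    if len(yv) == 0:
        raise ValueError("validation set is empty")
    if len(np.unique(yt)) < 2:
        raise ValueError("training set must contain both classes")
    w = class_weights(yt).astype(np.float32) if tcfg.class_weighted \
        else np.ones(2, dtype=np.float32)
    rng = np.random.default_rng(tcfg.seed)
    opt = _Adam(list(model.params) + [f"bn{i}_{s}" for i in (1, 2, 3) for s in "gb"],
                tcfg.lr)
    history = ConvTrainHistory()
    best_state, best_val = model.state(), np.inf
    n = len(yt)
    for epoch in range(tcfg.max_epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, tcfg.batch_size):
            idx = order[start:start + tcfg.batch_size]
            loss, grads = model.loss_and_grads(Xt[idx], yt[idx], w, rng)
            total += loss * len(idx)
            opt.step(model.params, grads, (model.bn1, model.bn2, model.bn3))
            _apply_maxnorm(model.params)
        history.train_loss.append(total / n)
        pv = model.predict_proba(Xv)
        logp = np.log(np.clip(pv[np.arange(len(yv)), yv], 1e-12, None))
        vloss = float(np.mean(-w[yv] * logp))
        history.val_loss.append(vloss)
        if vloss < best_val:
            best_val = vloss
            best_state = model.state()
            history.best_epoch = epoch
    model.load_state(best_state)
    return model, history


def extract_feature_maps(model: EEGNet, trials: np.ndarray,
                         tap: str = "block1") -> np.ndarray:
    """Block-1 (or block-2) post-ELU, pre-pooling activation per trial, (n, D, N)."""
    trials = np.asarray(trials, dtype=np.float32)
    if trials.ndim == 2:
        trials = trials[None]
    return model.feature_maps(trials, tap=tap)


# --------------------------------------------------------------------------
# Estimator


class EEGNetFeatureExtractor(BaseEstimator, TransformerMixin):
    """Fit the full EEGNet, transform trials to convolutional feature maps.

    ``fit(X, y)`` trains EEGNet-8,2 end-to-end with class-weighted
    cross-entropy and validation stopping (an explicit validation set
    may be passed, otherwise ``val_fraction`` of the data is held out);
    ``transform(X)`` returns the post-ELU, pre-pooling activation of
    the requested block, shape (n_trials, 16, n_time).
    """

    def __init__(self, tap: str = "block1", max_epochs: int = 100, lr: float = 1e-3,
                 batch_size: int = 64, val_fraction: float = 0.2, dropout_p: float = 0.25,
                 class_weighted: bool = True, random_state: int | None = None):
        self.tap = tap
        self.max_epochs = max_epochs
        self.lr = lr
        self.batch_size = batch_size
        self.val_fraction = val_fraction
        self.dropout_p = dropout_p
        self.class_weighted = class_weighted
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray,
            validation: tuple[np.ndarray, np.ndarray] | None = None) -> "EEGNetFeatureExtractor":
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=int)
        seed = self.random_state if self.random_state is not None else 0
        cfg = ConvNetConfig(n_channels=X.shape[1], n_samples=X.shape[2],
                            dropout_p=self.dropout_p)
        self.model_ = build_eegnet(cfg, seed=seed)
        rng = np.random.default_rng(seed)
        if validation is None:
            n_val = max(1, int(round(self.val_fraction * len(y))))
            perm = rng.permutation(len(y))
            val_idx, fit_idx = np.sort(perm[:n_val]), np.sort(perm[n_val:])
            validation = (X[val_idx], y[val_idx])
            X, y = X[fit_idx], y[fit_idx]
        tcfg = TrainConfig(lr=self.lr, max_epochs=self.max_epochs,
                           batch_size=self.batch_size, val_fraction=self.val_fraction,
                           class_weighted=self.class_weighted, seed=seed)
        self.model_, self.history_ = train_convnet(self.model_, (X, y), validation, tcfg)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "model_")
        return extract_feature_maps(self.model_, np.asarray(X, np.float32), tap=self.tap)
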