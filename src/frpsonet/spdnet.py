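"""SPD-matrix learning and classification network (SPDC-Net).

A Riemannian network on symmetric positive definite (SPD) inputs:

    BiMap:  B = W^T X W,  W on the compact Stiefel manifold (W^T W = I)
    ReEig:  X' = U max(Lam, eps I) U^T,  B = U Lam U^T   (eigen-rectification)
    LogEig: log(X) = U log(Lam) U^T, flattened row-major to d^2

Two BiMap+ReEig (BiRe) blocks without dimension reduction are followed
by LogEig, flatten, and an affine softmax classifier trained with
class-weighted cross-entropy.

Gradients are hand-derived.  Backpropagation through the eigendecompo-
sition uses the Loewner-matrix (Daleckii-Krein) form: for a spectral
function f(X) = U g(Lam) U^T with upstream gradient G,

    dL/dX = U (Gamma o (U^T sym(G) U)) U^T,
    Gamma_ij = (g(l_i) - g(l_j)) / (l_i - l_j)  (i != j),
    Gamma_ii = g'(l_i),

with pairwise eigenvalue-difference denominators clamped at 1e-10 in
magnitude to survive (near-)degenerate spectra.  BiMap weights are
optimized by Riemannian stochastic gradient descent: the Euclidean
gradient is projected to the tangent space of the Stiefel manifold and
the step is retracted back via a sign-fixed QR factorization.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "SPDNetConfig",
    "bimap",
    "reeig",
    "logeig",
    "stiefel_project",
    "stiefel_retract",
    "stiefel_step",
    "orthogonality_defect",
    "init_params",
    "spdnet_forward",
    "spdnet_loss_and_grads",
    "train_spdnet",
    "SPDNetClassifier",
]

_EIG_TOL = 1e-10  # clamp for pairwise eigenvalue-difference denominators


@dataclass
class SPDNetConfig:
    """Architecture and optimization settings for SPDC-Net.

    ``dims`` is constant across layers (no dimension reduction); ``eps``
    is the ReEig eigenvalue floor.
    """

    n_bire_blocks: int = 2
    eps: float = 1e-4
    lr: float = 1e-2
    batch_size: int = 32
    max_epochs: int = 100
    class_weighted: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.n_bire_blocks < 1 or self.max_epochs < 1:
            raise ValueError("n_bire_blocks and max_epochs must be >= 1")


# --------------------------------------------------------------------------
# Layers (single matrix or batched (B, d, d))


def _as_batch(X: np.ndarray) -> tuple[np.ndarray, bool]:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        return X[None], True
    if X.ndim == 3:
        return X, False
    raise ValueError("expected a (d, d) matrix or a (batch, d, d) stack")


def _check_symmetric(X: np.ndarray, name: str, atol: float = 1e-8) -> None:
    if X.shape[-1] != X.shape[-2]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(X, np.swapaxes(X, -1, -2), atol=atol):
        raise ValueError(f"{name} must be symmetric")


def bimap(X: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Bilinear mapping B = W^T X W (SPD-preserving for full-rank W)."""
    Xb, squeeze = _as_batch(X)
    W = np.asarray(W, dtype=float)
    if W.shape[0] != Xb.shape[-1]:
        raise ValueError(f"dimension mismatch: X is {Xb.shape[-1]}d, W has {W.shape[0]} rows")
    B = W.T @ Xb @ W
    return B[0] if squeeze else B


def reeig(B: np.ndarray, eps: float) -> np.ndarray:
    """Eigenvalue rectification U max(Lam, eps I) U^T."""
    Bb, squeeze = _as_batch(B)
    _check_symmetric(Bb, "ReEig input")
    lam, U = np.linalg.eigh(Bb)
    lam_r = np.maximum(lam, eps)
    out = (U * lam_r[..., None, :]) @ np.swapaxes(U, -1, -2)
    return out[0] if squeeze else out


def logeig(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Matrix logarithm via eigendecomposition; returns (log(X), flat).

    ``flat`` is the row-major flattening of log(X), length d^2.
    """
    Xb, squeeze = _as_batch(X)
    _check_symmetric(Xb, "LogEig input")
    lam, U = np.linalg.eigh(Xb)
    if np.any(lam <= 0):
        raise ValueError("LogEig requires a positive definite input")
    L = (U * np.log(lam)[..., None, :]) @ np.swapaxes(U, -1, -2)
    flat = L.reshape(L.shape[0], -1)
    return (L[0], flat[0]) if squeeze else (L, flat)


def _eig_fn_backward(U: np.ndarray, lam: np.ndarray, G: np.ndarray,
                     g_lam: np.ndarray, gprime_lam: np.ndarray) -> np.ndarray:
    """Gradient of L(U g(Lam) U^T) w.r.t. the symmetric input, batched."""
    Gs = 0.5 * (G + np.swapaxes(G, -1, -2))
    Ghat = np.swapaxes(U, -1, -2) @ Gs @ U
    diff = lam[..., :, None] - lam[..., None, :]
    denom = np.where(np.abs(diff) < _EIG_TOL,
                     np.where(diff < 0, -_EIG_TOL, _EIG_TOL), diff)
    Gamma = (g_lam[..., :, None] - g_lam[..., None, :]) / denom
    idx = np.arange(lam.shape[-1])
    Gamma[..., idx, idx] = gprime_lam
    return U @ (Gamma * Ghat) @ np.swapaxes(U, -1, -2)


# --------------------------------------------------------------------------
# Stiefel manifold optimization


def stiefel_project(W: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Project a Euclidean gradient onto the tangent space at W."""
    WtG = W.T @ G
    return G - W @ (0.5 * (WtG + WtG.T))


def stiefel_retract(M: np.ndarray) -> np.ndarray:
    """QR retraction with sign-fixed R diagonal (deterministic)."""
    Q, R = np.linalg.qr(M)
    d = np.sign(np.diag(R))
    d[d == 0] = 1.0
    return Q * d[None, :]


def stiefel_step(W: np.ndarray, euclidean_grad: np.ndarray, lr: float) -> np.ndarray:
    """One Riemannian SGD step: project, step, retract."""
    if not np.all(np.isfinite(euclidean_grad)):
        raise ValueError("non-finite gradient")
    xi = stiefel_project(W, euclidean_grad)
    return stiefel_retract(W - lr * xi)


def orthogonality_defect(W: np.ndarray) -> float:
    """Frobenius norm of W^T W - I."""
    d = W.shape[1]
    return float(np.linalg.norm(W.T @ W - np.eye(d)))


# --------------------------------------------------------------------------
# Full network


def init_params(d: int, n_blocks: int, n_classes: int,
                rng: np.random.Generator) -> dict:
    """Seeded initialization: orthonormal BiMap factors, scaled-Gaussian softmax."""
    Ws = [stiefel_retract(rng.standard_normal((d, d))) for _ in range(n_blocks)]
    A = rng.standard_normal((d * d, n_classes)) / np.sqrt(d * d)
    b = np.zeros(n_classes)
    return {"Ws": Ws, "A": A, "b": b}


def spdnet_forward(X: np.ndarray, params: dict, eps: float,
                   return_cache: bool = False):
    """Forward pass BiRe x n -> LogEig -> flatten -> affine -> softmax.

    ``X`` is a (batch, d, d) stack of SPD matrices; returns class
    probabilities (batch, K), plus the layer cache when requested.
    """
    Xb, squeeze = _as_batch(X)
    cache = {"inputs": [], "eigs": []}
    H = Xb
    for W in params["Ws"]:
        cache["inputs"].append(H)
        B = W.T @ H @ W
        lam, U = np.linalg.eigh(B)
        lam_r = np.maximum(lam, eps)
        cache["eigs"].append((U, lam, lam_r))
        H = (U * lam_r[..., None, :]) @ np.swapaxes(U, -1, -2)
    lam, U = np.linalg.eigh(H)
    if np.any(lam <= 0):  # ReEig guarantees this never triggers
        raise ValueError("LogEig received a non-PD matrix")
    cache["logeig_in"] = H
    cache["logeig"] = (U, lam)
    L = (U * np.log(lam)[..., None, :]) @ np.swapaxes(U, -1, -2)
    v = L.reshape(L.shape[0], -1)
    z = v @ params["A"] + params["b"]
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    cache["v"] = v
    if squeeze:
        p = p[0]
    return (p, cache) if return_cache else p


def _weighted_ce(p: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Mean over the batch of w_y * cross-entropy."""
    n = len(y)
    logp = np.log(np.clip(p[np.arange(n), y], 1e-12, None))
    return float(np.mean(-w[y] * logp))


def spdnet_loss_and_grads(X: np.ndarray, y: np.ndarray, params: dict, eps: float,
                          class_weights: np.ndarray) -> tuple[float, dict]:
    """Class-weighted cross-entropy and Euclidean gradients of all parameters."""
    p, cache = spdnet_forward(X, params, eps, return_cache=True)
    n, K = p.shape
    y = np.asarray(y, dtype=int)
    w = np.asarray(class_weights, dtype=float)
    loss = _weighted_ce(p, y, w)

    onehot = np.zeros((n, K))
    onehot[np.arange(n), y] = 1.0
    dz = (p - onehot) * w[y][:, None] / n
    dA = cache["v"].T @ dz
    db = dz.sum(axis=0)
    dv = dz @ params["A"].T
    d_dim = cache["logeig_in"].shape[-1]
    dL = dv.reshape(n, d_dim, d_dim)

    # LogEig backward
    U, lam = cache["logeig"]
    dH = _eig_fn_backward(U, lam, dL, np.log(lam), 1.0 / lam)

    dWs = [None] * len(params["Ws"])
    for i in range(len(params["Ws"]) - 1, -1, -1):
        W = params["Ws"][i]
        U, lam, lam_r = cache["eigs"][i]
        gprime = (lam > eps).astype(float)
        dB = _eig_fn_backward(U, lam, dH, lam_r, gprime)
        Hin = cache["inputs"][i]
        # B = W^T H W  =>  dW = H W dB + H^T W dB^T ; dH = W dB W^T
        dWs[i] = ((Hin @ W) @ dB).sum(axis=0) \
            + ((np.swapaxes(Hin, -1, -2) @ W) @ np.swapaxes(dB, -1, -2)).sum(axis=0)
        dH = W @ dB @ W.T
    return loss, {"Ws": dWs, "A": dA, "b": db}


# --------------------------------------------------------------------------
# Training


def class_weights(labels: np.ndarray) -> np.ndarray:
    """Inverse-proportion class weights with the majority class set to 1.

    Returns an array indexed by class label {0, 1}.
    """
    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels, minlength=2)
    if np.any(counts == 0):
        raise ValueError("class weights require both classes present")
    majority = counts.max()
    return majority / counts.astype(float)


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1

    @property
    def best_val_loss(self) -> float:
        return min(self.val_loss)


def train_spdnet(
    X: np.ndarray,
    y: np.ndarray,
    cfg: SPDNetConfig,
    validation: tuple[np.ndarray, np.ndarray] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[dict, TrainHistory]:
    """Riemannian SGD with class-weighted cross-entropy and validation stopping.

    BiMap weights take projected-and-retracted steps on the Stiefel
    manifold; the softmax parameters take plain SGD steps.  The weights
    of the minimum-validation-loss epoch are restored.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    w = class_weights(y) if cfg.class_weighted else np.ones(2)
    if validation is None:
        raise ValueError("validation set required for early stopping")
    Xv, yv = validation
    Xv = np.asarray(Xv, dtype=float)
    yv = np.asarray(yv, dtype=int)
    if len(yv) == 0:
        raise ValueError("validation set is empty")

    d = X.shape[-1]
    params = init_params(d, cfg.n_bire_blocks, 2, rng)
    history = TrainHistory()
    best = copy.deepcopy(params)
    best_val = np.inf
    n = len(y)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            loss, grads = spdnet_loss_and_grads(X[idx], y[idx], params, cfg.eps, w)
            epoch_loss += loss * len(idx)
            for i, (W, dW) in enumerate(zip(params["Ws"], grads["Ws"])):
                params["Ws"][i] = stiefel_step(W, dW, cfg.lr)
            params["A"] -= cfg.lr * grads["A"]
            params["b"] -= cfg.lr * grads["b"]
        history.train_loss.append(epoch_loss / n)
        pv = spdnet_forward(Xv, params, cfg.eps)
        vloss = _weighted_ce(pv, yv, w)
        history.val_loss.append(vloss)
        if vloss < best_val:
            best_val = vloss
            best = copy.deepcopy(params)
            history.best_epoch = epoch
    return best, history


# --------------------------------------------------------------------------
# Estimator


class SPDNetClassifier(BaseEstimator, ClassifierMixin):
    """SPD manifold network classifier (scikit-learn interface).

    Input samples are SPD matrices, ``X`` of shape (n_trials, d, d).
    Two BiRe blocks without dimension reduction, LogEig, and a
    class-weighted softmax, trained by Riemannian SGD with validation
    stopping.

    Parameters
    ----------
    n_bire_blocks : int
        Number of BiMap+ReEig blocks.
    eps : float
        ReEig eigenvalue floor.
    lr, batch_size, max_epochs : optimization settings.
    val_fraction : float
        Fraction of the training data held out for validation stopping
        when no explicit validation set is passed to :meth:`fit`.
    class_weighted : bool
        Weight the loss by inverse class proportions (majority = 1).
    random_state : int or None
        Seed for initialization, batch order, and the validation split.
    """

    def __init__(self, n_bire_blocks: int = 2, eps: float = 1e-4, lr: float = 1e-2,
                 batch_size: int = 32, max_epochs: int = 100, val_fraction: float = 0.2,
                 class_weighted: bool = True, random_state: int | None = None):
        self.n_bire_blocks = n_bire_blocks
        self.eps = eps
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.val_fraction = val_fraction
        self.class_weighted = class_weighted
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray,
            validation: tuple[np.ndarray, np.ndarray] | None = None) -> "SPDNetClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 3 or X.shape[1] != X.shape[2]:
            raise ValueError("X must be (n_trials, d, d) SPD matrices")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("both classes must be present in training data")
        rng = np.random.default_rng(self.random_state)
        if validation is None:
            n_val = max(1, int(round(self.val_fraction * len(y))))
            perm = rng.permutation(len(y))
            val_idx, fit_idx = np.sort(perm[:n_val]), np.sort(perm[n_val:])
            validation = (X[val_idx], y[val_idx])
            X, y = X[fit_idx], y[fit_idx]
        cfg = SPDNetConfig(n_bire_blocks=self.n_bire_blocks, eps=self.eps, lr=self.lr,
                           batch_size=self.batch_size, max_epochs=self.max_epochs,
                           class_weighted=self.class_weighted)
        self.params_, self.history_ = train_spdnet(X, y, cfg, validation, rng)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "params_")
        X = np.asarray(X, dtype=float)
        return spdnet_forward(X, self.params_, self.eps)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]
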