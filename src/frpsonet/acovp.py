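"""Augmented covariance pooling (ACOVP).

Second-order pooling of convolutional feature maps with target-template
concatenation.  A plain sample covariance of a D x N feature map,

    C = X_c X_c^T / (N - 1),          X_c row-centered,

is invariant to any permutation of the N time columns and therefore
discards the temporal ordering of the learned features.  ACOVP restores
that information by stacking the centered class-mean target template
X_tar above each centered trial,

    X_aug = [X_tar; X_c]  in R^{2D x N},
    AugC  = X_aug X_aug^T / (N - 1)   in R^{2D x 2D},

whose off-diagonal D x D cross block measures trial-template temporal
covariance and *does* change under time permutations of the trial.  A
trace-scaled ridge,

    AugC+ = AugC + lam * trace(AugC) * I,

guarantees strict positive definiteness, making every pooled trial a
point on the SPD manifold for the downstream Riemannian classifier.

The template is estimated from training-fold target trials only and is
frozen at test time; anything else leaks labels.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "center_rows",
    "covariance_pool",
    "target_template",
    "augment",
    "augmented_covariance",
    "ensure_spd",
    "acovp_transform",
    "AugmentedCovariance",
]

DEFAULT_SHRINKAGE = 1e-5


def center_rows(X: np.ndarray) -> np.ndarray:
    """Subtract each row's mean; rows of the result sum to zero."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("X must be a D x N matrix with N >= 2")
    return X - X.mean(axis=1, keepdims=True)


def covariance_pool(Xc: np.ndarray) -> np.ndarray:
    """Sample covariance C = Xc Xc^T / (N - 1) of a row-centered map."""
    Xc = np.asarray(Xc, dtype=float)
    if Xc.ndim != 2 or Xc.shape[1] < 2:
        raise ValueError("Xc must be a D x N matrix with N >= 2")
    n = Xc.shape[1]
    return Xc @ Xc.T / (n - 1)


def target_template(maps: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Centered entrywise mean of the target-class feature maps.

    Averaging and row-centering commute, so centering the mean of raw
    maps equals the mean of centered maps.
    """
    maps = np.asarray(maps, dtype=float)
    labels = np.asarray(labels)
    tgt = maps[labels == 1]
    if tgt.shape[0] == 0:
        raise ValueError("template requires targets: no target-class trials supplied")
    return center_rows(tgt.mean(axis=0))


def augment(template: np.ndarray, Xc: np.ndarray) -> np.ndarray:
    """Stack the centered template above the centered trial (2D x N)."""
    template = np.asarray(template, dtype=float)
    Xc = np.asarray(Xc, dtype=float)
    if template.shape != Xc.shape:
        raise ValueError(
            f"template shape {template.shape} does not match trial shape {Xc.shape}")
    return np.vstack([template, Xc])


def augmented_covariance(X_aug: np.ndarray) -> np.ndarray:
    """Joint sample covariance of the augmented trial (2D x 2D)."""
    return covariance_pool(X_aug)


def ensure_spd(C: np.ndarray, lam: float = DEFAULT_SHRINKAGE) -> np.ndarray:
    """Trace-scaled diagonal loading: C + lam * trace(C) * I.

    A degenerate all-zero covariance (an all-constant trial) cannot be
    made positive definite this way and is rejected.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("C must be square")
    if not np.allclose(C, C.T, atol=1e-8):
        raise ValueError("C must be symmetric")
    tr = np.trace(C)
    if lam > 0 and tr <= 0:
        raise ValueError("degenerate covariance (zero trace): constant trial rejected")
    return C + lam * tr * np.eye(C.shape[0])


def acovp_transform(
    maps: np.ndarray,
    labels: np.ndarray | None = None,
    template: np.ndarray | None = None,
    lam: float = DEFAULT_SHRINKAGE,
    mode: str = "augmented",
) -> np.ndarray:
    """Pool feature maps into SPD matrices.

    Train time: pass ``labels`` and the template is estimated from the
    target trials.  Test time: pass the frozen ``template``.  With
    ``mode='plain'`` the trial's own covariance is returned (the COVP
    ablation; D x D, no template needed).
    """
    est = AugmentedCovariance(shrinkage=lam, mode=mode)
    if mode == "plain":
        est.fit(maps, labels if labels is not None else np.zeros(len(maps), dtype=int))
    elif template is not None:
        est.template_ = np.asarray(template, dtype=float)
        est.n_features_in_ = maps.shape[1] if np.ndim(maps) == 3 else None
    else:
        if labels is None:
            raise ValueError("supply labels (train time) or a frozen template (test time)")
        est.fit(maps, labels)
    return est.transform(maps)


class AugmentedCovariance(BaseEstimator, TransformerMixin):
    """Augmented covariance pooling as a scikit-learn transformer.

    Parameters
    ----------
    shrinkage : float
        Trace-scaled diagonal loading coefficient (lam above).
    mode : {'augmented', 'plain'}
        'augmented' concatenates the fitted target template (output
        2D x 2D); 'plain' pools each trial alone (output D x D, the
        COVP ablation baseline).

    Attributes
    ----------
    template_ : ndarray of shape (D, N)
        Centered target-class mean feature map ('augmented' mode only).
    """

    def __init__(self, shrinkage: float = DEFAULT_SHRINKAGE, mode: str = "augmented"):
        self.shrinkage = shrinkage
        self.mode = mode

    def fit(self, X: np.ndarray, y: np.ndarray | None = None) -> "AugmentedCovariance":
        X = self._check_maps(X)
        if self.mode not in ("augmented", "plain"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self.n_features_in_ = X.shape[1]
        if self.mode == "augmented":
            if y is None:
                raise ValueError("'augmented' mode requires labels to build the template")
            self.template_ = target_template(X, np.asarray(y))
        else:
            self.template_ = None
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "n_features_in_")
        X = self._check_maps(X)
        n_trials, d, n = X.shape
        Xc = X - X.mean(axis=2, keepdims=True)
        if self.mode == "augmented":
            tpl = self.template_
            if tpl.shape != (d, n):
                raise ValueError(
                    f"trial shape ({d}, {n}) does not match template shape {tpl.shape}")
            stacked = np.concatenate(
                [np.broadcast_to(tpl, (n_trials, d, n)), Xc], axis=1)
        else:
            stacked = Xc
        cov = stacked @ stacked.transpose(0, 2, 1) / (n - 1)
        cov = 0.5 * (cov + cov.transpose(0, 2, 1))  # exact symmetry
        tr = np.trace(cov, axis1=1, axis2=2)
        if self.shrinkage > 0 and np.any(tr <= 0):
            raise ValueError("degenerate covariance (zero trace): constant trial rejected")
        eye = np.eye(cov.shape[1])
        return cov + self.shrinkage * tr[:, None, None] * eye

    @staticmethod
    def _check_maps(X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("X must be (n_trials, D, N)")
        if X.shape[2] < 2:
            raise ValueError("feature maps need N >= 2 time instances")
        if not np.all(np.isfinite(X)):
            raise ValueError("feature maps must be finite")
        return X
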