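"""End-to-end single-trial FRP classifier.

Three stages fitted in sequence (the convolutional frontend and the SPD
classifier are trained independently, not jointly):

1. ``EEGNetFeatureExtractor`` — full EEGNet-8,2 trained end-to-end;
   the block-1 post-ELU activation (16 x 128) is the feature map.
2. ``AugmentedCovariance`` — target-template concatenation and joint
   covariance pooling to a 32 x 32 SPD matrix per trial; the template
   comes from training targets only and is frozen afterwards.
3. ``SPDNetClassifier`` — two BiRe blocks + LogEig + softmax, trained
   by Riemannian SGD.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .acovp import AugmentedCovariance
from .eegnet import EEGNetFeatureExtractor
from .spdnet import SPDNetClassifier

__all__ = ["FRPClassifier"]


class FRPClassifier(BaseEstimator, ClassifierMixin):
    """CONV-Net -> ACOVP -> SPDC-Net pipeline as one scikit-learn classifier.

    Parameters
    ----------
    tap : {'block1', 'block2'}
        Which convolutional activation feeds the covariance pooling
        ('block2' exists for ablation; 'block1' preserves temporal
        structure and is the default).
    pooling : {'augmented', 'plain'}
        Augmented covariance (with target template) or plain trial
        covariance (the COVP ablation).
    shrinkage : float
        Trace-scaled diagonal loading of the pooled covariance.
    conv_epochs, conv_lr, conv_batch : EEGNet training settings.
    spd_epochs, spd_lr, spd_batch, eps, n_bire_blocks : SPDC-Net settings.
    val_fraction : float
        Held-out fraction for validation stopping when :meth:`fit` is
        called without an explicit validation set.
    random_state : int or None
        Master seed for both training stages.
    """

    def __init__(self, tap: str = "block1", pooling: str = "augmented",
                 shrinkage: float = 1e-5, conv_epochs: int = 100, conv_lr: float = 1e-3,
                 conv_batch: int = 64, spd_epochs: int = 100, spd_lr: float = 1e-2,
                 spd_batch: int = 32, eps: float = 1e-4, n_bire_blocks: int = 2,
                 val_fraction: float = 0.2, class_weighted: bool = True,
                 random_state: int | None = None):
        self.tap = tap
        self.pooling = pooling
        self.shrinkage = shrinkage
        self.conv_epochs = conv_epochs
        self.conv_lr = conv_lr
        self.conv_batch = conv_batch
        self.spd_epochs = spd_epochs
        self.spd_lr = spd_lr
        self.spd_batch = spd_batch
        self.eps = eps
        self.n_bire_blocks = n_bire_blocks
        self.val_fraction = val_fraction
        self.class_weighted = class_weighted
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray,
            validation: tuple[np.ndarray, np.ndarray] | None = None) -> "FRPClassifier":
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=int)
        seed = self.random_state if self.random_state is not None else 0
        if validation is None:
            rng = np.random.default_rng(seed)
            n_val = max(1, int(round(self.val_fraction * len(y))))
            perm = rng.permutation(len(y))
            val_idx, fit_idx = np.sort(perm[:n_val]), np.sort(perm[n_val:])
            validation = (X[val_idx], y[val_idx])
            X, y = X[fit_idx], y[fit_idx]
        Xv, yv = validation

        self.conv_ = EEGNetFeatureExtractor(
            tap=self.tap, max_epochs=self.conv_epochs, lr=self.conv_lr,
            batch_size=self.conv_batch, class_weighted=self.class_weighted,
            random_state=seed)
        self.conv_.fit(X, y, validation=(Xv, yv))

        maps_fit = self.conv_.transform(X)
        maps_val = self.conv_.transform(Xv)
        # template from all training-fold trials (fit + validation)
        self.pool_ = AugmentedCovariance(shrinkage=self.shrinkage, mode=self.pooling)
        self.pool_.fit(np.concatenate([maps_fit, maps_val]), np.concatenate([y, yv]))

        self.spd_ = SPDNetClassifier(
            n_bire_blocks=self.n_bire_blocks, eps=self.eps, lr=self.spd_lr,
            batch_size=self.spd_batch, max_epochs=self.spd_epochs,
            class_weighted=self.class_weighted, random_state=seed)
        self.spd_.fit(self.pool_.transform(maps_fit), y,
                      validation=(self.pool_.transform(maps_val), yv))
        self.classes_ = self.spd_.classes_
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "spd_")
        maps = self.conv_.transform(np.asarray(X, np.float32))
        return self.spd_.predict_proba(self.pool_.transform(maps))

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]
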