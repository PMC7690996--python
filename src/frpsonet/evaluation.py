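"""Experimental protocol: chronological CV, AUC scoring, reduced sets, ablations.

The cross-validation is *chronological with preserved class ratio*:
each class's chronologically ordered trials are cut into k contiguous
segments, and fold j's test set unions segment j of both classes — so
folds never mix future into past within a class and every fold's
target-to-nontarget ratio matches the full set to within one trial.
A random (seeded) 20% of each training fold is held out for validation
stopping.  Performance is rank-based AUC, which is insensitive to the
~1:8 class imbalance.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .acovp import AugmentedCovariance
from .eegnet import EEGNetFeatureExtractor
from .spdnet import SPDNetClassifier
from .synth import EEGTrialSet

logger = logging.getLogger(__name__)

__all__ = [
    "CVSplit",
    "CVResult",
    "PipelineConfig",
    "chrono_cv_splits",
    "val_split",
    "auc",
    "reduced_set",
    "run_pipeline",
    "ablation",
    "run_reduced",
]


@dataclass(frozen=True)
class CVSplit:
    fold_id: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    val_idx: np.ndarray | None = None


@dataclass
class CVResult:
    """Per-fold AUCs with sample-std aggregate and experiment provenance."""

    per_fold_auc: list[float]
    fraction: float = 1.0
    repeat_id: int = 0
    seed: int = 0
    variant: str = "acovp"

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_fold_auc))

    @property
    def std(self) -> float:
        return float(np.std(self.per_fold_auc, ddof=1))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"CVResult(variant={self.variant!r}, fraction={self.fraction}, "
                f"mean={self.mean:.4f}, std={self.std:.4f}, folds={len(self.per_fold_auc)})")


@dataclass
class PipelineConfig:
    """All tunables of the end-to-end experiment in one place."""

    k_folds: int = 5
    val_fraction: float = 0.2
    shrinkage: float = 1e-5
    conv_epochs: int = 100
    conv_lr: float = 1e-3
    conv_batch: int = 64
    spd_epochs: int = 100
    spd_lr: float = 1e-2
    spd_batch: int = 32
    eps: float = 1e-4
    n_bire_blocks: int = 2
    class_weighted: bool = True

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


# --------------------------------------------------------------------------
# Protocol primitives


def chrono_cv_splits(labels: np.ndarray, order: np.ndarray | None = None,
                     k: int = 5) -> list[CVSplit]:
    """Chronological k-fold splits with per-class contiguous segmentation."""
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    if order is None:
        order = np.arange(n)
    chron = np.argsort(np.asarray(order))
    if k < 2:
        raise ValueError("k must be at least 2 (k = 1 leaves no training data)")
    counts = np.bincount(labels, minlength=2)
    if np.any(counts == 0):
        raise ValueError("both classes must be present")
    if k > counts.min():
        raise ValueError(f"k = {k} exceeds the minority class count {counts.min()}")
    segments: dict[int, list[np.ndarray]] = {}
    for cls in (0, 1):
        cls_idx = chron[labels[chron] == cls]  # chronological within class
        segments[cls] = np.array_split(cls_idx, k)
    splits = []
    all_idx = np.arange(n)
    for j in range(k):
        test = np.sort(np.concatenate([segments[0][j], segments[1][j]]))
        train = np.setdiff1d(all_idx, test)
        splits.append(CVSplit(fold_id=j, train_idx=train, test_idx=test))
    return splits


def val_split(train_idx: np.ndarray, fraction: float = 0.2,
              rng: np.random.Generator | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Random seeded validation split of a training fold; both parts sorted."""
    train_idx = np.asarray(train_idx)
    if len(train_idx) == 0:
        raise ValueError("train_idx is empty")
    rng = rng or np.random.default_rng()
    n_val = int(round(fraction * len(train_idx)))
    perm = rng.permutation(len(train_idx))
    val = np.sort(train_idx[perm[:n_val]])
    fit = np.sort(train_idx[perm[n_val:]])
    return fit, val


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC; ties count one half."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def reduced_set(dataset: EEGTrialSet, fraction: float,
                rng: np.random.Generator | None = None, k: int = 5) -> EEGTrialSet:
    """Per-class random subsampling that preserves the class ratio.

    ``round(fraction * class count)`` trials are drawn per class without
    replacement; survivors keep their chronological order.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    rng = rng or np.random.default_rng()
    labels = dataset.labels
    keep: list[np.ndarray] = []
    for cls in (0, 1):
        cls_idx = np.flatnonzero(labels == cls)
        n_keep = int(round(fraction * len(cls_idx)))
        keep.append(rng.choice(cls_idx, size=n_keep, replace=False))
    idx = np.sort(np.concatenate(keep))
    n_min = min((labels[idx] == 0).sum(), (labels[idx] == 1).sum())
    if n_min < k:
        raise ValueError(f"reduced minority class ({n_min}) smaller than k = {k}")
    return dataset.subset(idx)


# --------------------------------------------------------------------------
# End-to-end runs

_VARIANTS = {
    # name: (conv tap, pooling mode)
    "acovp": ("block1", "augmented"),
    "covp": ("block1", "plain"),
    "block1": ("block1", "augmented"),
    "block2": ("block2", "augmented"),
}


def _sub_seed(seed: int, fold: int, tag: int) -> int:
    ss = np.random.SeedSequence([int(seed), int(fold), int(tag)])
    return int(ss.generate_state(1)[0] % (2**31))


def _run_cv(dataset: EEGTrialSet, cfg: PipelineConfig, seed: int,
            variants: tuple[str, ...]) -> dict[str, CVResult]:
    """Shared CV driver: one trained CONV-Net per fold serves all variants."""
    for v in variants:
        if v not in _VARIANTS:
            raise ValueError(f"unknown variant {v!r}; choose from {sorted(_VARIANTS)}")
    X = dataset.data.astype(np.float32)
    y = dataset.labels
    splits = chrono_cv_splits(y, dataset.order, cfg.k_folds)
    taps = sorted({_VARIANTS[v][0] for v in variants})
    fold_aucs: dict[str, list[float]] = {v: [] for v in variants}
    for split in splits:
        j = split.fold_id
        try:
            vrng = np.random.default_rng(seed + j)
            fit_idx, val_idx = val_split(split.train_idx, cfg.val_fraction, vrng)
            conv = EEGNetFeatureExtractor(
                max_epochs=cfg.conv_epochs, lr=cfg.conv_lr, batch_size=cfg.conv_batch,
                class_weighted=cfg.class_weighted, random_state=_sub_seed(seed, j, 1))
            conv.fit(X[fit_idx], y[fit_idx], validation=(X[val_idx], y[val_idx]))
            maps = {tap: {"fit": conv.model_.feature_maps(X[fit_idx], tap=tap),
                          "val": conv.model_.feature_maps(X[val_idx], tap=tap),
                          "test": conv.model_.feature_maps(X[split.test_idx], tap=tap)}
                    for tap in taps}
            for v in variants:
                tap, mode = _VARIANTS[v]
                m = maps[tap]
                pool = AugmentedCovariance(shrinkage=cfg.shrinkage, mode=mode)
                pool.fit(np.concatenate([m["fit"], m["val"]]),
                         np.concatenate([y[fit_idx], y[val_idx]]))
                spd = SPDNetClassifier(
                    n_bire_blocks=cfg.n_bire_blocks, eps=cfg.eps, lr=cfg.spd_lr,
                    batch_size=cfg.spd_batch, max_epochs=cfg.spd_epochs,
                    class_weighted=cfg.class_weighted,
                    random_state=_sub_seed(seed, j, 2))
                spd.fit(pool.transform(m["fit"]), y[fit_idx],
                        validation=(pool.transform(m["val"]), y[val_idx]))
                scores = spd.predict_proba(pool.transform(m["test"]))[:, 1]
                fold_aucs[v].append(auc(scores, y[split.test_idx]))
                logger.info("fold %d variant %s AUC %.4f", j, v, fold_aucs[v][-1])
        except Exception as exc:  # noqa: BLE001 - re-raise with fold provenance
            raise RuntimeError(f"fold {j} failed: {exc}") from exc
    return {v: CVResult(per_fold_auc=fold_aucs[v], seed=seed, variant=v)
            for v in variants}


def run_pipeline(dataset: EEGTrialSet, cfg: PipelineConfig | None = None,
                 seed: int = 0) -> CVResult:
    """Chronological k-fold CV of the full CONV-Net -> ACOVP -> SPDC-Net model."""
    cfg = cfg or PipelineConfig()
    return _run_cv(dataset, cfg, seed, ("acovp",))["acovp"]


def ablation(dataset: EEGTrialSet, variant: str, cfg: PipelineConfig | None = None,
             seed: int = 0) -> tuple[CVResult, CVResult]:
    """Run the pipeline and one component substitution, everything else fixed.

    Returns ``(baseline, variant)`` results; the trained CONV-Net is
    shared within each fold so the comparison isolates the substituted
    component.  ``variant='acovp'`` (or 'block1') is the identity
    ablation and reproduces :func:`run_pipeline` exactly.
    """
    cfg = cfg or PipelineConfig()
    if variant not in _VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {sorted(_VARIANTS)}")
    if variant in ("acovp", "block1"):
        res = _run_cv(dataset, cfg, seed, ("acovp",))["acovp"]
        return res, res
    out = _run_cv(dataset, cfg, seed, ("acovp", variant))
    return out["acovp"], out[variant]


def run_reduced(dataset: EEGTrialSet, fraction: float, repeats: int = 10,
                cfg: PipelineConfig | None = None, seed: int = 0) -> list[CVResult]:
    """Reduced-set robustness runs: subsample, run CV, repeat.

    At fraction 1.0 the subsampling is the identity, so a single repeat
    equals the full-set run for the same seed.
    """
    cfg = cfg or PipelineConfig()
    results = []
    for r in range(repeats):
        sel_rng = np.random.default_rng(seed + 7919 * r)
        sub = reduced_set(dataset, fraction, sel_rng, k=cfg.k_folds)
        res = run_pipeline(sub, cfg, seed)
        res.fraction = fraction
        res.repeat_id = r
        results.append(res)
    return results


def results_to_frame(results: list[CVResult], subject: str = "synthetic"):
    """Flatten CVResults to a tidy table (one row per fold)."""
    import pandas as pd

    rows = []
    for res in results:
        for fold, a in enumerate(res.per_fold_auc):
            rows.append({"subject": subject, "fraction": res.fraction,
                         "repeat": res.repeat_id, "fold": fold, "auc": a,
                         "seed": res.seed, "variant": res.variant})
    return pd.DataFrame(rows)
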