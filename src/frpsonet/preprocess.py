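"""Coregistration preprocessing: from continuous EEG + gaze to epoched FRP trials.

The chain mirrors standard fixation-related-potential dataset
construction: velocity/acceleration/dispersion fixation parsing of the
gaze trace, validation of the first on-circle fixation per trial,
zero-phase Butterworth bandpass of the EEG, fixation-locked epoching,
pre-onset baseline correction, sliding-window peak-to-peak artifact
rejection, and polyphase downsampling to 128 Hz.

Ocular-artifact removal by independent component analysis is a
deliberate no-op stage here: the synthetic sessions this package
processes contain no ocular sources, and the stage is logged for
provenance only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, filtfilt, resample_poly

from .synth import EEGTrialSet, RawRecording

logger = logging.getLogger(__name__)

__all__ = [
    "FixationEvent",
    "PreprocConfig",
    "detect_fixations",
    "validate_fixations",
    "bandpass",
    "epoch_trials",
    "baseline_correct",
    "reject_artifacts",
    "resample_epochs",
    "preprocess_recording",
]


@dataclass(frozen=True)
class FixationEvent:
    onset_sample: int          # index at the raw sampling rate
    duration_ms: float
    centroid: tuple[float, float]  # degrees of visual angle

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")


@dataclass(frozen=True)
class PreprocConfig:
    """Thresholds and windows of the FRP extraction chain.

    Defaults: 30 deg/s velocity, 8000 deg/s^2 acceleration and 0.15 deg
    dispersion fixation parsing; 3 deg validity radius and 350 ms
    minimum duration; 1-40 Hz order-2 zero-phase Butterworth; epochs
    -200..1000 ms with a -200..-100 ms baseline; 100 uV peak-to-peak
    rejection in 50 ms windows slid by 25 ms; 128 Hz output rate.
    """

    velocity_thr: float = 30.0
    accel_thr: float = 8000.0
    motion_thr: float = 0.15
    valid_radius: float = 3.0
    min_fix_ms: float = 350.0
    band: tuple[float, float] = (1.0, 40.0)
    filter_order: int = 2
    epoch_window: tuple[float, float] = (-200.0, 1000.0)
    baseline_window: tuple[float, float] = (-200.0, -100.0)
    p2p_thr: float = 100.0
    p2p_win_ms: float = 50.0
    p2p_step_ms: float = 25.0
    fs_out: float = 128.0
    smooth_samples: int = 5  # moving-average width for gaze derivatives

    def __post_init__(self) -> None:
        for name in ("velocity_thr", "accel_thr", "motion_thr", "valid_radius",
                     "min_fix_ms", "p2p_thr", "p2p_win_ms", "p2p_step_ms", "fs_out"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.baseline_window
        if not (self.epoch_window[0] <= lo < hi <= self.epoch_window[1]):
            raise ValueError("baseline_window must lie within the epoch window")


# --------------------------------------------------------------------------
# Fixation parsing


def detect_fixations(gaze: np.ndarray, fs: float,
                     cfg: PreprocConfig | None = None) -> list[FixationEvent]:
    """Parse a uniformly sampled gaze trace into fixation events.

    Samples below both the velocity and the acceleration threshold are
    fixation candidates; maximal candidate runs are split wherever their
    spatial excursion since fixation start reaches ``motion_thr``.
    Derivatives use central differences on a moving-average-smoothed
    trace.
    """
    cfg = cfg or PreprocConfig()
    gaze = np.asarray(gaze, dtype=float)
    if gaze.ndim != 2 or gaze.shape[1] != 2:
        raise ValueError("gaze must be (n_samples, 2)")
    n = gaze.shape[0]
    if n < 2:
        raise ValueError("gaze trace must contain at least 2 samples")

    smooth = uniform_filter1d(gaze, size=cfg.smooth_samples, axis=0, mode="nearest")
    vel = np.gradient(smooth, axis=0) * fs          # deg/s per axis
    speed = np.hypot(vel[:, 0], vel[:, 1])
    acc = np.gradient(vel, axis=0) * fs             # deg/s^2 per axis
    acc_mag = np.hypot(acc[:, 0], acc[:, 1])

    candidate = (speed < cfg.velocity_thr) & (acc_mag < cfg.accel_thr)

    events: list[FixationEvent] = []
    edges = np.flatnonzero(np.diff(candidate.astype(np.int8)))
    starts = [0] if candidate[0] else []
    starts += [int(e) + 1 for e in edges if candidate[e + 1]]
    ends = [int(e) + 1 for e in edges if candidate[e]]
    if candidate[-1]:
        ends.append(n)

    for run_start, run_end in zip(starts, ends):
        seg_start = run_start
        xmin = xmax = gaze[run_start, 0]
        ymin = ymax = gaze[run_start, 1]
        for i in range(run_start + 1, run_end):
            x, y = gaze[i]
            nxmin, nxmax = min(xmin, x), max(xmax, x)
            nymin, nymax = min(ymin, y), max(ymax, y)
            if (nxmax - nxmin) >= cfg.motion_thr or (nymax - nymin) >= cfg.motion_thr:
                events.append(_make_event(gaze, seg_start, i, fs))
                seg_start = i
                xmin = xmax = x
                ymin = ymax = y
            else:
                xmin, xmax, ymin, ymax = nxmin, nxmax, nymin, nymax
        events.append(_make_event(gaze, seg_start, run_end, fs))
    return [e for e in events if e is not None]


def _make_event(gaze: np.ndarray, start: int, end: int, fs: float) -> FixationEvent | None:
    if end - start < 2:
        return None
    seg = gaze[start:end]
    return FixationEvent(
        onset_sample=int(start),
        duration_ms=(end - start) / fs * 1000.0,
        centroid=(float(seg[:, 0].mean()), float(seg[:, 1].mean())),
    )


def validate_fixations(
    fixations: list[FixationEvent],
    trials: list[tuple[int, int, tuple[float, float]]],
    cfg: PreprocConfig | None = None,
) -> list[tuple[int, FixationEvent]]:
    """Keep the first valid fixation per trial interval.

    ``trials`` is a list of ``(start_sample, end_sample, circle_center)``
    intervals.  A fixation is valid when its onset falls in the
    interval, its centroid lies within ``valid_radius`` of the guiding
    circle's center, and it lasts strictly longer than ``min_fix_ms``.
    Returns ``(trial_index, fixation)`` pairs.
    """
    cfg = cfg or PreprocConfig()
    kept: list[tuple[int, FixationEvent]] = []
    fixations = sorted(fixations, key=lambda e: e.onset_sample)
    for t_idx, (start, end, center) in enumerate(trials):
        for fix in fixations:
            if not (start <= fix.onset_sample < end):
                continue
            dist = np.hypot(fix.centroid[0] - center[0], fix.centroid[1] - center[1])
            if dist <= cfg.valid_radius and fix.duration_ms > cfg.min_fix_ms:
                kept.append((t_idx, fix))
                break
    return kept


# --------------------------------------------------------------------------
# EEG chain


def bandpass(eeg: np.ndarray, fs: float, cfg: PreprocConfig | None = None) -> np.ndarray:
    """Zero-phase (forward-backward) order-2 Butterworth bandpass per channel."""
    cfg = cfg or PreprocConfig()
    eeg = np.asarray(eeg, dtype=float)
    if not np.all(np.isfinite(eeg)):
        raise ValueError("EEG contains non-finite values")
    if fs <= 2 * cfg.band[1]:
        raise ValueError("sampling rate must exceed twice the upper band edge")
    b, a = butter(cfg.filter_order, cfg.band, btype="bandpass", fs=fs)
    return filtfilt(b, a, eeg, axis=-1)


def ica_ocular_removal(eeg: np.ndarray) -> np.ndarray:
    """Ocular-artifact stage: intentionally a pass-through.

    Synthetic sessions contain no ocular sources; the stage exists so
    the chain's provenance log mirrors a full coregistration pipeline.
    """
    logger.info("ICA ocular-artifact stage: no-op (no ocular sources present)")
    return eeg


def epoch_trials(eeg: np.ndarray, onsets: np.ndarray, fs: float,
                 cfg: PreprocConfig | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Cut fixation-locked epochs from continuous EEG.

    The window is closed at the left edge and half-open at the right
    (1200 samples for -200..1000 ms at 1 kHz); the sample at the onset
    is the t = 0 sample.  Onsets without a full window are dropped with
    a logged warning.  Returns ``(epochs, kept_mask)``.
    """
    cfg = cfg or PreprocConfig()
    eeg = np.asarray(eeg, dtype=float)
    onsets = np.asarray(onsets, dtype=int)
    lo = int(round(cfg.epoch_window[0] / 1000.0 * fs))
    hi = int(round(cfg.epoch_window[1] / 1000.0 * fs))
    n = eeg.shape[-1]
    kept = np.ones(len(onsets), dtype=bool)
    epochs = []
    for i, onset in enumerate(onsets):
        if onset + lo < 0 or onset + hi > n:
            logger.warning("dropping onset %d: epoch window outside recording", onset)
            kept[i] = False
            continue
        epochs.append(eeg[..., onset + lo:onset + hi])
    if not epochs:
        return np.empty((0, eeg.shape[0], hi - lo)), kept
    return np.stack(epochs), kept


def baseline_correct(epochs: np.ndarray, fs: float,
                     cfg: PreprocConfig | None = None) -> np.ndarray:
    """Subtract the per-epoch, per-channel mean over the baseline window."""
    cfg = cfg or PreprocConfig()
    epochs = np.asarray(epochs, dtype=float)
    lo = int(round((cfg.baseline_window[0] - cfg.epoch_window[0]) / 1000.0 * fs))
    hi = int(round((cfg.baseline_window[1] - cfg.epoch_window[0]) / 1000.0 * fs))
    base = epochs[..., lo:hi].mean(axis=-1, keepdims=True)
    return epochs - base


def reject_artifacts(epochs: np.ndarray, fs: float,
                     cfg: PreprocConfig | None = None) -> np.ndarray:
    """Peak-to-peak artifact rejection; returns a keep mask.

    An epoch is rejected iff any channel's max-min in any sliding window
    (final partial window included) strictly exceeds ``p2p_thr``.
    """
    cfg = cfg or PreprocConfig()
    epochs = np.asarray(epochs, dtype=float)
    n = epochs.shape[-1]
    win = int(round(cfg.p2p_win_ms / 1000.0 * fs))
    step = int(round(cfg.p2p_step_ms / 1000.0 * fs))
    if n <= win:
        raise ValueError("epoch must be longer than one peak-to-peak window")
    keep = np.ones(epochs.shape[0], dtype=bool)
    for start in range(0, n, step):
        seg = epochs[..., start:start + win]
        p2p = seg.max(axis=-1) - seg.min(axis=-1)     # (trials, channels)
        keep &= ~(p2p > cfg.p2p_thr).any(axis=-1)
        if start + win >= n:
            break
    return keep


def resample_epochs(epochs: np.ndarray, fs: float,
                    cfg: PreprocConfig | None = None) -> np.ndarray:
    """Crop epochs to the (0, 1000) ms analysis window and resample to fs_out.

    Rational polyphase resampling (16/125 for 1000 -> 128 Hz) yields
    exactly 128 samples per epoch.
    """
    cfg = cfg or PreprocConfig()
    if cfg.fs_out >= fs:
        raise ValueError("fs_out must be below the raw sampling rate")
    epochs = np.asarray(epochs, dtype=float)
    lo = int(round((0.0 - cfg.epoch_window[0]) / 1000.0 * fs))
    hi = int(round((1000.0 - cfg.epoch_window[0]) / 1000.0 * fs))
    cropped = epochs[..., lo:hi]
    from fractions import Fraction

    frac = Fraction(int(round(cfg.fs_out)), int(round(fs)))
    return resample_poly(cropped, frac.numerator, frac.denominator, axis=-1)


# --------------------------------------------------------------------------
# Full chain


def preprocess_recording(rec: RawRecording,
                         cfg: PreprocConfig | None = None) -> EEGTrialSet:
    """Run the full coregistration chain on a continuous session.

    Fixation detection/validation on the gaze trace; bandpass, epoching,
    baseline correction, artifact rejection, and downsampling on the
    EEG; labels taken from the per-trial target flag of the validated
    fixations.
    """
    cfg = cfg or PreprocConfig()
    fixations = detect_fixations(rec.gaze, rec.fs, cfg)
    bounds = [s for (s, _, _) in rec.events] + [rec.eeg.shape[1]]
    trials = [(bounds[i], bounds[i + 1], rec.events[i][1])
              for i in range(len(rec.events))]
    valid = validate_fixations(fixations, trials, cfg)
    logger.info("fixation validation kept %d / %d trials", len(valid), len(trials))

    filtered = ica_ocular_removal(bandpass(rec.eeg, rec.fs, cfg))
    onsets = np.array([fix.onset_sample for (_, fix) in valid], dtype=int)
    labels = np.array([rec.events[t_idx][2] for (t_idx, _) in valid], dtype=int)

    epochs, kept = epoch_trials(filtered, onsets, rec.fs, cfg)
    labels = labels[kept]
    epochs = baseline_correct(epochs, rec.fs, cfg)
    keep = reject_artifacts(epochs, rec.fs, cfg)
    logger.info("artifact rejection kept %d / %d epochs", int(keep.sum()), len(keep))
    epochs, labels = epochs[keep], labels[keep]
    data = resample_epochs(epochs, rec.fs, cfg)
    return EEGTrialSet(data=data, labels=labels, fs=cfg.fs_out, layout=rec.layout,
                       order=np.arange(len(labels)))
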