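"""Synthetic fixation-related potential (FRP) generator.

Emulates the statistical structure of a guided visual-search FRP study:
rare (~12%) target fixations elicit a sustained positive P300-like
component with a centroparietal topography, superimposed on spatially
correlated colored background EEG; nontarget fixations contain noise
only.  Both pre-epoched trial sets and continuous coregistered
EEG + gaze sessions can be generated, so the whole downstream pipeline
(coregistration preprocessing, convolutional frontend, covariance
pooling, manifold classifier) is testable without access to recorded
data.

All randomness flows from a single integer seed; generation is
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CHANNEL_NAMES",
    "ChannelLayout",
    "SynthConfig",
    "EEGTrialSet",
    "RawRecording",
    "make_channel_layout",
    "synth_trial",
    "synth_dataset",
    "synth_session",
]

#: The 19-electrode montage of the study (10-10 subset, posterior-heavy).
CHANNEL_NAMES = (
    "Fz", "FCz", "Cz", "C3", "C4", "CPz", "Pz", "P3", "P4", "P7",
    "P8", "POz", "PO3", "PO4", "PO7", "PO8", "Oz", "O1", "O2",
)

# Unit-free P300 topography: maximal over the centroparietal midline
# (Cz, CPz, Pz), falling off toward frontal and occipital sites.
_P300_WEIGHTS = {
    "Fz": 0.60, "FCz": 0.85, "Cz": 1.00, "C3": 0.70, "C4": 0.70,
    "CPz": 1.00, "Pz": 1.00, "P3": 0.85, "P4": 0.85, "P7": 0.50,
    "P8": 0.50, "POz": 0.65, "PO3": 0.55, "PO4": 0.55, "PO7": 0.40,
    "PO8": 0.40, "Oz": 0.35, "O1": 0.30, "O2": 0.30,
}


@dataclass(frozen=True)
class ChannelLayout:
    """Ordered electrode names with a per-channel topographic weight."""

    names: tuple[str, ...]
    spatial_weight: np.ndarray  # shape (n_channels,), values in [0, 1]

    def __post_init__(self) -> None:
        if len(self.names) != 19:
            raise ValueError(f"layout requires exactly 19 channels, got {len(self.names)}")
        if len(set(self.names)) != len(self.names):
            raise ValueError("channel names must be unique")
        w = np.asarray(self.spatial_weight, dtype=float)
        if w.shape != (len(self.names),):
            raise ValueError("spatial_weight must have one entry per channel")
        object.__setattr__(self, "spatial_weight", w)

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def weight(self, name: str) -> float:
        return float(self.spatial_weight[self.index(name)])


def make_channel_layout() -> ChannelLayout:
    """Return the fixed 19-channel montage with P300 spatial weights."""
    w = np.array([_P300_WEIGHTS[name] for name in CHANNEL_NAMES])
    return ChannelLayout(names=CHANNEL_NAMES, spatial_weight=w)


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic FRP model.

    Amplitudes are in microvolts, latencies and widths in milliseconds.
    ``target_rate`` defaults to 0.12, the target appearance probability
    of a 5x5 letter grid containing 3 targets (3/25).
    """

    fs_raw: float = 1000.0
    fs_out: float = 128.0
    epoch_window: tuple[float, float] = (0.0, 1000.0)
    p300_amplitude: float = 5.0
    p300_latency_mean: float = 400.0
    p300_latency_jitter_sd: float = 30.0
    p300_width: float = 300.0
    noise_sd: float = 10.0
    noise_model: str = "pink"
    target_rate: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_rate <= 1.0:
            raise ValueError("target_rate must lie in [0, 1]")
        if self.noise_model not in ("pink", "AR1"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        for name in ("p300_amplitude", "p300_latency_mean", "p300_width", "noise_sd"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.fs_out > self.fs_raw:
            raise ValueError("fs_out must not exceed fs_raw")

    @property
    def n_samples_out(self) -> int:
        span_s = (self.epoch_window[1] - self.epoch_window[0]) / 1000.0
        return int(round(self.fs_out * span_s))


@dataclass
class EEGTrialSet:
    """Epoched trials: ``data`` is (trials, channels, samples) in microvolts."""

    data: np.ndarray
    labels: np.ndarray  # 1 = target, 0 = nontarget
    fs: float
    layout: ChannelLayout
    order: np.ndarray = field(default=None)  # chronological trial index

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must equal trial count")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data must be finite")
        if self.order is None:
            self.order = np.arange(self.data.shape[0])
        self.order = np.asarray(self.order, dtype=int)
        if np.any(np.diff(self.order) <= 0):
            raise ValueError("order must be strictly ascending")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def subset(self, idx: np.ndarray) -> "EEGTrialSet":
        idx = np.asarray(idx, dtype=int)
        return EEGTrialSet(
            data=self.data[idx],
            labels=self.labels[idx],
            fs=self.fs,
            layout=self.layout,
            order=self.order[idx],
        )


@dataclass
class RawRecording:
    """Continuous coregistered session on a common clock.

    ``eeg``: (channels, samples) microvolts at ``fs``; ``gaze``:
    (samples, 2) horizontal/vertical gaze position in degrees of visual
    angle; ``events``: one ``(onset_sample, (x, y), is_target)`` triple
    per guiding-circle movement.
    """

    eeg: np.ndarray
    gaze: np.ndarray
    events: list[tuple[int, tuple[float, float], bool]]
    fs: float
    layout: ChannelLayout

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.gaze = np.asarray(self.gaze, dtype=float)
        if self.eeg.shape[1] != self.gaze.shape[0]:
            raise ValueError("eeg and gaze must share a common clock (equal sample count)")
        n = self.eeg.shape[1]
        for s, _, _ in self.events:
            if not 0 <= s < n:
                raise ValueError("event sample outside recording bounds")


# --------------------------------------------------------------------------
# Noise model


def _pink_noise(n_series: int, n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise via spectral shaping."""
    white = rng.standard_normal((n_series, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    x = np.fft.irfft(spec * scale, n=n_samples, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _ar1_noise(n_series: int, n_samples: int, rng: np.random.Generator,
               phi: float = 0.95) -> np.ndarray:
    """Unit-variance AR(1) noise, stationary initialization."""
    e = rng.standard_normal((n_series, n_samples)) * np.sqrt(1.0 - phi**2)
    from scipy.signal import lfilter

    x = lfilter([1.0], [1.0, -phi], e, axis=-1)
    x[:, 0] = rng.standard_normal(n_series)  # stationary start
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _mixing_matrix(n_channels: int) -> np.ndarray:
    """Fixed spatial mixing of independent noise sources.

    A structural constant of the generator (not a random variable): rows
    are unit-norm so the per-channel noise SD is preserved, and the
    off-diagonal loading induces realistic inter-channel correlation.
    """
    rng = np.random.default_rng(1859)
    mix = np.eye(n_channels) + 0.5 * rng.standard_normal((n_channels, n_channels))
    mix /= np.linalg.norm(mix, axis=1, keepdims=True)
    return mix


_MIX_CACHE: dict[int, np.ndarray] = {}


def _noise(n_channels: int, n_samples: int, cfg: SynthConfig,
           rng: np.random.Generator) -> np.ndarray:
    if cfg.noise_sd == 0:
        return np.zeros((n_channels, n_samples))
    if cfg.noise_model == "pink":
        src = _pink_noise(n_channels, n_samples, rng)
    else:
        src = _ar1_noise(n_channels, n_samples, rng)
    if n_channels not in _MIX_CACHE:
        _MIX_CACHE[n_channels] = _mixing_matrix(n_channels)
    return cfg.noise_sd * (_MIX_CACHE[n_channels] @ src)


# --------------------------------------------------------------------------
# Waveform model


def _p300_pulse(t_s: np.ndarray, center_ms: float, width_ms: float,
                amplitude: float) -> np.ndarray:
    """Half-period raised-cosine positivity: smooth, unimodal, compact."""
    c = center_ms / 1000.0
    w = width_ms / 1000.0
    if w <= 0:
        return np.zeros_like(t_s)
    phase = (t_s - c) / w
    pulse = np.where(np.abs(phase) <= 0.5,
                     0.5 * amplitude * (1.0 + np.cos(2.0 * np.pi * phase)),
                     0.0)
    return pulse


def _draw_latency(cfg: SynthConfig, rng: np.random.Generator) -> float:
    """Gaussian latency jitter, truncated so the pulse stays in the epoch."""
    lat = cfg.p300_latency_mean + cfg.p300_latency_jitter_sd * rng.standard_normal()
    lo = cfg.epoch_window[0] + cfg.p300_width / 2.0
    hi = cfg.epoch_window[1] - cfg.p300_width / 2.0
    return float(np.clip(lat, lo, hi))


def synth_trial(label: int, cfg: SynthConfig,
                rng: np.random.Generator | None = None,
                layout: ChannelLayout | None = None) -> np.ndarray:
    """Generate one epoched trial, (19 channels, fs_out * 1 s samples), in uV.

    Target trials (label 1) receive an additive raised-cosine positivity
    at a jittered latency, scaled per channel by the P300 topography;
    nontarget trials (label 0) contain background noise only.
    """
    if label not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {label!r}")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if layout is None:
        layout = make_channel_layout()
    n = cfg.n_samples_out
    t_s = cfg.epoch_window[0] / 1000.0 + np.arange(n) / cfg.fs_out
    trial = _noise(layout.n_channels, n, cfg, rng)
    # Keep the per-trial random stream layout identical for both labels
    # so label flips do not shift subsequent trials' noise draws.
    lat = _draw_latency(cfg, rng)
    if label == 1:
        pulse = _p300_pulse(t_s, lat, cfg.p300_width, cfg.p300_amplitude)
        trial = trial + layout.spatial_weight[:, None] * pulse[None, :]
    return trial


def _target_positions(n_trials: int, target_rate: float,
                      rng: np.random.Generator) -> np.ndarray:
    n_targets = int(round(n_trials * target_rate))
    labels = np.zeros(n_trials, dtype=int)
    pos = rng.permutation(n_trials)[:n_targets]
    labels[pos] = 1
    return labels


def synth_dataset(cfg: SynthConfig, n_trials: int,
                  rng: np.random.Generator | None = None) -> EEGTrialSet:
    """Generate an epoched trial set with exactly round(n * target_rate) targets."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    layout = make_channel_layout()
    labels = _target_positions(n_trials, cfg.target_rate, rng)
    data = np.empty((n_trials, layout.n_channels, cfg.n_samples_out))
    for i, lab in enumerate(labels):
        data[i] = synth_trial(int(lab), cfg, rng, layout)
    return EEGTrialSet(data=data, labels=labels, fs=cfg.fs_out, layout=layout,
                       order=np.arange(n_trials))


# --------------------------------------------------------------------------
# Continuous session


_GRID_DEG = 4.0        # letter spacing in degrees of visual angle
_SACCADE_MS = 40.0     # guided saccade duration
_TRIAL_MS = 1000.0     # guiding-circle dwell per letter
_LEAD_MS = 400.0       # settling fixation before the first movement
_TAIL_MS = 1200.0      # trailing context so the last epoch fits
_DRIFT_AMP_DEG = 0.03  # slow within-fixation ocular drift amplitude
_DRIFT_HZ = 1.3


def synth_session(cfg: SynthConfig, n_fixations: int,
                  rng: np.random.Generator | None = None) -> RawRecording:
    """Generate a continuous coregistered EEG + gaze session.

    The gaze trace alternates high-velocity saccades between 5x5 grid
    positions with long (> 350 ms) low-dispersion fixations; FRP
    responses are embedded in the EEG at target fixation onsets.
    """
    if n_fixations < 1:
        raise ValueError("n_fixations must be >= 1")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    layout = make_channel_layout()
    fs = cfg.fs_raw
    n_total = int(round((_LEAD_MS + n_fixations * _TRIAL_MS + _TAIL_MS) / 1000.0 * fs))
    ms2samp = fs / 1000.0

    grid = np.array([(-2 + i) * _GRID_DEG for i in range(5)])
    coords = np.array([(x, y) for x in grid for y in grid])

    is_target = _target_positions(n_fixations, cfg.target_rate, rng).astype(bool)
    pos_idx = rng.integers(0, len(coords), size=n_fixations + 1)
    # guiding circle always moves to a *different* letter
    for i in range(1, n_fixations + 1):
        while pos_idx[i] == pos_idx[i - 1]:
            pos_idx[i] = rng.integers(0, len(coords))
    positions = coords[pos_idx]

    gaze = np.empty((n_total, 2))
    gaze[:] = positions[0]
    t = np.arange(n_total) / fs
    events: list[tuple[int, tuple[float, float], bool]] = []

    n_sacc = int(round(_SACCADE_MS * ms2samp))
    for i in range(n_fixations):
        move_start = int(round((_LEAD_MS + i * _TRIAL_MS) * ms2samp))
        onset = move_start + n_sacc
        seg_end = int(round((_LEAD_MS + (i + 1) * _TRIAL_MS) * ms2samp))
        frac = np.linspace(0.0, 1.0, n_sacc, endpoint=False)[:, None]
        gaze[move_start:onset] = positions[i] + frac * (positions[i + 1] - positions[i])
        phase = rng.uniform(0, 2 * np.pi, size=2)
        drift = _DRIFT_AMP_DEG * np.sin(
            2 * np.pi * _DRIFT_HZ * t[onset:seg_end, None] + phase[None, :])
        gaze[onset:seg_end] = positions[i + 1] + drift
        gaze[seg_end:] = positions[i + 1]
        events.append((onset, (float(positions[i + 1][0]), float(positions[i + 1][1])),
                       bool(is_target[i])))

    eeg = _noise(layout.n_channels, n_total, cfg, rng)
    t_ms = np.arange(n_total) / ms2samp
    for (onset, _, tgt) in events:
        lat = _draw_latency(cfg, rng)
        if tgt:
            onset_ms = onset / ms2samp
            lo = int(max(0, onset + (lat - cfg.p300_width) * ms2samp))
            hi = int(min(n_total, onset + (lat + cfg.p300_width) * ms2samp))
            pulse = _p300_pulse(t_ms[lo:hi] / 1000.0, onset_ms + lat, cfg.p300_width,
                                cfg.p300_amplitude)
            eeg[:, lo:hi] += layout.spatial_weight[:, None] * pulse[None, :]
    return RawRecording(eeg=eeg, gaze=gaze, events=events, fs=fs, layout=layout)
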