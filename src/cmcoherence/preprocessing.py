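"""Conditioning chain from raw session to analysis-ready hold-phase segments.

The fixed pipeline order is: band-pass filter -> average reference -> full-wave
rectify (EMG only) -> extract hold-phase windows -> per-segment demean ->
per-channel unit-variance normalization.  Rectification and normalization do
not commute, so `preprocess` is the one public entry point that applies all
stages in order; the individual stages are exposed for testing and reuse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

from .synthetic import EEG_CHANNEL, EMG_CHANNELS, Session

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    """Filtering, referencing, rectification and windowing settings.

    Defaults reproduce the standard corticomuscular-coherence chain: 5-1000 Hz
    zero-phase band-pass, average reference, full-wave rectified EMG, and a
    2 s hold-phase window starting 0.85 s after ramp onset.
    """

    hp_hz: float = 5.0
    lp_hz: float = 1000.0
    reference: str = "average"
    eeg_channel: str = EEG_CHANNEL
    emg_channels: tuple[str, ...] = EMG_CHANNELS
    rectify_emg: bool = True
    window_start_s: float = 0.85
    window_len_s: float = 2.0
    demean_segments: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.hp_hz < self.lp_hz):
            raise ValueError(
                f"need 0 < hp_hz < lp_hz, got ({self.hp_hz}, {self.lp_hz})"
            )
        if self.reference not in ("average", "none"):
            raise ValueError(f"unknown reference {self.reference!r}")
        if self.window_len_s <= 0:
            raise ValueError("window_len_s must be > 0")


@dataclass
class SegmentSet:
    """L aligned segments of T samples for one channel pair (x, y)."""

    x_segments: np.ndarray  # (L, T)
    y_segments: np.ndarray  # (L, T)
    fs_hz: float
    pair: tuple[str, str]

    def __post_init__(self) -> None:
        self.x_segments = np.asarray(self.x_segments, dtype=float)
        self.y_segments = np.asarray(self.y_segments, dtype=float)
        if self.x_segments.ndim != 2 or self.y_segments.ndim != 2:
            raise ValueError("segments must be 2-D (L, T) arrays")
        if self.x_segments.shape != self.y_segments.shape:
            raise ValueError(
                f"x and y segment shapes differ: "
                f"{self.x_segments.shape} vs {self.y_segments.shape}"
            )
        if self.L < 2:
            raise ValueError("need at least 2 segments")

    @property
    def L(self) -> int:
        return self.x_segments.shape[0]

    @property
    def T(self) -> int:
        return self.x_segments.shape[1]


def bandpass_sos(hp_hz: float, lp_hz: float, fs_hz: float) -> np.ndarray:
    nyq = fs_hz / 2.0
    if lp_hz >= nyq:
        clipped = 0.99 * nyq
        logger.warning(
            "low-pass corner %.6g Hz at or above Nyquist (%.6g Hz); "
            "clipping to %.6g Hz", lp_hz, nyq, clipped,
        )
        lp_hz = clipped
    return signal.butter(4, [hp_hz, lp_hz], btype="bandpass", fs=fs_hz,
                         output="sos")


def filter_channels(session: Session, cfg: PreprocessConfig) -> Session:
    """Zero-phase band-pass of every EEG/EMG channel; force/trigger untouched."""
    sos = bandpass_sos(cfg.hp_hz, cfg.lp_hz, session.fs_hz)
    out = session.copy()
    for name in session.signal_channels():
        out.channels[name] = signal.sosfiltfilt(sos, session.channels[name])
    return out


def average_reference(
    session: Session, eeg_channel_names: Sequence[str]
) -> Session:
    """Subtract the instantaneous mean of the EEG montage from each EEG
    channel.  With fewer than two EEG channels this is a logged no-op (the
    64-channel montage of a real recording is not reproduced synthetically)."""
    for name in eeg_channel_names:
        if name not in session.channels:
            raise KeyError(f"unknown EEG channel {name!r}")
    if len(eeg_channel_names) < 2:
        logger.info(
            "average reference skipped: %d EEG channel(s) present",
            len(eeg_channel_names),
        )
        return session.copy()
    out = session.copy()
    mean = np.mean([session.channels[n] for n in eeg_channel_names], axis=0)
    for name in eeg_channel_names:
        out.channels[name] = session.channels[name] - mean
    return out


def rectify(emg_samples: np.ndarray) -> np.ndarray:
    """Full-wave rectification: elementwise absolute value."""
    return np.abs(np.asarray(emg_samples))


def normalize_segments(segments: np.ndarray) -> np.ndarray:
    """Scale so the pooled sample variance across all segments is one."""
    pooled_var = float(np.mean(segments**2) - np.mean(segments) ** 2)
    if pooled_var <= 0:
        raise ValueError("cannot normalize: zero pooled variance")
    return segments / np.sqrt(pooled_var)


def extract_segments(
    session: Session, cfg: PreprocessConfig, pair: Sequence[str]
) -> SegmentSet:
    """Cut the per-trial hold-phase windows for a channel pair.

    Windows are 0-based, half-open [start, start + T) anchored at
    onset + window_start_s.  EMG channels are rectified first when the config
    says so; each segment is then mean-subtracted and each channel scaled to
    pooled unit variance.  Trials whose window falls outside the record are
    dropped with a warning.
    """
    fs = session.fs_hz
    T = int(round(cfg.window_len_s * fs))
    n = session.n_samples

    data = {}
    for name in pair:
        if name not in session.channels:
            raise KeyError(f"channel {name!r} not in session")
        x = session.channels[name]
        if cfg.rectify_emg and name in cfg.emg_channels:
            x = rectify(x)
        data[name] = x

    starts = []
    for onset in session.trial_onsets_s:
        s = int(round((onset + cfg.window_start_s) * fs))
        if s < 0 or s + T > n:
            logger.warning(
                "trial at %.3f s: window [%d, %d) outside record of %d "
                "samples; dropped", onset, s, s + T, n,
            )
            continue
        starts.append(s)
    if len(starts) < 2:
        raise ValueError(
            f"only {len(starts)} usable trial(s); need at least 2"
        )

    segs = {}
    for name in pair:
        x = data[name]
        m = np.stack([x[s : s + T] for s in starts])
        if cfg.demean_segments:
            m = m - m.mean(axis=1, keepdims=True)
        segs[name] = normalize_segments(m)

    return SegmentSet(
        x_segments=segs[pair[0]],
        y_segments=segs[pair[1]],
        fs_hz=fs,
        pair=(pair[0], pair[1]),
    )


def preprocess(
    session: Session, cfg: PreprocessConfig, pair: Sequence[str]
) -> SegmentSet:
    """Full conditioning chain in the fixed order:
    filter -> reference -> rectify -> segment -> demean -> normalize."""
    s = filter_channels(session, cfg)
    if cfg.reference == "average":
        eeg = [c for c in s.signal_channels() if c not in cfg.emg_channels]
        s = average_reference(s, eeg)
    return extract_segments(s, cfg, pair)
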