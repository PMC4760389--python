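"""Synthetic EEG/EMG/force sessions with a known band-limited common drive.

The generative model is a single cortical "common drive" process c(t): white
Gaussian noise band-pass filtered to the beta band (15-30 Hz by default) and
standardized to zero mean, unit variance.  One EEG channel receives the drive
directly; two hand-muscle EMG channels (APB, FDI) receive it after a
corticospinal conduction delay (~11 ms).  Independent Gaussian noise is added
to every channel.  Because every parameter of the model is known, the
downstream spectral estimators can be validated by parameter recovery:
`theoretical_coherence` gives the exact coherence the estimators should find.

Two EMG modes are provided:

``linear``
    EMG_k(t) = g_k * c(t - delay_k) + noise_k(t).  The coherence between any
    two channels has the closed form implemented in `theoretical_coherence`,
    so this mode is the quantitative recovery target (with rectification
    disabled downstream).

``modulation``
    EMG_k(t) = (1 + m_k * c(t - delay_k)) * carrier_k(t) with a broadband
    Gaussian carrier.  This mimics an interference-pattern EMG whose envelope
    is driven by the cortical input, which is the regime where full-wave
    rectification is physiologically meaningful.  No closed-form coherence is
    claimed; it is validated qualitatively.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

EEG_CHANNEL = "C4"
EMG_CHANNELS = ("APB", "FDI")
FORCE_CHANNEL = "FORCE"

_FILTER_ORDER = 4  # Butterworth band-pass order for the drive process


@dataclass(frozen=True)
class DriveModelParams:
    """Parameters of the common-drive generative model.

    Gains are dimensionless couplings of the unit-variance drive into each
    channel; in ``modulation`` mode the EMG gains are reused as modulation
    depths.  Delays are corticospinal conduction delays in seconds.  The
    default gains (0.1 against unit noise SD) put beta-band coherence near
    0.2, the order of magnitude seen in real corticomuscular recordings.
    """

    band_lo_hz: float = 15.0
    band_hi_hz: float = 30.0
    g_eeg: float = 0.1
    g_apb: float = 0.1
    g_fdi: float = 0.1
    delay_apb_s: float = 0.011
    delay_fdi_s: float = 0.011
    noise_sd_eeg: float = 1.0
    noise_sd_apb: float = 1.0
    noise_sd_fdi: float = 1.0
    emg_mode: str = "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.band_lo_hz < self.band_hi_hz):
            raise ValueError(
                f"need 0 < band_lo_hz < band_hi_hz, got "
                f"({self.band_lo_hz}, {self.band_hi_hz})"
            )
        for name in ("g_eeg", "g_apb", "g_fdi",
                     "noise_sd_eeg", "noise_sd_apb", "noise_sd_fdi"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.delay_apb_s < 0 or self.delay_fdi_s < 0:
            raise ValueError("delays must be >= 0")
        if self.emg_mode not in ("linear", "modulation"):
            raise ValueError(f"unknown emg_mode {self.emg_mode!r}")

    def gain(self, channel: str) -> float:
        return {"C4": self.g_eeg, "APB": self.g_apb, "FDI": self.g_fdi}[channel]

    def noise_sd(self, channel: str) -> float:
        return {
            "C4": self.noise_sd_eeg,
            "APB": self.noise_sd_apb,
            "FDI": self.noise_sd_fdi,
        }[channel]

    def delay_s(self, channel: str) -> float:
        return {"C4": 0.0, "APB": self.delay_apb_s, "FDI": self.delay_fdi_s}[channel]


@dataclass(frozen=True)
class ProtocolParams:
    """Ramp-hold force-tracking protocol: 3 blocks of 50 trials, each a
    0.5 s ramp to a 5.5 N plateau held 3 s, followed by 3 s rest, at 2048 Hz."""

    fs_hz: float = 2048.0
    n_blocks: int = 3
    trials_per_block: int = 50
    plateau_n: float = 5.5
    plateau_s: float = 3.0
    rest_s: float = 3.0
    ramp_rise_s: float = 0.5
    force_noise_sd: float = 0.1

    def __post_init__(self) -> None:
        for name in ("plateau_s", "rest_s", "ramp_rise_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be > 0")
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise ValueError("need at least one block and one trial per block")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def trial_period_s(self) -> float:
        return self.ramp_rise_s + self.plateau_s + self.rest_s


@dataclass
class Session:
    """One subject x one measurement: named channels, sampling rate, trial
    ramp-onset times and free-form metadata."""

    channels: dict[str, np.ndarray]
    fs_hz: float
    trial_onsets_s: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {name: len(x) for name, x in self.channels.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"channels have unequal lengths: {lengths}")
        self.trial_onsets_s = np.asarray(self.trial_onsets_s, dtype=float)
        if len(self.trial_onsets_s) and not np.all(
            np.diff(self.trial_onsets_s) > 0
        ):
            raise ValueError("trial onsets must be strictly increasing")
        if len(self.trial_onsets_s):
            if self.trial_onsets_s[0] < 0 or (
                self.trial_onsets_s[-1] > self.n_samples / self.fs_hz
            ):
                raise ValueError("trial onsets outside the record")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def signal_channels(self) -> list[str]:
        """EEG/EMG channel names (everything except force/trigger traces)."""
        return [c for c in self.channels if c not in (FORCE_CHANNEL, "TRIG")]

    def copy(self) -> "Session":
        return Session(
            channels={k: v.copy() for k, v in self.channels.items()},
            fs_hz=self.fs_hz,
            trial_onsets_s=self.trial_onsets_s.copy(),
            metadata=dict(self.metadata),
        )


def _session_rng(seed: int, subject_id: str, condition: str,
                 session_label: str = "") -> np.random.Generator:
    # Stable stream per (seed, subject, condition[, session]); crc32 rather
    # than hash() so streams survive interpreter restarts.
    keys = [seed & 0x7FFFFFFF]
    for s in (subject_id, condition, session_label):
        keys.append(zlib.crc32(str(s).encode("utf-8")))
    return np.random.default_rng(np.random.SeedSequence(keys))


def drive_filter_sos(params: DriveModelParams, fs_hz: float) -> np.ndarray:
    """Band-pass filter defining the drive's spectral support."""
    nyq = fs_hz / 2.0
    if not (0.0 < params.band_lo_hz < params.band_hi_hz < nyq):
        raise ValueError(
            f"drive band ({params.band_lo_hz}, {params.band_hi_hz}) Hz must "
            f"lie strictly inside (0, {nyq}) Hz"
        )
    return signal.butter(
        _FILTER_ORDER,
        [params.band_lo_hz, params.band_hi_hz],
        btype="bandpass",
        fs=fs_hz,
        output="sos",
    )


def generate_common_drive(
    params: DriveModelParams,
    fs_hz: float,
    duration_s: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian drive confined to the drive band.

    White noise is filtered forward-backward (zero phase) with a 4th-order
    Butterworth band-pass and re-standardized, so the realization has exactly
    zero sample mean and unit sample variance.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = int(round(duration_s * fs_hz))
    if n < 16:
        raise ValueError("duration too short for drive synthesis")
    sos = drive_filter_sos(params, fs_hz)
    raw = rng.standard_normal(n)
    c = signal.sosfiltfilt(sos, raw)
    c = c - c.mean()
    sd = c.std()
    if sd == 0:
        raise RuntimeError("degenerate drive realization")
    return c / sd


def drive_psd(
    params: DriveModelParams, fs_hz: float, freqs_hz: np.ndarray
) -> np.ndarray:
    """Two-sided PSD (units 1/Hz) of the standardized drive at ``freqs_hz``.

    The forward-backward filter has squared magnitude response |H|^4; after
    re-standardization the drive PSD is |H|^4 normalized to integrate to one
    over the full two-sided frequency axis.
    """
    sos = drive_filter_sos(params, fs_hz)
    n_grid = 1 << 14
    w, h = signal.sosfreqz(sos, worN=n_grid, fs=fs_hz)
    shape = np.abs(h) ** 4
    total = 2.0 * np.trapezoid(shape, w)  # two-sided normalization
    freqs_hz = np.atleast_1d(np.asarray(freqs_hz, dtype=float))
    _, h_at = signal.sosfreqz(sos, worN=np.abs(freqs_hz), fs=fs_hz)
    return (np.abs(h_at) ** 4) / total


def theoretical_coherence(
    params: DriveModelParams,
    pair: Sequence[str],
    freq_hz,
    fs_hz: float = 2048.0,
):
    """Exact magnitude-squared coherence of the linear-mode model.

    For channels a, b with gains g_a, g_b, drive PSD S_c(f) and white-noise
    PSD sigma^2/fs, coherence factorizes as

        |R(f)|^2 = [g_a^2 S_c / (g_a^2 S_c + S_a)] *
                   [g_b^2 S_c / (g_b^2 S_c + S_b)].

    Scalar in, scalar out; array in, array out.
    """
    if params.emg_mode != "linear":
        raise ValueError(
            "theoretical_coherence is only defined for emg_mode='linear'"
        )
    a, b = pair
    if a == b:
        raise ValueError("pair must name two distinct channels")
    scalar = np.isscalar(freq_hz)
    f = np.atleast_1d(np.asarray(freq_hz, dtype=float))
    s_c = drive_psd(params, fs_hz, f)
    out = np.ones_like(f)
    for ch in (a, b):
        g2 = params.gain(ch) ** 2
        s_n = params.noise_sd(ch) ** 2 / fs_hz  # two-sided white-noise PSD
        num = g2 * s_c
        den = num + s_n
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(den > 0, num / den, 0.0)
        out = out * frac
    return float(out[0]) if scalar else out


def gain_for_band_coherence(
    target_coh: float,
    params: DriveModelParams,
    fs_hz: float = 2048.0,
    noise_sd: float = 1.0,
) -> float:
    """Gain giving coherence ``target_coh`` at the band centre when both
    channels share that gain and noise SD (the symmetric linear model)."""
    if not 0.0 <= target_coh < 1.0:
        raise ValueError("target coherence must be in [0, 1)")
    if target_coh == 0.0:
        return 0.0
    f_centre = 0.5 * (params.band_lo_hz + params.band_hi_hz)
    s_c = float(drive_psd(params, fs_hz, np.array([f_centre]))[0])
    s_n = noise_sd**2 / fs_hz
    a = np.sqrt(target_coh)  # per-channel fraction
    return float(np.sqrt(s_n * a / (s_c * (1.0 - a))))


def force_trace(
    protocol: ProtocolParams, n_samples: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Ramp-plateau-rest force template plus low-pass tracking noise.

    Returns (force, trial_onsets_s); onsets mark the start of each ramp.
    """
    fs = protocol.fs_hz
    lead_in_s = 1.0
    period = int(round(protocol.trial_period_s * fs))
    ramp_n = int(round(protocol.ramp_rise_s * fs))
    plateau_n = int(round(protocol.plateau_s * fs))

    template = np.zeros(period)
    template[:ramp_n] = np.linspace(0.0, 1.0, ramp_n, endpoint=False)
    template[ramp_n : ramp_n + plateau_n] = 1.0
    template *= protocol.plateau_n

    force = np.zeros(n_samples)
    onsets = []
    start = int(round(lead_in_s * fs))
    for _ in range(protocol.n_trials):
        if start + period > n_samples:
            raise ValueError("record too short for the requested protocol")
        force[start : start + period] = template
        onsets.append(start / fs)
        start += period

    if protocol.force_noise_sd > 0:
        # tracking error is slow relative to the tremor band
        sos = signal.butter(2, 4.0, btype="lowpass", fs=fs, output="sos")
        noise = signal.sosfiltfilt(sos, rng.standard_normal(n_samples))
        noise *= protocol.force_noise_sd / noise.std()
        force = force + noise
    return force, np.asarray(onsets)


def _delayed(c: np.ndarray, pad: int, delay_samples: int, n: int) -> np.ndarray:
    """Slice a length-n view delayed by ``delay_samples`` out of a drive
    stream with ``pad`` lead-in samples (pad >= max delay)."""
    start = pad - delay_samples
    return c[start : start + n]


def generate_session(
    params: DriveModelParams,
    protocol: ProtocolParams,
    subject_id: str = "S01",
    condition: str = "pre",
    session_label: str = "practice",
) -> Session:
    """Simulate one full recording session of the ramp-hold protocol.

    The RNG stream is derived from (seed, subject_id, condition,
    session_label), so regenerating the same measurement is bit-identical and
    different measurements are independent.
    """
    fs = protocol.fs_hz
    rng = _session_rng(params.seed, subject_id, condition, session_label)

    lead_in_s, tail_s = 1.0, 1.0
    duration_s = (
        lead_in_s + protocol.n_trials * protocol.trial_period_s + tail_s
    )
    n = int(round(duration_s * fs))

    max_delay = max(params.delay_apb_s, params.delay_fdi_s)
    pad = int(np.ceil(max_delay * fs)) + 8
    c_full = generate_common_drive(params, fs, (n + pad) / fs, rng)

    channels: dict[str, np.ndarray] = {}
    c_eeg = _delayed(c_full, pad, 0, n)
    channels[EEG_CHANNEL] = (
        params.g_eeg * c_eeg + params.noise_sd_eeg * rng.standard_normal(n)
    )

    for ch in EMG_CHANNELS:
        d = int(round(params.delay_s(ch) * fs))
        c_d = _delayed(c_full, pad, d, n)
        g = params.gain(ch)
        sd = params.noise_sd(ch)
        if params.emg_mode == "linear":
            channels[ch] = g * c_d + sd * rng.standard_normal(n)
        else:
            envelope = 1.0 + g * c_d
            neg_frac = float(np.mean(envelope < 0))
            if neg_frac > 0.01:
                logger.warning(
                    "modulation depth %.3g on %s drives the envelope negative "
                    "in %.1f%% of samples; clipping at zero",
                    g, ch, 100 * neg_frac,
                )
            envelope = np.clip(envelope, 0.0, None)
            channels[ch] = envelope * (sd * rng.standard_normal(n))

    force, onsets = force_trace(protocol, n, rng)
    channels[FORCE_CHANNEL] = force

    return Session(
        channels=channels,
        fs_hz=fs,
        trial_onsets_s=onsets,
        metadata={
            "subject_id": subject_id,
            "condition": condition,
            "session": session_label,
            "seed": params.seed,
            "emg_mode": params.emg_mode,
        },
    )


def simulate_segment_set(
    params: DriveModelParams,
    pair: Sequence[str],
    n_segments: int = 150,
    t_samples: int = 4096,
    fs_hz: float = 2048.0,
    rng: np.random.Generator | None = None,
    normalize: bool = True,
):
    """Sample the linear drive model directly as hold-phase segments.

    Generates a continuous drive stream of ``n_segments * t_samples`` samples,
    forms the two requested channels, and reshapes into an (L, T) segment set
    — the same statistical model as `generate_session` followed by window
    extraction, minus the force/rest plumbing.  Intended for Monte-Carlo
    calibration studies where thousands of records are needed.
    """
    from .preprocessing import SegmentSet, normalize_segments

    if params.emg_mode != "linear":
        raise ValueError("simulate_segment_set supports linear mode only")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = n_segments * t_samples
    max_delay = max(params.delay_s(ch) for ch in pair)
    pad = int(np.ceil(max_delay * fs_hz)) + 8
    c_full = generate_common_drive(params, fs_hz, (n + pad) / fs_hz, rng)

    segs = []
    for ch in pair:
        d = int(round(params.delay_s(ch) * fs_hz))
        x = params.gain(ch) * _delayed(c_full, pad, d, n)
        x = x + params.noise_sd(ch) * rng.standard_normal(n)
        x = x.reshape(n_segments, t_samples)
        x = x - x.mean(axis=1, keepdims=True)
        if normalize:
            x = normalize_segments(x)
        segs.append(x)

    return SegmentSet(
        x_segments=segs[0],
        y_segments=segs[1],
        fs_hz=fs_hz,
        pair=(pair[0], pair[1]),
    )


def practice_params(
    params: DriveModelParams, gain_factor: float
) -> DriveModelParams:
    """Post-practice parameter set: all drive gains scaled by gain_factor,
    emulating a strengthened common corticospinal drive."""
    return replace(
        params,
        g_eeg=params.g_eeg * gain_factor,
        g_apb=params.g_apb * gain_factor,
        g_fdi=params.g_fdi * gain_factor,
    )
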