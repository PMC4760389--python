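"""Disjoint-segment spectral estimation, coherence and cumulant density.

Spectra are estimated by averaging raw (rectangular-taper) periodograms over
L disjoint segments of T samples — the classical scheme for trial-based
recordings, chosen because it admits the exact confidence limit
1 - alpha^(1/(L-1)) for zero coherence.  Densities follow the two-sided
convention sampled at the non-negative DFT bins: the auto-spectrum of a
unit-variance white process is flat at 1/fs, and summing the full two-sided
spectrum times the bin width fs/T recovers the average segment variance
(Parseval).

The cumulant density q_xy(u) is the inverse DFT of the two-sided
cross-spectrum scaled to the cross-covariance of the (unit-variance) input
series; its peak lag estimates the conduction delay between the channels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .preprocessing import SegmentSet


@dataclass
class SpectralEstimate:
    """Averaged periodogram estimate for one channel pair.

    ``f_xx``, ``f_yy`` and the complex ``f_xy`` hold the two-sided spectral
    density sampled at the non-negative frequencies ``freqs_hz`` (length
    T//2 + 1); the negative-frequency half follows by conjugate symmetry.
    """

    freqs_hz: np.ndarray
    f_xx: np.ndarray
    f_yy: np.ndarray
    f_xy: np.ndarray
    L: int
    T: int
    fs_hz: float
    pair: tuple[str, str] = ("x", "y")

    @property
    def resolution_hz(self) -> float:
        return self.fs_hz / self.T


@dataclass
class CoherenceResult:
    """Per-frequency coherence and/or cumulant density with 95% limits.

    ``coh`` is |R_xy|^2 in [0, 1]; bins where an auto-spectrum vanishes are
    undefined (``defined`` False, coh NaN) rather than silently zero.
    ``q`` is the cumulant density over symmetric lags with the lag-independent
    95% band ``q_cl95``.
    """

    freqs_hz: np.ndarray | None = None
    coh: np.ndarray | None = None
    cl95: float | None = None
    defined: np.ndarray | None = None
    lags_s: np.ndarray | None = None
    q: np.ndarray | None = None
    q_cl95: float | None = None
    L: int = 0
    T: int = 0
    fs_hz: float = 0.0
    pair: tuple[str, str] = ("x", "y")


def estimate_spectra(segs: SegmentSet) -> SpectralEstimate:
    """Average the per-segment periodograms and cross-periodograms.

    Rectangular taper, disjoint segments, no overlap.  Normalization is
    |X_k|^2 / (T * fs), the two-sided density convention.
    """
    L, T, fs = segs.L, segs.T, segs.fs_hz
    X = np.fft.rfft(segs.x_segments, axis=1)
    Y = np.fft.rfft(segs.y_segments, axis=1)
    scale = 1.0 / (T * fs)
    f_xx = np.mean(np.abs(X) ** 2, axis=0) * scale
    f_yy = np.mean(np.abs(Y) ** 2, axis=0) * scale
    f_xy = np.mean(X * np.conj(Y), axis=0) * scale
    freqs = np.fft.rfftfreq(T, d=1.0 / fs)
    return SpectralEstimate(
        freqs_hz=freqs, f_xx=f_xx, f_yy=f_yy, f_xy=f_xy,
        L=L, T=T, fs_hz=fs, pair=segs.pair,
    )


def coherence_confidence_limit(L: int, alpha: float = 0.05) -> float:
    """Upper 100(1-alpha)% confidence limit for coherence of independent
    signals estimated from L disjoint segments: 1 - alpha^(1/(L-1))."""
    if L < 2:
        raise ValueError("need L >= 2 segments")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return 1.0 - alpha ** (1.0 / (L - 1))


def coherence(spec: SpectralEstimate, alpha: float = 0.05) -> CoherenceResult:
    """Magnitude-squared coherence |f_xy|^2 / (f_xx f_yy) per bin."""
    defined = (spec.f_xx > 0) & (spec.f_yy > 0)
    coh = np.full(len(spec.freqs_hz), np.nan)
    np.divide(
        np.abs(spec.f_xy) ** 2,
        spec.f_xx * spec.f_yy,
        out=coh,
        where=defined,
    )
    # guard against round-off pushing a coherent bin past 1
    coh[defined] = np.clip(coh[defined], 0.0, 1.0)
    return CoherenceResult(
        freqs_hz=spec.freqs_hz,
        coh=coh,
        cl95=coherence_confidence_limit(spec.L, alpha),
        defined=defined,
        L=spec.L, T=spec.T, fs_hz=spec.fs_hz, pair=spec.pair,
    )


def _two_sided(one_sided: np.ndarray, T: int) -> np.ndarray:
    """Full-length two-sided spectrum from the non-negative-frequency half."""
    full = np.empty(T, dtype=complex)
    half = T // 2
    full[: half + 1] = one_sided
    full[half + 1 :] = np.conj(one_sided[1 : T - half][::-1])
    return full


def cumulant_density(spec: SpectralEstimate) -> CoherenceResult:
    """Cumulant density: inverse DFT of the two-sided cross-spectrum.

    Scaled so that for jointly stationary unit-variance series q equals the
    cross-covariance cov(x(t), y(t+u)): a positive peak lag means y lags x,
    so an EEG->EMG conduction delay appears at positive lag.  Lags run over
    [-T/2, T/2) / fs.  The 95% band is 1.96 times the lag-independent
    asymptotic standard deviation

        var(q) = (fs/T)^2 * sum_k f_xx(k) f_yy(k) / L

    with the sum over all T two-sided bins.
    """
    T, L, fs = spec.T, spec.L, spec.fs_hz
    # conj flips f_xy = <X Y*> into <Y X*>, putting "y lags x" at positive u
    fxy_full = _two_sided(np.conj(spec.f_xy), T)
    q = fs * np.fft.ifft(fxy_full).real
    q = np.fft.fftshift(q)
    lags = (np.arange(T) - T // 2) / fs

    fxx_full = _two_sided(spec.f_xx.astype(complex), T).real
    fyy_full = _two_sided(spec.f_yy.astype(complex), T).real
    var_q = (fs / T) ** 2 * np.sum(fxx_full * fyy_full) / L
    return CoherenceResult(
        lags_s=lags,
        q=q,
        q_cl95=1.96 * float(np.sqrt(var_q)),
        L=L, T=T, fs_hz=fs, pair=spec.pair,
    )


def analyze(spec: SpectralEstimate, alpha: float = 0.05) -> CoherenceResult:
    """Coherence and cumulant density in one result."""
    c = coherence(spec, alpha)
    d = cumulant_density(spec)
    c.lags_s, c.q, c.q_cl95 = d.lags_s, d.q, d.q_cl95
    return c


def find_cumulant_peak(
    res: CoherenceResult, lag_window_s: Sequence[float]
) -> tuple[float, float, bool]:
    """Lag, value and significance of the largest |q| inside a lag window.

    Ties are broken toward the smaller absolute lag.  Significant means
    |q| exceeds the 95% band.
    """
    if res.q is None or res.lags_s is None:
        raise ValueError("result carries no cumulant density")
    lo, hi = lag_window_s
    mask = (res.lags_s >= lo) & (res.lags_s <= hi)
    if not np.any(mask):
        raise ValueError(f"empty lag window [{lo}, {hi}] s")
    lags = res.lags_s[mask]
    q = res.q[mask]
    absq = np.abs(q)
    best = absq.max()
    candidates = np.flatnonzero(absq >= best * (1 - 1e-12))
    i = candidates[np.argmin(np.abs(lags[candidates]))]
    return float(lags[i]), float(q[i]), bool(absq[i] > res.q_cl95)
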