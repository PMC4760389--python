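"""Multi-record pooled coherence and the extended chi-squared
difference-of-coherence test.

Pooling operates on the spectra: the pooled auto- and cross-spectra are
segment-count-weighted means over records, so the pooled coherence equals the
coherence computed on the union of all segments exactly.  The difference test
compares k independent (pooled) coherence estimates per frequency bin via the
variance-stabilizing transform z = atanh(sqrt(coh)), whose asymptotic variance
is 1/(2n) for n segments; the statistic

    X^2 = sum_i w_i (z_i - zbar)^2,   w_i = 2 n_i

is chi-squared with k - 1 degrees of freedom under equal coherence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .spectral import (
    CoherenceResult,
    SpectralEstimate,
    coherence,
    coherence_confidence_limit,
    cumulant_density,
)

_ATANH_CLIP = 1.0 - 1e-12


@dataclass
class PooledEstimate:
    """Segment-weighted pooled spectra and coherence across records."""

    freqs_hz: np.ndarray
    f_xx: np.ndarray
    f_yy: np.ndarray
    f_xy: np.ndarray
    n_total: int
    per_record_L: list[int]
    coh: np.ndarray
    cl95: float
    defined: np.ndarray
    T: int
    fs_hz: float
    pair: tuple[str, str] = ("x", "y")
    label: str = ""

    def as_spectral_estimate(self) -> SpectralEstimate:
        return SpectralEstimate(
            freqs_hz=self.freqs_hz, f_xx=self.f_xx, f_yy=self.f_yy,
            f_xy=self.f_xy, L=self.n_total, T=self.T, fs_hz=self.fs_hz,
            pair=self.pair,
        )


@dataclass
class PooledComparison:
    """Per-frequency chi-squared comparison of k pooled estimates."""

    freqs_hz: np.ndarray
    chi2: np.ndarray
    df: int
    threshold: float
    significant: np.ndarray
    groups: list[PooledEstimate] = field(default_factory=list)
    alpha: float = 0.05


def _check_common_grid(records: Sequence) -> None:
    first = records[0]
    for r in records[1:]:
        if r.T != first.T or r.fs_hz != first.fs_hz or not np.allclose(
            r.freqs_hz, first.freqs_hz
        ):
            raise ValueError(
                "records are not on a common frequency grid "
                f"(T={r.T} vs {first.T}, fs={r.fs_hz} vs {first.fs_hz})"
            )


def pool_records(
    records: Sequence[SpectralEstimate],
    alpha: float = 0.05,
    label: str = "",
) -> PooledEstimate:
    """Pool per-record spectra with segment-count weights.

    The weighted mean sum_i L_i f_i / sum_i L_i equals the plain periodogram
    average over the union of all segments, so pooled coherence inherits the
    single-record confidence limit evaluated at n_total segments.
    """
    if len(records) < 1:
        raise ValueError("need at least one record")
    _check_common_grid(records)
    Ls = [r.L for r in records]
    n_total = int(sum(Ls))
    w = np.asarray(Ls, dtype=float)[:, None] / n_total
    f_xx = np.sum(w * np.stack([r.f_xx for r in records]), axis=0)
    f_yy = np.sum(w * np.stack([r.f_yy for r in records]), axis=0)
    f_xy = np.sum(w * np.stack([r.f_xy for r in records]), axis=0)

    first = records[0]
    pooled_spec = SpectralEstimate(
        freqs_hz=first.freqs_hz, f_xx=f_xx, f_yy=f_yy, f_xy=f_xy,
        L=n_total, T=first.T, fs_hz=first.fs_hz, pair=first.pair,
    )
    c = coherence(pooled_spec, alpha)
    return PooledEstimate(
        freqs_hz=first.freqs_hz, f_xx=f_xx, f_yy=f_yy, f_xy=f_xy,
        n_total=n_total, per_record_L=list(Ls), coh=c.coh,
        cl95=coherence_confidence_limit(n_total, alpha), defined=c.defined,
        T=first.T, fs_hz=first.fs_hz, pair=first.pair, label=label,
    )


def pooled_cumulant(
    records: Sequence[SpectralEstimate], alpha: float = 0.05
) -> CoherenceResult:
    """Cumulant density of the pooled cross-spectrum, with limits at the
    pooled segment count."""
    pooled = pool_records(records, alpha)
    return cumulant_density(pooled.as_spectral_estimate())


def chi2_quantile(df: int, alpha: float) -> float:
    """Upper-alpha quantile of the chi-squared distribution."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return float(stats.chi2.ppf(1.0 - alpha, df))


def difference_of_coherence_test(
    groups: Sequence[PooledEstimate], alpha: float = 0.05
) -> PooledComparison:
    """Extended chi-squared test of equality of k independent coherences.

    Per bin: z_i = atanh(sqrt(coh_i)) with weight w_i = 2 n_i;
    X^2 = sum w_i (z_i - zbar)^2 on k - 1 degrees of freedom.  Bins undefined
    in any group are NaN and never flagged significant.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    for g in groups:
        if g.n_total < 2:
            raise ValueError("every group needs at least 2 segments")
    _check_common_grid(groups)

    k = len(groups)
    w = np.asarray([2.0 * g.n_total for g in groups])[:, None]
    coh = np.stack([g.coh for g in groups])
    defined = np.all(np.stack([g.defined for g in groups]), axis=0)
    z = np.arctanh(np.sqrt(np.clip(coh, 0.0, _ATANH_CLIP)))
    zbar = np.sum(w * z, axis=0) / np.sum(w)
    chi2 = np.sum(w * (z - zbar) ** 2, axis=0)
    chi2 = np.where(defined, chi2, np.nan)

    df = k - 1
    threshold = chi2_quantile(df, alpha)
    significant = defined & (chi2 > threshold)
    return PooledComparison(
        freqs_hz=groups[0].freqs_hz,
        chi2=chi2,
        df=df,
        threshold=threshold,
        significant=significant,
        groups=list(groups),
        alpha=alpha,
    )
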