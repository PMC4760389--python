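"""Band-level summary statistics and per-subject exports.

The per-subject scalar reported for group comparisons is the cumulated sum of
log coherence over the frequency bins of a band (beta, 15-30 Hz, by default):
larger (less negative) values mean stronger coupling.  `pre_post_table`
assembles these into the tidy long-format table an external mixed-model or
ANOVA fit consumes, together with post - pre change scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .spectral import CoherenceResult

BETA_BAND = (15.0, 30.0)

_EDGE_TOL = 1e-9  # absolute tolerance when matching band edges to bin freqs


@dataclass(frozen=True)
class BandStat:
    """Sum of ln(coherence) over the inclusive bins of one frequency band."""

    subject_id: str
    session: str  # practice / control
    condition: str  # pre / post
    pair: str
    band_lo_hz: float
    band_hi_hz: float
    n_bins: int
    value: float


def band_bins(freqs_hz: np.ndarray, band: Sequence[float]) -> np.ndarray:
    """Indices of the bins inside [lo, hi], edges inclusive, bin 0 excluded."""
    lo, hi = band
    if lo > hi:
        raise ValueError(f"empty band ({lo}, {hi})")
    mask = (freqs_hz >= lo - _EDGE_TOL) & (freqs_hz <= hi + _EDGE_TOL)
    mask &= freqs_hz > 0
    return np.flatnonzero(mask)


def band_log_sum(
    res: CoherenceResult,
    band: Sequence[float] = BETA_BAND,
    subject_id: str = "",
    session: str = "",
    condition: str = "",
) -> BandStat:
    """Cumulated natural-log coherence over the band's bins.

    Every bin in the band must carry a defined, strictly positive coherence;
    a zero would make the log undefined and signals an upstream problem
    (typically an all-zero channel), so it raises rather than propagating
    -inf.
    """
    if res.coh is None or res.freqs_hz is None:
        raise ValueError("result carries no coherence spectrum")
    idx = band_bins(res.freqs_hz, band)
    if len(idx) == 0:
        raise ValueError(f"band {band} contains no frequency bins")
    coh = res.coh[idx]
    bad = ~np.isfinite(coh)
    if res.defined is not None:
        bad |= ~res.defined[idx]
    if np.any(bad):
        raise ValueError(
            f"undefined coherence at {res.freqs_hz[idx[bad]]} Hz; "
            "inspect the input spectra"
        )
    if np.any(coh <= 0):
        raise ValueError(
            f"zero coherence at {res.freqs_hz[idx[coh <= 0]]} Hz: log "
            "undefined; inspect the inputs (an all-zero segment is the "
            "usual cause)"
        )
    return BandStat(
        subject_id=subject_id,
        session=session,
        condition=condition,
        pair=f"{res.pair[0]}:{res.pair[1]}",
        band_lo_hz=float(band[0]),
        band_hi_hz=float(band[1]),
        n_bins=int(len(idx)),
        value=float(np.sum(np.log(coh))),
    )


def band_stats_frame(stats_list: Sequence[BandStat]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "session": s.session,
                "condition": s.condition,
                "pair": s.pair,
                "band_lo_hz": s.band_lo_hz,
                "band_hi_hz": s.band_hi_hz,
                "n_bins": s.n_bins,
                "value": s.value,
            }
            for s in stats_list
        ]
    )


def pre_post_table(
    stats_list: Sequence[BandStat],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format table plus per-subject change scores (post - pre).

    Every (subject, session, pair) cell must contain exactly one pre and one
    post entry; a missing or duplicated cell raises, naming the offender.
    """
    long = band_stats_frame(stats_list)
    if long.empty:
        raise ValueError("no band statistics supplied")

    counts = long.groupby(
        ["subject_id", "session", "pair", "condition"]
    ).size()
    for (subj, sess, pair, cond), n in counts.items():
        if n != 1:
            raise ValueError(
                f"subject {subj!r}, session {sess!r}, pair {pair!r}: "
                f"{n} {cond!r} entries (expected exactly 1)"
            )
    wide = long.pivot_table(
        index=["subject_id", "session", "pair"],
        columns="condition",
        values="value",
        aggfunc="first",
    )
    for cond in ("pre", "post"):
        if cond not in wide.columns:
            raise ValueError(f"no {cond!r} entries present")
        missing = wide.index[wide[cond].isna()]
        if len(missing):
            subj = missing[0]
            raise ValueError(
                f"missing {cond!r} value for subject {subj[0]!r}, "
                f"session {subj[1]!r}, pair {subj[2]!r}"
            )
    change = wide.reset_index()
    change["change"] = change["post"] - change["pre"]
    return long, change[["subject_id", "session", "pair", "pre", "post",
                         "change"]]


def pearson_r(x_values, y_values) -> tuple[float, float]:
    """Sample Pearson correlation with the two-tailed p-value from the
    t transform on n - 2 degrees of freedom."""
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
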