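"""Session containers, trigger parsing and tidy result tables.

The native container is HDF5: one dataset per channel plus attributes for the
sampling rate, trial onsets and metadata — self-describing and bit-exact on
round trip.  Delimited text (one column per channel, TSV, with a JSON sidecar
for the attributes) is supported for small fixtures, and BioSemi BDF/EDF
recordings are read through :mod:`mne` with onsets recovered from a trigger
channel.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

from .pooled import PooledComparison
from .spectral import CoherenceResult
from .synthetic import Session

_TEXT_SUFFIXES = {".tsv", ".csv", ".txt"}


def save_session(session: Session, path) -> Path:
    """Write a Session to the native HDF5 container."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        for name, data in session.channels.items():
            f.create_dataset(f"channels/{name}", data=data)
        f.attrs["fs_hz"] = session.fs_hz
        f.attrs["trial_onsets_s"] = session.trial_onsets_s
        f.attrs["metadata"] = json.dumps(session.metadata)
        f.attrs["channel_order"] = json.dumps(list(session.channels))
    return path


def _read_native(path: Path) -> Session:
    with h5py.File(path, "r") as f:
        order = json.loads(f.attrs["channel_order"])
        channels = {name: f[f"channels/{name}"][:] for name in order}
        return Session(
            channels=channels,
            fs_hz=float(f.attrs["fs_hz"]),
            trial_onsets_s=np.asarray(f.attrs["trial_onsets_s"], dtype=float),
            metadata=json.loads(f.attrs["metadata"]),
        )


def save_session_text(session: Session, path) -> Path:
    """Delimited-text export (TSV, header row) with a JSON sidecar holding
    the sampling rate, onsets and metadata.  Intended for small fixtures."""
    path = Path(path)
    pd.DataFrame(session.channels).to_csv(path, sep="\t", index=False)
    sidecar = {
        "fs_hz": session.fs_hz,
        "trial_onsets_s": session.trial_onsets_s.tolist(),
        "metadata": session.metadata,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1)
    )
    return path


def onsets_from_trigger(trig: np.ndarray, fs_hz: float) -> np.ndarray:
    """Ramp-onset times from the rising edges of a trigger/pulse channel.

    Threshold at half the peak amplitude; each upward crossing is one onset.
    """
    trig = np.asarray(trig, dtype=float)
    peak = trig.max()
    if peak <= 0:
        raise ValueError("trigger channel has no positive pulses")
    above = trig >= peak / 2.0
    edges = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if above[0]:
        edges = np.concatenate([[0], edges])
    return edges / fs_hz


def _read_text(path: Path, channel_map: Mapping[str, str] | None) -> Session:
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"delimited session {path} needs a sidecar {sidecar_path.name} "
            "with fs_hz (and trial_onsets_s unless a TRIG column is present)"
        )
    sidecar = json.loads(sidecar_path.read_text())
    fs = float(sidecar["fs_hz"])
    channels = {c: df[c].to_numpy(dtype=float) for c in df.columns}
    if channel_map:
        channels = {role: channels[src] for role, src in channel_map.items()}
    onsets = sidecar.get("trial_onsets_s")
    if onsets is None:
        if "TRIG" not in channels:
            raise ValueError(
                "no trial_onsets_s in sidecar and no TRIG channel to parse"
            )
        onsets = onsets_from_trigger(channels["TRIG"], fs)
    return Session(
        channels=channels,
        fs_hz=fs,
        trial_onsets_s=np.asarray(onsets, dtype=float),
        metadata=sidecar.get("metadata", {}),
    )


def _read_edf(path: Path, channel_map: Mapping[str, str] | None) -> Session:
    import mne  # deferred: optional dependency, slow import

    reader = (
        mne.io.read_raw_bdf if path.suffix.lower() == ".bdf"
        else mne.io.read_raw_edf
    )
    raw = reader(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    data = raw.get_data()
    by_name = {name: data[i] for i, name in enumerate(raw.ch_names)}
    if channel_map:
        missing = [src for src in channel_map.values() if src not in by_name]
        if missing:
            raise KeyError(f"channels {missing} not found in {path.name}")
        channels = {role: by_name[src] for role, src in channel_map.items()}
    else:
        channels = by_name
    if "TRIG" not in channels:
        raise ValueError(
            "EDF/BDF sessions need a trigger channel mapped to 'TRIG' for "
            "trial onsets"
        )
    onsets = onsets_from_trigger(channels["TRIG"], fs)
    return Session(
        channels=channels, fs_hz=fs, trial_onsets_s=onsets,
        metadata={"source": str(path)},
    )


def read_session(path, channel_map: Mapping[str, str] | None = None) -> Session:
    """Load a Session from the native container, EDF/BDF, or delimited text.

    ``channel_map`` maps pipeline channel roles (e.g. ``"C4"``, ``"APB"``,
    ``"TRIG"``) to channel names in the file; unused for the native format,
    which stores roles directly.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        return _read_native(path)
    if suffix in (".edf", ".bdf"):
        return _read_edf(path, channel_map)
    if suffix in _TEXT_SUFFIXES:
        return _read_text(path, channel_map)
    raise ValueError(f"unrecognized session format: {path.name}")


# ---------------------------------------------------------------------------
# tidy result tables

def coherence_table(res: CoherenceResult) -> pd.DataFrame:
    pair = f"{res.pair[0]}:{res.pair[1]}"
    return pd.DataFrame(
        {
            "pair": pair,
            "freq_hz": res.freqs_hz,
            "coh": res.coh,
            "cl95": res.cl95,
        }
    )


def cumulant_table(res: CoherenceResult) -> pd.DataFrame:
    pair = f"{res.pair[0]}:{res.pair[1]}"
    return pd.DataFrame(
        {
            "pair": pair,
            "lag_s": res.lags_s,
            "q": res.q,
            "q_cl95": res.q_cl95,
        }
    )


def comparison_table(
    cmp: PooledComparison, labels: Sequence[str] | None = None
) -> pd.DataFrame:
    if labels is None:
        labels = [g.label or f"group{i}" for i, g in enumerate(cmp.groups)]
    pair = cmp.groups[0].pair
    out = {"pair": f"{pair[0]}:{pair[1]}", "freq_hz": cmp.freqs_hz}
    for lab, g in zip(labels, cmp.groups):
        out[f"coh_{lab}"] = g.coh
    out["chi2"] = cmp.chi2
    out["threshold"] = cmp.threshold
    out["significant"] = cmp.significant
    return pd.DataFrame(out)


def write_table(
    df: pd.DataFrame,
    path,
    config_hash: str | None = None,
    float_format: str | None = None,
) -> Path:
    """Write a TSV table; the config hash rides along as a comment line.

    Full float precision by default so tables round-trip exactly; spectral
    tables pass ``float_format="%.6g"`` for compact frequency columns.
    """
    path = Path(path)
    with open(path, "w") as f:
        if config_hash:
            f.write(f"# config_hash: {config_hash}\n")
        df.to_csv(f, sep="\t", index=False, float_format=float_format)
    return path


def read_table(path) -> pd.DataFrame:
    # round_trip parser so full-precision tables read back bit-exactly
    return pd.read_csv(path, sep="\t", comment="#",
                       float_precision="round_trip")
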