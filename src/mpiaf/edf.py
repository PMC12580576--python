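"""Minimal EDF (European Data Format) writer/reader for synthetic recordings.

Recordings are stored as standard 16-bit EDF with one-second data
records, each channel's physical range set from its data min/max, plus a
JSON sidecar carrying the epoch structure and the ground-truth spectral
parameters of the simulated observer.  No EDF-writing library is relied
upon; reading goes through MNE, which validates the files against an
independent EDF implementation.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .cohort import ObserverProfile, Recording

__all__ = ["write_recording_edf", "read_recording_edf"]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(text: str, width: int) -> bytes:
    b = str(text)[:width].encode("ascii")
    return b + b" " * (width - len(b))


def _num8(v: float) -> str:
    """Shortest decimal representation of v that fits EDF's 8-char fields."""
    for prec in range(7, 0, -1):
        s = f"{v:.{prec}g}"
        if len(s) <= 8:
            return s
    return f"{v:.0e}"


def write_recording_edf(
    recording: Recording,
    path: str | Path,
    profile: ObserverProfile | None = None,
) -> Path:
    """Write an epoched recording as EDF plus a JSON sidecar.

    Epochs are concatenated; the sidecar records (n_epochs, epoch
    samples, fs) so the epoch structure can be restored exactly, and the
    observer's true spectral parameters when a profile is given.
    """
    path = Path(path)
    n_epochs, n_ch, n_samp = recording.epochs.shape
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    fs = int(round(fs))
    if n_samp % fs != 0:
        raise ValueError("epoch length must be a whole number of seconds")
    data = recording.epochs.transpose(1, 0, 2).reshape(n_ch, n_epochs * n_samp)
    n_records = data.shape[1] // fs

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin <= 0
    pmax[flat] = pmin[flat] + 1.0  # avoid zero physical range on flat channels
    # round-trip the ranges through their 8-char header fields so the
    # digitization scale matches what a reader will parse
    pmin_s = [_num8(v) for v in pmin]
    pmax_s = [_num8(v) for v in pmax]
    pmin = np.array([float(s) for s in pmin_s])
    pmax = np.maximum(np.array([float(s) for s in pmax_s]), pmin + 1e-6)
    scale = (pmax - pmin) / (_DIG_MAX - _DIG_MIN)
    digital = np.round((data - pmin[:, None]) / scale[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    header = b"".join(
        [
            _field("0", 8),
            _field(recording.observer_id, 80),
            _field("mpiaf synthetic resting-state EEG", 80),
            _field("01.01.00", 8),
            _field("00.00.00", 8),
            _field(str(256 * (1 + n_ch)), 8),
            _field("", 44),
            _field(str(n_records), 8),
            _field("1", 8),
            _field(str(n_ch), 4),
        ]
    )
    sig = b"".join(_field(lab, 16) for lab in recording.channel_labels)
    sig += b"".join(_field("AgAgCl electrode", 80) for _ in range(n_ch))
    sig += b"".join(_field("uV", 8) for _ in range(n_ch))
    sig += b"".join(_field(s, 8) for s in pmin_s)
    sig += b"".join(_field(_num8(v), 8) for v in pmax)
    sig += b"".join(_field(str(_DIG_MIN), 8) for _ in range(n_ch))
    sig += b"".join(_field(str(_DIG_MAX), 8) for _ in range(n_ch))
    sig += b"".join(_field("", 80) for _ in range(n_ch))
    sig += b"".join(_field(str(fs), 8) for _ in range(n_ch))
    sig += b"".join(_field("", 32) for _ in range(n_ch))

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        # data records: per second, all channels sequentially
        rec = digital.reshape(n_ch, n_records, fs).transpose(1, 0, 2)
        fh.write(rec.tobytes())

    sidecar = {
        "observer_id": recording.observer_id,
        "fs": fs,
        "n_epochs": n_epochs,
        "epoch_samples": n_samp,
        "channel_labels": list(recording.channel_labels),
    }
    if profile is not None:
        sidecar["ground_truth"] = {
            "alpha_cf": profile.alpha_cf,
            "alpha_power": profile.alpha_power,
            "alpha_bw": profile.alpha_bw,
            "aperiodic_offset": profile.aperiodic_offset,
            "aperiodic_exponent": profile.aperiodic_exponent,
        }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_recording_edf(path: str | Path) -> Recording:
    """Read an EDF written by :func:`write_recording_edf` back into epochs.

    Uses MNE's EDF reader; the JSON sidecar restores the epoch split.
    """
    import mne

    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data(units="uV")
    n_epochs = sidecar["n_epochs"]
    n_samp = sidecar["epoch_samples"]
    data = data[:, : n_epochs * n_samp]
    epochs = data.reshape(data.shape[0], n_epochs, n_samp).transpose(1, 0, 2)
    return Recording(
        observer_id=sidecar["observer_id"],
        epochs=epochs,
        fs=float(sidecar["fs"]),
        channel_labels=tuple(sidecar["channel_labels"]),
    )
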