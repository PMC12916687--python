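"""Recording readers/writers and dataset manifests.

Three on-disk forms are supported for a (channels x samples) recording:

* ``edf`` — 16-bit European Data Format. Writing uses the package's own
  minimal EDF encoder (1-second data records, per-channel physical scaling);
  reading goes through MNE, which also serves as an independent check of the
  writer in the test suite.
* ``csv`` — channels-as-rows delimited text plus a JSON sidecar carrying the
  sampling rate, channel labels, ids and label (no EEG text standard exists;
  this convention is documented here).
* ``npz`` — NumPy array container with the same metadata embedded.

A dataset is a directory of recordings plus a ``manifest.csv`` with columns
subject_id, trial_id, label, path.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import RawRecording

__all__ = ["save_recording", "read_recording", "save_dataset", "load_dataset",
           "write_edf"]


# -- EDF ----------------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    s = f"{value:<{width}}"
    if len(s) > width:
        s = s[:width]
    return s.encode("ascii")


def write_edf(path: str | Path, data: np.ndarray, fs: float,
              channel_labels: Sequence[str], *, phys_dim: str = "uV") -> None:
    """Minimal EDF writer: int16 samples, 1-second data records.

    Requires an integer sampling rate and a sample count divisible by fs (no
    padding is ever written, so a read-back returns exactly the same length).
    """
    data = np.asarray(data, dtype=np.float64)
    c, L = data.shape
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    fs_i = int(round(fs))
    if L % fs_i != 0:
        raise ValueError("EDF export requires a whole number of seconds")
    n_records = L // fs_i
    phys_max = np.maximum(np.abs(data).max(axis=1), 1e-6)
    # the printed (<=7 char) physical maximum is the scaling contract; the
    # minimum is its exact negation so read-back gain matches bit-for-bit
    pm_strs = [f"{m:.6g}"[:7] for m in phys_max]
    printed_max = np.array([float(s) for s in pm_strs])
    dig_max = 32767
    header = b"".join([
        _edf_field("0", 8),
        _edf_field("X X X X", 80),
        _edf_field("Startdate X X X X", 80),
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(256 * (1 + c), 8),
        _edf_field("", 44),
        _edf_field(n_records, 8),
        _edf_field(1, 8),
        _edf_field(c, 4),
    ])
    per_signal = b"".join([
        b"".join(_edf_field(lbl, 16) for lbl in channel_labels),
        b"".join(_edf_field("", 80) for _ in range(c)),
        b"".join(_edf_field(phys_dim, 8) for _ in range(c)),
        b"".join(_edf_field("-" + s, 8) for s in pm_strs),
        b"".join(_edf_field(s, 8) for s in pm_strs),
        b"".join(_edf_field(-dig_max, 8) for _ in range(c)),
        b"".join(_edf_field(dig_max, 8) for _ in range(c)),
        b"".join(_edf_field("", 80) for _ in range(c)),
        b"".join(_edf_field(fs_i, 8) for _ in range(c)),
        b"".join(_edf_field("", 32) for _ in range(c)),
    ])
    # physical->digital, clipped to the int16 range
    scaled = np.round(data / printed_max[:, None] * dig_max)
    digital = np.clip(scaled, -dig_max, dig_max).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_signal)
        for r in range(n_records):
            for ch in range(c):
                fh.write(digital[ch, r * fs_i:(r + 1) * fs_i].tobytes())


def _validate_finite(data: np.ndarray, labels: Sequence[str]) -> None:
    bad = np.where(~np.isfinite(np.asarray(data)).all(axis=1))[0]
    if bad.size:
        raise ValueError(f"non-finite samples in channel(s) "
                         f"{[labels[i] for i in bad]}")


def _read_edf(path: Path) -> RawRecording:
    import mne
    raw = mne.io.read_raw_edf(path, preload=True, verbose="ERROR")
    data = raw.get_data() * 1e6  # MNE returns volts; recordings are microvolt
    _validate_finite(data, list(raw.ch_names))
    meta = _sidecar_meta(path)
    return RawRecording(data=data, fs=float(raw.info["sfreq"]),
                        channel_labels=list(raw.ch_names),
                        subject_id=meta.get("subject_id", -1),
                        trial_id=meta.get("trial_id", -1),
                        label=meta.get("label", "unknown"))


# -- delimited / npz ----------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _sidecar_meta(path: Path) -> dict:
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        return json.loads(sidecar.read_text())
    return {}


def _write_sidecar(path: Path, rec: RawRecording) -> None:
    meta = {"fs": rec.fs, "channel_labels": rec.channel_labels,
            "subject_id": rec.subject_id, "trial_id": rec.trial_id,
            "label": rec.label}
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def save_recording(rec: RawRecording, path: str | Path,
                   fmt: str | None = None) -> Path:
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "edf":
        write_edf(path, rec.data, rec.fs, rec.channel_labels)
        _write_sidecar(path, rec)
    elif fmt == "csv":
        np.savetxt(path, rec.data, delimiter=",")
        _write_sidecar(path, rec)
    elif fmt == "npz":
        np.savez(path, data=rec.data, fs=rec.fs,
                 channel_labels=np.array(rec.channel_labels),
                 subject_id=rec.subject_id, trial_id=rec.trial_id,
                 label=str(rec.label))
    else:
        raise ValueError(f"unknown format {fmt!r} (edf, csv or npz)")
    return path


def read_recording(path: str | Path, fmt: str | None = None) -> RawRecording:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording not found: {path}")
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "edf":
        rec = _read_edf(path)
    elif fmt == "csv":
        data = np.loadtxt(path, delimiter=",", ndmin=2)
        meta = _sidecar_meta(path)
        if "fs" not in meta:
            raise ValueError(f"missing JSON sidecar with fs for {path}")
        _validate_finite(data, meta["channel_labels"])
        rec = RawRecording(data=data, fs=meta["fs"],
                           channel_labels=meta["channel_labels"],
                           subject_id=meta.get("subject_id", -1),
                           trial_id=meta.get("trial_id", -1),
                           label=meta.get("label", "unknown"))
    elif fmt == "npz":
        with np.load(path, allow_pickle=False) as z:
            _validate_finite(z["data"], [str(x) for x in z["channel_labels"]])
            rec = RawRecording(data=z["data"], fs=float(z["fs"]),
                               channel_labels=[str(x) for x in z["channel_labels"]],
                               subject_id=int(z["subject_id"]),
                               trial_id=int(z["trial_id"]),
                               label=str(z["label"]))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return rec


# -- manifests ----------------------------------------------------------------

def save_dataset(recordings: Sequence[RawRecording], out_dir: str | Path,
                 fmt: str = "csv") -> Path:
    """Write every recording plus a manifest.csv; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        name = f"sub{rec.subject_id:03d}_trial{rec.trial_id:03d}.{fmt}"
        save_recording(rec, out_dir / name, fmt)
        rows.append({"subject_id": rec.subject_id, "trial_id": rec.trial_id,
                     "label": rec.label, "path": name})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_dataset(manifest: str | Path) -> list[RawRecording]:
    manifest = Path(manifest)
    if not manifest.exists():
        raise FileNotFoundError(f"manifest not found: {manifest}")
    df = pd.read_csv(manifest)
    recs = []
    for row in df.itertuples():
        rec = read_recording(manifest.parent / row.path)
        rec.subject_id = int(row.subject_id)
        rec.trial_id = int(row.trial_id)
        rec.label = row.label
        recs.append(rec)
    return recs
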