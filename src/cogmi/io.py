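"""File I/O: the HDF5 epochs container, EDF import/export, CSV/JSON
reports, and the provenance run log.

The internal container is a single HDF5 file: one group per subject with
``cognitive`` / ``mi`` epoch groups (data array + sampling rate + channel
names + a JSON annotation block) and the producing configuration hash in
the root attributes.

EDF support is a deliberately small codec for the classic 16-bit EDF
layout (one data record per second, integer sampling rates), sufficient
for interoperability round-trips; it is not a general EDF+ reader. Epoch
onset events travel in a plain-text sidecar table.
"""

from __future__ import annotations

import datetime as _dt
import json
import platform
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .preprocess import EEGEpochs
from .synthetic_data import SubjectDataset

RUN_LOG = "run_log.jsonl"


# --------------------------------------------------------------------------
# epochs container (HDF5)
# --------------------------------------------------------------------------

def _write_epochs_group(grp: h5py.Group, epochs: EEGEpochs) -> None:
    grp.create_dataset("data", data=epochs.data, compression="gzip",
                       compression_opts=1)
    grp.attrs["fs"] = float(epochs.fs)
    grp.attrs["channel_names"] = json.dumps(list(epochs.channel_names))
    grp.attrs["annotations"] = epochs.annotations.to_json(orient="records")


def _read_epochs_group(grp: h5py.Group) -> EEGEpochs:
    from io import StringIO
    ann = pd.read_json(StringIO(grp.attrs["annotations"]), orient="records")
    return EEGEpochs(grp["data"][...], float(grp.attrs["fs"]),
                     json.loads(grp.attrs["channel_names"]), ann)


def save_cohort(cohort: list[SubjectDataset], path, config_hash: str = "") -> None:
    with h5py.File(path, "w") as f:
        f.attrs["config_hash"] = config_hash
        f.attrs["n_subjects"] = len(cohort)
        for subject in cohort:
            grp = f.create_group(f"subject_{subject.subject_id:03d}")
            grp.attrs["subject_id"] = subject.subject_id
            grp.attrs["true_strong_action"] = subject.true_strong_action
            _write_epochs_group(grp.create_group("cognitive"),
                                subject.cognitive_epochs)
            _write_epochs_group(grp.create_group("mi"), subject.mi_epochs)


def load_cohort(path) -> tuple[list[SubjectDataset], str]:
    cohort = []
    with h5py.File(path, "r") as f:
        config_hash = str(f.attrs.get("config_hash", ""))
        for name in sorted(k for k in f if k.startswith("subject_")):
            grp = f[name]
            cohort.append(SubjectDataset(
                int(grp.attrs["subject_id"]),
                _read_epochs_group(grp["cognitive"]),
                _read_epochs_group(grp["mi"]),
                int(grp.attrs["true_strong_action"]),
            ))
    return cohort, config_hash


# --------------------------------------------------------------------------
# EDF (classic 16-bit, one record per second)
# --------------------------------------------------------------------------

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", "replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(path, data: np.ndarray, fs: float, channel_names: list[str],
              physical_dim: str = "uV") -> None:
    """Write a continuous multichannel recording as classic EDF."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n_ch, n_samp = data.shape
    if len(channel_names) != n_ch:
        raise ValueError("one channel name per row required")
    fs_int = int(round(fs))
    if abs(fs - fs_int) > 1e-9:
        raise ValueError("EDF export needs an integer sampling rate")
    if n_samp % fs_int:
        raise ValueError(
            "EDF export needs a whole number of 1 s records "
            f"({n_samp} samples at {fs_int} Hz)"
        )
    n_rec = n_samp // fs_int
    phys_max = np.maximum(np.abs(data).max(axis=1), 1e-6)
    dig_max = 32767
    scale = phys_max / dig_max
    digital = np.round(data / scale[:, None]).astype("<i2")

    now = _dt.datetime(2000, 1, 1)
    header = b"".join([
        _pad("0", 8), _pad("X", 80), _pad("X", 80),
        _pad(now.strftime("%d.%m.%y"), 8), _pad(now.strftime("%H.%M.%S"), 8),
        _pad(str(256 * (1 + n_ch)), 8), _pad("", 44),
        _pad(str(n_rec), 8), _pad("1", 8), _pad(str(n_ch), 4),
    ])
    sig_fields = [
        [_pad(name.upper(), 16) for name in channel_names],
        [_pad("EEG", 80)] * n_ch,
        [_pad(physical_dim, 8)] * n_ch,
        [_pad(f"{-p:.6g}"[:8], 8) for p in phys_max],
        [_pad(f"{p:.6g}"[:8], 8) for p in phys_max],
        [_pad(str(-dig_max), 8)] * n_ch,
        [_pad(str(dig_max), 8)] * n_ch,
        [_pad("", 80)] * n_ch,
        [_pad(str(fs_int), 8)] * n_ch,
        [_pad("", 32)] * n_ch,
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for group in sig_fields:
            fh.write(b"".join(group))
        for r in range(n_rec):
            sl = slice(r * fs_int, (r + 1) * fs_int)
            fh.write(digital[:, sl].tobytes())


def read_raw_edf(path, expected_channels: list[str] | None = None,
                 expected_fs: float | None = None
                 ) -> tuple[np.ndarray, float, list[str]]:
    """Read a classic EDF file into (channels × samples, fs, names).

    Channel names are uppercased to 10–20 labels. Raises on malformed
    headers, on a missing expected channel (naming it), and on a sampling
    rate differing from ``expected_fs`` (no silent resampling).
    """
    with open(path, "rb") as fh:
        header = fh.read(256)
        if len(header) != 256 or header[:8].strip() != b"0":
            raise ValueError(f"{path}: not a classic EDF file")
        n_rec = int(header[236:244])
        rec_dur = float(header[244:252])
        n_ch = int(header[252:256])
        sig = fh.read(256 * n_ch)
        if len(sig) != 256 * n_ch:
            raise ValueError(f"{path}: truncated signal header")

        # unpack the per-signal header blocks sequentially
        widths = [16, 80, 8, 8, 8, 8, 8, 80, 8, 32]
        blocks, off = [], 0
        for w in widths:
            blocks.append([sig[off + i * w: off + (i + 1) * w].decode("ascii").strip()
                           for i in range(n_ch)])
            off += w * n_ch
        names = [b.upper() for b in blocks[0]]
        phys_min = np.array([float(v) for v in blocks[3]])
        phys_max = np.array([float(v) for v in blocks[4]])
        dig_min = np.array([float(v) for v in blocks[5]])
        dig_max = np.array([float(v) for v in blocks[6]])
        spr = np.array([int(v) for v in blocks[8]])
        if len(set(spr)) != 1:
            raise ValueError("mixed per-channel sampling rates unsupported")
        fs = spr[0] / rec_dur
        raw = np.frombuffer(fh.read(2 * n_ch * spr[0] * n_rec), dtype="<i2")
        if raw.size != n_ch * spr[0] * n_rec:
            raise ValueError(f"{path}: truncated data payload")
    data = (raw.reshape(n_rec, n_ch, spr[0]).transpose(1, 0, 2)
            .reshape(n_ch, -1).astype(float))
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    data = data * gain[:, None] + (phys_min - dig_min * gain)[:, None]
    if expected_fs is not None and abs(fs - expected_fs) > 1e-9:
        raise ValueError(
            f"{path}: sampling rate {fs} Hz differs from configured "
            f"{expected_fs} Hz (no silent resampling)"
        )
    if expected_channels is not None:
        missing = [c for c in expected_channels if c.upper() not in names]
        if missing:
            raise ValueError(f"{path}: missing channel(s) {missing}")
    return data, float(fs), names


def export_epochs_edf(epochs: EEGEpochs, edf_path, events_path=None) -> None:
    """Export an epoch set as one continuous EDF plus an events sidecar.

    Trials are concatenated along time (total duration must be a whole
    number of seconds); the sidecar CSV records each trial's onset and
    annotations so the epoching can be reconstructed.
    """
    data = epochs.data.transpose(1, 0, 2).reshape(epochs.n_channels, -1)
    write_edf(edf_path, data, epochs.fs, epochs.channel_names)
    events = epochs.annotations.copy()
    events.insert(0, "onset_s", np.arange(epochs.n_trials) * epochs.duration)
    events.insert(1, "duration_s", epochs.duration)
    if events_path is None:
        events_path = Path(edf_path).with_suffix(".events.csv")
    events.to_csv(events_path, index=False)


def read_events_csv(path) -> pd.DataFrame:
    """Epoch-onset events: a CSV with columns onset_s, action, hand."""
    events = pd.read_csv(path)
    required = {"onset_s", "action"}
    if not required.issubset(events.columns):
        raise ValueError(f"{path}: event table needs columns {sorted(required)}")
    return events


# --------------------------------------------------------------------------
# reports, matrices, provenance
# --------------------------------------------------------------------------

def save_adjacency_csv(path, matrix: np.ndarray,
                       channel_names: list[str]) -> None:
    pd.DataFrame(matrix, index=channel_names,
                 columns=channel_names).to_csv(path, float_format="%.6g")


def save_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def load_json(path) -> dict:
    return json.loads(Path(path).read_text())


def append_run_log(out_dir, stage: str, config_hash: str, seed: int,
                   extra: dict | None = None) -> None:
    record = {
        "stage": stage,
        "config_hash": config_hash,
        "seed": int(seed),
        "python": platform.python_version(),
        "numpy": np.__version__,
    }
    if extra:
        record.update(extra)
    path = Path(out_dir) / RUN_LOG
    with open(path, "a") as fh:
        fh.write(json.dumps(record, sort_keys=True) + "\n")


def check_hash(artifact_hash: str, expected: str, artifact: str) -> None:
    if expected and artifact_hash and artifact_hash != expected:
        raise ValueError(
            f"{artifact}: config hash {artifact_hash[:12]}… does not match "
            f"current configuration {expected[:12]}… (mixed-provenance "
            "inputs refused)"
        )
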