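"""Readers and writers for the pipeline's plain-text artifacts.

Raw recordings travel as CSV: one comment header line carrying subject id,
sampling rate and start time, then ``timestamp,x,y,z`` rows with the
timestamp in seconds from the start (ISO-8601 timestamps are also
accepted on input) and accelerations in g.  Gzip-compressed files
(``.gz``) are read and written transparently.
"""
from __future__ import annotations

import gzip
import hashlib
import io as _io
import json
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .signal_core import TriaxialRecording

_MAGIC = "# gaitpal-recording"


def _open(path: Path, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_recording(recording: TriaxialRecording, path: str | Path) -> None:
    """Write a recording to the CSV dialect (lossless float round-trip)."""
    path = Path(path)
    start = recording.start_time.isoformat() if recording.start_time else "-"
    t = np.arange(recording.n_samples) / recording.fs
    df = pd.DataFrame({"timestamp": t, "x": recording.x, "y": recording.y,
                       "z": recording.z})
    with _open(path, "w") as f:
        f.write(f"{_MAGIC} subject_id={recording.subject_id} "
                f"fs={recording.fs!r} start_time={start}\n")
        df.to_csv(f, index=False, float_format="%.17g")


def _parse_header(line: str, path: Path) -> dict:
    if not line.startswith(_MAGIC):
        raise FormatError(f"{path}: missing recording header line")
    fields = {}
    for token in line[len(_MAGIC):].split():
        if "=" not in token:
            raise FormatError(f"{path}: malformed header token {token!r}")
        k, v = token.split("=", 1)
        fields[k] = v
    if "fs" not in fields:
        raise FormatError(f"{path}: header does not declare fs")
    return fields


def read_recording(path: str | Path, gap_factor: float = 1.5) -> TriaxialRecording:
    """Read a recording, validate it, and detect timestamp gaps.

    Sample spacings larger than ``gap_factor``/fs are reported in the
    recording's ``gaps`` list as (t_start, t_end) seconds.  Malformed rows
    raise :class:`FormatError` with a line number; a declared rate
    inconsistent with the timestamps (by more than 1%) is also an error.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    with _open(path, "r") as f:
        header = f.readline()
        if not header.strip():
            raise FormatError(f"{path}: empty file")
        meta = _parse_header(header.strip(), path)
        body = f.read()
    if not body.strip():
        raise FormatError(f"{path}: no samples after header")
    fs = float(meta["fs"])
    df = pd.read_csv(_io.StringIO(body), float_precision="round_trip")
    required = {"timestamp", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: columns must include {sorted(required)}")
    ts_raw = df["timestamp"]
    try:
        t = ts_raw.astype(float).to_numpy()
    except (TypeError, ValueError):
        try:
            dt = pd.to_datetime(ts_raw)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: unparseable timestamps: {exc}") from None
        t = (dt - dt.iloc[0]).dt.total_seconds().to_numpy()
    axes = {}
    for col in ("x", "y", "z"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy())
        if bad.size:
            # +3: header line, column line, 1-based
            raise FormatError(f"{path}: malformed value in column {col!r} "
                              f"at line {int(bad[0]) + 3}")
        axes[col] = vals.to_numpy(dtype=float)
    gaps = []
    if t.size > 1:
        dts = np.diff(t)
        med = float(np.median(dts))
        if med > 0 and abs(1.0 / med - fs) / fs > 0.01:
            raise FormatError(f"{path}: declared fs={fs} inconsistent with "
                              f"timestamp spacing ({1.0 / med:.3f} Hz)")
        for i in np.flatnonzero(dts > gap_factor / fs):
            gaps.append((float(t[i]), float(t[i + 1])))
    start = None
    if meta.get("start_time", "-") != "-":
        start = datetime.fromisoformat(meta["start_time"])
    return TriaxialRecording(meta.get("subject_id", ""), fs, axes["x"],
                             axes["y"], axes["z"], start_time=start, gaps=gaps)


def write_labels(path: str | Path, frame: pd.DataFrame) -> None:
    """Per-epoch labels/features table (epoch_index, label, counts, ...)."""
    frame.to_csv(path, index=False)


def read_labels(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "label" not in df.columns or "counts" not in df.columns:
        raise FormatError(f"{path}: labels file needs label and counts columns")
    return df


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | Path, config, inputs: list, seed=None,
                   extra: dict | None = None) -> dict:
    """Snapshot of a run: config, input hashes, package version, seed."""
    from . import __version__
    manifest = {
        "package": "gaitpal",
        "version": __version__,
        "created": datetime.now().isoformat(timespec="seconds"),
        "seed": seed,
        "config": config.to_dict(),
        "inputs": [{"path": str(p), "sha256": sha256_file(p)}
                   for p in inputs if Path(p).exists()],
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2))
    return manifest
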