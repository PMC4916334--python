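"""Raw triaxial acceleration handling: vector magnitude, epochs, activity counts.

The intensity currency of the whole pipeline is the *activity count*: the
time integral of detrended, rectified acceleration over a 5-second epoch,
summed over the three axes, in units of g*s (1 kcount = 1000 counts).
Epochs whose count rate is strictly below the inactivity threshold
(10^-3 counts/s by default) are flagged inactive and excluded from all
downstream activity-time and counts aggregates.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime

import numpy as np

from .config import DEFAULT_CONFIG, PipelineConfig
from .errors import InputShapeError, ParameterError


@dataclass
class TriaxialRecording:
    """A timestamped triaxial acceleration series.

    x, y, z are accelerations in g (1 g = 9.81 m/s^2), sampled at ``fs`` Hz.
    ``start_time`` anchors the recording on the calendar; ``gaps`` lists
    (t_start_s, t_end_s) intervals where samples are missing.
    """

    subject_id: str
    fs: float
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    start_time: datetime | None = None
    gaps: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ParameterError("sampling rate must be positive")
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (self.x.shape == self.y.shape == self.z.shape) or self.x.ndim != 1:
            raise InputShapeError("x, y, z must be 1-D series of equal length")

    @property
    def n_samples(self) -> int:
        return self.x.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def data(self) -> np.ndarray:
        """Samples as an (n, 3) array, columns x, y, z."""
        return np.column_stack([self.x, self.y, self.z])


@dataclass
class Epoch:
    """One fixed-duration analysis window of a recording."""

    index: int
    fs: float
    per_axis: np.ndarray  # (n_samples, 3)
    duration_s: float = 5.0

    @property
    def n_samples(self) -> int:
        return self.per_axis.shape[0]

    @property
    def vm(self) -> np.ndarray:
        """Pointwise Euclidean norm of the three axes (vector magnitude)."""
        return np.sqrt(np.sum(self.per_axis ** 2, axis=1))


@dataclass
class EpochCounts:
    """Activity counts of one epoch (g*s), their rate, and the inactivity flag."""

    counts: float
    rate: float
    inactive: bool


def vector_magnitude(recording) -> np.ndarray:
    """Elementwise Euclidean norm of (x, y, z).

    Accepts a :class:`TriaxialRecording` or any (n, 3) array.
    """
    if isinstance(recording, TriaxialRecording):
        arr = recording.data
    else:
        arr = np.asarray(recording, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise InputShapeError("expected an (n, 3) acceleration array")
    return np.sqrt(np.sum(arr ** 2, axis=1))


def resample_recording(recording: TriaxialRecording, fs_new: float) -> TriaxialRecording:
    """Linearly resample a recording onto a new uniform rate."""
    if fs_new <= 0:
        raise ParameterError("target rate must be positive")
    if recording.fs == fs_new or recording.n_samples == 0:
        return TriaxialRecording(recording.subject_id, fs_new, recording.x,
                                 recording.y, recording.z, recording.start_time,
                                 list(recording.gaps))
    t_old = np.arange(recording.n_samples) / recording.fs
    n_new = int(np.floor(recording.duration_s * fs_new)) + 1
    t_new = np.arange(n_new) / fs_new
    t_new = t_new[t_new <= t_old[-1] + 1e-12]
    axes = [np.interp(t_new, t_old, a) for a in (recording.x, recording.y, recording.z)]
    return TriaxialRecording(recording.subject_id, fs_new, *axes,
                             start_time=recording.start_time, gaps=list(recording.gaps))


def epoch_sample_count(fs: float, epoch_s: float) -> int:
    n = fs * epoch_s
    if abs(n - round(n)) > 1e-9:
        raise ParameterError(
            f"epoch of {epoch_s}s is not a whole number of samples at {fs} Hz; "
            "resample the recording first")
    return int(round(n))


def segment_epochs(recording: TriaxialRecording, epoch_s: float | None = None,
                   config: PipelineConfig | None = None) -> list[Epoch]:
    """Cut a recording into consecutive, non-overlapping fixed-length epochs.

    A trailing partial epoch is discarded.  Recordings whose rate does not
    divide the epoch evenly are first resampled to the configured rate.
    """
    cfg = config or DEFAULT_CONFIG
    epoch_s = cfg.epoch_s if epoch_s is None else float(epoch_s)
    if epoch_s <= 0:
        raise ParameterError("epoch duration must be positive")
    n = recording.fs * epoch_s
    if abs(n - round(n)) > 1e-9:
        recording = resample_recording(recording, cfg.fs)
    length = epoch_sample_count(recording.fs, epoch_s)
    m = recording.n_samples // length
    data = recording.data
    return [Epoch(index=i, fs=recording.fs,
                  per_axis=data[i * length:(i + 1) * length],
                  duration_s=epoch_s)
            for i in range(m)]


def _detrended(seg: np.ndarray, mode: str) -> np.ndarray:
    # seg: (n_epochs, length, 3)
    out = seg - seg.mean(axis=1, keepdims=True)
    if mode == "linear":
        length = seg.shape[1]
        t = np.arange(length) - (length - 1) / 2.0
        denom = np.sum(t ** 2)
        slope = np.einsum("l,nlk->nk", t, out) / denom
        out = out - slope[:, None, :] * t[None, :, None]
    return out


def counts_from_samples(data: np.ndarray, fs: float, epoch_len: int,
                        detrend: str = "mean") -> np.ndarray:
    """Per-epoch activity counts for an (n, 3) sample block, vectorized.

    Counts = sum over axes of the rectangular-rule integral of the
    detrended, rectified axis signal: sum |a - mean| / fs, in g*s.
    Only full epochs are used; the trailing remainder is ignored.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] != 3:
        raise InputShapeError("expected an (n, 3) acceleration array")
    m = data.shape[0] // epoch_len
    if m == 0:
        return np.empty(0)
    seg = data[:m * epoch_len].reshape(m, epoch_len, 3)
    d = _detrended(seg, detrend)
    np.abs(d, out=d)
    return d.sum(axis=(1, 2)) / fs


def flag_inactive(rate, threshold: float | None = None,
                  config: PipelineConfig | None = None):
    """True iff the count rate is strictly below the inactivity threshold."""
    cfg = config or DEFAULT_CONFIG
    thr = cfg.inactivity_rate if threshold is None else threshold
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0):
        raise ParameterError("count rate cannot be negative")
    out = rate < thr
    return bool(out) if out.ndim == 0 else out


def epoch_counts(epoch: Epoch, config: PipelineConfig | None = None) -> EpochCounts:
    """Activity counts, rate and inactivity flag for one epoch."""
    cfg = config or DEFAULT_CONFIG
    c = float(counts_from_samples(epoch.per_axis, epoch.fs,
                                  epoch.n_samples, cfg.detrend)[0])
    rate = c / epoch.duration_s
    return EpochCounts(counts=c, rate=rate,
                       inactive=flag_inactive(rate, config=cfg))


def recording_counts(recording: TriaxialRecording,
                     config: PipelineConfig | None = None) -> np.ndarray:
    """Counts for every full epoch of a recording (convenience wrapper)."""
    cfg = config or DEFAULT_CONFIG
    length = epoch_sample_count(recording.fs, cfg.epoch_s)
    return counts_from_samples(recording.data, recording.fs, length, cfg.detrend)
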