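"""Personalized gait templates and the two classifier features, SDs and SDcc.

A subject's gait template is a prototype waveform of one gait cycle (one
stride) extracted from a treadmill calibration session: the vector-magnitude
signal is segmented at its dominant stride periodicity, the cycles are
resampled to a common length, aligned, and averaged.  Every 5-s epoch is
then summarized by two features: SDs, the standard deviation of its
vector-magnitude signal (signal power), and SDcc, the standard deviation of
its cross-correlation with the template (periodicity and shape match).
Both use the population (n) denominator.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import fftconvolve, find_peaks

from .errors import CalibrationQualityError, InputShapeError, ParameterError
from .signal_core import Epoch, EpochCounts, TriaxialRecording, vector_magnitude

# plausible stride-frequency band (strides/s); steps are twice as frequent
_STRIDE_F_MIN = 0.4
_STRIDE_F_MAX = 1.75


@dataclass
class GaitTemplate:
    """Prototype vector-magnitude waveform of one gait cycle, mean-removed."""

    subject_id: str
    fs: float
    waveform: np.ndarray
    cycle_len: int
    n_cycles_used: int
    source_speeds: tuple = ()

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        if self.cycle_len < 2 or self.waveform.size != self.cycle_len:
            raise ParameterError("template must hold >= 2 samples")
        amp = np.max(np.abs(self.waveform)) or 1.0
        if abs(self.waveform.mean()) > 1e-9 * amp:
            raise ParameterError("template waveform must be mean-removed")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({
            "subject_id": self.subject_id,
            "fs": self.fs,
            "cycle_len": self.cycle_len,
            "n_cycles_used": self.n_cycles_used,
            "source_speeds": list(self.source_speeds),
            "waveform": self.waveform.tolist(),
        })
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "GaitTemplate":
        if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
            text = Path(source).read_text()
        else:
            text = str(source)
        d = json.loads(text)
        return cls(subject_id=d["subject_id"], fs=d["fs"],
                   waveform=np.asarray(d["waveform"]),
                   cycle_len=d["cycle_len"], n_cycles_used=d["n_cycles_used"],
                   source_speeds=tuple(d["source_speeds"]))


@dataclass
class EpochFeatures:
    """The classifier's per-epoch summary: SDs, SDcc and the epoch counts."""

    sd_s: float
    sd_cc: float
    counts: EpochCounts | None = None


def estimate_stride_period(vm: np.ndarray, fs: float,
                           cadence_hint: float | None = None,
                           min_autocorr: float = 0.3) -> int:
    """Dominant stride period (samples) of a vector-magnitude signal.

    Uses the biased normalized autocorrelation; the search window is the
    plausible stride band, or +/-20% around the hinted step cadence
    (strides run at half the step frequency).  Raises
    :class:`CalibrationQualityError` when no sufficiently strong
    periodicity exists.
    """
    v = np.asarray(vm, dtype=float)
    v = v - v.mean()
    n = v.size
    if n < 4 or not np.any(v):
        raise CalibrationQualityError("signal too short or constant")
    acf = np.correlate(v, v, mode="full")[n - 1:]
    if acf[0] <= 0:
        raise CalibrationQualityError("zero-variance signal")
    acf = acf / acf[0]
    if cadence_hint is not None:
        p0 = 2.0 * fs / cadence_hint
        lo, hi = int(np.floor(0.8 * p0)), int(np.ceil(1.2 * p0))
    else:
        lo = int(np.floor(fs / _STRIDE_F_MAX))
        hi = int(np.ceil(fs / _STRIDE_F_MIN))
    lo = max(lo, 2)
    hi = min(hi, n // 2)
    if hi <= lo:
        raise CalibrationQualityError("signal too short for periodicity search")
    lag = lo + int(np.argmax(acf[lo:hi + 1]))
    if acf[lag] < min_autocorr:
        raise CalibrationQualityError(
            f"no dominant gait periodicity (peak autocorrelation "
            f"{acf[lag]:.2f} < {min_autocorr})")
    return lag


def extract_gait_cycles(calibration: TriaxialRecording,
                        cadence_hint: float | None = None,
                        min_autocorr: float = 0.3) -> list[np.ndarray]:
    """Segment a treadmill recording into individual gait-cycle waveforms.

    Cycles are cut peak-to-peak on the vector-magnitude signal at the
    dominant stride periodicity; segments far from the estimated period
    (outside 70-130%) are dropped.  Each returned cycle is mean-removed.
    """
    vm = vector_magnitude(calibration)
    period = estimate_stride_period(vm, calibration.fs, cadence_hint,
                                    min_autocorr)
    vc = vm - vm.mean()
    peaks, _ = find_peaks(vc, distance=max(int(0.7 * period), 1))
    cycles = []
    for a, b in zip(peaks[:-1], peaks[1:]):
        if 0.7 * period <= b - a <= 1.3 * period:
            seg = vm[a:b]
            cycles.append(seg - seg.mean())
    if not cycles:
        raise CalibrationQualityError("no usable gait cycles found")
    return cycles


def _resample_cycle(cycle: np.ndarray, length: int) -> np.ndarray:
    src = np.linspace(0.0, 1.0, cycle.size, endpoint=False)
    dst = np.linspace(0.0, 1.0, length, endpoint=False)
    return np.interp(dst, src, cycle)


def _circular_align(ref: np.ndarray, cyc: np.ndarray) -> np.ndarray:
    # periodic waveforms: find the circular shift maximizing the dot product
    shifts = np.array([np.roll(cyc, s) for s in range(cyc.size)])
    best = int(np.argmax(shifts @ ref))
    return shifts[best]


def build_template(cycles: list[np.ndarray], subject_id: str = "",
                   fs: float = 60.0, source_speeds: tuple = ()) -> GaitTemplate:
    """Average aligned gait cycles into a personalized template.

    Cycles are resampled to the median cycle length, circularly aligned to
    the first cycle by cross-correlation lag, pointwise averaged, and
    mean-removed.
    """
    if not cycles:
        raise ParameterError("need at least one gait cycle")
    lengths = [np.asarray(c).size for c in cycles]
    if min(lengths) < 2:
        raise ParameterError("cycles must hold >= 2 samples")
    length = int(round(float(np.median(lengths))))
    rs = [_resample_cycle(np.asarray(c, dtype=float), length) for c in cycles]
    ref = rs[0]
    aligned = [rs[0]] + [_circular_align(ref, c) for c in rs[1:]]
    waveform = np.mean(aligned, axis=0)
    waveform = waveform - waveform.mean()
    return GaitTemplate(subject_id=subject_id, fs=fs, waveform=waveform,
                        cycle_len=length, n_cycles_used=len(cycles),
                        source_speeds=tuple(source_speeds))


def features_from_vm(vm_epochs: np.ndarray,
                     template: GaitTemplate) -> tuple[np.ndarray, np.ndarray]:
    """SDs and SDcc for a block of epochs, vectorized.

    Parameters
    ----------
    vm_epochs : (n_epochs, epoch_len) array
        Vector-magnitude signal of each epoch.
    template : GaitTemplate

    Returns
    -------
    (sd_s, sd_cc) : two (n_epochs,) arrays
        Population standard deviations of the epoch signal and of its
        cross-correlation with the template at all full-overlap lags.
    """
    vm_epochs = np.atleast_2d(np.asarray(vm_epochs, dtype=float))
    t = template.waveform
    if vm_epochs.shape[1] < t.size:
        raise InputShapeError("epoch shorter than the template cycle")
    vc = vm_epochs - vm_epochs.mean(axis=1, keepdims=True)
    sd_s = vm_epochs.std(axis=1)
    if vc.shape[0] >= 32:  # FFT pays off on large batches; exact dot otherwise
        cc = fftconvolve(vc, t[::-1][None, :], mode="valid", axes=1)
    else:
        windows = sliding_window_view(vc, t.size, axis=1)
        cc = windows @ t
    sd_cc = cc.std(axis=1)
    return sd_s, sd_cc


def epoch_features(epoch: Epoch, template: GaitTemplate,
                   counts: EpochCounts | None = None) -> EpochFeatures:
    """SDs/SDcc features for a single epoch."""
    sd_s, sd_cc = features_from_vm(epoch.vm[None, :], template)
    return EpochFeatures(sd_s=float(sd_s[0]), sd_cc=float(sd_cc[0]),
                         counts=counts)
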