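"""Synthetic accelerometry and cohorts with ground-truth labels.

Everything the pipeline consumes can be generated here so the whole chain
is testable without real recordings:

* quasi-periodic gait signal (harmonic series at the step frequency, with a
  stride-level asymmetry component and Gaussian sensor noise);
* aperiodic non-walking movement (band-limited 0.3-8 Hz noise scaled to a
  target count intensity);
* idle wear (noise below the inactivity threshold) and non-wear (exact
  zeros, device off);
* four-speed treadmill calibration sessions;
* free-living day schedules with a known daily summary;
* whole cohorts of per-subject daily times/intensities and true PALs, for
  regression parameter-recovery studies.

Defaults emulate a healthy older-adult cohort: ~10.5 h/day of activity of
which ~130 min is walking (83% of it in bouts under a minute), nonwalking
intensity ~7 counts/min, walking ~21 counts/min, and PAL ~1.84 on average.
All generators are deterministic for a fixed seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from . import aggregation
from .classifier import LABEL_INACTIVE, LABEL_NONWALK, LABEL_WALK
from .config import DEFAULT_CONFIG, PipelineConfig
from .energy_models import REFERENCE_SIMPLE_MODEL, PALModel
from .errors import ParameterError
from .signal_core import TriaxialRecording, counts_from_samples, epoch_sample_count

LABEL_NONWEAR = "nonwear"

# Reference daily activity structure of a healthy older-adult cohort:
# mean time (min/day), counts (kcounts/day) and intensity (counts/minute)
# per category.  These are the targets the default generators emulate.
REFERENCE_DAILY_ACTIVITY = {
    "physical_activity": {"time_min": 630.0, "kcounts": 6.2, "intensity": 9.8},
    "nonwalking": {"time_min": 500.0, "kcounts": 3.5, "intensity": 7.0},
    "walking": {"time_min": 130.0, "kcounts": 2.7, "intensity": 21.5},
    "short_walk": {"time_min": 106.0, "kcounts": 2.1, "intensity": 20.9},
    "long_walk": {"time_min": 24.0, "kcounts": 0.6, "intensity": 23.3},
}

REFERENCE_MEAN_PAL = 1.84

# attenuation and phase lead of the horizontal axes relative to the
# vertical gait component
_AXIS_ATTEN = (0.55, 0.35)
_AXIS_PHASE = (np.pi / 2, np.pi / 3)

# affine speed (km/h) -> gait parameter mapping for treadmill simulation
_SPEED_TO_STEP_F = (1.10, 0.14)    # step_freq = 1.10 + 0.14 * speed
_SPEED_TO_AMPLITUDE = (0.05, 0.055)  # amplitude = 0.05 + 0.055 * speed

DEFAULT_TREADMILL_SPEEDS = (3.0, 4.0, 5.0, 6.0)


@dataclass
class GaitParams:
    """Parameters of the harmonic gait-signal model.

    step_freq is in Hz (steps/s; strides run at half that), amplitude in g
    is the fundamental's amplitude on the vertical axis, harmonics are
    amplitudes of the 2nd, 3rd, ... multiples relative to the fundamental,
    cycle_asymmetry adds a component at the stride frequency (making the
    stride, not the step, the true signal period), and noise_sd is the
    white sensor noise per axis in g.
    """

    step_freq: float = 1.8
    amplitude: float = 0.3
    harmonics: tuple = (0.4, 0.2)
    cycle_asymmetry: float = 0.15
    noise_sd: float = 0.03

    def __post_init__(self) -> None:
        if not 0.5 < self.step_freq < 3.5:
            raise ParameterError("step_freq must lie in (0.5, 3.5) Hz")
        if self.amplitude <= 0 or self.noise_sd < 0:
            raise ParameterError("amplitude must be > 0 and noise_sd >= 0")


@dataclass
class Segment:
    """One constant-activity block of a simulated day."""

    kind: str          # walk | nonwalk | inactive | nonwear
    duration_s: float
    params: dict = field(default_factory=dict)


@dataclass
class DaySchedule:
    """Ordered activity segments making up one simulated day."""

    segments: list
    seed: int | None = None

    def __post_init__(self) -> None:
        total = sum(s.duration_s for s in self.segments)
        if any(s.duration_s <= 0 for s in self.segments):
            raise ParameterError("segment durations must be positive")
        if total > 24 * 3600:
            raise ParameterError("schedule exceeds 24 h")


@dataclass
class CohortSpec:
    """Distributional description of a synthetic cohort (summary level).

    time_dist / intensity_dist give (mean, SD) of per-subject daily time
    (min/day) and intensity (counts/min) per category; defaults match the
    reference healthy older-adult cohort.  PAL is generated from
    ``pal_model`` applied to the subject's true counts plus Gaussian noise.
    """

    n_subjects: int = 31
    n_days: int = 14
    time_dist: dict = field(default_factory=lambda: {
        "nonwalking": (500.0, 97.0),
        "short_walk": (106.0, 49.0),
        "long_walk": (24.0, 17.0)})
    intensity_dist: dict = field(default_factory=lambda: {
        "nonwalking": (7.0, 1.2),
        "short_walk": (20.9, 3.1),
        "long_walk": (23.3, 3.6)})
    pal_model: PALModel = field(default_factory=lambda: REFERENCE_SIMPLE_MODEL)
    pal_noise_sd: float = 0.13
    day_cv: float = 0.15   # within-subject day-to-day variation
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ParameterError("n_subjects must be >= 2")
        for d in (self.time_dist, self.intensity_dist):
            if any(sd < 0 for _, sd in d.values()):
                raise ParameterError("distribution SDs must be >= 0")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def gait_params_for_speed(speed_kmh: float, noise_sd: float = 0.03,
                          harmonics: tuple = (0.4, 0.2),
                          cycle_asymmetry: float = 0.15) -> GaitParams:
    """Affine treadmill-speed to gait-parameter mapping (monotone in speed)."""
    return GaitParams(
        step_freq=_SPEED_TO_STEP_F[0] + _SPEED_TO_STEP_F[1] * speed_kmh,
        amplitude=_SPEED_TO_AMPLITUDE[0] + _SPEED_TO_AMPLITUDE[1] * speed_kmh,
        harmonics=harmonics, cycle_asymmetry=cycle_asymmetry,
        noise_sd=noise_sd)


def _gait_axes(params: GaitParams, n: int, fs: float, phase: float) -> np.ndarray:
    t = np.arange(n) / fs
    f = params.step_freq

    def series(ph):
        s = np.sin(2 * np.pi * f * t + ph)
        for i, h in enumerate(params.harmonics, start=2):
            s = s + h * np.sin(2 * np.pi * i * f * t + i * ph)
        s = params.amplitude * s
        # stride-frequency component breaks left/right step symmetry
        s = s + params.cycle_asymmetry * params.amplitude * np.sin(
            2 * np.pi * (f / 2) * t + ph / 2)
        return s

    z = series(phase)
    x = _AXIS_ATTEN[0] * series(phase + _AXIS_PHASE[0])
    y = _AXIS_ATTEN[1] * series(phase + _AXIS_PHASE[1])
    return np.column_stack([x, y, z])


def simulate_walk(params: GaitParams, duration_s: float, fs: float = 60.0,
                  seed=None, subject_id: str = "sim",
                  random_phase: bool = True):
    """Quasi-periodic walking signal with per-epoch truth labels.

    The vertical axis carries 1 g gravity plus the harmonic gait series;
    horizontal axes are attenuated, phase-shifted copies.  Returns
    (TriaxialRecording, labels) with one "walk" label per full 5-s epoch.
    """
    if duration_s < 5:
        raise ParameterError("need at least one 5-s epoch of walking")
    rng = _rng(seed)
    n = int(round(duration_s * fs))
    phase = float(rng.uniform(0, 2 * np.pi)) if random_phase else 0.0
    sig = _gait_axes(params, n, fs, phase)
    if params.noise_sd > 0:
        sig = sig + rng.normal(0.0, params.noise_sd, size=sig.shape)
    sig[:, 2] += 1.0  # gravity on the vertical axis
    rec = TriaxialRecording(subject_id, fs, sig[:, 0], sig[:, 1], sig[:, 2])
    n_ep = n // epoch_sample_count(fs, DEFAULT_CONFIG.epoch_s)
    return rec, np.array([LABEL_WALK] * n_ep, dtype=object)


def simulate_nonwalk(intensity_target: float, duration_s: float,
                     fs: float = 60.0, seed=None, band=(0.3, 8.0),
                     subject_id: str = "sim",
                     config: PipelineConfig | None = None):
    """Aperiodic movement noise scaled to a target count intensity.

    White noise on all three axes is band-limited to ``band`` Hz and
    rescaled so the mean realized epoch count rate equals
    ``intensity_target`` counts/min exactly (counts are linear in
    amplitude).  A target of 0 produces a still, worn device (all epochs
    inactive).
    """
    if intensity_target < 0:
        raise ParameterError("intensity_target must be >= 0")
    cfg = config or DEFAULT_CONFIG
    rng = _rng(seed)
    n = int(round(duration_s * fs))
    sig = np.zeros((n, 3))
    if intensity_target > 0 and n > 18:  # sosfiltfilt needs some padding
        raw = rng.standard_normal((n, 3))
        sos = butter(4, band, btype="bandpass", fs=fs, output="sos")
        sig = sosfiltfilt(sos, raw, axis=0)
        length = epoch_sample_count(fs, cfg.epoch_s)
        counts = counts_from_samples(sig, fs, length, cfg.detrend)
        realized = counts.mean() if counts.size else 0.0
        target_per_epoch = intensity_target * cfg.epoch_s / 60.0
        if realized > 0:
            sig = sig * (target_per_epoch / realized)
    rec = TriaxialRecording(subject_id, fs, sig[:, 0], sig[:, 1], 1.0 + sig[:, 2])
    length = epoch_sample_count(fs, cfg.epoch_s)
    counts = counts_from_samples(rec.data, fs, length, cfg.detrend)
    rate = counts / cfg.epoch_s
    labels = np.where(rate < cfg.inactivity_rate, LABEL_INACTIVE,
                      LABEL_NONWALK).astype(object)
    return rec, labels


def simulate_nonwear(duration_s: float, fs: float = 60.0,
                     subject_id: str = "sim"):
    """Device off: exact zeros on all axes."""
    n = int(round(duration_s * fs))
    z = np.zeros(n)
    rec = TriaxialRecording(subject_id, fs, z, z.copy(), z.copy())
    n_ep = n // epoch_sample_count(fs, DEFAULT_CONFIG.epoch_s)
    return rec, np.array([LABEL_NONWEAR] * n_ep, dtype=object)


def simulate_treadmill_session(speeds=DEFAULT_TREADMILL_SPEEDS,
                               duration_each_s: float = 180.0,
                               fs: float = 60.0, seed=None,
                               noise_sd: float = 0.03,
                               subject_id: str = "sim"):
    """Concatenated constant-speed walking blocks (the calibration session).

    Returns (TriaxialRecording, labels, block_speeds) where block_speeds
    gives the treadmill speed of every epoch.  Speed maps affinely (and
    monotonically) onto step frequency and amplitude.
    """
    rng = _rng(seed)
    blocks, labels, ep_speeds = [], [], []
    for speed in speeds:
        params = gait_params_for_speed(speed, noise_sd=noise_sd)
        rec, lab = simulate_walk(params, duration_each_s, fs, rng,
                                 subject_id=subject_id)
        blocks.append(rec.data)
        labels.append(lab)
        ep_speeds.extend([speed] * lab.size)
    data = np.vstack(blocks)
    rec = TriaxialRecording(subject_id, fs, data[:, 0], data[:, 1], data[:, 2])
    return rec, np.concatenate(labels), np.array(ep_speeds)


_SEGMENT_BUILDERS = {}


def _build_segment(seg: Segment, fs: float, rng) -> tuple[np.ndarray, np.ndarray]:
    if seg.kind == "walk":
        params = seg.params.get("gait")
        if params is None:
            speed = seg.params.get("speed", 4.5)
            params = gait_params_for_speed(speed)
        rec, lab = simulate_walk(params, seg.duration_s, fs, rng)
    elif seg.kind == "nonwalk":
        rec, lab = simulate_nonwalk(seg.params.get("intensity", 7.0),
                                    seg.duration_s, fs, rng)
    elif seg.kind == "inactive":
        # worn but still: movement noise well below the inactivity threshold
        rec, lab = simulate_nonwalk(seg.params.get("intensity", 0.02),
                                    seg.duration_s, fs, rng)
        lab = np.array([LABEL_INACTIVE] * lab.size, dtype=object)
    elif seg.kind == "nonwear":
        rec, lab = simulate_nonwear(seg.duration_s, fs)
    else:
        raise ParameterError(f"unknown segment kind {seg.kind!r}")
    return rec.data, lab


def simulate_day(schedule: DaySchedule, fs: float = 60.0,
                 subject_id: str = "sim",
                 config: PipelineConfig | None = None):
    """Assemble a day from its schedule; return recording, truth and summary.

    Segment durations are snapped to whole epochs so truth labels align
    with the epoch grid.  The returned truth
    :class:`~gaitpal.aggregation.DailySummary` is computed from the truth
    labels and the measured per-epoch counts, with wear time taken from
    the schedule (recorded duration minus non-wear segments).

    Returns ``(recording, labels, truth_summary)``.
    """
    cfg = config or DEFAULT_CONFIG
    rng = _rng(schedule.seed)
    if not schedule.segments:
        rec = TriaxialRecording(subject_id, fs, np.empty(0), np.empty(0),
                                np.empty(0))
        empty = aggregation.summarize_day(np.empty(0, dtype=object),
                                          np.empty(0), wear_time_h=0.0,
                                          config=cfg)
        return rec, np.empty(0, dtype=object), empty
    parts, labels = [], []
    for seg in schedule.segments:
        dur = max(cfg.epoch_s,
                  round(seg.duration_s / cfg.epoch_s) * cfg.epoch_s)
        seg = Segment(seg.kind, dur, seg.params)
        d, lab = _build_segment(seg, fs, rng)
        parts.append(d)
        labels.append(lab)
    data = np.vstack(parts)
    labels = np.concatenate(labels)
    rec = TriaxialRecording(subject_id, fs, data[:, 0], data[:, 1], data[:, 2])
    length = epoch_sample_count(fs, cfg.epoch_s)
    counts = counts_from_samples(data, fs, length, cfg.detrend)
    nonwear_s = sum(s.duration_s for s in schedule.segments
                    if s.kind == "nonwear")
    wear_h = (rec.duration_s - nonwear_s) / 3600.0
    agg_labels = np.where(labels == LABEL_NONWEAR, LABEL_INACTIVE,
                          labels).astype(object)
    truth = aggregation.summarize_day(agg_labels, counts,
                                      wear_time_h=wear_h, config=cfg)
    return rec, labels, truth


def default_day_schedule(seed=None, wear_h_mean: float = 15.0,
                         nonwalk_min_mean: float = 500.0,
                         walk_min_mean: float = 130.0,
                         short_fraction: float = 0.83,
                         nonwalk_intensity: float = 7.0,
                         speed_range=(3.0, 6.0)) -> DaySchedule:
    """A free-living day with the reference cohort's activity structure.

    Walking time splits into many sub-minute bouts and a few long bouts;
    nonwalking movement and idle time fill the remaining wear window.
    Walking speed varies bout-to-bout within ``speed_range``.
    """
    rng = _rng(seed)
    walks: list[Segment] = []
    walk_total = max(20.0, rng.normal(walk_min_mean, walk_min_mean * 0.3))
    short_total = walk_total * short_fraction * 60.0
    long_total = walk_total * (1 - short_fraction) * 60.0
    t = 0.0
    while t < short_total:
        d = float(rng.uniform(10, 55))
        walks.append(Segment("walk", d,
                             {"speed": float(rng.uniform(*speed_range))}))
        t += d
    t = 0.0
    while t < long_total:
        d = float(rng.uniform(60, 240))
        walks.append(Segment("walk", d,
                             {"speed": float(rng.uniform(*speed_range))}))
        t += d
    fillers: list[Segment] = []
    nonwalk_total = max(60.0, rng.normal(nonwalk_min_mean,
                                         nonwalk_min_mean * 0.15)) * 60.0
    t = 0.0
    while t < nonwalk_total:
        d = float(rng.uniform(300, 1500))
        fillers.append(Segment("nonwalk", d,
                               {"intensity": float(max(0.5, rng.normal(
                                   nonwalk_intensity, 1.0)))}))
        t += d
    wear_s = max(11.0, rng.normal(wear_h_mean, 1.0)) * 3600.0
    idle_s = wear_s - sum(s.duration_s for s in walks + fillers)
    while idle_s > 60.0:
        d = float(min(idle_s, rng.uniform(300, 1800)))
        fillers.append(Segment("inactive", d))
        idle_s -= d
    # walk bouts must stay isolated (one bout per run of walk epochs), so
    # split fillers until there is a non-walk separator for every bout
    while len(fillers) < len(walks) + 1:
        fillers.sort(key=lambda s: -s.duration_s)
        big = fillers[0]
        if big.duration_s < 20.0:
            fillers.append(Segment("inactive", 10.0))
            continue
        half = big.duration_s / 2.0
        fillers[0] = Segment(big.kind, half, big.params)
        fillers.append(Segment(big.kind, big.duration_s - half, big.params))
    rng.shuffle(walks)
    rng.shuffle(fillers)
    segs: list[Segment] = []
    for i, w in enumerate(walks):
        segs.append(fillers[i])
        segs.append(w)
    segs.extend(fillers[len(walks):])
    return DaySchedule(segments=segs, seed=int(rng.integers(2 ** 31)))


def _trunc_normal(rng, mean, sd, lo):
    return float(max(lo, rng.normal(mean, sd)))


def simulate_cohort(spec: CohortSpec, seed=None) -> pd.DataFrame:
    """Summary-level cohort generator with known ground truth.

    Per-subject mean daily times and intensities per category are drawn
    from the spec's (mean, SD) distributions (truncated at small positive
    values); daily values vary around the subject mean with coefficient of
    variation ``day_cv`` and are averaged over ``n_days``.  True PAL is
    the configured model evaluated at the subject's true counts plus
    Gaussian noise.  Returns one row per subject with times (min/day),
    counts (counts/day), derived totals, the short-walk time fraction of
    walking, and PAL.
    """
    rng = _rng(spec.seed if seed is None else seed)
    rows = []
    for i in range(spec.n_subjects):
        row = {"subject_id": f"S{i + 1:03d}"}
        for cat in aggregation.CATEGORIES:
            mu_t, sd_t = spec.time_dist[cat]
            mu_i, sd_i = spec.intensity_dist[cat]
            t_mean = _trunc_normal(rng, mu_t, sd_t, 1.0)
            inten = _trunc_normal(rng, mu_i, sd_i, 0.5)
            daily_t = np.maximum(
                0.0, t_mean * (1.0 + spec.day_cv * rng.standard_normal(spec.n_days)))
            row[f"{cat}_time_min"] = float(daily_t.mean())
            row[f"{cat}_counts"] = float((daily_t * inten).mean())
            row[f"{cat}_intensity"] = inten
        row["walking_time_min"] = row["short_walk_time_min"] + row["long_walk_time_min"]
        row["walking_counts"] = row["short_walk_counts"] + row["long_walk_counts"]
        row["activity_time_min"] = row["walking_time_min"] + row["nonwalking_time_min"]
        row["activity_counts"] = row["walking_counts"] + row["nonwalking_counts"]
        row["short_walk_time_fraction"] = (
            row["short_walk_time_min"] / row["walking_time_min"]
            if row["walking_time_min"] > 0 else np.nan)
        rows.append(row)
    df = pd.DataFrame(rows)
    pal_true = spec.pal_model.predict(df)
    df["pal"] = pal_true + rng.normal(0.0, spec.pal_noise_sd,
                                      size=spec.n_subjects)
    return df
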