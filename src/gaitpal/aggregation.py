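"""Bouts, daily summaries, subject averages and cohort tables.

Classified epochs are grouped into walking bouts (maximal runs of
consecutive walk epochs, no gap tolerance); bouts shorter than one minute
are short walks, bouts of at least one minute long walks.  Day-level time
and counts are tallied per category (nonwalking, short walks, long walks);
walking = short + long and activity = walking + nonwalking hold exactly at
every level.  Days with under 10 h of wear, or with missing data, are
excluded; the subject summary is the unweighted mean over valid days.
Intensity (counts/minute) is the ratio of a subject's mean daily counts to
mean daily time, and cohort intensity averages the per-subject ratios.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifier import LABEL_INACTIVE, LABEL_NONWALK, LABEL_WALK
from .config import DEFAULT_CONFIG, PipelineConfig
from .errors import InputShapeError, NoValidDaysError, ParameterError

CATEGORIES = ("nonwalking", "short_walk", "long_walk")


@dataclass
class WalkBout:
    """A maximal run of consecutive walk epochs."""

    start_epoch: int
    n_epochs: int
    duration_s: float
    category: str  # "short" | "long"
    counts: float = 0.0


@dataclass
class DailySummary:
    """Per-day activity tally: minutes and counts per category."""

    date: object
    wear_time_h: float
    time_min: dict = field(default_factory=dict)     # category -> min
    counts: dict = field(default_factory=dict)       # category -> counts (g*s)
    valid: bool = True
    missing: bool = False

    @property
    def walking_time_min(self) -> float:
        return self.time_min["short_walk"] + self.time_min["long_walk"]

    @property
    def walking_counts(self) -> float:
        return self.counts["short_walk"] + self.counts["long_walk"]

    @property
    def activity_time_min(self) -> float:
        return self.walking_time_min + self.time_min["nonwalking"]

    @property
    def activity_counts(self) -> float:
        return self.walking_counts + self.counts["nonwalking"]


@dataclass
class SubjectSummary:
    """Valid-day means for one subject, plus intensities (counts/minute)."""

    subject_id: str
    n_valid_days: int
    time_min: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    intensity: dict = field(default_factory=dict)    # None when time is 0

    @property
    def walking_time_min(self) -> float:
        return self.time_min["short_walk"] + self.time_min["long_walk"]

    @property
    def walking_counts(self) -> float:
        return self.counts["short_walk"] + self.counts["long_walk"]

    @property
    def activity_time_min(self) -> float:
        return self.walking_time_min + self.time_min["nonwalking"]

    @property
    def activity_counts(self) -> float:
        return self.walking_counts + self.counts["nonwalking"]

    @property
    def activity_time_h(self) -> float:
        return self.activity_time_min / 60.0


def find_bouts(labels, counts=None, epoch_s: float | None = None,
               bout_threshold_s: float | None = None,
               config: PipelineConfig | None = None) -> list[WalkBout]:
    """Maximal runs of consecutive walk epochs, categorized short/long.

    A single non-walk (or inactive) epoch ends a bout; there is no gap
    tolerance.  category == "short" iff duration < the bout threshold
    (60 s by default).
    """
    cfg = config or DEFAULT_CONFIG
    epoch_s = cfg.epoch_s if epoch_s is None else epoch_s
    thr = cfg.bout_threshold_s if bout_threshold_s is None else bout_threshold_s
    labels = np.asarray(labels, dtype=object)
    c = np.zeros(labels.size) if counts is None else np.asarray(counts, dtype=float)
    if c.size != labels.size:
        raise InputShapeError("counts and labels must have equal length")
    bouts: list[WalkBout] = []
    i = 0
    n = labels.size
    while i < n:
        if labels[i] == LABEL_WALK:
            j = i
            while j < n and labels[j] == LABEL_WALK:
                j += 1
            dur = (j - i) * epoch_s
            bouts.append(WalkBout(start_epoch=i, n_epochs=j - i,
                                  duration_s=dur,
                                  category="short" if dur < thr else "long",
                                  counts=float(c[i:j].sum())))
            i = j
        else:
            i += 1
    return bouts


def wear_time_from_counts(counts, epoch_s: float | None = None,
                          config: PipelineConfig | None = None) -> float:
    """Wear time in hours estimated from the count series.

    Runs of at least `nonwear_run_min` consecutive minutes of zero-count
    epochs are treated as non-wear; wear = recorded duration minus
    non-wear.
    """
    cfg = config or DEFAULT_CONFIG
    epoch_s = cfg.epoch_s if epoch_s is None else epoch_s
    counts = np.asarray(counts, dtype=float)
    run_epochs = int(round(cfg.nonwear_run_min * 60.0 / epoch_s))
    zero = counts == 0.0
    nonwear = 0
    i = 0
    while i < zero.size:
        if zero[i]:
            j = i
            while j < zero.size and zero[j]:
                j += 1
            if j - i >= run_epochs:
                nonwear += j - i
            i = j
        else:
            i += 1
    return (counts.size - nonwear) * epoch_s / 3600.0


def summarize_day(labels, counts, date=None, wear_time_h: float | None = None,
                  missing: bool = False, indices=None,
                  config: PipelineConfig | None = None) -> DailySummary:
    """Tally one day of labeled epochs into category times and counts.

    Time per category is the epoch duration times the epoch tally; counts
    are summed.  Inactive (and non-worn) epochs contribute to neither.
    When ``wear_time_h`` is not supplied it is estimated from the count
    series via the non-wear run rule.
    """
    cfg = config or DEFAULT_CONFIG
    labels = np.asarray(labels, dtype=object)
    counts = np.asarray(counts, dtype=float)
    if labels.size != counts.size:
        raise InputShapeError("labels and counts must have equal length")
    if indices is not None:
        idx = np.asarray(indices)
        if np.unique(idx).size != idx.size or np.any(np.diff(idx) <= 0):
            raise InputShapeError("epoch indices must be strictly increasing "
                                  "and unique (overlap/duplication)")
    if wear_time_h is None:
        wear_time_h = wear_time_from_counts(counts, config=cfg)
    bouts = find_bouts(labels, counts, config=cfg)
    t_min = {c: 0.0 for c in CATEGORIES}
    c_sum = {c: 0.0 for c in CATEGORIES}
    for b in bouts:
        cat = "short_walk" if b.category == "short" else "long_walk"
        t_min[cat] += b.duration_s / 60.0
        c_sum[cat] += b.counts
    nonwalk = labels == LABEL_NONWALK
    t_min["nonwalking"] = float(nonwalk.sum()) * cfg.epoch_s / 60.0
    c_sum["nonwalking"] = float(counts[nonwalk].sum())
    valid = (wear_time_h >= cfg.wear_min_h) and not missing
    return DailySummary(date=date, wear_time_h=float(wear_time_h),
                        time_min=t_min, counts=c_sum, valid=valid,
                        missing=missing)


def summarize_subject(days: list[DailySummary],
                      subject_id: str = "") -> SubjectSummary:
    """Unweighted mean over valid days; invalid days are ignored entirely.

    Raises :class:`NoValidDaysError` when no day is valid (the subject is
    excluded).  Intensity per category is mean counts / mean time, reported
    as None (missing) when the mean time is zero.
    """
    valid = [d for d in days if d.valid]
    if not valid:
        raise NoValidDaysError(f"subject {subject_id!r} has no valid days")
    t = {c: float(np.mean([d.time_min[c] for d in valid])) for c in CATEGORIES}
    cs = {c: float(np.mean([d.counts[c] for d in valid])) for c in CATEGORIES}
    inten = {c: (cs[c] / t[c] if t[c] > 0 else None) for c in CATEGORIES}
    return SubjectSummary(subject_id=subject_id, n_valid_days=len(valid),
                          time_min=t, counts=cs, intensity=inten)


_ROWS = (
    ("physical_activity", ("nonwalking", "short_walk", "long_walk")),
    ("nonwalking_activity", ("nonwalking",)),
    ("walking_activity", ("short_walk", "long_walk")),
    ("short_walks", ("short_walk",)),
    ("long_walks", ("long_walk",)),
)


def cohort_table(subjects: list[SubjectSummary]) -> pd.DataFrame:
    """Cohort mean (SD) of time, counts and intensity per activity row.

    Time is min/day, counts kcounts/day, intensity counts/minute.  Cohort
    intensity is the mean of per-subject intensities (not a ratio of the
    cohort means); SDs use the sample (n-1) denominator.
    """
    if len(subjects) < 2:
        raise ParameterError("a cohort table needs at least two subjects")
    rows = {}
    for name, cats in _ROWS:
        t = np.array([sum(s.time_min[c] for c in cats) for s in subjects])
        k = np.array([sum(s.counts[c] for c in cats) for s in subjects]) / 1000.0
        inten = np.array([(1000.0 * ki / ti) if ti > 0 else np.nan
                          for ti, ki in zip(t, k)])
        rows[name] = {
            "time_min_mean": t.mean(), "time_min_sd": t.std(ddof=1),
            "kcounts_mean": k.mean(), "kcounts_sd": k.std(ddof=1),
            "intensity_mean": np.nanmean(inten),
            "intensity_sd": np.nanstd(inten, ddof=1),
        }
    return pd.DataFrame(rows).T


def daily_frame(days: list[DailySummary]) -> pd.DataFrame:
    """One row per day: wear, validity, and time/counts per category."""
    recs = []
    for d in days:
        rec = {"date": d.date, "wear_time_h": d.wear_time_h,
               "valid": d.valid, "missing": d.missing}
        for c in CATEGORIES:
            rec[f"{c}_time_min"] = d.time_min[c]
            rec[f"{c}_counts"] = d.counts[c]
        rec["walking_time_min"] = d.walking_time_min
        rec["walking_counts"] = d.walking_counts
        rec["activity_time_min"] = d.activity_time_min
        rec["activity_counts"] = d.activity_counts
        recs.append(rec)
    return pd.DataFrame(recs)
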