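"""End-to-end orchestration: calibration -> classification -> summaries.

``calibrate_subject`` turns a treadmill session into a personalized gait
template and a fitted walking-likelihood model; ``process_day`` labels the
epochs of one free-living recording; ``run_pipeline`` chains both over a
subject's days and produces daily and subject summaries plus a run
manifest.
"""
from __future__ import annotations

from dataclasses import dataclass
from datetime import timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .aggregation import (DailySummary, SubjectSummary, daily_frame,
                          summarize_day, summarize_subject)
from .classifier import LikelihoodModel, classify_epochs, fit_likelihoods
from .config import DEFAULT_CONFIG, PipelineConfig
from .errors import NoValidDaysError
from .signal_core import (TriaxialRecording, counts_from_samples,
                          epoch_sample_count, resample_recording)
from .template_features import (GaitTemplate, build_template,
                                extract_gait_cycles, features_from_vm)


def _epoch_matrixes(recording: TriaxialRecording, config: PipelineConfig):
    """(vm_epochs, counts, rates) for all full epochs of a recording."""
    if abs(recording.fs * config.epoch_s
           - round(recording.fs * config.epoch_s)) > 1e-9:
        recording = resample_recording(recording, config.fs)
    length = epoch_sample_count(recording.fs, config.epoch_s)
    data = recording.data
    m = data.shape[0] // length
    seg = data[:m * length].reshape(m, length, 3)
    vm = np.sqrt(np.sum(seg ** 2, axis=2))
    counts = counts_from_samples(data, recording.fs, length, config.detrend)
    return recording, vm, counts, counts / config.epoch_s


def calibrate_subject(calibration: TriaxialRecording,
                      cadence_hint: float | None = None,
                      source_speeds=(),
                      config: PipelineConfig | None = None
                      ) -> tuple[GaitTemplate, LikelihoodModel]:
    """Template + likelihood model from a treadmill walking session."""
    cfg = config or DEFAULT_CONFIG
    cycles = extract_gait_cycles(calibration, cadence_hint=cadence_hint)
    template = build_template(cycles, subject_id=calibration.subject_id,
                              fs=calibration.fs, source_speeds=source_speeds)
    _, vm, counts, rates = _epoch_matrixes(calibration, cfg)
    sd_s, sd_cc = features_from_vm(vm, template)
    model = fit_likelihoods(sd_s, sd_cc, config=cfg)
    return template, model


def process_day(recording: TriaxialRecording, template: GaitTemplate,
                model: LikelihoodModel,
                config: PipelineConfig | None = None) -> pd.DataFrame:
    """Per-epoch frame for one recording: features, counts, label, date."""
    cfg = config or DEFAULT_CONFIG
    recording, vm, counts, rates = _epoch_matrixes(recording, cfg)
    if vm.shape[0] == 0:
        return pd.DataFrame(columns=["epoch_index", "date", "sd_s", "sd_cc",
                                     "counts", "rate", "label"])
    sd_s, sd_cc = features_from_vm(vm, template)
    inactive = rates < cfg.inactivity_rate
    labels = classify_epochs(sd_s, sd_cc, inactive, model, cfg)
    if recording.start_time is not None:
        dates = [(recording.start_time
                  + timedelta(seconds=i * cfg.epoch_s)).date().isoformat()
                 for i in range(vm.shape[0])]
    else:
        dates = [""] * vm.shape[0]
    return pd.DataFrame({"epoch_index": np.arange(vm.shape[0]),
                         "date": dates, "sd_s": sd_s, "sd_cc": sd_cc,
                         "counts": counts, "rate": rates, "label": labels})


def summarize_epoch_frame(frame: pd.DataFrame,
                          wear_time_h: float | None = None,
                          config: PipelineConfig | None = None
                          ) -> list[DailySummary]:
    """Daily summaries from a per-epoch frame, split on calendar date."""
    cfg = config or DEFAULT_CONFIG
    if frame.empty:
        return []
    out = []
    for date, sub in frame.groupby("date", sort=True, dropna=False):
        out.append(summarize_day(sub["label"].to_numpy(dtype=object),
                                 sub["counts"].to_numpy(dtype=float),
                                 date=date if date != "" else None,
                                 wear_time_h=wear_time_h, config=cfg))
    return out


@dataclass
class PipelineResult:
    template: GaitTemplate
    model: LikelihoodModel
    epoch_frames: list
    days: list
    subject: SubjectSummary | None


def run_pipeline(calibration, day_recordings, subject_id: str | None = None,
                 cadence_hint: float | None = None,
                 config: PipelineConfig | None = None,
                 out_dir: str | Path | None = None,
                 seed=None) -> PipelineResult:
    """Full chain for one subject.

    ``calibration`` and the day recordings may be
    :class:`TriaxialRecording` objects or paths to recording CSVs.  When
    ``out_dir`` is given, the template, likelihood model, per-day and
    subject CSVs and a run manifest are written there.

    Raises :class:`NoValidDaysError` when every day fails the wear/missing
    rules (the subject is excluded).
    """
    cfg = config or DEFAULT_CONFIG
    input_paths = [p for p in [calibration, *day_recordings]
                   if isinstance(p, (str, Path))]
    if isinstance(calibration, (str, Path)):
        calibration = gio.read_recording(calibration)
    day_recs = [gio.read_recording(d) if isinstance(d, (str, Path)) else d
                for d in day_recordings]
    subject_id = subject_id or calibration.subject_id
    template, model = calibrate_subject(calibration, cadence_hint,
                                        config=cfg)
    frames, days = [], []
    for rec in day_recs:
        missing = any((b - a) > cfg.missing_gap_h * 3600.0
                      for a, b in rec.gaps)
        frame = process_day(rec, template, model, cfg)
        frames.append(frame)
        for day in summarize_epoch_frame(frame, config=cfg):
            day.missing = missing
            day.valid = day.valid and not missing
            days.append(day)
    try:
        subject = summarize_subject(days, subject_id)
    except NoValidDaysError:
        subject = None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        template.to_json(out / "template.json")
        model.to_json(out / "model.json")
        daily_frame(days).to_csv(out / "daily.csv", index=False)
        if subject is not None:
            subject_frame([subject]).to_csv(out / "subject.csv", index=False)
        gio.write_manifest(out / "manifest.json", cfg, input_paths, seed=seed,
                           extra={"subject_id": subject_id,
                                  "n_days": len(days),
                                  "excluded": subject is None})
    if subject is None:
        raise NoValidDaysError(f"subject {subject_id!r}: no valid days")
    return PipelineResult(template=template, model=model,
                          epoch_frames=frames, days=days, subject=subject)


def subject_frame(subjects: list[SubjectSummary]) -> pd.DataFrame:
    """One row per subject with times, counts and intensities per category."""
    recs = []
    for s in subjects:
        rec = {"subject_id": s.subject_id, "n_valid_days": s.n_valid_days,
               "activity_time_h": s.activity_time_h}
        for c in ("nonwalking", "short_walk", "long_walk"):
            rec[f"{c}_time_min"] = s.time_min[c]
            rec[f"{c}_counts"] = s.counts[c]
            rec[f"{c}_intensity"] = s.intensity[c]
        rec["walking_time_min"] = s.walking_time_min
        rec["walking_counts"] = s.walking_counts
        rec["activity_time_min"] = s.activity_time_min
        rec["activity_counts"] = s.activity_counts
        recs.append(rec)
    return pd.DataFrame(recs)
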