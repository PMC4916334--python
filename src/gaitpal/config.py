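"""Pipeline configuration.

Every fixed numeric constant of the walking-recognition pipeline lives here,
once, as a :class:`PipelineConfig` default, so that a single YAML file can
override any of them and a run manifest can snapshot them all.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ParameterError

_DENSITIES = ("kde", "lognormal")
_TIE_RULES = ("nonwalk", "walk")
_DETRENDS = ("mean", "linear")


@dataclass
class PipelineConfig:
    """All tunable constants of the walking-recognition pipeline.

    Attributes
    ----------
    fs : float
        Nominal sampling rate in Hz; recordings at other rates are linearly
        resampled to this before epoching.
    epoch_s : float
        Epoch duration in seconds.
    inactivity_rate : float
        Count rate (counts/s) strictly below which an epoch is inactivity and
        is excluded from all activity-time and counts aggregates.
    bout_threshold_s : float
        Walking bouts shorter than this are short walks; bouts at least this
        long are long walks.
    wear_min_h : float
        Minimum daily wear time in hours for a day to be valid.
    k_numerator, k_factor : float
        Constants of the likelihood scaling k = k_numerator /
        (k_factor * max joint calibration likelihood); the walk decision is
        equivalent to "joint likelihood > k_factor * max".
    density : str
        Family for the per-feature walking likelihoods: "kde" (Gaussian
        kernel, Silverman bandwidth) or "lognormal" (parametric fit).
    tie_rule : str
        Label assigned when the walk score equals 0.5 exactly.
    nonwear_run_min : float
        Runs of at least this many consecutive minutes of zero-count epochs
        are treated as non-wear when wear time is estimated from the signal.
    missing_gap_h : float
        A timestamp gap longer than this inside a day flags the day missing.
    stepwise_entry_p, stepwise_removal_p : float
        p-value thresholds for forward entry / backward removal in stepwise
        predictor selection.
    detrend : str
        Per-epoch detrending before rectification: "mean" removal (default)
        or "linear" trend removal.
    min_calibration_epochs : int
        Below this many treadmill epochs a calibration-quality warning is
        issued.
    """

    fs: float = 60.0
    epoch_s: float = 5.0
    inactivity_rate: float = 1e-3
    bout_threshold_s: float = 60.0
    wear_min_h: float = 10.0
    k_numerator: float = 0.5
    k_factor: float = 0.14
    density: str = "kde"
    tie_rule: str = "nonwalk"
    nonwear_run_min: float = 60.0
    missing_gap_h: float = 1.0
    stepwise_entry_p: float = 0.05
    stepwise_removal_p: float = 0.10
    detrend: str = "mean"
    min_calibration_epochs: int = 30

    def __post_init__(self) -> None:
        for name in ("fs", "epoch_s", "inactivity_rate", "bout_threshold_s",
                     "wear_min_h", "k_numerator", "k_factor",
                     "nonwear_run_min", "missing_gap_h",
                     "stepwise_entry_p", "stepwise_removal_p"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.density not in _DENSITIES:
            raise ParameterError(f"density must be one of {_DENSITIES}")
        if self.tie_rule not in _TIE_RULES:
            raise ParameterError(f"tie_rule must be one of {_TIE_RULES}")
        if self.detrend not in _DETRENDS:
            raise ParameterError(f"detrend must be one of {_DETRENDS}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


DEFAULT_CONFIG = PipelineConfig()
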