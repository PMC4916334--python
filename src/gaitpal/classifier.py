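"""Naive Bayes walking classifier over the SDs/SDcc features.

Two univariate likelihoods P(SDs | walk) and P(SDcc | walk) are fitted to
the treadmill calibration epochs and combined under naive conditional
independence into a walk score

    score = k * P(SDs | walk) * P(SDcc | walk),
    k     = 0.5 / (0.14 * max joint calibration likelihood).

The score is not a calibrated probability (it reaches 0.5/0.14 ~ 3.57 at
the best calibration epoch); the classifier only uses the algebraically
equivalent decision rule "joint likelihood > 0.14 * max", expressed as
score > 0.5.  A tie goes to non-walk by default.  Inactive epochs bypass
classification entirely.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .config import DEFAULT_CONFIG, PipelineConfig
from .errors import CalibrationQualityWarning, DegenerateCalibrationError, ParameterError
from .template_features import EpochFeatures

LABEL_WALK = "walk"
LABEL_NONWALK = "nonwalk"
LABEL_INACTIVE = "inactive"


@dataclass
class GridDensity:
    """A univariate density stored as samples on a uniform grid.

    Evaluation interpolates linearly between grid points and is zero
    outside the grid.  The grid representation (rather than the fitted
    object itself) *is* the model: it makes JSON round-trips bit-exact and
    scoring identical before and after serialization.
    """

    grid: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.grid.size != self.density.size or self.grid.size < 2:
            raise ParameterError("grid and density must match, length >= 2")

    def __call__(self, x):
        return np.interp(x, self.grid, self.density, left=0.0, right=0.0)

    @property
    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))

    @classmethod
    def from_samples(cls, data, kind: str = "kde", n_grid: int = 512,
                     pad_bw: float = 5.0) -> "GridDensity":
        """Fit a density to 1-D feature samples.

        kind="kde": Gaussian kernel density, Silverman bandwidth.
        kind="lognormal": parametric log-normal fit (location fixed at 0).
        """
        data = np.asarray(data, dtype=float)
        scale = abs(float(np.mean(data))) + 1.0
        if data.size < 2 or float(np.std(data)) <= 1e-12 * scale:
            raise DegenerateCalibrationError(
                "feature has (near-)zero variance over calibration epochs")
        if kind == "kde":
            try:
                kde = stats.gaussian_kde(data, bw_method="silverman")
            except np.linalg.LinAlgError as exc:
                raise DegenerateCalibrationError(
                    "singular calibration feature distribution") from exc
            bw = float(kde.factor) * float(np.std(data, ddof=1))
            lo = float(data.min()) - pad_bw * bw
            hi = float(data.max()) + pad_bw * bw
            grid = np.linspace(lo, hi, n_grid)
            dens = kde(grid)
        elif kind == "lognormal":
            if np.any(data <= 0):
                raise DegenerateCalibrationError(
                    "log-normal likelihood requires strictly positive features")
            shape, loc, scale = stats.lognorm.fit(data, floc=0)
            lo = float(data.min()) * 0.1
            hi = float(data.max()) * 3.0
            grid = np.linspace(lo, hi, n_grid)
            dens = stats.lognorm.pdf(grid, shape, loc, scale)
        else:
            raise ParameterError(f"unknown density family {kind!r}")
        return cls(grid=grid, density=dens)


@dataclass
class LikelihoodModel:
    """Fitted walking-likelihood model: two densities plus the scaling k."""

    dens_sds: GridDensity
    dens_sdcc: GridDensity
    k: float
    max_joint: float
    n_epochs: int
    k_numerator: float = 0.5
    k_factor: float = 0.14

    def joint(self, sd_s, sd_cc):
        return self.dens_sds(sd_s) * self.dens_sdcc(sd_cc)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({
            "dens_sds": {"grid": self.dens_sds.grid.tolist(),
                         "density": self.dens_sds.density.tolist()},
            "dens_sdcc": {"grid": self.dens_sdcc.grid.tolist(),
                          "density": self.dens_sdcc.density.tolist()},
            "k": self.k, "max_joint": self.max_joint,
            "n_epochs": self.n_epochs,
            "k_numerator": self.k_numerator, "k_factor": self.k_factor,
        })
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "LikelihoodModel":
        if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
            text = Path(source).read_text()
        else:
            text = str(source)
        d = json.loads(text)
        return cls(
            dens_sds=GridDensity(np.asarray(d["dens_sds"]["grid"]),
                                 np.asarray(d["dens_sds"]["density"])),
            dens_sdcc=GridDensity(np.asarray(d["dens_sdcc"]["grid"]),
                                  np.asarray(d["dens_sdcc"]["density"])),
            k=d["k"], max_joint=d["max_joint"], n_epochs=d["n_epochs"],
            k_numerator=d["k_numerator"], k_factor=d["k_factor"])


def _as_feature_arrays(features) -> tuple[np.ndarray, np.ndarray]:
    if len(features) and isinstance(features[0], EpochFeatures):
        sd_s = np.array([f.sd_s for f in features], dtype=float)
        sd_cc = np.array([f.sd_cc for f in features], dtype=float)
        return sd_s, sd_cc
    raise ParameterError("expected a list of EpochFeatures")


def fit_likelihoods(sd_s, sd_cc=None,
                    config: PipelineConfig | None = None) -> LikelihoodModel:
    """Fit the walking-likelihood model from treadmill walking epochs.

    Accepts either two feature arrays (sd_s, sd_cc) or a single list of
    :class:`EpochFeatures`.  max_joint is taken over the calibration epochs
    themselves, evaluated through the same grid densities used for scoring.
    """
    cfg = config or DEFAULT_CONFIG
    if sd_cc is None:
        sd_s, sd_cc = _as_feature_arrays(sd_s)
    sd_s = np.asarray(sd_s, dtype=float)
    sd_cc = np.asarray(sd_cc, dtype=float)
    if sd_s.shape != sd_cc.shape:
        raise ParameterError("sd_s and sd_cc must have equal length")
    n = sd_s.size
    if n < cfg.min_calibration_epochs:
        warnings.warn(f"only {n} calibration epochs "
                      f"(< {cfg.min_calibration_epochs}); likelihoods may be "
                      "unstable", CalibrationQualityWarning, stacklevel=2)
    d1 = GridDensity.from_samples(sd_s, kind=cfg.density)
    d2 = GridDensity.from_samples(sd_cc, kind=cfg.density)
    joint = d1(sd_s) * d2(sd_cc)
    max_joint = float(np.max(joint))
    if max_joint <= 0:
        raise DegenerateCalibrationError("joint calibration likelihood is zero")
    k = cfg.k_numerator / (cfg.k_factor * max_joint)
    return LikelihoodModel(dens_sds=d1, dens_sdcc=d2, k=k,
                           max_joint=max_joint, n_epochs=n,
                           k_numerator=cfg.k_numerator, k_factor=cfg.k_factor)


def score_epoch(features, model: LikelihoodModel, sd_cc=None):
    """Walk score k * P(SDs|walk) * P(SDcc|walk).

    Call as ``score_epoch(EpochFeatures, model)`` or
    ``score_epoch(sd_s_array, model, sd_cc_array)`` (vectorized).
    """
    if isinstance(features, EpochFeatures):
        sd_s, sd_cc = features.sd_s, features.sd_cc
    else:
        sd_s = features
        if sd_cc is None:
            raise ParameterError("vectorized call needs sd_cc")
    s = model.k * model.joint(sd_s, sd_cc)
    return float(s) if np.ndim(s) == 0 else s


def classify_scores(scores, tie_rule: str = "nonwalk"):
    """Map walk scores to labels; tie at 0.5 goes to the configured side."""
    scores = np.asarray(scores, dtype=float)
    walk = scores >= 0.5 if tie_rule == "walk" else scores > 0.5
    return np.where(walk, LABEL_WALK, LABEL_NONWALK)


def classify_epoch(features: EpochFeatures, model: LikelihoodModel,
                   config: PipelineConfig | None = None) -> str:
    """Label a single active epoch walk / nonwalk (inactive epochs bypass)."""
    cfg = config or DEFAULT_CONFIG
    if features.counts is not None and features.counts.inactive:
        return LABEL_INACTIVE
    s = score_epoch(features, model)
    return str(classify_scores([s], cfg.tie_rule)[0])


def classify_epochs(sd_s, sd_cc, inactive=None,
                    model: LikelihoodModel | None = None,
                    config: PipelineConfig | None = None) -> np.ndarray:
    """Vectorized labeling of a day of epochs.

    Inactive epochs receive the "inactive" label and are never scored as
    walk or nonwalk.
    """
    if model is None:
        raise ParameterError("a fitted LikelihoodModel is required")
    cfg = config or DEFAULT_CONFIG
    labels = classify_scores(score_epoch(np.asarray(sd_s, dtype=float), model,
                                         np.asarray(sd_cc, dtype=float)),
                             cfg.tie_rule)
    labels = labels.astype(object)
    if inactive is not None:
        labels[np.asarray(inactive, dtype=bool)] = LABEL_INACTIVE
    return labels.astype(str)
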