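"""Physical activity level (PAL) models.

PAL is total energy expenditure divided by basal metabolic rate (both in
the same unit, typically MJ/day); it is the dimensionless currency linking
accelerometer counts to free-living energy expenditure.  This module
computes PAL, evaluates the two reference prediction equations for healthy
older adults (a simple model on daily activity counts and a multiple model
on nonwalking + short-walk counts), and fits/selects ordinary
least-squares models of PAL from daily count categories, with the usual
diagnostics (r^2, standard error of the estimate, coefficient SDs,
standardized betas, residual correlations).  Count predictors enter in
counts/day, which puts the slopes on the 1e-5 scale of the reference
equations.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import CollinearityWarning, ParameterError

PAL_PLAUSIBLE = (1.1, 2.6)
CANDIDATE_PREDICTORS = ("nonwalking_counts", "short_walk_counts",
                        "long_walk_counts")


@dataclass
class EnergyRecord:
    """One subject's energy-expenditure numbers and the derived PAL."""

    subject_id: str
    tee: float  # MJ/day (or any unit shared with bmr)
    bmr: float
    pal: float = field(init=False)

    def __post_init__(self) -> None:
        self.pal = compute_pal(self.tee, self.bmr)


@dataclass
class PALModel:
    """A linear prediction equation for PAL from daily count categories."""

    name: str
    predictors: tuple
    intercept: float
    coefficients: tuple
    r2: float | None = None
    see: float | None = None          # residual SD, n - p - 1 denominator
    coef_sd: tuple | None = None
    betas: tuple | None = None        # standardized coefficients
    pvalues: tuple | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.predictors):
            raise ParameterError("one coefficient per predictor required")

    def predict(self, data=None, **kwargs):
        """Evaluate the equation on a DataFrame or keyword count values."""
        if data is None:
            data = pd.DataFrame({k: np.atleast_1d(v) for k, v in kwargs.items()})
            scalar = all(np.ndim(v) == 0 for v in kwargs.values())
        else:
            scalar = False
        out = np.full(len(data), self.intercept, dtype=float)
        for name, coef in zip(self.predictors, self.coefficients):
            out = out + coef * np.asarray(data[name], dtype=float)
        return float(out[0]) if scalar and out.size == 1 else out

    def to_json(self, path: str | Path | None = None) -> str:
        d = {"name": self.name, "predictors": list(self.predictors),
             "intercept": self.intercept,
             "coefficients": list(self.coefficients),
             "r2": self.r2, "see": self.see,
             "coef_sd": list(self.coef_sd) if self.coef_sd else None,
             "betas": list(self.betas) if self.betas else None,
             "pvalues": list(self.pvalues) if self.pvalues else None,
             "n": self.n}
        payload = json.dumps(d)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "PALModel":
        if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
            text = Path(source).read_text()
        else:
            text = str(source)
        d = json.loads(text)
        return cls(name=d["name"], predictors=tuple(d["predictors"]),
                   intercept=d["intercept"],
                   coefficients=tuple(d["coefficients"]),
                   r2=d.get("r2"), see=d.get("see"),
                   coef_sd=tuple(d["coef_sd"]) if d.get("coef_sd") else None,
                   betas=tuple(d["betas"]) if d.get("betas") else None,
                   pvalues=tuple(d["pvalues"]) if d.get("pvalues") else None,
                   n=d.get("n"))


# Reference prediction equations for healthy older adults (counts/day scale).
REFERENCE_SIMPLE_MODEL = PALModel(
    name="reference_simple",
    predictors=("activity_counts",),
    intercept=1.24, coefficients=(9.70e-5,),
    r2=0.53, see=0.13, coef_sd=(1.71e-5,), betas=(0.73,))

REFERENCE_MULTIPLE_MODEL = PALModel(
    name="reference_multiple",
    predictors=("nonwalking_counts", "short_walk_counts"),
    intercept=1.17, coefficients=(10.92e-5, 13.42e-5),
    r2=0.58, see=0.12, coef_sd=(1.99e-5, 3.64e-5), betas=(0.68, 0.46))


def compute_pal(tee: float, bmr: float) -> float:
    """PAL = TEE / BMR; warns when the result is outside the plausible band."""
    if tee <= 0 or bmr <= 0:
        raise ParameterError("TEE and BMR must be positive")
    pal = tee / bmr
    if not PAL_PLAUSIBLE[0] <= pal <= PAL_PLAUSIBLE[1]:
        warnings.warn(f"PAL {pal:.2f} outside plausible band {PAL_PLAUSIBLE}",
                      UserWarning, stacklevel=2)
    return pal


def predict_pal_simple(activity_counts,
                       model: PALModel = REFERENCE_SIMPLE_MODEL):
    """PAL from total daily activity counts via the simple reference model."""
    return model.predict(activity_counts=activity_counts)


def predict_pal_multiple(nonwalking_counts, short_walk_counts,
                         model: PALModel = REFERENCE_MULTIPLE_MODEL):
    """PAL from nonwalking + short-walk daily counts (multiple model)."""
    return model.predict(nonwalking_counts=nonwalking_counts,
                         short_walk_counts=short_walk_counts)


def fit_pal_model(data: pd.DataFrame, predictors, response: str = "pal",
                  name: str = "fitted") -> PALModel:
    """Ordinary least squares of PAL on the chosen count predictors.

    Reports r^2, the standard error of the estimate (residual SD with
    n - p - 1 denominator), coefficient SDs, standardized betas and
    two-sided coefficient p-values.  Warns on an ill-conditioned design.
    """
    predictors = tuple(predictors)
    n = len(data)
    if n <= len(predictors) + 1:
        raise ParameterError("need more subjects than predictors + 1")
    y = np.asarray(data[response], dtype=float)
    X = sm.add_constant(data[list(predictors)].astype(float), has_constant="add")
    res = sm.OLS(y, X).fit()
    if np.linalg.cond(np.asarray(X)) > 1e8:
        warnings.warn("design matrix is ill-conditioned (collinear predictors)",
                      CollinearityWarning, stacklevel=2)
    see = float(np.sqrt(res.ssr / res.df_resid))
    sy = float(np.std(y, ddof=1))
    betas = tuple(float(res.params[p]) * float(np.std(data[p], ddof=1)) / sy
                  for p in predictors)
    return PALModel(name=name, predictors=predictors,
                    intercept=float(res.params["const"]),
                    coefficients=tuple(float(res.params[p]) for p in predictors),
                    r2=float(res.rsquared), see=see,
                    coef_sd=tuple(float(res.bse[p]) for p in predictors),
                    betas=betas,
                    pvalues=tuple(float(res.pvalues[p]) for p in predictors),
                    n=n)


def _candidate_pvalue(data, response, current, candidate):
    model = fit_pal_model(data, current + (candidate,), response)
    return model.pvalues[-1]


def stepwise_select(data: pd.DataFrame,
                    candidates=CANDIDATE_PREDICTORS,
                    response: str = "pal",
                    entry_p: float = 0.05, removal_p: float = 0.10,
                    name: str = "stepwise") -> PALModel:
    """Forward-entry / backward-removal stepwise OLS predictor selection.

    At each step the candidate with the smallest p-value enters if it is
    below ``entry_p``; any included predictor whose p-value rises above
    ``removal_p`` is then dropped.  Returns the final fitted model (an
    intercept-only model, with a warning, if nothing enters).
    """
    candidates = list(candidates)
    selected: tuple = ()
    while True:
        remaining = [c for c in candidates if c not in selected]
        entered = False
        if remaining:
            pvals = {c: _candidate_pvalue(data, response, selected, c)
                     for c in remaining}
            best = min(pvals, key=pvals.get)
            if pvals[best] < entry_p:
                selected = selected + (best,)
                entered = True
        # backward pass
        removed = True
        while removed and selected:
            model = fit_pal_model(data, selected, response)
            worst = int(np.argmax(model.pvalues))
            if model.pvalues[worst] > removal_p:
                selected = tuple(p for i, p in enumerate(selected) if i != worst)
            else:
                removed = False
        if not entered:
            break
    if not selected:
        warnings.warn("no candidate met the entry criterion; "
                      "returning intercept-only model", UserWarning,
                      stacklevel=2)
        y = np.asarray(data[response], dtype=float)
        see = float(np.std(y, ddof=1))
        return PALModel(name=name, predictors=(), intercept=float(y.mean()),
                        coefficients=(), r2=0.0, see=see, n=len(data))
    model = fit_pal_model(data, selected, response, name=name)
    return model


def pearson(x, y) -> tuple[float, float]:
    """Pearson correlation with a two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ParameterError("need equal-length samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ParameterError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def residual_correlation(model: PALModel, data: pd.DataFrame, aux,
                         response: str = "pal") -> tuple[float, float]:
    """Correlation between the model's residuals and an auxiliary variable."""
    resid = np.asarray(data[response], dtype=float) - model.predict(data)
    aux = np.asarray(data[aux], dtype=float) if isinstance(aux, str) else np.asarray(aux, dtype=float)
    return pearson(resid, aux)
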