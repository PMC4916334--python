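"""PAL computation, the reference prediction equations and OLS machinery."""
import numpy as np
import pandas as pd
import pytest

import gaitpal as gp
from gaitpal.energy_models import (REFERENCE_MULTIPLE_MODEL,
                                   REFERENCE_SIMPLE_MODEL, compute_pal,
                                   fit_pal_model, pearson,
                                   predict_pal_multiple, predict_pal_simple,
                                   residual_correlation, stepwise_select)
from gaitpal.errors import ParameterError


def test_pal_is_tee_over_bmr():
    with pytest.warns(UserWarning):  # 1.0 sits below the plausible band
        assert compute_pal(6.0, 6.0) == 1.0
    assert compute_pal(12.0, 6.0) == pytest.approx(2.0)


def test_pal_rejects_nonpositive():
    with pytest.raises(ParameterError):
        compute_pal(0.0, 6.0)
    with pytest.raises(ParameterError):
        compute_pal(10.0, -1.0)


def test_pal_warns_outside_plausible_band():
    with pytest.warns(UserWarning):
        compute_pal(30.0, 6.0)


@pytest.mark.parametrize("counts,expected", [
    (0.0, 1.24),
    (6200.0, 1.8414),
    (10000.0, 2.21),
])
def test_simple_equation_values(counts, expected):
    assert predict_pal_simple(counts) == pytest.approx(expected, abs=1e-4)


@pytest.mark.parametrize("nonwalk,short,expected", [
    (0.0, 0.0, 1.17),
    (3500.0, 2100.0, 1.83402),
    (7000.0, 0.0, 1.9344),
])
def test_multiple_equation_values(nonwalk, short, expected):
    assert predict_pal_multiple(nonwalk, short) == pytest.approx(expected,
                                                                 abs=1e-4)


def test_prediction_linearity(rng):
    x = rng.uniform(2000, 10000, 50)
    assert predict_pal_simple(x.mean()) == pytest.approx(
        np.mean([predict_pal_simple(v) for v in x]))


def test_fit_recovers_exact_linear_data(rng):
    x = rng.uniform(2000, 10000, 30)
    df = pd.DataFrame({"activity_counts": x, "pal": 1.3 + 8e-5 * x})
    m = fit_pal_model(df, ["activity_counts"])
    assert m.r2 == pytest.approx(1.0)
    assert m.see == pytest.approx(0.0, abs=1e-10)
    assert m.coefficients[0] == pytest.approx(8e-5)
    assert m.intercept == pytest.approx(1.3)


def test_fit_invariant_to_subject_order(rng):
    x = rng.uniform(2000, 10000, 30)
    df = pd.DataFrame({"activity_counts": x,
                       "pal": 1.3 + 8e-5 * x + rng.normal(0, 0.1, 30)})
    a = fit_pal_model(df, ["activity_counts"])
    b = fit_pal_model(df.sample(frac=1.0, random_state=1), ["activity_counts"])
    assert a.coefficients[0] == pytest.approx(b.coefficients[0])
    assert a.r2 == pytest.approx(b.r2)


def test_residuals_sum_to_zero_and_predict_reproduces_fit(rng):
    x = rng.uniform(2000, 10000, 40)
    df = pd.DataFrame({"activity_counts": x,
                       "pal": 1.3 + 8e-5 * x + rng.normal(0, 0.1, 40)})
    m = fit_pal_model(df, ["activity_counts"])
    resid = df["pal"] - m.predict(df)
    assert float(resid.sum()) == pytest.approx(0.0, abs=1e-9)


@pytest.mark.parametrize("y_sign", [1.0, -1.0])
def test_pearson_perfect_correlation(y_sign, rng):
    x = rng.normal(0, 1, 30)
    r, p = pearson(x, y_sign * x)
    assert r == pytest.approx(y_sign)
    assert p < 1e-10


def test_pearson_null_distribution(rng):
    hits = 0
    for _ in range(100):
        r, _ = pearson(rng.normal(0, 1, 42), rng.normal(0, 1, 42))
        hits += abs(r) < 0.4
    assert hits >= 95


def test_pearson_zero_variance_signalled():
    with pytest.raises(ParameterError):
        pearson(np.ones(10), np.arange(10.0))


def test_residuals_orthogonal_to_predictors(rng):
    x = rng.uniform(2000, 10000, 40)
    df = pd.DataFrame({"activity_counts": x,
                       "pal": 1.3 + 8e-5 * x + rng.normal(0, 0.1, 40)})
    m = fit_pal_model(df, ["activity_counts"])
    r, _ = residual_correlation(m, df, "activity_counts")
    assert r == pytest.approx(0.0, abs=1e-8)
    resid = df["pal"] - m.predict(df)
    r2, _ = residual_correlation(m, df, resid)
    assert r2 == pytest.approx(1.0)


def test_omitted_variable_shows_in_residuals(rng):
    n = 40
    x = rng.uniform(2000, 10000, n)
    frac = rng.uniform(0.5, 1.0, n)
    df = pd.DataFrame({
        "activity_counts": x,
        "short_walk_time_fraction": frac,
        "pal": 1.2 + 8e-5 * x - 0.4 * frac + rng.normal(0, 0.02, n)})
    m = fit_pal_model(df, ["activity_counts"])
    r, p = residual_correlation(m, df, "short_walk_time_fraction")
    assert r < -0.5 and p < 0.01


def test_stepwise_single_strong_candidate(rng):
    x = rng.uniform(2000, 6000, 31)
    df = pd.DataFrame({"nonwalking_counts": x,
                       "short_walk_counts": rng.uniform(500, 3000, 31),
                       "long_walk_counts": rng.uniform(100, 1000, 31),
                       "pal": 1.2 + 1.2e-4 * x + rng.normal(0, 0.03, 31)})
    m = stepwise_select(df)
    assert "nonwalking_counts" in m.predictors


def test_stepwise_all_noise_gives_intercept_only(rng):
    df = pd.DataFrame({"nonwalking_counts": rng.normal(3500, 1000, 31),
                       "short_walk_counts": rng.normal(2100, 700, 31),
                       "long_walk_counts": rng.normal(600, 400, 31),
                       "pal": rng.normal(1.84, 0.19, 31)})
    with pytest.warns(UserWarning):
        m = stepwise_select(df)
    assert m.predictors == ()
    assert m.intercept == pytest.approx(df["pal"].mean())


def test_reference_models_roundtrip(tmp_path):
    path = tmp_path / "m.json"
    REFERENCE_MULTIPLE_MODEL.to_json(path)
    back = gp.PALModel.from_json(path)
    assert back.coefficients == REFERENCE_MULTIPLE_MODEL.coefficients
    assert back.predictors == REFERENCE_MULTIPLE_MODEL.predictors


def test_energy_record_derives_pal():
    rec = gp.EnergyRecord("s1", tee=12.0, bmr=6.5)
    assert rec.pal == pytest.approx(12.0 / 6.5)
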