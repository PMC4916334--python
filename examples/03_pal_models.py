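"""Physical activity level (PAL): reference equations and model fitting.

PAL = TEE / BMR.  This script evaluates the two reference prediction
equations at cohort-mean counts, then fits and stepwise-selects PAL
regressions on a synthetic cohort whose ground truth is known.
"""
import warnings

import gaitpal as gp

# PAL from measured energy expenditure
rec = gp.EnergyRecord("S001", tee=11.9, bmr=6.5)
print(f"TEE 11.9 / BMR 6.5 MJ/day -> PAL {rec.pal:.2f}")

# reference equations at the reference cohort means
simple = gp.predict_pal_simple(6200.0)
multiple = gp.predict_pal_multiple(3500.0, 2100.0)
print(f"simple model   @ 6.2 kcounts/day          -> PAL {simple:.4f}")
print(f"multiple model @ 3.5 nonwalk + 2.1 short  -> PAL {multiple:.4f}")
print("both land on the cohort-mean PAL of 1.84 within 0.01\n")

# fit on a synthetic cohort generated from the multiple model (noise 0.12);
# long-walk counts carry no signal, so stepwise usually drops them (a ~5%
# false-inclusion rate is inherent to the p<0.05 entry rule)
spec = gp.CohortSpec(pal_model=gp.REFERENCE_MULTIPLE_MODEL, pal_noise_sd=0.12)
df = gp.simulate_cohort(spec, seed=2)

fit = gp.fit_pal_model(df, ["activity_counts"])
print(f"simple refit:   r2={fit.r2:.2f}, SEE={fit.see:.3f} PAL, "
      f"slope={fit.coefficients[0]:.2e} per count/day")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    step = gp.stepwise_select(df)
print(f"stepwise keeps: {list(step.predictors)} "
      f"(r2={step.r2:.2f}, SEE={step.see:.3f})")

r, p = gp.residual_correlation(fit, df, "short_walk_time_fraction")
print(f"simple-model residuals vs short-walk time fraction: "
      f"r={r:.2f} (p={p:.3f})")
print("a nonzero r means the short-walk share explains PAL variance the "
      "total-counts model misses")
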