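"""The two standard baseline estimators on a fixed-drift dataset.

The method of moments matches the outcome ratio and the conditional RT
moments (mean, variance, skewness per boundary); the method of trial means
matches each trial's raw RT to its model-implied conditional expectation.
Both are given the true drift, the regime in which they work best.
"""

from ocddm import (
    NativeParams,
    SimConfig,
    fit_method_of_moments,
    fit_trial_means,
    simulate_dataset,
)

truth = NativeParams(v=0.5, x0=1.0, b=10.0, sigma=4.0, t_nd=0.3)
ds = simulate_dataset(truth, cfg=SimConfig(seed=9, n_trials=2000))

mom = fit_method_of_moments(ds, regime="fixed_drift", drift_value=0.5, seed=0)
motm = fit_trial_means(ds, regime="fixed_drift", drift_value=0.5, seed=0)

print(f"{'':12}{'truth':>8}{'MoM':>10}{'MoTM':>10}")
for name in ("sigma", "b", "x0", "t_nd"):
    print(f"{name:12}{getattr(truth, name):8.2f}"
          f"{getattr(mom.native_point, name):10.2f}"
          f"{getattr(motm.native_point, name):10.2f}")
print("\nBoth estimators match the vanilla first-passage predictions of the "
      "model to the data; with a known fixed drift the scale parameters "
      "(sigma, b) and the non-decision time come out close, while the "
      "initial bias is the least constrained by moment-level information.")
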