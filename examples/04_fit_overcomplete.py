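"""Fit the overcomplete self-consistency model to a varying-drift dataset.

A per-trial drift predictor (e.g. the value difference between options) is
known to the analyst; the fit recovers the remaining parameters — diffusion
SD, bound, initial bias, non-decision time — and, as a by-product, a
per-trial estimate of the latent accumulation noise.
"""

import numpy as np

from ocddm import NativeParams, SimConfig, fit_overcomplete, simulate_dataset

truth = NativeParams(v=0.0, x0=1.0, b=10.0, sigma=4.0, t_nd=0.3)
rng = np.random.default_rng(7)
drifts = 0.5 * rng.standard_normal(200)  # the known per-trial predictor

ds = simulate_dataset(truth, cfg=SimConfig(seed=8, n_trials=200),
                      drift_sequence=drifts)
fit = fit_overcomplete(ds, regime="varying_drift")

est = fit.native_point
print(f"converged: {fit.converged} "
      f"(free energy {fit.free_energy_trace[-1]:.1f})")
print(f"{'':12}{'truth':>8}{'estimate':>10}")
for name, t in (("sigma", truth.sigma), ("b", truth.b),
                ("x0", truth.x0), ("t_nd", truth.t_nd)):
    print(f"{name:12}{t:8.2f}{getattr(est, name):10.2f}")

ok = ~ds.censored
r = np.corrcoef(fit.eta_tilde_est, ds.eta_tilde_true[ok])[0, 1]
print("\nSingle-dataset point estimates carry the model's well-known "
      "scale uncertainty (sigma, b and x0 move together); the recovery "
      "study in example 06 shows the statistical performance across many "
      "datasets.")
print(f"per-trial noise estimates vs simulated truth: r = {r:.2f}")
print("(these latent-noise estimates are the unique by-product of the "
      "overcomplete approach — usable as trial-wise regressors for "
      "concurrent neural data)")
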