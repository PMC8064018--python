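"""Synthetic value-based choice demo: a default-option bias, seen and unseen.

Subjects choose between two valued items; one option belongs to a
prior-favored "default" category.  The generator plants an initial-bias
advantage for the default option.  Encoding the same trials in the
default/alternative frame reveals the bias (both behaviorally and in the
fitted initial condition); encoding them as right-vs-left hides it.
"""

import numpy as np

from ocddm import ValueExperimentConfig, fit_value_experiment, generate_value_experiment
from ocddm.value_experiment import choice_and_rt_bias

data = generate_value_experiment(ValueExperimentConfig(n_subjects=8, seed=5))

biases = [choice_and_rt_bias(e["default_frame"]) for e in data["subjects"]]
print(f"mean choice bias toward the default (near-equal values): "
      f"{np.mean([b['choice_bias'] for b in biases]):+.3f}")
print(f"mean RT advantage for default choices: "
      f"{np.nanmean([b['rt_bias'] for b in biases]):+.3f} time units")

table = fit_value_experiment(data)
print("\nfitted initial bias per subject (x0):")
print(f"{'subject':>8}{'truth':>9}{'default frame':>15}{'native frame':>14}")
for _, row in table.iterrows():
    print(f"{int(row['subject']):8d}{row['x0_true']:9.2f}"
          f"{row['x0_def']:15.2f}{row['x0_nat']:14.2f}")
print("\nThe default/alternative frame recovers the planted bias; in the "
      "native (right/left) frame it averages out to ~0.")
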