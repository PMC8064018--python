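"""Synthetic stand-in for a value-based choice experiment.

Emulates a design in which participants choose between two items whose
likeability was rated beforehand, with trials blocked so that one option
category is the prior-favored "default".  Each subject's trials are
simulated from a DDM whose per-trial drift is the decision value (the
likeability difference) and whose initial bias is shifted toward the
default option.  The same trials are emitted in two frames: the
default/alternative frame (outcome +1 = default chosen; the bias is visible
here) and the native right/left frame (the default lands on a random side
each trial, so the bias averages out).

This generator exists so the demo analysis runs with no external data; it
emulates the qualitative structure of such experiments (a choice bias and
an RT advantage for default choices at equal values), not any particular
dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .overcomplete import fit_overcomplete
from .params import NativeParams, vanilla_spec
from .simulate import Dataset, SimConfig, simulate_dataset

__all__ = [
    "ValueExperimentConfig",
    "generate_value_experiment",
    "frame_relabel",
    "fit_value_experiment",
]


@dataclass
class ValueExperimentConfig:
    n_subjects: int = 24
    n_trials: int = 200
    # likeability ratings are i.i.d. normal per item; the sd is chosen so
    # the median |decision value| sits near the reference drift magnitude
    # 0.5 (keeping error rates near the ~30% reference regime).
    likeability_sd: float = 0.52
    # initial bias toward the default option, as a fraction of the bound
    bias_effect: float = 0.1
    bias_subject_sd: float = 0.04
    b: float = 10.0
    sigma: float = 4.0
    t_nd: float = 0.3
    subject_log_jitter: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0 or self.n_trials <= 0:
            raise ValueError("sizes must be positive")
        if not np.isfinite(self.bias_effect):
            raise ValueError("bias_effect must be finite")


def frame_relabel(dataset: Dataset, flip: np.ndarray) -> Dataset:
    """Re-encode a dataset's outcomes/drifts in the opposite frame for
    trials where ``flip`` is -1.  Applying the same flip twice returns the
    original dataset exactly (involution)."""
    flip = np.asarray(flip)
    if flip.shape != dataset.rt.shape:
        raise ValueError("flip mask must have one entry per trial")
    return Dataset(
        rt=dataset.rt.copy(),
        outcome=(dataset.outcome * flip).astype(int),
        drift=dataset.drift * flip,
        censored=dataset.censored.copy(),
        hit_time=None if dataset.hit_time is None else dataset.hit_time.copy(),
        eta_tilde_true=(
            None if dataset.eta_tilde_true is None else dataset.eta_tilde_true.copy()
        ),
        provenance=dict(dataset.provenance),
    )


def generate_value_experiment(config: ValueExperimentConfig) -> dict:
    """Per-subject datasets in both frames, plus a subjects manifest.

    Returns ``{"subjects": [...], "manifest": DataFrame}`` where each
    subject entry holds the default/alternative-frame and native-frame
    datasets and the generating truth.
    """
    root = np.random.SeedSequence(config.seed)
    subjects = []
    manifest_rows = []
    for s, ss in enumerate(root.spawn(config.n_subjects)):
        rng = np.random.default_rng(ss)
        b = config.b * math.exp(config.subject_log_jitter * rng.standard_normal())
        sig = config.sigma * math.exp(config.subject_log_jitter * rng.standard_normal())
        t_nd = config.t_nd * math.exp(0.1 * rng.standard_normal())
        x0_frac = config.bias_effect + config.bias_subject_sd * rng.standard_normal()
        x0_frac = float(np.clip(x0_frac, -0.9, 0.9))
        x0 = x0_frac * b
        params = NativeParams(v=0.0, x0=x0, b=b, sigma=sig, t_nd=t_nd)

        values = rng.normal(0.0, config.likeability_sd, size=(config.n_trials, 2))
        decision_value = values[:, 0] - values[:, 1]  # V_def - V_alt
        side = rng.choice([-1, 1], size=config.n_trials)  # default's native side
        sim_seed = int(ss.generate_state(1)[0] % (2**31 - 1))
        ds_def = simulate_dataset(
            params, vanilla_spec(),
            SimConfig(seed=sim_seed, n_trials=config.n_trials),
            drift_sequence=decision_value,
        )
        ds_native = frame_relabel(ds_def, side)
        subjects.append(
            {
                "subject": s,
                "default_frame": ds_def,
                "native_frame": ds_native,
                "side": side,
                "truth": {"x0": x0, "b": b, "sigma": sig, "t_nd": t_nd},
            }
        )
        manifest_rows.append(
            {"subject": s, "x0_true": x0, "b_true": b, "sigma_true": sig,
             "t_nd_true": t_nd, "sim_seed": sim_seed}
        )
    return {"subjects": subjects, "manifest": pd.DataFrame(manifest_rows)}


def choice_and_rt_bias(dataset: Dataset, value_window: float = 0.25) -> dict:
    """Empirical default-choice bias and RT bias near null decision value.

    Choice bias: P(default chosen) - 0.5 among trials with |decision value|
    below ``value_window``.  RT bias: mean RT of alternative choices minus
    default choices in the same window (positive = default choices faster).
    """
    ds = dataset.uncensored()
    near = np.abs(ds.drift) <= value_window
    if near.sum() < 5:
        near = np.abs(ds.drift) <= np.quantile(np.abs(ds.drift), 0.3)
    chosen_default = ds.outcome[near] == 1
    choice_bias = float(np.mean(chosen_default)) - 0.5
    rt_def = ds.rt[near][chosen_default]
    rt_alt = ds.rt[near][~chosen_default]
    rt_bias = (
        float(np.mean(rt_alt) - np.mean(rt_def))
        if len(rt_def) > 1 and len(rt_alt) > 1
        else float("nan")
    )
    return {"choice_bias": choice_bias, "rt_bias": rt_bias}


def fit_value_experiment(data: dict, frames: tuple[str, ...] = ("default_frame", "native_frame")) -> pd.DataFrame:
    """Fit the overcomplete model per subject in each frame (drift set to
    the decision value) and tabulate the native parameter estimates."""
    rows = []
    for entry in data["subjects"]:
        row = {"subject": entry["subject"], "x0_true": entry["truth"]["x0"],
               "sigma_true": entry["truth"]["sigma"], "b_true": entry["truth"]["b"],
               "t_nd_true": entry["truth"]["t_nd"]}
        for frame in frames:
            fit = fit_overcomplete(entry[frame], regime="varying_drift")
            nat = fit.native_point
            tag = "def" if frame.startswith("default") else "nat"
            row[f"x0_{tag}"] = nat.x0
            row[f"sigma_{tag}"] = nat.sigma
            row[f"b_{tag}"] = nat.b
            row[f"t_nd_{tag}"] = nat.t_nd
        rows.append(row)
    return pd.DataFrame(rows)
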