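"""Forward simulation of vanilla and generalized DDM trials.

Trials are generated by Euler–Maruyama discretization of the diffusion
``dx = v dt + sigma dW``: per step, ``x_{k+1} = x_k + v*dt + sigma*sqrt(dt)*eta_k``
with ``eta_k ~ N(0,1)``.  A decision is triggered at the first step where the
transformed accumulator ``|z(x)|`` reaches the (possibly time-varying) bound;
the signed bound hit gives the outcome, and the observed response time is the
hitting time plus the non-decision time.  The simulator records full ground
truth per trial — hitting time, and the normalized cumulative perturbation
``eta_tilde = sum(eta_k) / sqrt(n_steps)`` — which downstream modules treat
as latent.

Each trial draws from its own counter-based RNG stream derived from
``(seed, trial index)``, so datasets are bit-reproducible regardless of
execution order.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .params import GeneralizedSpec, NativeParams, vanilla_spec

__all__ = [
    "SimConfig",
    "TrialRecord",
    "Dataset",
    "default_dt",
    "fine_dt",
    "default_horizon",
    "simulate_trial",
    "simulate_dataset",
    "moment_signature",
]

_CHUNK = 512


def default_dt(params: NativeParams, spec: Optional[GeneralizedSpec] = None) -> float:
    """Time step such that one diffusion step is small relative to the bound.

    Chosen so that ``sigma*sqrt(dt) <= 0.05 * b(0)``, which controls the
    bound-overshoot bias of the Euler scheme.
    """
    spec = spec or vanilla_spec()
    b0 = float(spec.bound(params, 0.0))
    return (0.05 * b0 / params.sigma) ** 2


def fine_dt(params: NativeParams, spec: Optional[GeneralizedSpec] = None) -> float:
    """Time step for self-consistency demonstrations.

    The residual of the self-consistency equation at the generating
    parameters is the bound overshoot converted to time, of order
    ``sigma*sqrt(dt)/|v|`` per trial; this step keeps the overshoot small
    relative to the *time* scale (``sigma*sqrt(dt) <= 1e-3 * b(0)``), which
    is far stricter than the state-resolution default used for general
    simulation.
    """
    spec = spec or vanilla_spec()
    b0 = float(spec.bound(params, 0.0))
    return (1e-3 * b0 / params.sigma) ** 2


def default_horizon(params: NativeParams, spec: Optional[GeneralizedSpec] = None) -> float:
    """Simulation horizon covering the bulk of the first-passage distribution.

    Ten times the slower of the drift-dominated time scale ``b/|v|`` and the
    diffusion-dominated scale ``(b+|x0|)^2/sigma^2``; for a collapsing bound
    the horizon is additionally capped once the bound has decayed to a
    negligible height (absorption is then certain).
    """
    spec = spec or vanilla_spec()
    b0 = float(spec.bound(params, 0.0))
    span = b0 + abs(params.x0)
    v_eff = max(abs(params.v), params.sigma**2 / span)
    horizon = 10.0 * span / v_eff
    om1 = getattr(spec, "omega1", None)
    if om1 is not None and om1 > 0:
        om0 = spec.omega0 if spec.omega0 is not None else np.log(params.b)
        horizon = min(horizon, (om0 + 12.0) / om1 + 1.0)
    return horizon


@dataclass
class SimConfig:
    """Simulation settings; ``dt``/``max_steps`` default per-parameter."""

    dt: Optional[float] = None
    max_steps: Optional[int] = None
    seed: int = 0
    n_trials: int = 200

    def resolve(self, params: NativeParams, spec: GeneralizedSpec) -> tuple[float, int]:
        dt = self.dt if self.dt is not None else default_dt(params, spec)
        if dt <= 0:
            raise ValueError(f"dt must be positive, got {dt}")
        if self.max_steps is not None:
            max_steps = int(self.max_steps)
        else:
            max_steps = int(np.ceil(default_horizon(params, spec) / dt))
        return dt, max(max_steps, 1)


@dataclass
class TrialRecord:
    """One simulated trial, with latent ground truth."""

    rt: float
    outcome: int
    hit_time: float
    eta_tilde_true: float
    drift_used: float
    censored: bool = False


@dataclass
class Dataset:
    """Trial-by-trial choice/RT data, stored columnar, with provenance."""

    rt: np.ndarray
    outcome: np.ndarray
    drift: np.ndarray
    censored: np.ndarray
    hit_time: Optional[np.ndarray] = None
    eta_tilde_true: Optional[np.ndarray] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.rt) == 0:
            raise ValueError("Dataset must be nonempty")

    def __len__(self) -> int:
        return len(self.rt)

    @property
    def n_trials(self) -> int:
        return len(self.rt)

    def uncensored(self) -> "Dataset":
        """Drop censored (non-absorbed) trials, warning if any are present."""
        mask = ~self.censored
        if mask.all():
            return self
        warnings.warn(
            f"excluding {int((~mask).sum())} censored trial(s) from analysis",
            stacklevel=2,
        )
        return Dataset(
            rt=self.rt[mask],
            outcome=self.outcome[mask],
            drift=self.drift[mask],
            censored=self.censored[mask],
            hit_time=None if self.hit_time is None else self.hit_time[mask],
            eta_tilde_true=(
                None if self.eta_tilde_true is None else self.eta_tilde_true[mask]
            ),
            provenance=self.provenance,
        )

    def correct_labels(self) -> np.ndarray:
        """Per-trial correctness: outcome matches sign of the trial's drift.

        Tie-break for exactly zero drift: the trial counts as correct when
        the outcome is +1 (documented arbitrary convention).
        """
        sign = np.where(self.drift > 0, 1, np.where(self.drift < 0, -1, 1))
        return self.outcome == sign

    @property
    def min_rt(self) -> float:
        return float(np.min(self.rt[~self.censored]))

    def records(self) -> list[TrialRecord]:
        out = []
        for i in range(len(self)):
            out.append(
                TrialRecord(
                    rt=float(self.rt[i]),
                    outcome=int(self.outcome[i]),
                    hit_time=float(self.hit_time[i]) if self.hit_time is not None else np.nan,
                    eta_tilde_true=(
                        float(self.eta_tilde_true[i])
                        if self.eta_tilde_true is not None
                        else np.nan
                    ),
                    drift_used=float(self.drift[i]),
                    censored=bool(self.censored[i]),
                )
            )
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(len(self)),
                "rt": self.rt,
                "outcome": self.outcome,
                "drift": self.drift,
                "censored": self.censored.astype(int),
            }
        )

    def to_csv(self, path: str, ground_truth: bool = True) -> None:
        """Write observed columns to ``path``; ground truth to a sidecar."""
        self.to_frame().to_csv(path, index=False)
        if ground_truth and self.hit_time is not None:
            truth = pd.DataFrame(
                {
                    "trial": np.arange(len(self)),
                    "hit_time": self.hit_time,
                    "eta_tilde_true": self.eta_tilde_true,
                }
            )
            truth.to_csv(_truth_path(path), index=False)
        if self.provenance:
            with open(_provenance_path(path), "w") as fh:
                json.dump(self.provenance, fh, indent=1, default=float)

    @classmethod
    def from_csv(cls, path: str) -> "Dataset":
        df = pd.read_csv(path)
        for col in ("rt", "outcome"):
            if col not in df.columns:
                raise ValueError(f"dataset CSV missing required column '{col}'")
        bad = np.flatnonzero(~(df["rt"].to_numpy(dtype=float) > 0))
        if bad.size:
            raise ValueError(f"non-positive rt at row(s) {bad.tolist()}")
        out_vals = df["outcome"].to_numpy(dtype=int)
        if not np.isin(out_vals, (-1, 1)).all():
            raise ValueError("outcome column must contain only -1/+1")
        drift = (
            df["drift"].to_numpy(dtype=float)
            if "drift" in df.columns
            else np.zeros(len(df))
        )
        cens = (
            df["censored"].to_numpy(dtype=bool)
            if "censored" in df.columns
            else np.zeros(len(df), dtype=bool)
        )
        ds = cls(
            rt=df["rt"].to_numpy(dtype=float),
            outcome=out_vals,
            drift=drift,
            censored=cens,
        )
        try:
            truth = pd.read_csv(_truth_path(path))
            ds.hit_time = truth["hit_time"].to_numpy(dtype=float)
            ds.eta_tilde_true = truth["eta_tilde_true"].to_numpy(dtype=float)
        except (OSError, KeyError):
            pass
        return ds


def _truth_path(path: str) -> str:
    return path.rsplit(".csv", 1)[0] + ".truth.csv"


def _provenance_path(path: str) -> str:
    return path.rsplit(".csv", 1)[0] + ".provenance.json"


def simulate_trial(
    params: NativeParams,
    spec: GeneralizedSpec,
    cfg: SimConfig,
    rng: np.random.Generator,
    drift: Optional[float] = None,
) -> TrialRecord:
    """Simulate one trial; censoring (no bound hit in the horizon) is flagged,
    not raised."""
    dt, max_steps = cfg.resolve(params, spec)
    v = params.v if drift is None else float(drift)
    sqdt = np.sqrt(dt)
    sig_step = params.sigma * sqdt

    # Degenerate start: already at/over the bound.
    z0 = float(spec.z(np.asarray(params.x0, dtype=float)))
    b0 = float(spec.bound(params, 0.0))
    if abs(z0) >= b0:
        outcome = 1 if z0 >= 0 else -1
        return TrialRecord(
            rt=params.t_nd, outcome=outcome, hit_time=0.0,
            eta_tilde_true=0.0, drift_used=v, censored=False,
        )

    x_base = params.x0
    eta_sum = 0.0
    step0 = 0
    chunk = _CHUNK
    while step0 < max_steps:
        k = min(chunk, max_steps - step0)
        chunk = min(chunk * 2, 1 << 16)  # grow for long paths
        eta = rng.standard_normal(k)
        cs = np.cumsum(eta)
        steps = step0 + np.arange(1, k + 1)
        xs = x_base + v * dt * (steps - step0) + sig_step * cs
        ts = steps * dt
        zx = spec.z(xs)
        bb = spec.bound(params, ts)
        hit = np.abs(zx) >= bb
        if hit.any():
            j = int(np.argmax(hit))
            n_steps = step0 + j + 1
            tau = n_steps * dt
            outcome = 1 if zx[j] >= 0 else -1
            eta_tilde = (eta_sum + cs[j]) / np.sqrt(n_steps)
            return TrialRecord(
                rt=tau + params.t_nd,
                outcome=outcome,
                hit_time=tau,
                eta_tilde_true=float(eta_tilde),
                drift_used=v,
                censored=False,
            )
        x_base = float(xs[-1])
        eta_sum += float(cs[-1])
        step0 += k

    return TrialRecord(
        rt=np.nan, outcome=0, hit_time=np.nan,
        eta_tilde_true=(eta_sum / np.sqrt(max_steps) if max_steps else 0.0),
        drift_used=v, censored=True,
    )


def simulate_dataset(
    params: NativeParams,
    spec: Optional[GeneralizedSpec] = None,
    cfg: Optional[SimConfig] = None,
    drift_sequence: Optional[Sequence[float]] = None,
) -> Dataset:
    """Simulate ``cfg.n_trials`` independent trials, optionally with
    per-trial drift rates overriding ``params.v``."""
    spec = spec or vanilla_spec()
    cfg = cfg or SimConfig()
    n = cfg.n_trials
    if drift_sequence is not None and len(drift_sequence) != n:
        raise ValueError(
            f"drift_sequence length {len(drift_sequence)} != n_trials {n}"
        )
    streams = np.random.SeedSequence(cfg.seed).spawn(n)
    rt = np.empty(n)
    outcome = np.empty(n, dtype=int)
    hit = np.empty(n)
    eta = np.empty(n)
    drift = np.empty(n)
    cens = np.zeros(n, dtype=bool)
    for i in range(n):
        rng = np.random.Generator(np.random.Philox(streams[i]))
        d = None if drift_sequence is None else float(drift_sequence[i])
        rec = simulate_trial(params, spec, cfg, rng, drift=d)
        rt[i] = rec.rt
        outcome[i] = rec.outcome
        hit[i] = rec.hit_time
        eta[i] = rec.eta_tilde_true
        drift[i] = rec.drift_used
        cens[i] = rec.censored
    dt, max_steps = cfg.resolve(params, spec)
    prov = {
        "params": vars(params).copy(),
        "variant": spec.variant,
        "omega0": spec.omega0,
        "omega1": spec.omega1,
        "dt": dt,
        "max_steps": max_steps,
        "seed": cfg.seed,
        "n_trials": n,
    }
    return Dataset(
        rt=rt, outcome=outcome, drift=drift, censored=cens,
        hit_time=hit, eta_tilde_true=eta, provenance=prov,
    )


def _moments(t: np.ndarray) -> tuple[float, float, float]:
    m = float(np.mean(t))
    v = float(np.var(t))
    if v > 0 and len(t) > 2:
        sk = float(np.mean((t - m) ** 3) / v**1.5)
        n = len(t)
        sk *= np.sqrt(n * (n - 1)) / (n - 2)  # adjusted Fisher-Pearson
    else:
        sk = np.nan
    return m, v, sk


def moment_signature(
    params: NativeParams,
    spec: Optional[GeneralizedSpec] = None,
    cfg: Optional[SimConfig] = None,
) -> dict:
    """Empirical outcome ratio and conditional hitting-time moments.

    Returns ``{p_up, mean/var/skew_up, mean/var/skew_down, missing_class}``;
    an outcome class with fewer than 10 uncensored trials is reported as NaN
    moments with the flag set.
    """
    ds = simulate_dataset(params, spec, cfg).uncensored()
    up = ds.hit_time[ds.outcome == 1]
    down = ds.hit_time[ds.outcome == -1]
    sig = {"p_up": len(up) / len(ds), "missing_class": False}
    for name, t in (("up", up), ("down", down)):
        if len(t) >= 10:
            m, v, sk = _moments(t)
        else:
            m = v = sk = np.nan
            sig["missing_class"] = True
        sig[f"mean_{name}"] = m
        sig[f"var_{name}"] = v
        sig[f"skew_{name}"] = sk
    return sig
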