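"""Standard comparison estimators: method of moments and method of trial
means.

Both match vanilla-DDM first-passage predictions to data (they deliberately
stay vanilla even when the data come from a collapsing-bound model, which is
how they are used as robustness baselines).  The method of moments adjusts
parameters so the model-implied outcome ratio and conditional RT moments (up
to third order) match their sample counterparts, weighted by bootstrap
standard errors.  The method of trial means matches each trial's raw RT to
its model-implied conditional expectation — exploiting per-trial drift
predictors when available — plus a Bernoulli outcome-probability term, with
the residual variance profiled out in closed form.  Both maximize a
standard-normal-prior-penalized objective over the unconstrained parameters
with a seeded multi-start quasi-Newton optimizer.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import minimize

from .params import NativeParams, sigmoid
from .fpt import moments_ode, model_moments
from .simulate import Dataset

__all__ = [
    "MomentTargets",
    "BaselineFitResult",
    "observed_moments",
    "fit_method_of_moments",
    "fit_trial_means",
]

_STAT_KEYS = ["p_up", "mean_up", "var_up", "skew_up", "mean_down", "var_down", "skew_down"]


@dataclass
class MomentTargets:
    """Observed outcome ratio and conditional RT moments with bootstrap SEs."""

    stats: dict
    se: dict
    used: list[str]


@dataclass
class BaselineFitResult:
    method: str
    param_names: list[str]
    phi_mean: np.ndarray
    native_point: NativeParams
    objective: float
    regime: str
    min_rt: float
    converged: bool
    lambda_est: Optional[float] = None
    used_stats: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "method": self.method,
                "param_names": self.param_names,
                "phi_mean": self.phi_mean.tolist(),
                "native_point": vars(self.native_point),
                "objective": self.objective,
                "regime": self.regime,
                "min_rt": self.min_rt,
                "converged": self.converged,
                "lambda_est": self.lambda_est,
            }
        )


def _class_stats(rt: np.ndarray, outcome: np.ndarray) -> dict:
    out = {}
    up = rt[outcome == 1]
    down = rt[outcome == -1]
    out["p_up"] = len(up) / len(rt)
    for name, t in (("up", up), ("down", down)):
        if len(t) >= 2:
            m = float(np.mean(t))
            v = float(np.var(t))
            out[f"mean_{name}"] = m
            out[f"var_{name}"] = v
            if len(t) > 2 and v > 0:
                sk = float(np.mean((t - m) ** 3)) / v**1.5
                n = len(t)
                out[f"skew_{name}"] = sk * math.sqrt(n * (n - 1)) / (n - 2)
    return out


def observed_moments(
    dataset: Dataset, n_boot: int = 500, seed: int = 0
) -> MomentTargets:
    """Sample statistics with seeded bootstrap standard errors.

    Classes with fewer than 10 trials contribute only the moments their size
    supports (skewness needs >= 10, variance >= 5, mean >= 2), with a
    warning.
    """
    ds = dataset.uncensored()
    stats = _class_stats(ds.rt, ds.outcome)
    n = len(ds)
    used = ["p_up"]
    for name in ("up", "down"):
        n_cls = int((ds.outcome == (1 if name == "up" else -1)).sum())
        if n_cls >= 10:
            used += [f"mean_{name}", f"var_{name}", f"skew_{name}"]
        elif n_cls >= 5:
            used += [f"mean_{name}", f"var_{name}"]
            warnings.warn(f"{name} class has {n_cls} trials; skewness dropped")
        elif n_cls >= 2:
            used += [f"mean_{name}"]
            warnings.warn(f"{name} class has {n_cls} trials; variance/skewness dropped")
        else:
            warnings.warn(f"{name} class empty/degenerate; its moments dropped")
    used = [k for k in used if k in stats or k == "p_up"]

    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xB007)))
    boots: dict[str, list[float]] = {k: [] for k in used}
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        bs = _class_stats(ds.rt[idx], ds.outcome[idx])
        for k in used:
            if k in bs:
                boots[k].append(bs[k])
    se = {}
    for k in used:
        vals = np.asarray(boots[k])
        scale = max(abs(stats[k]), 1.0) if k != "p_up" else 1.0
        se[k] = max(float(np.std(vals, ddof=1)) if len(vals) > 1 else np.inf,
                    1e-4 * scale)
    return MomentTargets(stats=stats, se=se, used=used)


def _free_names(regime: str) -> list[str]:
    if regime == "full":
        return ["phi1", "phi2", "phi3", "phi4", "phi5"]
    return ["phi1", "phi2", "phi3", "phi4"]


def _phi_to_native(
    phi: np.ndarray, regime: str, min_rt: float, drift_value: Optional[float]
) -> NativeParams:
    b = math.exp(phi[0])
    sig = math.exp(phi[1])
    t_nd = min_rt * sigmoid(phi[2])
    x0 = b * (2.0 * sigmoid(phi[3]) - 1.0)
    if regime == "full":
        limit = (b + abs(x0)) / (min_rt - t_nd)
        v = limit * (2.0 * sigmoid(phi[4]) - 1.0)
    else:
        v = float(drift_value)
    return NativeParams(v=v, x0=x0, b=b, sigma=sig, t_nd=t_nd)


def _starts(k: int, n_starts: int, seed: int, full: bool, outcome_mean: float) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x57A7)))
    starts = [np.zeros(k)]
    if full:
        starts[0][4] = 0.5 if outcome_mean >= 0 else -0.5
    for _ in range(n_starts - 1):
        starts.append(0.75 * rng.standard_normal(k))
    return np.asarray(starts)


def _resolve_drift(dataset: Dataset, regime: str, drift_value: Optional[float], method: str) -> Optional[float]:
    if regime == "full":
        return None
    if drift_value is not None:
        return float(drift_value)
    d = dataset.drift
    if np.unique(d).size > 1 and method == "mom":
        warnings.warn(
            "drift varies over trials but the method of moments assumes a "
            "fixed drift; using the across-trial mean"
        )
    return float(np.mean(d))


def fit_method_of_moments(
    dataset: Dataset,
    regime: Optional[str] = None,
    drift_value: Optional[float] = None,
    n_starts: int = 5,
    seed: int = 0,
    n_boot: int = 500,
    n_grid: int = 400,
    maxiter: int = 80,
) -> BaselineFitResult:
    """Bootstrap-weighted moment matching on the unconstrained scale.

    Maximizes ``-0.5 * sum_k ((obs_k - model_k)/SE_k)^2`` plus a standard
    normal log-prior on the free parameters, with a seeded multi-start
    quasi-Newton optimizer (moment surfaces are multi-modal).
    """
    ds = dataset.uncensored()
    if regime is None:
        regime = "varying_drift" if np.unique(ds.drift).size > 1 else "full"
    drift = _resolve_drift(ds, regime, drift_value, "mom")
    targets = observed_moments(ds, n_boot=n_boot, seed=seed)
    min_rt = ds.min_rt
    names = _free_names(regime)
    k = len(names)
    obs = np.array([targets.stats[key] for key in targets.used])
    ses = np.array([targets.se[key] for key in targets.used])

    def neg_obj(phi: np.ndarray) -> float:
        if np.any(np.abs(phi) > 20):  # far outside the standard-normal prior
            return 1e12
        try:
            native = _phi_to_native(phi, regime, min_rt, drift)
            mod = model_moments(native, backend="ode")
        except (ValueError, FloatingPointError, OverflowError):
            return 1e12
        vals = np.array([mod.get(key, np.nan) for key in targets.used])
        if not np.all(np.isfinite(vals)):
            return 1e12
        chi2 = float(np.sum(((obs - vals) / ses) ** 2))
        return 0.5 * chi2 + 0.5 * float(phi @ phi)

    best = None
    for x0 in _starts(k, n_starts, seed, regime == "full", float(np.mean(ds.outcome))):
        res = minimize(neg_obj, x0, method="L-BFGS-B",
                       options={"maxiter": maxiter, "maxfun": 4 * maxiter * (k + 1)})
        if best is None or res.fun < best.fun:
            best = res
    phi = best.x
    return BaselineFitResult(
        method="mom",
        param_names=names,
        phi_mean=phi,
        native_point=_phi_to_native(phi, regime, min_rt, drift),
        objective=-float(best.fun),
        regime=regime,
        min_rt=min_rt,
        converged=bool(best.success) or np.isfinite(best.fun),
        used_stats=list(targets.used),
    )


class _TrialMeanBackend:
    """Per-trial conditional RT means and outcome probabilities, with a
    drift-grid PCHIP interpolation when many distinct drifts are present."""

    def __init__(self, drifts: np.ndarray, n_grid: int, grid_size: int = 13):
        self.drifts = drifts
        uniq = np.unique(drifts)
        self.n_grid = n_grid
        if uniq.size <= grid_size:
            self.eval_points = uniq
            self.interp = False
        else:
            lo, hi = float(uniq.min()), float(uniq.max())
            self.eval_points = np.linspace(lo, hi, grid_size)
            self.interp = True

    def __call__(self, native: NativeParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        p_up = np.empty(self.eval_points.size)
        m_up = np.empty(self.eval_points.size)
        m_down = np.empty(self.eval_points.size)
        for i, v in enumerate(self.eval_points):
            par = NativeParams(v=float(v), x0=native.x0, b=native.b,
                               sigma=native.sigma, t_nd=0.0)
            mom = moments_ode(par, n_grid=self.n_grid, max_order=1)
            p_up[i] = mom["p_up"]
            m_up[i] = mom["mean_up"]
            m_down[i] = mom["mean_down"]
        if self.interp and self.eval_points.size >= 4:
            fp = PchipInterpolator(self.eval_points, p_up)
            fu = PchipInterpolator(self.eval_points, m_up)
            fd = PchipInterpolator(self.eval_points, m_down)
            return fp(self.drifts), fu(self.drifts), fd(self.drifts)
        idx = np.searchsorted(self.eval_points, self.drifts)
        idx = np.clip(idx, 0, self.eval_points.size - 1)
        return p_up[idx], m_up[idx], m_down[idx]


def fit_trial_means(
    dataset: Dataset,
    regime: Optional[str] = None,
    drift_value: Optional[float] = None,
    include_outcome_term: bool = False,
    n_starts: int = 5,
    seed: int = 0,
    n_grid: int = 300,
    maxiter: int = 80,
) -> BaselineFitResult:
    """Match raw trial-by-trial RTs to their model-implied conditional means.

    Gaussian likelihood around the per-trial conditional expectation
    ``E[RT | outcome_i, v_i]`` (residual variance profiled out in closed
    form) and a standard normal log-prior on the free parameters.  By
    default the estimator is blind to accuracy beyond the two conditional
    means; ``include_outcome_term=True`` adds the Bernoulli
    log-probability of each observed outcome.
    """
    ds = dataset.uncensored()
    if regime is None:
        regime = "varying_drift" if np.unique(ds.drift).size > 1 else "full"
    min_rt = ds.min_rt
    names = _free_names(regime)
    k = len(names)
    n = len(ds)
    up_mask = ds.outcome == 1

    if regime == "varying_drift":
        drifts = ds.drift.astype(float)
    elif regime == "fixed_drift":
        dv = drift_value if drift_value is not None else float(np.mean(ds.drift))
        drifts = np.full(n, dv)
    else:
        drifts = None  # estimated via phi5

    def neg_obj(phi: np.ndarray) -> float:
        if np.any(np.abs(phi) > 20):
            return 1e12
        try:
            native = _phi_to_native(
                phi, regime, min_rt, drifts[0] if drifts is not None else None
            )
        except (ValueError, FloatingPointError, OverflowError):
            return 1e12
        d = drifts if drifts is not None else np.full(n, native.v)
        backend = _TrialMeanBackend(d, n_grid)
        try:
            p_up, m_up, m_down = backend(native)
        except (ValueError, FloatingPointError, OverflowError):
            return 1e12
        mu = np.where(up_mask, m_up, m_down) + native.t_nd
        if not np.all(np.isfinite(mu)):
            return 1e12
        r = ds.rt - mu
        lam = max(float(np.mean(r**2)), 1e-12)
        ll = -0.5 * n * (math.log(2 * math.pi * lam) + 1.0)
        if include_outcome_term:
            p = np.clip(np.where(up_mask, p_up, 1.0 - p_up), 1e-12, 1.0)
            ll += float(np.sum(np.log(p)))
        return -(ll - 0.5 * float(phi @ phi))

    best = None
    for x0 in _starts(k, n_starts, seed, regime == "full", float(np.mean(ds.outcome))):
        res = minimize(neg_obj, x0, method="L-BFGS-B",
                       options={"maxiter": maxiter, "maxfun": 4 * maxiter * (k + 1)})
        if best is None or res.fun < best.fun:
            best = res
    phi = best.x
    native = _phi_to_native(
        phi, regime, min_rt,
        (drifts[0] if regime == "fixed_drift" else float(np.mean(ds.drift)))
        if regime != "full" else None,
    )
    # recompute profiled residual variance at the optimum for reporting
    d = drifts if drifts is not None else np.full(n, native.v)
    p_up, m_up, m_down = _TrialMeanBackend(d, n_grid)(native)
    mu = np.where(up_mask, m_up, m_down) + native.t_nd
    lam = float(np.mean((ds.rt - mu) ** 2))
    return BaselineFitResult(
        method="motm",
        param_names=names,
        phi_mean=phi,
        native_point=native,
        objective=-float(best.fun),
        regime=regime,
        min_rt=min_rt,
        converged=bool(best.success) or np.isfinite(best.fun),
        lambda_est=lam,
    )
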