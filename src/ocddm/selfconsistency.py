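"""The DDM self-consistency equation.

Rewriting the discretized accumulator as ``x_t = x0 + v t + sigma sqrt(t)
eta_tilde_t`` (with ``eta_tilde`` the normalized cumulative perturbation)
and imposing the bound-hit condition at the decision time yields an
algebraic identity that an observed response time must satisfy:

    y_i ≈ g(...) + eps_i,
    g = ( z^{-1}(o_i * b(y_i - t_nd)) - x0 - sigma*sqrt(y_i - t_nd)*eta_i ) / v + t_nd

which reduces, for the vanilla DDM (identity transform, constant bound), to

    y_i ≈ (o_i*b - x0)/v - (sigma*sqrt(y_i - t_nd)/v)*eta_i + t_nd + eps_i.

The observed RT appears on both sides, so the identity can be *fitted* but
never used to generate data; simulation lives in :mod:`ocddm.simulate`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .params import GeneralizedSpec, NativeParams, vanilla_spec
from .simulate import Dataset

__all__ = [
    "SingularDriftError",
    "normalized_cumulative_perturbation",
    "self_consistent_rt",
    "residuals",
    "implied_eta_tilde",
    "SelfConsistencyResult",
]

# Drift magnitudes below this raise rather than returning astronomically
# large self-consistent RTs.
_V_MIN = 1e-10


class SingularDriftError(ValueError):
    """Drift rate too close to zero for the self-consistency equation."""


def normalized_cumulative_perturbation(increments: Sequence[float]) -> float:
    """``sum(eta) / sqrt(n)`` over the per-step unit-normal noise draws.

    Under the no-barrier law this is N(0,1) at every horizon, which is the
    reason for the sqrt normalization.
    """
    inc = np.asarray(increments, dtype=float)
    if inc.size == 0:
        raise ValueError("increments must be nonempty")
    return float(np.sum(inc) / np.sqrt(inc.size))


def _check_rt(rt: np.ndarray, t_nd: float) -> np.ndarray:
    tau = np.asarray(rt, dtype=float) - t_nd
    if np.any(tau <= 0):
        bad = np.flatnonzero(tau <= 0)
        raise ValueError(f"rt <= t_nd at trial index/indices {bad.tolist()}")
    return tau


def self_consistent_rt(
    params: NativeParams,
    spec: Optional[GeneralizedSpec],
    outcome: np.ndarray | int,
    rt: np.ndarray | float,
    eta_tilde: np.ndarray | float,
    drift: Optional[np.ndarray | float] = None,
) -> np.ndarray | float:
    """Self-consistent response time g for one or many trials.

    ``drift`` optionally overrides ``params.v`` per trial (trial-varying
    drift designs).  Raises :class:`SingularDriftError` on |v| < 1e-10 and
    ``ValueError`` on ``rt <= t_nd``.
    """
    spec = spec or vanilla_spec()
    o = np.asarray(outcome, dtype=float)
    tau = _check_rt(rt, params.t_nd)
    v = np.asarray(params.v if drift is None else drift, dtype=float)
    if np.any(np.abs(v) < _V_MIN):
        raise SingularDriftError("drift magnitude below 1e-10")
    bound = spec.bound(params, tau)
    inv = spec.z_inv(o * np.asarray(bound, dtype=float))
    if not np.all(np.isfinite(inv)):
        raise ValueError("signed bound value outside the range of z")
    g = (inv - params.x0 - params.sigma * np.sqrt(tau) * np.asarray(eta_tilde)) / v
    g = g + params.t_nd
    if np.ndim(rt) == 0 and np.ndim(outcome) == 0:
        return float(g)
    return g


def implied_eta_tilde(
    params: NativeParams,
    spec: Optional[GeneralizedSpec],
    dataset: Dataset,
) -> np.ndarray:
    """Normalized cumulative perturbation implied by each observed trial.

    Inverts the bound-hit identity for eta: the unique value that makes the
    trial exactly self-consistent under the given parameters.  Used for
    diagnostics and to initialize the overcomplete fit.
    """
    spec = spec or vanilla_spec()
    tau = _check_rt(dataset.rt, params.t_nd)
    has_drift = np.any(dataset.drift != 0)
    v = np.where(dataset.drift != 0, dataset.drift, params.v) if has_drift else np.full(len(dataset), params.v)
    bound = np.asarray(spec.bound(params, tau), dtype=float)
    inv = spec.z_inv(dataset.outcome * bound)
    return (inv - params.x0 - v * tau) / (params.sigma * np.sqrt(tau))


@dataclass
class SelfConsistencyResult:
    g: np.ndarray
    residual: np.ndarray


def residuals(
    dataset: Dataset,
    params: NativeParams,
    spec: Optional[GeneralizedSpec],
    eta_tilde: np.ndarray,
    drift: Optional[np.ndarray] = None,
) -> SelfConsistencyResult:
    """Per-trial residuals ``y_i - g_i`` of the self-consistency equation."""
    if len(eta_tilde) != len(dataset):
        raise ValueError("eta_tilde length must match the dataset")
    if np.any(dataset.censored):
        raise ValueError("residuals require an uncensored dataset")
    g = self_consistent_rt(
        params, spec, dataset.outcome, dataset.rt, np.asarray(eta_tilde), drift=drift
    )
    return SelfConsistencyResult(g=np.asarray(g), residual=dataset.rt - np.asarray(g))
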