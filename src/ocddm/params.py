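"""Parameter spaces of the drift-diffusion model and the mappings between them.

The DDM's interpretable ("native") parameters are the drift rate ``v``, the
initial bias ``x0``, the bound height ``b`` (or, for collapsing-bound
variants, the bound parameters ``omega0``/``omega1``), the diffusion standard
deviation ``sigma`` and the non-decision time ``t_nd``.  Fitting is carried
out on an unconstrained scale: dummy parameters ``phi1..phi5`` on which
standard-normal priors live, related to the native parameters through
sigmoid/exponential maps that enforce the model's hard constraints
(positivity of ``b`` and ``sigma``, ``|x0| < b``, ``0 < t_nd < min(RT)``,
and the "ballistic" bound on the drift magnitude).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Optional

import numpy as np

__all__ = [
    "NativeParams",
    "UnconstrainedParams",
    "GeneralizedSpec",
    "MinRTContext",
    "sigmoid",
    "logit",
    "map_phi_to_native",
    "map_native_to_phi",
    "bound_height",
    "ballistic_drift_limit",
    "vanilla_spec",
    "collapsing_spec",
    "sinh_spec",
]

# Sigmoid outputs are clamped away from {0, 1}: the parameter maps divide by
# 1 - s(phi3), which would overflow at extreme phi.
_SIG_CLIP = 1e-9


class InvalidInputError(ValueError):
    """Non-finite or out-of-domain input to a parameter mapping."""


class InvalidContextError(ValueError):
    """A MinRTContext that cannot support the requested mapping."""


class NonInvertibleError(ValueError):
    """Native parameters at or outside a constraint boundary."""


def sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    """Standard logistic sigmoid, clamped to (0, 1) open interval."""
    out = 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))
    out = np.clip(out, _SIG_CLIP, 1.0 - _SIG_CLIP)
    if np.ndim(x) == 0:
        return float(out)
    return out


def logit(p: np.ndarray | float) -> np.ndarray | float:
    p = np.asarray(p, dtype=float)
    out = np.log(p) - np.log1p(-p)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class MinRTContext:
    """Smallest observed response time of the dataset being fitted.

    The non-decision time is constrained to (0, min_rt) and the drift
    magnitude to its ballistic limit, both of which depend on this
    data-derived quantity.
    """

    min_rt: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.min_rt) or self.min_rt <= 0:
            raise InvalidContextError(f"min_rt must be positive, got {self.min_rt}")


@dataclass
class NativeParams:
    """Interpretable DDM parameters (arbitrary, consistent time units)."""

    v: float = 0.5
    x0: float = 1.0
    b: float = 10.0
    sigma: float = 4.0
    t_nd: float = 0.0

    def validate(self, ctx: Optional[MinRTContext] = None) -> "NativeParams":
        if self.sigma <= 0:
            raise InvalidInputError(f"sigma must be positive, got {self.sigma}")
        if self.b <= 0:
            raise InvalidInputError(f"b must be positive, got {self.b}")
        if abs(self.x0) >= self.b:
            raise InvalidInputError(f"|x0| must be < b, got x0={self.x0}, b={self.b}")
        if self.t_nd < 0:
            raise InvalidInputError(f"t_nd must be non-negative, got {self.t_nd}")
        if ctx is not None:
            if self.t_nd >= ctx.min_rt:
                raise InvalidContextError(
                    f"t_nd={self.t_nd} must be < min_rt={ctx.min_rt}"
                )
            limit = ballistic_drift_limit(self.b, self.x0, ctx, self.t_nd)
            if abs(self.v) >= limit:
                raise InvalidInputError(
                    f"|v|={abs(self.v)} at or above ballistic limit {limit}"
                )
        return self

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "NativeParams":
        return cls(**json.loads(s))


@dataclass
class UnconstrainedParams:
    """Dummy parameters phi1..phi5 (plus optional bound/drift coefficients).

    phi1 -> b, phi2 -> sigma, phi3 -> t_nd, phi4 -> x0, phi5 -> v.  For
    collapsing-bound variants ``omega0``/``omega1`` (initial log-height and
    decay rate) replace phi1; they carry no positivity transform, so an
    expanding bound (omega1 < 0) is permitted.  ``v0``/``v1`` are the
    optional affine coefficients of a trial-varying drift.
    """

    phi1: float = 0.0
    phi2: float = 0.0
    phi3: float = 0.0
    phi4: float = 0.0
    phi5: float = 0.0
    omega0: Optional[float] = None
    omega1: Optional[float] = None
    v0: Optional[float] = None
    v1: Optional[float] = None

    def as_array(self) -> np.ndarray:
        return np.array([self.phi1, self.phi2, self.phi3, self.phi4, self.phi5])

    def validate(self) -> "UnconstrainedParams":
        vals = [self.phi1, self.phi2, self.phi3, self.phi4, self.phi5]
        vals += [x for x in (self.omega0, self.omega1, self.v0, self.v1) if x is not None]
        if not np.all(np.isfinite(vals)):
            raise InvalidInputError(f"non-finite unconstrained parameters: {vals}")
        return self

    def to_json(self) -> str:
        return json.dumps({k: v for k, v in asdict(self).items() if v is not None})

    @classmethod
    def from_json(cls, s: str) -> "UnconstrainedParams":
        return cls(**json.loads(s))


def bound_height(omega0: float, omega1: float, t: np.ndarray | float) -> np.ndarray | float:
    """Exponentially collapsing bound ``exp(omega0 - omega1 * t)``.

    ``omega1 = 0`` gives a constant (vanilla) bound ``exp(omega0)``; a
    negative decay rate gives an expanding bound (permitted, documented).
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise InvalidInputError("bound_height requires t >= 0")
    out = np.exp(omega0 - omega1 * t_arr)
    if np.ndim(t) == 0:
        return float(out)
    return out


def ballistic_drift_limit(
    b: float, x0: float, ctx: MinRTContext, t_nd: float
) -> float:
    """Largest drift magnitude compatible with the fastest observed RT.

    With zero noise the accumulator covers at most ``b + |x0|`` before
    absorption, in at most ``min_rt - t_nd`` of decision time, so
    ``|v| < (b + |x0|) / (min_rt - t_nd)``.
    """
    if t_nd >= ctx.min_rt:
        raise InvalidContextError(f"t_nd={t_nd} must be < min_rt={ctx.min_rt}")
    return (b + abs(x0)) / (ctx.min_rt - t_nd)


def map_phi_to_native(phi: UnconstrainedParams, ctx: MinRTContext) -> NativeParams:
    """Map unconstrained parameters to native DDM parameters.

    b = exp(phi1); sigma = exp(phi2); t_nd = min_rt * s(phi3);
    x0 = b * (2 s(phi4) - 1); v = ballistic_limit * (2 s(phi5) - 1),
    with s the standard logistic sigmoid.  All native invariants hold by
    construction for any finite phi.
    """
    phi.validate()
    b = math.exp(phi.phi1)
    sig = math.exp(phi.phi2)
    t_nd = ctx.min_rt * sigmoid(phi.phi3)
    x0 = b * (2.0 * sigmoid(phi.phi4) - 1.0)
    limit = ballistic_drift_limit(b, x0, ctx, t_nd)
    v = limit * (2.0 * sigmoid(phi.phi5) - 1.0)
    return NativeParams(v=v, x0=x0, b=b, sigma=sig, t_nd=t_nd)


def map_native_to_phi(native: NativeParams, ctx: MinRTContext) -> UnconstrainedParams:
    """Inverse of :func:`map_phi_to_native` (exact where it exists).

    Raises :class:`NonInvertibleError` for parameters at or outside a
    constraint boundary (e.g. ``t_nd >= min_rt`` or a drift at its
    ballistic limit).
    """
    try:
        native.validate(ctx)
    except (InvalidInputError, InvalidContextError) as exc:
        raise NonInvertibleError(str(exc)) from exc
    phi1 = math.log(native.b)
    phi2 = math.log(native.sigma)
    u3 = native.t_nd / ctx.min_rt
    if not (0.0 < u3 < 1.0):
        raise NonInvertibleError(f"t_nd/min_rt={u3} outside (0, 1)")
    phi3 = logit(u3)
    u4 = 0.5 * (native.x0 / native.b + 1.0)
    phi4 = logit(u4)
    limit = ballistic_drift_limit(native.b, native.x0, ctx, native.t_nd)
    u5 = 0.5 * (native.v / limit + 1.0)
    phi5 = logit(u5)
    return UnconstrainedParams(phi1=phi1, phi2=phi2, phi3=phi3, phi4=phi4, phi5=phi5)


@dataclass
class GeneralizedSpec:
    """DDM variant: state transformation z and (possibly time-varying) bound.

    A decision is triggered at the first time the transformed accumulator
    ``z(x_t)`` reaches the threshold ``±bound_fn(t)``.  ``z`` must be
    strictly monotone with exact inverse ``z_inv``; the vanilla model is
    ``z = identity`` with a constant bound.
    """

    z: Callable[[np.ndarray], np.ndarray] = field(default=lambda x: x)
    z_inv: Callable[[np.ndarray], np.ndarray] = field(default=lambda u: u)
    bound_fn: Callable[[np.ndarray], np.ndarray] = field(default=None)  # type: ignore[assignment]
    variant: str = "vanilla"
    omega0: Optional[float] = None
    omega1: Optional[float] = None

    def __post_init__(self) -> None:
        if self.bound_fn is None:
            if self.omega0 is not None:
                om1 = 0.0 if self.omega1 is None else self.omega1
                self.bound_fn = lambda t: bound_height(self.omega0, om1, t)
            else:
                self.bound_fn = None  # filled per-call from NativeParams.b

    def bound(self, params: NativeParams, t: np.ndarray | float) -> np.ndarray | float:
        if self.bound_fn is not None:
            return self.bound_fn(t)
        return params.b * np.ones_like(np.asarray(t, dtype=float)) if np.ndim(t) else params.b

    def check_inverse(self, grid: np.ndarray, atol: float = 1e-9) -> bool:
        u = np.asarray(grid, dtype=float)
        return bool(np.allclose(self.z(self.z_inv(u)), u, atol=atol))


def vanilla_spec() -> GeneralizedSpec:
    """Vanilla DDM: identity transform, constant bound taken from params.b."""
    return GeneralizedSpec(variant="vanilla")


def collapsing_spec(omega0: float, omega1: float) -> GeneralizedSpec:
    """Exponentially collapsing (or expanding) bound exp(omega0 - omega1 t)."""
    return GeneralizedSpec(variant="collapsing", omega0=omega0, omega1=omega1)


def sinh_spec(gamma: float) -> GeneralizedSpec:
    """Example nonlinear state transformation z(x) = sinh(gamma x) / gamma."""
    if gamma == 0:
        return vanilla_spec()
    return GeneralizedSpec(
        z=lambda x: np.sinh(gamma * x) / gamma,
        z_inv=lambda u: np.arcsinh(gamma * u) / gamma,
        variant="transformed",
    )
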