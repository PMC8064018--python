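"""The "no barrier" prior on normalized cumulative perturbations.

If the accumulator had no absorbing bounds, the normalized cumulative
perturbation eta_tilde would be exactly N(0,1) at every horizon.  Correct
decisions then correspond to perturbations above a critical value
``eta_crit`` chosen so that ``P(eta >= eta_crit)`` equals the observed
proportion of correct responses, and the conditional distributions of
eta_tilde given correctness are approximated by moment-matched Gaussians
whose means and variances are the standard truncated-normal expressions.

A deterministic moment-enforcing mapping ``h`` turns free per-trial dummy
variables into perturbation estimates whose within-group sample moments
match those targets exactly, whatever the dummies are.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ConditionalMoments",
    "critical_value",
    "conditional_moments",
    "enforce_moments",
    "DegenerateGroupError",
]

_Q_CLIP = 1e-6


class DegenerateGroupError(ValueError):
    """A correctness group too small or with constant dummies."""


@dataclass
class ConditionalMoments:
    """Truncated-normal conditional moments of eta_tilde given correctness."""

    q_correct: float
    eta_crit: float
    mu_correct: float
    mu_error: float
    var_correct: float
    var_error: float

    def total_mean(self) -> float:
        return self.q_correct * self.mu_correct + (1 - self.q_correct) * self.mu_error

    def total_second_moment(self) -> float:
        q = self.q_correct
        return q * (self.var_correct + self.mu_correct**2) + (1 - q) * (
            self.var_error + self.mu_error**2
        )


def _check_q(q_correct: float) -> float:
    if not np.isfinite(q_correct) or not (0.0 < q_correct < 1.0):
        raise ValueError(f"q_correct must lie in (0, 1), got {q_correct}")
    return float(np.clip(q_correct, _Q_CLIP, 1.0 - _Q_CLIP))


def critical_value(q_correct: float) -> float:
    """Standard-normal threshold with upper-tail mass ``q_correct``.

    Inputs are clamped to [1e-6, 1-1e-6]; the exact limits q -> 0/1 diverge.
    """
    q = _check_q(q_correct)
    return float(stats.norm.ppf(1.0 - q))


def conditional_moments(
    q_correct: float, printed_variant: bool = False
) -> ConditionalMoments:
    """Conditional mean/variance of a standard normal split at the critical
    value.

    The default uses the standard truncated-normal first moments
    ``mu_correct = pdf(c)/q`` and ``mu_error = -pdf(c)/(1-q)``, which satisfy
    the law of total expectation exactly.  ``printed_variant=True`` swaps the
    two denominators (an alternative transcription kept for comparison; it
    violates the total-expectation identity except at q = 1/2).  Variances
    are ``1 + c*mu - mu^2`` in each group.  No DDM parameter enters.
    """
    q = _check_q(q_correct)
    c = float(stats.norm.ppf(1.0 - q))
    pdf_c = float(stats.norm.pdf(c))
    if printed_variant:
        mu_c = pdf_c / (1.0 - q)
        mu_e = -pdf_c / q
    else:
        mu_c = pdf_c / q
        mu_e = -pdf_c / (1.0 - q)
    var_c = 1.0 + c * mu_c - mu_c**2
    var_e = 1.0 + c * mu_e - mu_e**2
    return ConditionalMoments(
        q_correct=q, eta_crit=c,
        mu_correct=mu_c, mu_error=mu_e,
        var_correct=var_c, var_error=var_e,
    )


def enforce_moments(
    dummy: np.ndarray,
    correct_labels: np.ndarray,
    q_correct: float | None = None,
    moments: ConditionalMoments | None = None,
) -> np.ndarray:
    """Moment-enforcing mapping h: dummies -> perturbation estimates.

    Within each correctness group the dummies are centered, rescaled so the
    group's population variance (denominator = group size) equals the target
    conditional variance, and shifted to the target conditional mean.  The
    output moments are therefore exact regardless of the dummy values; the
    map is invariant to positive-affine transformations of the dummies
    within a group.
    """
    dummy = np.asarray(dummy, dtype=float)
    labels = np.asarray(correct_labels, dtype=bool)
    if dummy.shape != labels.shape:
        raise ValueError("dummy and correct_labels must have the same shape")
    if moments is None:
        if q_correct is None:
            q_correct = float(np.mean(labels))
        moments = conditional_moments(q_correct)
    out = np.empty_like(dummy)
    for is_correct, mu, var in (
        (True, moments.mu_correct, moments.var_correct),
        (False, moments.mu_error, moments.var_error),
    ):
        idx = labels == is_correct
        n_g = int(idx.sum())
        if n_g < 2:
            raise DegenerateGroupError(
                f"{'correct' if is_correct else 'error'} group has {n_g} < 2 trials"
            )
        g = dummy[idx]
        centered = g - g.mean()
        ss = float(np.sum(centered**2))
        if ss <= 0:
            raise DegenerateGroupError(
                f"constant dummies in the {'correct' if is_correct else 'error'} group"
            )
        out[idx] = mu + centered * np.sqrt(n_g * var / ss)
    return out
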