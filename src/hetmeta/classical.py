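"""Conventional random-effects meta-analysis of one set of SMD estimates.

Implements Cochran's Q, the DerSimonian-Laird moment estimate of the
between-study variance tau^2 (truncated at zero), the pooled effect with a
normal-theory confidence interval, the I^2 inconsistency percentage, and
the Q-profile confidence interval for tau^2 obtained by inverting the
generalized Q statistic against chi-square quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .effects import EffectEstimate, as_arrays

__all__ = [
    "ClassicalResult",
    "cochran_q",
    "dl_tau2",
    "q_profile_ci",
    "paule_mandel_tau2",
    "classical_meta_analysis",
]


@dataclass(frozen=True)
class ClassicalResult:
    """Summary of a conventional (DL) random-effects meta-analysis."""

    k: int
    q: float
    tau2_dl: float
    tau2_ci: tuple[float, float]
    mu_hat: float
    mu_ci: tuple[float, float]
    i2: float

    def __post_init__(self) -> None:
        if self.tau2_dl < 0 or self.tau2_ci[0] > self.tau2_ci[1]:
            raise ValueError("invalid tau^2 summary")
        if not (0 <= self.i2 < 100):
            raise ValueError("I^2 must lie in [0, 100)")


def cochran_q(effects) -> tuple[float, float]:
    """Cochran's Q and the fixed-effect (inverse-variance) mean.

    Q = sum_i w_i (y_i - ybar_w)^2 with w_i = 1/v_i.
    """
    y, v = as_arrays(effects)
    if y.size < 2:
        raise ValueError(f"need >= 2 effect estimates, got {y.size}")
    w = 1.0 / v
    ybar = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - ybar) ** 2))
    return q, float(ybar)


def dl_tau2(effects, level: float = 0.95) -> ClassicalResult:
    """DerSimonian-Laird estimate of tau^2 and the derived pooled summary.

    tau^2 = max(0, (Q - (k-1)) / C) with C = sum w - sum w^2 / sum w;
    the pooled mean and its CI use weights 1/(v + tau^2);
    I^2 = max(0, (Q - (k-1)) / Q) * 100.
    """
    y, v = as_arrays(effects)
    k = y.size
    q, _ = cochran_q((y, v))
    w = 1.0 / v
    c = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - (k - 1)) / c)
    wstar = 1.0 / (v + tau2)
    mu = float(np.sum(wstar * y) / np.sum(wstar))
    se = float(np.sqrt(1.0 / np.sum(wstar)))
    z = stats.norm.ppf(0.5 + level / 2.0)
    i2 = max(0.0, (q - (k - 1)) / q) * 100.0 if q > 0 else 0.0
    return ClassicalResult(
        k=k,
        q=q,
        tau2_dl=tau2,
        tau2_ci=q_profile_ci((y, v), level=level),
        mu_hat=mu,
        mu_ci=(mu - z * se, mu + z * se),
        i2=i2,
    )


def _generalized_q(tau2: float, y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / (v + tau2)
    ybar = np.sum(w * y) / np.sum(w)
    return float(np.sum(w * (y - ybar) ** 2))


def _bisect_q(target, y, v, lo, hi, tol=1e-8, max_steps=200):
    # Q_gen is strictly decreasing in tau^2: root of Q_gen(t) - target.
    # The relative term keeps the stopping rule attainable when the bound
    # is huge (k = 2 upper bounds can exceed 1e7, beyond float64's
    # absolute resolution).
    for _ in range(max_steps):
        mid = 0.5 * (lo + hi)
        if _generalized_q(mid, y, v) > target:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(1.0, lo):
            return 0.5 * (lo + hi)
    raise RuntimeError(
        f"Q-profile bisection did not converge: target={target}, bracket=({lo},{hi})"
    )


def q_profile_ci(effects, level: float = 0.95) -> tuple[float, float]:
    """Confidence interval for tau^2 by the Q-profile method.

    Bounds solve Q_gen(tau^2) = chi^2_{k-1} upper/lower quantiles by
    bisection (tolerance 1e-8), truncated at zero.  If even Q_gen(0) falls
    below the lower quantile the interval collapses to [0, 0].
    """
    y, v = as_arrays(effects)
    k = y.size
    if k < 2:
        raise ValueError("need >= 2 effect estimates")
    alpha = 1.0 - level
    q_hi = stats.chi2.ppf(1.0 - alpha / 2.0, k - 1)
    q_lo = stats.chi2.ppf(alpha / 2.0, k - 1)
    q0 = _generalized_q(0.0, y, v)

    def upper_bracket(target: float) -> float:
        hi = 100.0  # tau^2 > 100 on the SMD scale is not plausible
        while _generalized_q(hi, y, v) > target:
            hi *= 2.0
            if hi > 1e12:
                raise RuntimeError("failed to bracket Q-profile bound")
        return hi

    if q0 < q_lo:
        return (0.0, 0.0)
    lower = 0.0 if q0 <= q_hi else _bisect_q(q_hi, y, v, 0.0, upper_bracket(q_hi))
    upper = _bisect_q(q_lo, y, v, 0.0, upper_bracket(q_lo))
    return (lower, upper)


def paule_mandel_tau2(effects, tol: float = 1e-10) -> float:
    """Mandel-Paule point estimate: solves Q_gen(tau^2) = k - 1."""
    y, v = as_arrays(effects)
    k = y.size
    if _generalized_q(0.0, y, v) <= k - 1:
        return 0.0
    hi = 100.0
    while _generalized_q(hi, y, v) > k - 1:
        hi *= 2.0
    return _bisect_q(float(k - 1), y, v, 0.0, hi, tol=tol)


def classical_meta_analysis(effects, level: float = 0.95) -> ClassicalResult:
    """Full conventional analysis (alias for :func:`dl_tau2`)."""
    return dl_tau2(effects, level=level)
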