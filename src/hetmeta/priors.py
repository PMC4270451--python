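"""Parametric approximations to predictive distributions for tau^2.

Predictive samples of the between-study variance expected in a future
meta-analysis are summarised by two parametric families:

* a log-t distribution with 5 degrees of freedom — log(tau^2) ~
  t(location, scale^2, 5) — fitted by quantile matching (median and
  central 95% width on the log scale);
* an inverse-gamma distribution, fitted by least squares on the
  (0.025, 0.5, 0.975) quantiles, useful as a conjugate prior.

The module also ships the published registry of fitted log-t priors for
the 8 outcome-type x 3 comparison-type grid (medical areas other than
cancer and respiratory diseases) plus the general-setting fit; these can
be used directly as informative priors for tau^2 in a new meta-analysis.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from functools import lru_cache
from typing import Union

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .schema import Setting

__all__ = [
    "LogTParams",
    "IGParams",
    "CautionError",
    "fit_log_t",
    "fit_inverse_gamma",
    "log_t_summary",
    "published_prior",
    "load_registry",
    "list_priors",
]

_T975 = stats.t.ppf(0.975, 5)


class CautionError(LookupError):
    """Requested prior is appendix-only and flagged as use-with-caution."""


@dataclass(frozen=True)
class LogTParams:
    """t(location, scale^2, df) distribution for log(tau^2); df fixed at 5."""

    location: float
    scale: float
    df: int = 5

    def __post_init__(self) -> None:
        if not (self.scale > 0):
            raise ValueError(f"scale must be > 0, got {self.scale}")
        if self.df != 5:
            raise ValueError("the log-t family is used with df = 5")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw tau^2 values (untransformed scale)."""
        return np.exp(self.location + self.scale * rng.standard_t(self.df, size=n))

    def logpdf_log_tau2(self, x) -> np.ndarray:
        """Log density of log(tau^2) at x."""
        return stats.t.logpdf(x, self.df, loc=self.location, scale=self.scale)


@dataclass(frozen=True)
class IGParams:
    """Inverse-gamma(shape, scale): density ∝ x^(-shape-1) exp(-scale/x)."""

    shape: float
    scale: float

    def __post_init__(self) -> None:
        if not (self.shape > 0 and self.scale > 0):
            raise ValueError("shape and scale must be > 0")

    def dist(self):
        return stats.invgamma(self.shape, scale=self.scale)


def _check_samples(samples) -> np.ndarray:
    x = np.asarray(samples, float).ravel()
    if x.size < 1000:
        raise ValueError(f"need >= 1000 samples, got {x.size}")
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise ValueError("samples of tau^2 must be positive and finite")
    return x


def fit_log_t(samples) -> LogTParams:
    """Fit a log-t(., ., 5) distribution to predictive samples of tau^2.

    Quantile matching: location = median of log(tau^2); scale = central
    95% width of log(tau^2) divided by twice the t5 97.5% quantile.
    """
    x = np.log(_check_samples(samples))
    location = float(np.median(x))
    q_lo, q_hi = np.quantile(x, [0.025, 0.975])
    scale = float((q_hi - q_lo) / (2.0 * _T975))
    if scale <= 0:
        raise ValueError("degenerate sample: zero spread on the log scale")
    return LogTParams(location=location, scale=scale, df=5)


def fit_inverse_gamma(samples) -> IGParams:
    """Fit an inverse-gamma distribution to predictive samples of tau^2.

    Least-squares match of the model's (0.025, 0.5, 0.975) quantiles to
    the empirical ones.  Residuals are scaled by the empirical median so
    the objective is scale-free; on this (raw-quantile) scale the upper
    tail carries most of the weight, which is what makes the fitted
    distribution usable as a prior: the 97.5% quantile is reproduced
    closely even for heavy-tailed input.
    """
    x = _check_samples(samples)
    probs = np.array([0.025, 0.5, 0.975])
    emp = np.quantile(x, probs)
    if emp[0] >= emp[2]:
        raise ValueError("degenerate sample: zero interquantile spread")

    def objective(p: np.ndarray) -> float:
        a, b = np.exp(p)
        model = stats.invgamma.ppf(probs, a, scale=b)
        return float(np.sum(((model - emp) / emp[1]) ** 2))

    # moment-free initial guess: shape from tail heaviness, then scale from
    # the median identity b = q50 * invgamma.ppf(0.5, a, scale=1)^-1
    best = None
    for a0 in (0.3, 0.5, 1.0, 2.0, 4.0):
        b0 = emp[1] * stats.invgamma.ppf(0.5, a0)  # scale solving the median
        res = optimize.minimize(
            objective,
            x0=np.log([a0, b0]),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError(f"inverse-gamma fit failed: {best}")
    a, b = np.exp(best.x)
    return IGParams(shape=float(a), scale=float(b))


@dataclass(frozen=True)
class TauSquaredSummary:
    median: float
    lower: float
    upper: float


def log_t_summary(params: LogTParams, level: float = 0.95) -> TauSquaredSummary:
    """Median and central interval of tau^2 implied by log-t parameters."""
    alpha = 1.0 - level
    t = stats.t(params.df, loc=params.location, scale=params.scale)
    return TauSquaredSummary(
        median=float(np.exp(params.location)),
        lower=float(np.exp(t.ppf(alpha / 2.0))),
        upper=float(np.exp(t.ppf(1.0 - alpha / 2.0))),
    )


@lru_cache(maxsize=1)
def load_registry() -> pd.DataFrame:
    """The shipped registry of published log-t priors (one row per setting)."""
    ref = importlib.resources.files("hetmeta").joinpath("data/prior_registry.csv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def list_priors() -> pd.DataFrame:
    """Registry as a DataFrame (copy)."""
    return load_registry().copy()


def published_prior(setting: Union[Setting, str]) -> LogTParams:
    """Published log-t prior for tau^2 in a given setting.

    Parameters
    ----------
    setting
        A :class:`~hetmeta.schema.Setting`, or the string ``"general"``
        for the all-settings fit.

    Raises
    ------
    CautionError
        For cancer or respiratory-disease settings: those cells sit
        outside the main published grid and carry an explicit
        use-with-caution warning, so they are not served silently.
    """
    reg = load_registry()
    if isinstance(setting, str):
        if setting != "general":
            raise KeyError(f"unknown prior name {setting!r}; use 'general' or a Setting")
        row = reg[(reg.outcome_type == "general") & (reg.comparison_type == "general")]
    else:
        if setting.medical_area in ("cancer", "respiratory"):
            raise CautionError(
                f"priors for medical area {setting.medical_area!r} are appendix-only; "
                "the published advice is to use them with caution, so they are not "
                "shipped in the registry — supply explicit log-t parameters instead"
            )
        row = reg[
            (reg.outcome_type == setting.outcome_type)
            & (reg.comparison_type == setting.comparison_type)
        ]
    if len(row) != 1:
        raise KeyError(f"no registry entry for {setting!r}")
    r = row.iloc[0]
    return LogTParams(location=float(r.location), scale=float(r.scale), df=int(r.df))
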