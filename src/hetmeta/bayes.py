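"""Bayesian random-effects meta-analysis of a single meta-analysis.

Model (SMD scale):

    y_i     ~ Normal(theta_i, v_i)        observed effects, v_i known
    theta_i ~ Normal(mu, tau^2)           true study effects
    mu      ~ Normal(0, sd 10)            vague prior for the summary effect
    tau^2   ~ one of a menu of priors     (see PriorSpec)

Available priors for the heterogeneity variance: an informative log-t
(t(location, scale^2, 5) on log tau^2, taken from the published registry
or given explicitly), a conjugate inverse-gamma, a uniform(0, U) prior on
tau, and a positive half-normal prior on tau.  Sampling is by Gibbs:
conjugate normal updates for theta_i and mu, a conjugate inverse-gamma
draw for tau^2 under the IG prior, and slice sampling on log(tau^2)
otherwise.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from ._mcmc import McmcConfig, SliceError, slice_sample
from .effects import as_arrays, effects_for
from .priors import LogTParams, IGParams, published_prior
from .schema import MetaAnalysis, Setting

__all__ = ["PriorSpec", "PosteriorSummary", "make_prior", "fit_bayes_rema"]

_VARIANTS = ("log_t", "inverse_gamma", "uniform_tau", "half_normal_tau", "point_mass")


@dataclass(frozen=True)
class PriorSpec:
    """A fully parameterised prior for the between-study variance tau^2."""

    variant: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.variant not in _VARIANTS:
            raise ValueError(f"unknown prior variant {self.variant!r}")
        p = self.params
        if self.variant == "log_t":
            if p.get("df", 5) != 5:
                raise ValueError("log-t prior uses df = 5")
            if not p["scale"] > 0:
                raise ValueError("log-t scale must be > 0")
        elif self.variant == "inverse_gamma":
            if not (p["shape"] > 0 and p["scale"] > 0):
                raise ValueError("inverse-gamma shape and scale must be > 0")
        elif self.variant == "uniform_tau":
            if not p["upper"] > 0:
                raise ValueError("uniform upper bound must be > 0")
        elif self.variant == "half_normal_tau":
            if not p["value"] > 0:
                raise ValueError("half-normal parameter must be > 0")
            if p.get("interpretation", "variance") not in ("variance", "sd"):
                raise ValueError("interpretation must be 'variance' or 'sd'")
        elif self.variant == "point_mass":
            if p["tau2"] < 0:
                raise ValueError("point-mass tau^2 must be >= 0")

    # -- constructors ------------------------------------------------------
    @classmethod
    def log_t(cls, location: float, scale: float, df: int = 5) -> "PriorSpec":
        return cls("log_t", {"location": location, "scale": scale, "df": df})

    @classmethod
    def from_log_t_params(cls, params: LogTParams) -> "PriorSpec":
        return cls.log_t(params.location, params.scale, params.df)

    @classmethod
    def inverse_gamma(cls, shape: float, scale: float) -> "PriorSpec":
        return cls("inverse_gamma", {"shape": shape, "scale": scale})

    @classmethod
    def uniform_tau(cls, upper: float) -> "PriorSpec":
        return cls("uniform_tau", {"upper": upper})

    @classmethod
    def half_normal_tau(
        cls, value: float, interpretation: str = "variance"
    ) -> "PriorSpec":
        # "half normal (0, 10)" is read with 10 as the variance of the
        # underlying normal for tau (sd ~ 3.16); pass interpretation="sd"
        # for the other reading.
        return cls("half_normal_tau", {"value": value, "interpretation": interpretation})

    @classmethod
    def point_mass(cls, tau2: float) -> "PriorSpec":
        return cls("point_mass", {"tau2": tau2})


_NAME_RE = re.compile(r"^\s*([a-z_]+)\s*\(([^)]*)\)\s*$")


def make_prior(spec: Union[str, Setting, PriorSpec, LogTParams, IGParams]) -> PriorSpec:
    """Build a PriorSpec from a name string, a Setting, or parameter objects.

    Strings look like ``"uniform_tau(5)"``, ``"half_normal_tau(10)"``,
    ``"log_t(-3.85,1.93)"`` or ``"inverse_gamma(0.94,0.00005)"``.  A
    :class:`Setting` is resolved through the published prior registry.
    """
    if isinstance(spec, PriorSpec):
        return spec
    if isinstance(spec, LogTParams):
        return PriorSpec.from_log_t_params(spec)
    if isinstance(spec, IGParams):
        return PriorSpec.inverse_gamma(spec.shape, spec.scale)
    if isinstance(spec, Setting):
        return PriorSpec.from_log_t_params(published_prior(spec))
    if isinstance(spec, str):
        if spec == "general":
            return PriorSpec.from_log_t_params(published_prior("general"))
        m = _NAME_RE.match(spec)
        if not m:
            raise ValueError(f"cannot parse prior name {spec!r}")
        name, args = m.group(1), [float(a) for a in m.group(2).split(",") if a.strip()]
        if name == "uniform_tau" and len(args) == 1:
            return PriorSpec.uniform_tau(args[0])
        if name == "half_normal_tau" and len(args) == 1:
            return PriorSpec.half_normal_tau(args[0])
        if name == "log_t" and len(args) in (2, 3):
            return PriorSpec.log_t(*args)
        if name == "inverse_gamma" and len(args) == 2:
            return PriorSpec.inverse_gamma(*args)
        raise ValueError(f"unknown prior {name!r} or wrong arity in {spec!r}")
    raise TypeError(f"cannot build a prior from {type(spec)}")


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior medians, central 95% intervals and convergence diagnostics."""

    mu_median: float
    mu_ci95: tuple[float, float]
    tau2_median: float
    tau2_ci95: tuple[float, float]
    rhat: dict
    ess: dict
    converged: bool
    n_draws: int

    def __post_init__(self) -> None:
        if self.mu_ci95[0] > self.mu_ci95[1] or self.tau2_ci95[0] > self.tau2_ci95[1]:
            raise ValueError("credible-interval bounds out of order")


def _log_prior_phi(prior: PriorSpec, phi: np.ndarray) -> np.ndarray:
    """Log prior density of phi = log(tau^2), up to a constant."""
    p = prior.params
    if prior.variant == "log_t":
        return stats.t.logpdf(phi, p.get("df", 5), loc=p["location"], scale=p["scale"])
    if prior.variant == "uniform_tau":
        # tau ~ U(0, upper); Jacobian tau/2 on the phi scale
        out = 0.5 * phi
        return np.where(phi < 2.0 * np.log(p["upper"]), out, -np.inf)
    if prior.variant == "half_normal_tau":
        var = p["value"] if p.get("interpretation", "variance") == "variance" else p["value"] ** 2
        return 0.5 * phi - np.exp(phi) / (2.0 * var)
    raise ValueError(f"no log-scale density for variant {prior.variant!r}")


def fit_bayes_rema(
    data: Union[MetaAnalysis, Sequence, tuple],
    prior: Union[str, Setting, PriorSpec, LogTParams, IGParams],
    cfg: McmcConfig,
    return_draws: bool = False,
):
    """Fit the Bayesian random-effects model to one meta-analysis.

    Parameters
    ----------
    data
        A :class:`MetaAnalysis`, a list of EffectEstimate, or an (y, v) pair.
    prior
        Anything :func:`make_prior` accepts.
    cfg
        MCMC settings; 2+ chains enable Brooks-Gelman-Rubin diagnostics.
    return_draws
        Also return the raw post-burn-in draws of mu and tau^2,
        shaped (chains, kept).

    Returns
    -------
    PosteriorSummary, and optionally a dict of draw arrays.
    """
    if isinstance(data, MetaAnalysis):
        y, v = effects_for(data)
    else:
        y, v = as_arrays(data)
    if y.size < 2:
        raise ValueError("need >= 2 studies")
    prior = make_prior(prior)

    mu_draws = np.empty((cfg.chains, cfg.kept))
    tau2_draws = np.empty((cfg.chains, cfg.kept))
    for c, rng in enumerate(cfg.chain_rngs()):
        mu_c, tau2_c = _run_chain(y, v, prior, cfg, rng)
        mu_draws[c] = mu_c
        tau2_draws[c] = tau2_c

    rhat: dict = {}
    ess: dict = {}
    if cfg.chains >= 2:
        from ._mcmc import gelman_rubin
        import arviz as az

        rhat = {"mu": gelman_rubin(mu_draws)}
        if np.ptp(tau2_draws) > 0:  # tau^2 is a sampled parameter
            rhat["log_tau2"] = gelman_rubin(np.log(tau2_draws))
        ess = {
            "mu": float(az.ess(az.convert_to_dataset(mu_draws))["x"]),
            "tau2": float(az.ess(az.convert_to_dataset(tau2_draws))["x"]),
        }
    converged = bool(rhat) and max(rhat.values()) < 1.05

    mu_flat = mu_draws.ravel()
    tau2_flat = tau2_draws.ravel()
    summary = PosteriorSummary(
        mu_median=float(np.median(mu_flat)),
        mu_ci95=tuple(np.quantile(mu_flat, [0.025, 0.975])),
        tau2_median=float(np.median(tau2_flat)),
        tau2_ci95=tuple(np.quantile(tau2_flat, [0.025, 0.975])),
        rhat=rhat,
        ess=ess,
        converged=converged,
        n_draws=mu_flat.size,
    )
    if return_draws:
        return summary, {"mu": mu_draws, "tau2": tau2_draws}
    return summary


def _run_chain(y, v, prior: PriorSpec, cfg: McmcConfig, rng: np.random.Generator):
    k = y.size
    s0sq = 100.0  # vague Normal(0, sd 10) prior for mu on the SMD scale
    mu_out = np.empty(cfg.kept)
    tau2_out = np.empty(cfg.kept)

    if prior.variant == "point_mass" and prior.params["tau2"] == 0.0:
        # degenerate limit: common-effect model, mu | y conjugate
        w = 1.0 / v
        prec = np.sum(w) + 1.0 / s0sq
        mean = np.sum(w * y) / prec
        sd = 1.0 / np.sqrt(prec)
        total = cfg.burn_in + cfg.iterations
        draws = mean + sd * rng.standard_normal(total)
        kept = draws[cfg.burn_in :][:: cfg.thin][: cfg.kept]
        return kept, np.zeros_like(kept)

    tau2 = prior.params["tau2"] if prior.variant == "point_mass" else 0.04
    phi = np.log(tau2)
    mu = float(np.sum(y / v) / np.sum(1.0 / v))
    theta = y.copy()

    total = cfg.burn_in + cfg.iterations
    kept_i = 0
    for it in range(total):
        # tau^2 first, with theta integrated out for the slice variants
        # (y_i | mu, tau^2 ~ N(mu, v_i + tau^2)): blocked update that
        # sidesteps the (theta, tau^2) funnel.
        if prior.variant == "point_mass":
            pass
        elif prior.variant == "inverse_gamma":
            # conjugate draw given theta, mu
            ss = float(np.sum((theta - mu) ** 2))
            shape = prior.params["shape"] + k / 2.0
            rate = prior.params["scale"] + ss / 2.0
            tau2 = rate / rng.gamma(shape)
            phi = np.log(tau2)
        else:

            def logpost(ph: np.ndarray) -> np.ndarray:
                denom = v[None, :] + np.exp(np.clip(ph, -60.0, 60.0))[:, None]
                marg = np.sum(np.log(denom) + (y - mu) ** 2 / denom, axis=1)
                out = -0.5 * marg + _log_prior_phi(prior, ph)
                return np.where(np.abs(ph) > 60.0, -np.inf, out)

            try:
                phi = float(slice_sample(logpost, np.array([phi]), cfg.slice_width, rng)[0])
            except SliceError as exc:
                raise RuntimeError(
                    f"sampler diverged at iteration {it} (seed {cfg.seed}): {exc}"
                ) from exc
        tau2 = np.exp(phi)
        # theta_i | rest : conjugate normal
        prec = 1.0 / v + 1.0 / tau2
        mean = (y / v + mu / tau2) / prec
        theta = mean + rng.standard_normal(k) / np.sqrt(prec)
        # mu | theta : conjugate normal
        prec_mu = k / tau2 + 1.0 / s0sq
        mu = float(np.sum(theta) / tau2 / prec_mu + rng.standard_normal() / np.sqrt(prec_mu))
        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0 and kept_i < cfg.kept:
            mu_out[kept_i] = mu
            tau2_out[kept_i] = np.exp(phi)
            kept_i += 1
    return mu_out, tau2_out
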