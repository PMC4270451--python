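"""Shared MCMC utilities: run configuration, a vectorised slice sampler,
and convergence helpers."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

__all__ = ["McmcConfig", "slice_sample", "SliceError", "gelman_rubin"]


@dataclass(frozen=True)
class McmcConfig:
    """MCMC run settings.

    Defaults follow the published analysis: 50,000 kept iterations after a
    10,000-iteration burn-in, two chains.  ``seed`` is mandatory so every
    run is reproducible.
    """

    seed: int
    chains: int = 2
    burn_in: int = 10_000
    iterations: int = 50_000
    thin: int = 1
    slice_width: float = 2.0  # step-out width on the log-variance scale

    def __post_init__(self) -> None:
        if self.iterations <= 0 or self.burn_in < 0 or self.thin < 1:
            raise ValueError("iterations > 0, burn_in >= 0, thin >= 1 required")
        if self.chains < 1:
            raise ValueError("need at least one chain")
        if self.slice_width <= 0:
            raise ValueError("slice_width must be > 0")

    @property
    def kept(self) -> int:
        return self.iterations // self.thin

    def chain_rngs(self) -> list[np.random.Generator]:
        return [np.random.default_rng(s) for s in
                np.random.SeedSequence(self.seed).spawn(self.chains)]


class SliceError(RuntimeError):
    """Slice-sampling shrinkage failed to terminate."""


def slice_sample(
    logpdf: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    width: float,
    rng: np.random.Generator,
    max_stepout: int = 100,
    max_shrink: int = 1000,
) -> np.ndarray:
    """One slice-sampling update applied componentwise to a vector state.

    ``logpdf`` must accept the full state vector and return *elementwise*
    log densities: the joint target must factorise over components given
    everything else (the usual situation inside a Gibbs sweep).  Uses
    Neal's stepping-out procedure followed by shrinkage; components
    outside the support may return ``-inf``.
    """
    x0 = np.atleast_1d(np.asarray(x0, float))
    f0 = logpdf(x0)
    if not np.all(np.isfinite(f0)):
        raise SliceError(f"slice sampler started outside support: logpdf={f0}")
    logy = f0 + np.log(rng.uniform(size=x0.shape))

    u = rng.uniform(size=x0.shape)
    left = x0 - u * width
    right = left + width

    grow = logpdf(left) > logy
    for _ in range(max_stepout):
        if not grow.any():
            break
        left = np.where(grow, left - width, left)
        grow = grow & (logpdf(left) > logy)
    grow = logpdf(right) > logy
    for _ in range(max_stepout):
        if not grow.any():
            break
        right = np.where(grow, right + width, right)
        grow = grow & (logpdf(right) > logy)

    out = x0.copy()
    done = np.zeros(x0.shape, bool)
    for _ in range(max_shrink):
        prop = left + rng.uniform(size=x0.shape) * (right - left)
        prop = np.where(done, out, prop)
        accept = logpdf(prop) >= logy
        newly = accept & ~done
        out[newly] = prop[newly]
        done |= accept
        if done.all():
            return out
        shrink = ~done
        left = np.where(shrink & (prop < x0), prop, left)
        right = np.where(shrink & (prop >= x0), prop, right)
    raise SliceError(
        f"slice shrinkage did not terminate for components {np.nonzero(~done)[0]}"
    )


def gelman_rubin(draws: np.ndarray) -> float:
    """Brooks-Gelman-Rubin potential scale reduction for one parameter.

    ``draws`` has shape (chains, iterations).  Uses arviz's rank-normalised
    split R-hat.
    """
    import arviz as az

    draws = np.asarray(draws, float)
    if draws.ndim != 2 or draws.shape[0] < 2:
        raise ValueError("need draws shaped (chains >= 2, iterations)")
    return float(az.rhat(az.convert_to_dataset(draws[None].transpose(1, 2, 0)))["x"][0])
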