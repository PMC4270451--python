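"""Hierarchical regression of log heterogeneity across many meta-analyses.

This is the package's central model.  For meta-analysis j with studies i:

    y_ij     ~ Normal(theta_ij, v_ij)                  (v_ij known)
    theta_ij ~ Normal(mu_j, tau^2_j)
    log tau^2_j = alpha + x_j' (beta, delta, gamma) + u_k(j) + eps_j
    eps_j    ~ t_5(0, sigma^2_o(j))      separate scale per outcome type
    u_k      ~ Normal(0, kappa^2_c(k))   separate scale per comparison type

with indicator covariates x_j for outcome type (reference: general
health-related), intervention-comparison type (reference: nonpharmacologic
vs any) and medical area (reference: cardiovascular).  Coefficients get
vague Normal(0, sd 10) priors; each variance component gets an
inverse-gamma(0.1, 0.1) prior.  The t_5 residual is represented as a
scale mixture of normals (eps_j | lam_j ~ N(0, sigma^2/lam_j),
lam_j ~ Gamma(5/2, 5/2)), which keeps every update conjugate except
log tau^2_j, sampled by slice sampling.

Products: ratios of between-study variances by category (exp of
coefficient draws), DIC for model comparison, and predictive draws of the
heterogeneity expected in a future meta-analysis in a given setting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import special, stats

from ._mcmc import McmcConfig, SliceError, slice_sample
from .effects import effects_for
from .schema import (
    COMPARISON_TYPES,
    MEDICAL_AREAS,
    OUTCOME_TYPES,
    MetaAnalysis,
    Setting,
)

__all__ = [
    "DesignInfo",
    "HierarchicalConfig",
    "HierarchicalDraws",
    "RatioSummary",
    "DicResult",
    "build_design",
    "fit_hierarchical",
    "fit_ig_comparator",
    "variance_ratios",
    "compute_dic",
    "draw_predictive",
]

# numerical support window for log tau^2: tau^2 outside [e^-60, e^60] is
# indistinguishable from the boundary on the SMD scale and would underflow
_PHI_LO, _PHI_HI = -60.0, 60.0

_REFERENCE = {
    "outcome_type": OUTCOME_TYPES[0],
    "comparison_type": COMPARISON_TYPES[0],
    "medical_area": MEDICAL_AREAS[0],
}
_VOCAB = {
    "outcome_type": OUTCOME_TYPES,
    "comparison_type": COMPARISON_TYPES,
    "medical_area": MEDICAL_AREAS,
}


@dataclass
class DesignInfo:
    """Design matrix and index maps for the hierarchical regression."""

    X: np.ndarray  # (J, p); column 0 is the intercept
    colnames: list
    factor_cols: dict  # factor -> {level -> column index}
    factor_references: dict  # factor -> reference level used in this fit
    ma_ids: list
    comparison_keys: list  # K pairwise-comparison identifiers
    comparison_index: np.ndarray  # (J,) -> k
    comp_type_levels: list  # observed comparison types (kappa^2 groups)
    comp_type_of_k: np.ndarray  # (K,) -> index into comp_type_levels
    outcome_levels: list  # observed outcome types (sigma^2 groups)
    outcome_index: np.ndarray  # (J,) -> index into outcome_levels

    @property
    def n_mas(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def build_design(collection: Sequence[MetaAnalysis]) -> DesignInfo:
    """Indicator design matrix with reference-category coding.

    Only categories observed in the data receive a coefficient column.
    Raises if the resulting matrix is rank deficient (e.g. a factor level
    fully confounded with the intercept because its reference is absent).
    """
    J = len(collection)
    if J < 2:
        raise ValueError("need at least 2 meta-analyses")
    counts = {
        f: {
            lvl: sum(getattr(ma.setting, f) == lvl for ma in collection)
            for lvl in _VOCAB[f]
        }
        for f in _VOCAB
    }
    references = {}
    for f in _VOCAB:
        if counts[f][_REFERENCE[f]] > 0:
            references[f] = _REFERENCE[f]
        else:
            # designated reference absent from this collection: relevel to
            # the most frequent observed category so the design stays
            # estimable; the intercept is then interpreted relative to it
            references[f] = max(counts[f], key=counts[f].get)
            warnings.warn(
                f"reference {_REFERENCE[f]!r} of {f} absent; "
                f"releveled to {references[f]!r}",
                stacklevel=2,
            )
    observed = {
        f: [lvl for lvl in _VOCAB[f]
            if counts[f][lvl] > 0 and lvl != references[f]]
        for f in _VOCAB
    }
    colnames = ["alpha"]
    factor_cols: dict = {}
    for f in ("outcome_type", "comparison_type", "medical_area"):
        factor_cols[f] = {}
        for lvl in observed[f]:
            factor_cols[f][lvl] = len(colnames)
            colnames.append(f"{f}:{lvl}")
    X = np.zeros((J, len(colnames)))
    X[:, 0] = 1.0
    for j, ma in enumerate(collection):
        for f in factor_cols:
            lvl = getattr(ma.setting, f)
            if lvl in factor_cols[f]:
                X[j, factor_cols[f][lvl]] = 1.0

    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the offending levels: columns whose removal restores full rank
        bad = [
            name
            for i, name in enumerate(colnames[1:], start=1)
            if np.linalg.matrix_rank(np.delete(X, i, axis=1)) == X.shape[1] - 1
        ]
        raise ValueError(
            "singular design matrix; confounded factor levels: "
            + ", ".join(bad or colnames)
        )

    comp_keys: list = []
    comp_of: dict = {}
    comp_index = np.empty(J, dtype=int)
    comp_type_levels = [c for c in COMPARISON_TYPES
                        if any(ma.setting.comparison_type == c for ma in collection)]
    comp_type_of_k: list = []
    for j, ma in enumerate(collection):
        key = (ma.review_id, ma.comparison_id)
        if key not in comp_of:
            comp_of[key] = len(comp_keys)
            comp_keys.append(key)
            comp_type_of_k.append(comp_type_levels.index(ma.setting.comparison_type))
        comp_index[j] = comp_of[key]

    outcome_levels = [o for o in OUTCOME_TYPES
                      if any(ma.setting.outcome_type == o for ma in collection)]
    outcome_index = np.array(
        [outcome_levels.index(ma.setting.outcome_type) for ma in collection]
    )
    return DesignInfo(
        X=X,
        colnames=colnames,
        factor_cols=factor_cols,
        factor_references=references,
        ma_ids=[ma.ma_id for ma in collection],
        comparison_keys=comp_keys,
        comparison_index=comp_index,
        comp_type_levels=comp_type_levels,
        comp_type_of_k=np.array(comp_type_of_k, dtype=int),
        outcome_levels=outcome_levels,
        outcome_index=outcome_index,
    )


@dataclass(frozen=True)
class HierarchicalConfig:
    """Priors and MCMC settings for the hierarchical fit.

    ``coef_prior_value`` with interpretation "sd" (default) reads the vague
    normal(0, 10) coefficient prior as mean 0, sd 10; "variance" and
    "precision" readings are available for sensitivity analysis.
    ``residual_df=None`` replaces the t_5 residual with a normal
    (the log-normal comparator model).
    """

    mcmc: McmcConfig
    coef_prior_value: float = 10.0
    coef_prior_interpretation: str = "sd"
    ig_shape: float = 0.1
    ig_rate: float = 0.1
    mu_prior_sd: float = 10.0
    residual_df: Optional[int] = 5
    store_study_effects: bool = False

    def __post_init__(self) -> None:
        if self.coef_prior_interpretation not in ("sd", "variance", "precision"):
            raise ValueError("interpretation must be sd | variance | precision")
        if self.coef_prior_value <= 0:
            raise ValueError("coefficient prior scale must be > 0")
        if self.residual_df is not None and self.residual_df < 1:
            raise ValueError("residual_df must be >= 1 or None")

    @property
    def coef_variance(self) -> float:
        v = self.coef_prior_value
        return {"sd": v * v, "variance": v, "precision": 1.0 / v}[
            self.coef_prior_interpretation
        ]


@dataclass
class HierarchicalDraws:
    """Posterior draws from the hierarchical regression.

    Array shapes: coefficients (chains, kept, p); u (chains, kept, K);
    kappa2 (chains, kept, C); sigma2 (chains, kept, O); tau2 and mu and
    lam (chains, kept, J); deviance (chains, kept).
    """

    design: DesignInfo
    config: HierarchicalConfig
    coef: np.ndarray
    u: np.ndarray
    kappa2: np.ndarray
    sigma2: np.ndarray
    tau2: np.ndarray
    mu: np.ndarray
    lam: np.ndarray
    deviance: np.ndarray
    theta_mean: np.ndarray
    theta: Optional[np.ndarray] = None

    @property
    def n_draws(self) -> int:
        return self.coef.shape[0] * self.coef.shape[1]

    def flat(self, arr: np.ndarray) -> np.ndarray:
        return arr.reshape(-1, *arr.shape[2:])

    def bgr(self) -> dict:
        """Brooks-Gelman-Rubin statistic for all top-level parameters."""
        from ._mcmc import gelman_rubin

        if self.coef.shape[0] < 2:
            raise ValueError("BGR diagnostics need >= 2 chains")
        out = {}
        for name, idx in zip(self.design.colnames, range(self.design.p)):
            out[name] = gelman_rubin(self.coef[:, :, idx])
        for i, c in enumerate(self.design.comp_type_levels):
            out[f"kappa2:{c}"] = gelman_rubin(np.log(self.kappa2[:, :, i]))
        for i, o in enumerate(self.design.outcome_levels):
            out[f"sigma2:{o}"] = gelman_rubin(np.log(self.sigma2[:, :, i]))
        return out


def _flatten(collection: Sequence[MetaAnalysis]):
    ys, vs, idx = [], [], []
    for j, ma in enumerate(collection):
        y, v = effects_for(ma)
        ys.append(y)
        vs.append(v)
        idx.append(np.full(y.size, j))
    return np.concatenate(ys), np.concatenate(vs), np.concatenate(idx)


def fit_hierarchical(
    collection: Sequence[MetaAnalysis], cfg: HierarchicalConfig
) -> HierarchicalDraws:
    """Fit the hierarchical log-t (or log-normal) regression by Gibbs/slice MCMC."""
    design = build_design(collection)
    y, v, ma_index = _flatten(collection)
    J, p = design.n_mas, design.p
    K = len(design.comparison_keys)
    C = len(design.comp_type_levels)
    O = len(design.outcome_levels)
    N = y.size
    X = design.X
    comp_idx = design.comparison_index
    ctype = design.comp_type_of_k
    oidx = design.outcome_index
    k_j = np.bincount(ma_index, minlength=J).astype(float)
    n_c = np.bincount(ctype, minlength=C).astype(float)
    n_o = np.bincount(oidx, minlength=O).astype(float)
    mcmc = cfg.mcmc
    vcoef = cfg.coef_variance
    df = cfg.residual_df
    s0sq = cfg.mu_prior_sd**2

    shape = (mcmc.chains, mcmc.kept)
    out = HierarchicalDraws(
        design=design,
        config=cfg,
        coef=np.empty(shape + (p,)),
        u=np.empty(shape + (K,)),
        kappa2=np.empty(shape + (C,)),
        sigma2=np.empty(shape + (O,)),
        tau2=np.empty(shape + (J,)),
        mu=np.empty(shape + (J,)),
        lam=np.empty(shape + (J,)),
        deviance=np.empty(shape),
        theta_mean=np.zeros(N),
        theta=np.empty(shape + (N,)) if cfg.store_study_effects else None,
    )

    total_kept = 0
    for c, rng in enumerate(mcmc.chain_rngs()):
        total_kept += _run_hier_chain(
            out, c, rng, y, v, ma_index, k_j, X, comp_idx, ctype, oidx,
            n_c, n_o, J, p, K, C, O, N, cfg,
        )
    out.theta_mean /= total_kept
    return out


def _run_hier_chain(
    out, chain, rng, y, v, ma_index, k_j, X, comp_idx, ctype, oidx,
    n_c, n_o, J, p, K, C, O, N, cfg: HierarchicalConfig,
):
    mcmc = cfg.mcmc
    df = cfg.residual_df
    vcoef = cfg.coef_variance
    s0sq = cfg.mu_prior_sd**2
    inv_v = 1.0 / v

    # initial state: per-MA moment estimates
    sw = np.bincount(ma_index, weights=inv_v, minlength=J)
    mu = np.bincount(ma_index, weights=y * inv_v, minlength=J) / sw
    resid2 = np.bincount(ma_index, weights=(y - mu[ma_index]) ** 2 * inv_v, minlength=J)
    phi = np.clip(np.log(np.maximum((resid2 - (k_j - 1)) / sw, 0.01)), _PHI_LO, _PHI_HI)
    theta = y.copy()
    b = np.zeros(p)
    b[0] = float(np.mean(phi))
    u = np.zeros(K)
    kappa2 = np.full(C, 0.5)
    sigma2 = np.full(O, 1.0)
    lam = np.ones(J)

    const_dev = float(np.sum(np.log(2.0 * np.pi * v)))
    kept_i = 0
    for it in range(mcmc.burn_in + mcmc.iterations):
        # --- (log tau^2_j, theta_.j) | . : blocked update.  First sample
        # log tau^2_j from its conditional with theta integrated out
        # (y_ij | mu_j, tau^2_j ~ N(mu_j, v_ij + tau^2_j)); this avoids the
        # funnel-induced stickiness of the uncollapsed pair.
        w = (lam if df is not None else 1.0) / sigma2[oidx]
        m = X @ b + u[comp_idx]
        resid_y = (y - mu[ma_index]) ** 2

        def logpost(ph: np.ndarray) -> np.ndarray:
            denom = v + np.exp(np.clip(ph, _PHI_LO, _PHI_HI))[ma_index]
            per_study = np.log(denom) + resid_y / denom
            marg = np.bincount(ma_index, weights=per_study, minlength=J)
            out = -0.5 * marg - 0.5 * w * (ph - m) ** 2
            return np.where((ph < _PHI_LO) | (ph > _PHI_HI), -np.inf, out)

        try:
            phi = slice_sample(logpost, phi, mcmc.slice_width, rng)
        except SliceError as exc:
            raise RuntimeError(
                f"hierarchical sampler diverged, chain {chain} iteration {it} "
                f"(seed {mcmc.seed}): {exc}"
            ) from exc
        tau2 = np.exp(phi)
        # --- theta_ij | . : conjugate normal (completes the block)
        prec = inv_v + 1.0 / tau2[ma_index]
        mean = (y * inv_v + (mu / tau2)[ma_index]) / prec
        theta = mean + rng.standard_normal(N) / np.sqrt(prec)
        # --- mu_j | . : conjugate normal
        sum_theta = np.bincount(ma_index, weights=theta, minlength=J)
        prec_mu = k_j / tau2 + 1.0 / s0sq
        mu = sum_theta / tau2 / prec_mu + rng.standard_normal(J) / np.sqrt(prec_mu)
        eps = phi - m
        # --- lam_j | . : conjugate gamma (t_df scale mixture)
        if df is not None:
            rate = 0.5 * (df + eps**2 / sigma2[oidx])
            lam = rng.gamma((df + 1.0) / 2.0, size=J) / rate
            w = lam / sigma2[oidx]
        # --- coefficients | . : conjugate multivariate normal
        z = phi - u[comp_idx]
        xtw = X.T * w
        P = xtw @ X + np.eye(p) / vcoef
        L = np.linalg.cholesky(P)
        bmean = np.linalg.solve(P, xtw @ z)
        b = bmean + np.linalg.solve(L.T, rng.standard_normal(p))
        # --- u_k | . : conjugate normal
        r = phi - X @ b
        sw_k = np.bincount(comp_idx, weights=w, minlength=K)
        swr_k = np.bincount(comp_idx, weights=w * r, minlength=K)
        prec_u = sw_k + 1.0 / kappa2[ctype]
        u = swr_k / prec_u + rng.standard_normal(K) / np.sqrt(prec_u)
        # --- kappa^2_c | . : conjugate inverse-gamma
        ssu = np.bincount(ctype, weights=u**2, minlength=C)
        kappa2 = (cfg.ig_rate + 0.5 * ssu) / np.maximum(
            rng.gamma(cfg.ig_shape + 0.5 * n_c, size=C), 1e-300
        )
        # --- sigma^2_o | . : conjugate inverse-gamma
        eps = phi - X @ b - u[comp_idx]
        wres = lam * eps**2 if df is not None else eps**2
        sse = np.bincount(oidx, weights=wres, minlength=O)
        sigma2 = (cfg.ig_rate + 0.5 * sse) / np.maximum(
            rng.gamma(cfg.ig_shape + 0.5 * n_o, size=O), 1e-300
        )
        # --- record
        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0 and kept_i < mcmc.kept:
            out.coef[chain, kept_i] = b
            out.u[chain, kept_i] = u
            out.kappa2[chain, kept_i] = kappa2
            out.sigma2[chain, kept_i] = sigma2
            out.tau2[chain, kept_i] = np.exp(phi)
            out.mu[chain, kept_i] = mu
            out.lam[chain, kept_i] = lam
            out.deviance[chain, kept_i] = const_dev + float(np.sum((y - theta) ** 2 * inv_v))
            out.theta_mean += theta
            if out.theta is not None:
                out.theta[chain, kept_i] = theta
            kept_i += 1
    return kept_i


@dataclass(frozen=True)
class RatioSummary:
    """Ratio of between-study variances for one category vs its reference."""

    level: str
    ratio: float
    ci95: tuple[float, float]
    reference: bool = False

    def __post_init__(self) -> None:
        if not (self.ci95[0] <= self.ratio <= self.ci95[1]) and not self.reference:
            # medians always sit inside their own central interval
            raise ValueError("ratio summary out of order")


def variance_ratios(draws: HierarchicalDraws, factor: str) -> list:
    """Per-category heterogeneity ratios: median and 95% CrI of exp(coef)."""
    if factor not in draws.design.factor_cols:
        raise KeyError(f"unknown factor {factor!r}")
    ref = draws.design.factor_references[factor]
    out = [RatioSummary(ref, 1.0, (1.0, 1.0), reference=True)]
    coef = draws.flat(draws.coef)
    for level, col in draws.design.factor_cols[factor].items():
        ratios = np.exp(coef[:, col])
        lo, med, hi = np.quantile(ratios, [0.025, 0.5, 0.975])
        out.append(RatioSummary(level, float(med), (float(lo), float(hi))))
    return out


@dataclass(frozen=True)
class DicResult:
    dic: float
    p_d: float
    mean_deviance: float


def compute_dic(draws, collection: Sequence[MetaAnalysis]) -> DicResult:
    """Deviance information criterion with study-level likelihood focus.

    DIC = Dbar + pD with pD = Dbar - D(posterior mean of theta); the
    deviance is -2 sum log N(y_ij | theta_ij, v_ij).
    """
    y, v, _ = _flatten(collection)
    dbar = float(np.mean(draws.deviance))
    d_hat = float(np.sum(np.log(2.0 * np.pi * v) + (y - draws.theta_mean) ** 2 / v))
    p_d = dbar - d_hat
    return DicResult(dic=dbar + p_d, p_d=p_d, mean_deviance=dbar)


def draw_predictive(
    draws: HierarchicalDraws,
    setting: Setting,
    n_draws: int,
    rng: Union[np.random.Generator, int, None] = None,
) -> np.ndarray:
    """Predictive sample of tau^2 for a future meta-analysis in ``setting``.

    For each posterior draw t: log tau^2_new = alpha + x_s' coef +
    u_new + eps_new with u_new ~ N(0, kappa^2_c^(t)) and eps_new ~
    t_5(0, sigma^2_o^(t)) (normal when the model was fitted with normal
    residuals).  Posterior draws are resampled with replacement to length
    ``n_draws``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    design = draws.design
    x = np.zeros(design.p)
    x[0] = 1.0
    for f in ("outcome_type", "comparison_type", "medical_area"):
        lvl = getattr(setting, f)
        if lvl == design.factor_references[f]:
            continue
        if lvl not in design.factor_cols[f]:
            raise KeyError(f"category {lvl!r} of {f} was not present in the fit")
    # fill after validation so errors fire before any randomness is consumed
    for f in ("outcome_type", "comparison_type", "medical_area"):
        lvl = getattr(setting, f)
        if lvl in design.factor_cols[f]:
            x[design.factor_cols[f][lvl]] = 1.0
    if setting.comparison_type not in design.comp_type_levels:
        raise KeyError(f"comparison type {setting.comparison_type!r} not in fit")
    if setting.outcome_type not in design.outcome_levels:
        raise KeyError(f"outcome type {setting.outcome_type!r} not in fit")
    c = design.comp_type_levels.index(setting.comparison_type)
    o = design.outcome_levels.index(setting.outcome_type)

    coef = draws.flat(draws.coef)
    kappa2 = draws.flat(draws.kappa2)[:, c]
    sigma2 = draws.flat(draws.sigma2)[:, o]
    idx = rng.integers(0, coef.shape[0], size=n_draws)
    lin = coef[idx] @ x
    u_new = rng.standard_normal(n_draws) * np.sqrt(kappa2[idx])
    df = draws.config.residual_df
    if df is not None:
        eps_new = rng.standard_t(df, size=n_draws) * np.sqrt(sigma2[idx])
    else:
        eps_new = rng.standard_normal(n_draws) * np.sqrt(sigma2[idx])
    return np.exp(lin + u_new + eps_new)


@dataclass
class IgComparatorDraws:
    """Draws from the inverse-gamma comparator model for tau^2.

    tau^2_j ~ InverseGamma(a, b) shared across meta-analyses, with the
    same study-level likelihood as the regression model; used for DIC
    comparison only.
    """

    a: np.ndarray  # (chains, kept)
    b: np.ndarray
    tau2: np.ndarray  # (chains, kept, J)
    deviance: np.ndarray
    theta_mean: np.ndarray


def fit_ig_comparator(
    collection: Sequence[MetaAnalysis], cfg: HierarchicalConfig
) -> IgComparatorDraws:
    """Fit the comparator model with inverse-gamma distributed tau^2_j."""
    y, v, ma_index = _flatten(collection)
    J = len(collection)
    N = y.size
    mcmc = cfg.mcmc
    s0sq = cfg.mu_prior_sd**2
    inv_v = 1.0 / v
    k_j = np.bincount(ma_index, minlength=J).astype(float)

    shape = (mcmc.chains, mcmc.kept)
    out = IgComparatorDraws(
        a=np.empty(shape),
        b=np.empty(shape),
        tau2=np.empty(shape + (J,)),
        deviance=np.empty(shape),
        theta_mean=np.zeros(N),
    )
    const_dev = float(np.sum(np.log(2.0 * np.pi * v)))
    total_kept = 0
    for c, rng in enumerate(mcmc.chain_rngs()):
        a, b = 1.0, 0.1
        tau2 = np.full(J, 0.05)
        mu = np.bincount(ma_index, weights=y * inv_v, minlength=J) / np.bincount(
            ma_index, weights=inv_v, minlength=J
        )
        phi = np.log(tau2)
        kept_i = 0
        for it in range(mcmc.burn_in + mcmc.iterations):
            # blocked (log tau^2_j, theta) update, as in the regression model
            resid_y = (y - mu[ma_index]) ** 2

            def logpost_phi(ph: np.ndarray) -> np.ndarray:
                phc = np.clip(ph, _PHI_LO, _PHI_HI)
                denom = v + np.exp(phc)[ma_index]
                per_study = np.log(denom) + resid_y / denom
                marg = np.bincount(ma_index, weights=per_study, minlength=J)
                out = -0.5 * marg - a * ph - b * np.exp(-phc)
                return np.where((ph < _PHI_LO) | (ph > _PHI_HI), -np.inf, out)

            phi = slice_sample(logpost_phi, phi, mcmc.slice_width, rng)
            tau2 = np.exp(phi)
            prec = inv_v + 1.0 / tau2[ma_index]
            mean = (y * inv_v + (mu / tau2)[ma_index]) / prec
            theta = mean + rng.standard_normal(N) / np.sqrt(prec)
            sum_theta = np.bincount(ma_index, weights=theta, minlength=J)
            prec_mu = k_j / tau2 + 1.0 / s0sq
            mu = sum_theta / tau2 / prec_mu + rng.standard_normal(J) / np.sqrt(prec_mu)
            # b | tau^2, a : conjugate gamma with Gamma(0.1, 0.1) prior
            b = rng.gamma(0.1 + J * a) / (0.1 + float(np.sum(1.0 / tau2)))
            # a | tau^2, b : slice on log a, Gamma(0.1, 0.1) prior
            slt = float(np.sum(np.log(tau2)))

            def logpost_a(psi: np.ndarray) -> np.ndarray:
                av = np.exp(psi)
                return (
                    J * (av * np.log(b) - special.gammaln(av))
                    - av * slt
                    + 0.1 * psi  # Gamma(0.1,.) prior density term a^(0.1-1) + Jacobian a
                    - 0.1 * av
                )

            a = float(np.exp(slice_sample(logpost_a, np.array([np.log(a)]), 1.0, rng)[0]))
            if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0 and kept_i < mcmc.kept:
                out.a[c, kept_i] = a
                out.b[c, kept_i] = b
                out.tau2[c, kept_i] = tau2
                out.deviance[c, kept_i] = const_dev + float(np.sum((y - theta) ** 2 * inv_v))
                out.theta_mean += theta
                kept_i += 1
        total_kept += kept_i
    out.theta_mean /= total_kept
    return out
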