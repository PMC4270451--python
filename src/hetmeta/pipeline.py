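"""End-to-end orchestration: data -> classical descriptives -> hierarchical
fit -> variance ratios & DIC -> predictive priors -> example Bayesian
re-analysis, driven by a YAML config, with a reproducibility manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from ._mcmc import McmcConfig
from .bayes import PriorSpec, fit_bayes_rema, make_prior
from .classical import classical_meta_analysis
from .effects import effects_for
from .hierarchy import (
    HierarchicalConfig,
    compute_dic,
    draw_predictive,
    fit_hierarchical,
    variance_ratios,
)
from .priors import fit_inverse_gamma, fit_log_t, published_prior
from .schema import Setting, read_study_table, write_study_table
from .simulate import default_config, generate_dataset

__all__ = ["PipelineError", "RunManifest", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunManifest:
    """Record of one pipeline run; reruns with equal manifests reproduce
    outputs exactly (all randomness is seed-derived)."""

    config_hash: str
    seed: int
    version: str
    out_dir: str
    stages: dict = field(default_factory=dict)
    converged: Optional[bool] = None
    bgr_max: Optional[float] = None

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


_DEFAULTS = {
    "seed": 0,
    "out_dir": "hetmeta-run",
    "simulate": {"n_meta_analyses": 200},
    "input_csv": None,
    # reduced-scale MCMC for desk runs; full_scale switches to 10k/50k
    "mcmc": {"chains": 2, "burn_in": 2000, "iterations": 2000, "thin": 1},
    "full_scale": False,
    "allow_nonconverged": False,
    # "reference" = the fitted model's reference setting; entries may also
    # be {outcome_type, comparison_type, medical_area} dicts
    "predict": ["reference"],
    "example": {"ma_id": None, "priors": ["uniform_tau(5)", "published"]},
}


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config, "r", encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
    elif isinstance(config, dict):
        user = dict(config)
    else:
        raise PipelineError(f"stage config: cannot read configuration from {config!r}")
    cfg = json.loads(json.dumps(_DEFAULTS))  # deep copy
    for key, value in user.items():
        if key not in cfg:
            raise PipelineError(f"stage config: unknown configuration key {key!r}")
        if isinstance(cfg[key], dict) and isinstance(value, dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def run_pipeline(config) -> RunManifest:
    """Execute all stages in order and write outputs plus a manifest.

    ``config`` is a YAML path or a dict.  Fails fast on non-convergence
    (any BGR statistic >= 1.05) unless ``allow_nonconverged`` is set.
    """
    cfg = _load_config(config)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    canonical = json.dumps(cfg, sort_keys=True).encode()
    manifest = RunManifest(
        config_hash=hashlib.sha256(canonical).hexdigest(),
        seed=int(cfg["seed"]),
        version=_version(),
        out_dir=str(out),
    )
    seeds = np.random.SeedSequence(cfg["seed"]).generate_state(8) % (2**31)

    # --- stage: data --------------------------------------------------
    try:
        if cfg["input_csv"]:
            collection, report = read_study_table(cfg["input_csv"])
            truth = None
        else:
            sim_cfg = default_config(seed=int(seeds[0]), **cfg["simulate"])
            ds = generate_dataset(sim_cfg)
            collection, report, truth = ds.collection, ds.report, ds.truth
            ds.to_csv(out / "dataset.csv")
            ds.truth_to_csv(out / "truth.csv")
        write_study_table(collection, out / "analysis_set.csv")
        manifest.stages["data"] = {
            "outputs": ["analysis_set.csv"],
            "n_meta_analyses": len(collection),
            "n_studies": report.n_retained,
            "exclusions": dataclasses.asdict(report),
        }
    except Exception as exc:
        raise PipelineError(f"stage data: {exc}") from exc

    # --- stage: classical ---------------------------------------------
    try:
        rows = []
        for ma in collection:
            r = classical_meta_analysis(effects_for(ma))
            rows.append(
                {
                    "ma_id": ma.ma_id,
                    "k": r.k,
                    "q": r.q,
                    "tau2_dl": r.tau2_dl,
                    "tau2_lo": r.tau2_ci[0],
                    "tau2_hi": r.tau2_ci[1],
                    "mu_hat": r.mu_hat,
                    "mu_lo": r.mu_ci[0],
                    "mu_hi": r.mu_ci[1],
                    "i2": round(r.i2, 1),
                }
            )
        classical = pd.DataFrame(rows)
        classical.to_csv(out / "classical.tsv", sep="\t", index=False)
        nonzero = classical.tau2_dl[classical.tau2_dl > 0]
        manifest.stages["classical"] = {
            "outputs": ["classical.tsv"],
            "prop_tau2_zero": float((classical.tau2_dl == 0).mean()),
            "median_nonzero_tau2": float(nonzero.median()) if len(nonzero) else None,
        }
    except Exception as exc:
        raise PipelineError(f"stage classical: {exc}") from exc

    # --- stage: hierarchical fit --------------------------------------
    try:
        m = cfg["mcmc"]
        if cfg["full_scale"]:
            m = {**m, "burn_in": 10_000, "iterations": 50_000}
        mcmc = McmcConfig(
            seed=int(seeds[1]),
            chains=int(m["chains"]),
            burn_in=int(m["burn_in"]),
            iterations=int(m["iterations"]),
            thin=int(m["thin"]),
        )
        hier_cfg = HierarchicalConfig(mcmc=mcmc)
        draws = fit_hierarchical(collection, hier_cfg)
        bgr = draws.bgr() if mcmc.chains >= 2 else {}
        if bgr:
            pd.Series(bgr, name="bgr").rename_axis("parameter").to_csv(
                out / "bgr.tsv", sep="\t"
            )
        bgr_max = max(bgr.values()) if bgr else None
        manifest.bgr_max = bgr_max
        manifest.converged = bool(bgr) and bgr_max < 1.05
        manifest.stages["hierarchical"] = {
            "outputs": ["bgr.tsv"] if bgr else [],
            "n_parameters": draws.design.p,
            "bgr_max": bgr_max,
        }
        if bgr and bgr_max >= 1.05 and not cfg["allow_nonconverged"]:
            raise RuntimeError(
                f"chains not converged (max BGR = {bgr_max:.3f} >= 1.05); "
                "increase iterations or set allow_nonconverged"
            )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage hierarchical: {exc}") from exc

    # --- stage: ratios & DIC ------------------------------------------
    try:
        ratio_rows = []
        for factor in ("outcome_type", "comparison_type", "medical_area"):
            for r in variance_ratios(draws, factor):
                ratio_rows.append(
                    {
                        "factor": factor,
                        "level": r.level,
                        "ratio": r.ratio,
                        "ci_lo": r.ci95[0],
                        "ci_hi": r.ci95[1],
                        "reference": r.reference,
                    }
                )
        pd.DataFrame(ratio_rows).to_csv(out / "ratios.tsv", sep="\t", index=False)
        dic = compute_dic(draws, collection)
        with open(out / "dic.json", "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(dic), fh, indent=2)
        manifest.stages["ratios_dic"] = {
            "outputs": ["ratios.tsv", "dic.json"],
            "dic": dic.dic,
        }
    except Exception as exc:
        raise PipelineError(f"stage ratios_dic: {exc}") from exc

    # --- stage: predictive priors -------------------------------------
    try:
        prior_rows = []
        rng = np.random.default_rng(int(seeds[2]))
        for spec in cfg["predict"]:
            if spec == "reference":
                refs = draws.design.factor_references
                spec = {f: refs[f] for f in
                        ("outcome_type", "comparison_type", "medical_area")}
            setting = Setting(**spec)
            sample = draw_predictive(draws, setting, n_draws=50_000, rng=rng)
            lt = fit_log_t(sample)
            ig = fit_inverse_gamma(sample)
            prior_rows.append(
                {
                    **spec,
                    "log_t_location": lt.location,
                    "log_t_scale": lt.scale,
                    "log_t_df": lt.df,
                    "ig_shape": ig.shape,
                    "ig_scale": ig.scale,
                    "tau2_median": float(np.median(sample)),
                }
            )
        pd.DataFrame(prior_rows).to_csv(out / "priors.tsv", sep="\t", index=False)
        manifest.stages["predictive_priors"] = {
            "outputs": ["priors.tsv"],
            "n_settings": len(prior_rows),
        }
    except Exception as exc:
        raise PipelineError(f"stage predictive_priors: {exc}") from exc

    # --- stage: example re-analysis -----------------------------------
    try:
        ma_id = cfg["example"]["ma_id"]
        if ma_id is None:
            ma = max(collection, key=len)
        else:
            matches = [m_ for m_ in collection if m_.ma_id == ma_id]
            if not matches:
                raise KeyError(f"meta-analysis {ma_id!r} not found")
            ma = matches[0]
        example_rows = []
        conv = classical_meta_analysis(effects_for(ma))
        example_rows.append(
            {
                "analysis": "conventional (DerSimonian-Laird)",
                "mu": conv.mu_hat,
                "mu_lo": conv.mu_ci[0],
                "mu_hi": conv.mu_ci[1],
                "tau2": conv.tau2_dl,
                "tau2_lo": conv.tau2_ci[0],
                "tau2_hi": conv.tau2_ci[1],
            }
        )
        for name in cfg["example"]["priors"]:
            prior = (
                make_prior(published_prior(ma.setting))
                if name == "published"
                else make_prior(name)
            )
            post = fit_bayes_rema(
                ma,
                prior,
                McmcConfig(
                    seed=int(seeds[3]),
                    chains=2,
                    burn_in=int(cfg["mcmc"]["burn_in"]),
                    iterations=int(cfg["mcmc"]["iterations"]),
                ),
            )
            example_rows.append(
                {
                    "analysis": f"bayesian, prior {name}",
                    "mu": post.mu_median,
                    "mu_lo": post.mu_ci95[0],
                    "mu_hi": post.mu_ci95[1],
                    "tau2": post.tau2_median,
                    "tau2_lo": post.tau2_ci95[0],
                    "tau2_hi": post.tau2_ci95[1],
                }
            )
        pd.DataFrame(example_rows).to_csv(out / "example.tsv", sep="\t", index=False)
        manifest.stages["example"] = {"outputs": ["example.tsv"], "ma_id": ma.ma_id}
    except Exception as exc:
        raise PipelineError(f"stage example: {exc}") from exc

    manifest.save(out / "manifest.json")
    return manifest


def _version() -> str:
    from . import __version__

    return __version__
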