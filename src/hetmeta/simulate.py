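"""Synthetic CDSR-like collections of continuous-outcome meta-analyses.

The generator emulates the hierarchical structure of the Cochrane extract
the published priors were derived from — reviews containing pairwise
comparisons containing meta-analyses containing two-arm studies — with
marginal frequencies of settings and structure summaries (median 3
studies per meta-analysis, IQR 2-5; median total sample size 61,
IQR 33-140) matching the printed descriptives.  Heterogeneity follows the
same generative law the hierarchical model assumes:

    log tau^2_j = alpha + x_j' coefs + u_k + sigma_o * t_5 draw,
    u_k ~ N(0, kappa^2_c),

so every pipeline stage can be tested against known generating truth.
Arm-level summaries (n, mean, sd) are simulated so the study's observed
SMD is a noisy estimate of its true effect theta_ij, and standard
deviations go missing at the configured rate, exercising the load-time
filtering rules end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .schema import (
    COMPARISON_TYPES,
    MEDICAL_AREAS,
    OUTCOME_TYPES,
    ArmSummary,
    LoadReport,
    MetaAnalysis,
    Setting,
    StudyRecord,
    apply_filters,
    write_study_table,
)
from .schema import _RawRow  # shared raw-row container

__all__ = ["SyntheticConfig", "SyntheticTruth", "SyntheticDataset",
           "default_config", "generate_dataset"]

# Observed marginal frequencies (percent) of meta-analysis settings in the
# source database; renormalised to probability vectors.
_OUTCOME_PCT = (20.0, 3.0, 7.0, 3.0, 38.0, 8.0, 16.0, 5.0)
_COMPARISON_PCT = (45.0, 37.0, 19.0)
_AREA_PCT = (7.0, 0.4, 11.0, 18.0, 2.0, 14.0, 10.0, 4.0, 21.0, 5.0, 8.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generating law for a synthetic collection.

    Structure laws (chosen to match the printed structure summaries):
    comparisons per review 1 + Geometric, meta-analyses per comparison
    1 + Geometric, studies per meta-analysis 2 + Geometric (median 3,
    IQR 2-5), total sample size lognormal (median 61, IQR ~33-140) split
    roughly 1:1 with at least 4 participants per arm.

    Truth parameters: alpha is the intercept of log tau^2; coefficient
    dicts map "factor:level" to a contrast on the log-variance scale;
    kappa2 / sigma2 are the comparison- and outcome-level variance
    components (shared across categories by default, calibrated so the
    marginal spread of log tau^2 matches the published general-setting
    predictive scale of 2.59).
    """

    seed: int = 0
    n_reviews: Optional[int] = None
    n_meta_analyses: Optional[int] = 500
    outcome_freq: tuple = tuple(p / sum(_OUTCOME_PCT) for p in _OUTCOME_PCT)
    comparison_freq: tuple = tuple(p / sum(_COMPARISON_PCT) for p in _COMPARISON_PCT)
    area_freq: tuple = tuple(p / sum(_AREA_PCT) for p in _AREA_PCT)
    comparisons_per_review_p: float = 0.46
    mas_per_comparison_p: float = 0.30
    studies_per_ma_p: float = 0.30
    min_studies: int = 2
    total_n_log_median: float = float(np.log(61.0))
    total_n_log_sd: float = 1.07
    min_arm_n: int = 4
    alpha: float = -3.4
    coefficients: dict = field(default_factory=dict)
    kappa2: float = 0.6
    sigma2: float = 3.6
    residual_df: int = 5
    mu_sd: float = 0.4
    missing_sd_rate: float = 0.024

    def __post_init__(self) -> None:
        for freq, size in ((self.outcome_freq, 8), (self.comparison_freq, 3),
                           (self.area_freq, 11)):
            if len(freq) != size:
                raise ValueError(f"frequency vector must have length {size}")
            if abs(sum(freq) - 1.0) > 1e-9 or min(freq) < 0:
                raise ValueError("frequencies must be nonnegative and sum to 1")
        if self.min_studies < 2:
            raise ValueError("studies-per-MA law must admit a minimum of 2")
        if (self.n_reviews is None) == (self.n_meta_analyses is None):
            raise ValueError("give exactly one of n_reviews / n_meta_analyses")
        if not (0 <= self.missing_sd_rate < 1):
            raise ValueError("missing_sd_rate must be in [0, 1)")
        if self.kappa2 < 0 or self.sigma2 < 0:
            raise ValueError("variance components must be >= 0")


def default_config(**overrides) -> SyntheticConfig:
    """Default configuration matching the published marginal summaries."""
    return SyntheticConfig(**overrides)


@dataclass
class SyntheticTruth:
    """Generating values recorded for recovery tests (pre-filter)."""

    table: pd.DataFrame  # one row per generated meta-analysis
    study_effects: pd.DataFrame  # one row per generated study: ma_id, theta
    config: SyntheticConfig

    def tau2_of(self, ma_id: str) -> float:
        return float(self.table.set_index("ma_id").loc[ma_id, "tau2"])


@dataclass
class SyntheticDataset:
    """A generated dataset: filtered collection + truth + raw rows."""

    collection: list
    truth: SyntheticTruth
    report: LoadReport
    _raw_rows: list

    def to_csv(self, path) -> None:
        """Write the raw (pre-filter) study table; reading it back applies
        the same filters and reproduces ``collection``."""
        import csv as _csv

        from .schema import CSV_COLUMNS, _format_float

        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = _csv.writer(fh)
            writer.writerow(CSV_COLUMNS)
            for row in self._raw_rows:
                s = row.study
                o, c, a = row.setting_labels
                writer.writerow([
                    s.review_id, s.comparison_id, s.ma_id, s.study_id,
                    s.subgroup_index,
                    s.arm1.n, _format_float(s.arm1.mean), _format_float(s.arm1.sd),
                    s.arm2.n, _format_float(s.arm2.mean), _format_float(s.arm2.sd),
                    o, c, a,
                ])

    def truth_to_csv(self, path) -> None:
        self.truth.table.to_csv(path, index=False)


def _contrast(config: SyntheticConfig, setting: Setting) -> float:
    total = 0.0
    for factor, vocab in (("outcome_type", OUTCOME_TYPES),
                          ("comparison_type", COMPARISON_TYPES),
                          ("medical_area", MEDICAL_AREAS)):
        lvl = getattr(setting, factor)
        total += config.coefficients.get(f"{factor}:{lvl}", 0.0)
    return total


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a synthetic collection with known truth; reproducible by seed."""
    rng = np.random.default_rng(config.seed)
    raw_rows: list = []
    truth_rows: list = []
    effect_rows: list = []

    n_reviews = config.n_reviews if config.n_reviews is not None else np.inf
    target_mas = config.n_meta_analyses if config.n_meta_analyses is not None else np.inf
    n_mas = 0
    review = 0
    while review < n_reviews and n_mas < target_mas:
        review += 1
        review_id = f"R{review:05d}"
        area = MEDICAL_AREAS[rng.choice(11, p=np.asarray(config.area_freq))]
        n_comp = int(rng.geometric(config.comparisons_per_review_p))
        for comp in range(1, n_comp + 1):
            comparison_id = f"C{comp:02d}"
            ctype = COMPARISON_TYPES[rng.choice(3, p=np.asarray(config.comparison_freq))]
            u_k = rng.normal(0.0, np.sqrt(config.kappa2))
            n_ma = int(rng.geometric(config.mas_per_comparison_p))
            for m in range(1, n_ma + 1):
                n_mas += 1
                ma_id = f"{review_id}.{comparison_id}.M{m:02d}"
                outcome = OUTCOME_TYPES[rng.choice(8, p=np.asarray(config.outcome_freq))]
                setting = Setting(outcome, ctype, area)
                eps = np.sqrt(config.sigma2) * rng.standard_t(config.residual_df)
                log_tau2 = config.alpha + _contrast(config, setting) + u_k + eps
                tau2 = float(np.exp(log_tau2))
                mu_j = rng.normal(0.0, config.mu_sd)
                n_studies = config.min_studies + rng.geometric(config.studies_per_ma_p) - 1
                truth_rows.append({
                    "review_id": review_id, "comparison_id": comparison_id,
                    "ma_id": ma_id, "outcome_type": outcome,
                    "comparison_type": ctype, "medical_area": area,
                    "u_k": u_k, "log_tau2": log_tau2, "tau2": tau2,
                    "mu": mu_j, "n_studies": n_studies,
                })
                for s in range(1, n_studies + 1):
                    theta = rng.normal(mu_j, np.sqrt(tau2))
                    total_n = int(np.round(np.exp(
                        config.total_n_log_median
                        + config.total_n_log_sd * rng.standard_normal()
                    )))
                    total_n = max(total_n, 2 * config.min_arm_n)
                    n1 = int(np.clip(rng.binomial(total_n, 0.5),
                                     config.min_arm_n, total_n - config.min_arm_n))
                    n2 = total_n - n1
                    # unit true SD in both arms; sampled SDs chi^2-scaled
                    sd1 = float(np.sqrt(rng.chisquare(n1 - 1) / (n1 - 1)))
                    sd2 = float(np.sqrt(rng.chisquare(n2 - 1) / (n2 - 1)))
                    mean1 = float(rng.normal(theta, 1.0 / np.sqrt(n1)))
                    mean2 = float(rng.normal(0.0, 1.0 / np.sqrt(n2)))
                    if rng.uniform() < config.missing_sd_rate:
                        if rng.uniform() < 0.5:
                            sd1 = None
                        else:
                            sd2 = None
                    study = StudyRecord(
                        review_id=review_id, comparison_id=comparison_id,
                        ma_id=ma_id, study_id=f"{ma_id}.S{s:02d}",
                        subgroup_index=1,
                        arm1=ArmSummary(n=n1, mean=mean1, sd=sd1),
                        arm2=ArmSummary(n=n2, mean=mean2, sd=sd2),
                    )
                    raw_rows.append(_RawRow(study, (outcome, ctype, area)))
                    effect_rows.append({"ma_id": ma_id, "study_id": study.study_id,
                                        "theta": theta})
            if n_mas >= target_mas:
                break

    report = LoadReport(n_rows=len(raw_rows))
    collection = apply_filters(raw_rows, report)
    report.check()
    truth = SyntheticTruth(
        table=pd.DataFrame(truth_rows),
        study_effects=pd.DataFrame(effect_rows),
        config=config,
    )
    return SyntheticDataset(collection=collection, truth=truth,
                            report=report, _raw_rows=raw_rows)
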