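"""Standardized mean differences and their within-study variances.

The default effect measure is Hedges' adjusted g with the sampling-variance
formula used by Cochrane's RevMan software,

    g = J * (m1 - m2) / s_p,      J = 1 - 3 / (4(n1+n2-2) - 1),
    s_p^2 = [(n1-1) sd1^2 + (n2-1) sd2^2] / (n1 + n2 - 2),
    var(g) = (n1+n2)/(n1 n2) + g^2 / (2 (n1+n2-3.94)).

Cohen's unadjusted d (J = 1, denominator 2(n1+n2-2) in the variance) is
available behind ``bias_correction=False`` for comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .schema import MetaAnalysis, StudyRecord

__all__ = ["EffectEstimate", "DegenerateStudyError", "hedges_g", "effects_for"]


class DegenerateStudyError(ValueError):
    """Pooled standard deviation is zero; the SMD is undefined."""


@dataclass(frozen=True)
class EffectEstimate:
    """An observed SMD and its within-study sampling variance."""

    y: float
    v: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.y):
            raise ValueError(f"SMD must be finite, got {self.y}")
        if not (self.v > 0):
            raise ValueError(f"within-study variance must be > 0, got {self.v}")


def hedges_g(study: StudyRecord, *, bias_correction: bool = True) -> EffectEstimate:
    """Standardized mean difference (arm1 minus arm2) for a two-arm study.

    Parameters
    ----------
    study
        Study with both arms' n, mean and sd present (n >= 2, sd > 0).
    bias_correction
        Apply Hedges' small-sample correction J (default).  With
        ``False``, Cohen's d and its classic variance are returned.

    Returns
    -------
    EffectEstimate
        y (unitless) and its variance v.
    """
    a1, a2 = study.arm1, study.arm2
    for arm in (a1, a2):
        if arm.n < 2:
            raise ValueError(
                f"study {study.study_id!r}: arm n must be >= 2 for an SMD, got {arm.n}"
            )
        if arm.sd is None:
            raise ValueError(f"study {study.study_id!r}: missing sd")
    n1, n2 = a1.n, a2.n
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * a1.sd**2 + (n2 - 1) * a2.sd**2) / df
    if sp2 <= 0:
        raise DegenerateStudyError(
            f"study {study.study_id!r}: pooled standard deviation is zero"
        )
    d = (a1.mean - a2.mean) / math.sqrt(sp2)
    if bias_correction:
        j = 1.0 - 3.0 / (4.0 * df - 1.0)
        y = j * d
        v = (n1 + n2) / (n1 * n2) + y**2 / (2.0 * (n1 + n2 - 3.94))
    else:
        y = d
        v = (n1 + n2) / (n1 * n2) + y**2 / (2.0 * df)
    return EffectEstimate(y=y, v=v)


def effects_for(
    ma: MetaAnalysis, *, bias_correction: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Vectors (y, v) of study effects for one meta-analysis."""
    estimates = [hedges_g(s, bias_correction=bias_correction) for s in ma.studies]
    return (
        np.array([e.y for e in estimates]),
        np.array([e.v for e in estimates]),
    )


def as_arrays(effects: Sequence[EffectEstimate] | tuple[np.ndarray, np.ndarray]):
    """Normalise a list of EffectEstimate or an (y, v) pair to arrays."""
    if isinstance(effects, tuple) and len(effects) == 2:
        y, v = np.asarray(effects[0], float), np.asarray(effects[1], float)
    else:
        y = np.array([e.y for e in effects], float)
        v = np.array([e.v for e in effects], float)
    if y.shape != v.shape:
        raise ValueError("y and v must have matching shapes")
    if np.any(v <= 0):
        raise ValueError("all within-study variances must be > 0")
    return y, v
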