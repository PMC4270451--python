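"""Data model and I/O for hierarchical collections of continuous-outcome meta-analyses.

The unit of analysis is a meta-analysis: a set of two-arm studies, each
summarised by per-arm sample size, mean and standard deviation, nested as
review -> pairwise comparison -> meta-analysis -> study.  Every meta-analysis
carries a *setting*: its outcome type (8 categories), intervention-comparison
type (3 categories) and medical area (11 categories).

Loading applies the inclusion rules used throughout the package, in a fixed
order so every dropped row is attributed to exactly one rule:

1. studies with a missing or zero standard deviation in either arm, or an
   arm with fewer than 2 participants, are removed;
2. duplicated (meta-analysis, study) pairs beyond the first occurrence
   (studies repeated across non-exclusive subgroups) are removed;
3. meta-analyses left with fewer than two studies are removed;
4. meta-analyses whose outcome type is "other" are removed.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

__all__ = [
    "OUTCOME_TYPES",
    "COMPARISON_TYPES",
    "MEDICAL_AREAS",
    "CSV_COLUMNS",
    "ArmSummary",
    "StudyRecord",
    "Setting",
    "MetaAnalysis",
    "LoadReport",
    "SchemaError",
    "read_study_table",
    "write_study_table",
    "apply_filters",
]

#: Outcome-type vocabulary (closed); the first entry is the reference
#: category of the hierarchical regression (general health-related
#: outcomes: general physical health, adverse events, pain, quality of
#: life/functioning).
OUTCOME_TYPES: tuple[str, ...] = (
    "general_health",
    "obstetric",
    "resource_use",
    "structure",
    "signs_symptoms",
    "mental_health",
    "biological_marker",
    "subjective",
)

#: Intervention-comparison vocabulary; nonpharmacologic-vs-any is the
#: reference category.
COMPARISON_TYPES: tuple[str, ...] = (
    "nonpharm_vs_any",
    "pharm_vs_placebo",
    "pharm_vs_pharm",
)

#: Medical-area vocabulary; cardiovascular is the reference category.
#: "other" here is a valid area label (unlike the outcome type "other",
#: which is excluded at load).
MEDICAL_AREAS: tuple[str, ...] = (
    "cardiovascular",
    "cancer",
    "cns_musculoskeletal",
    "digestive",
    "infectious",
    "mental_behavioural",
    "obstetrics_gynaecology",
    "pathological",
    "respiratory",
    "urogenital",
    "other",
)

#: Outcome label excluded at load time.
OTHER_OUTCOME = "other"

CSV_COLUMNS = [
    "review_id",
    "comparison_id",
    "ma_id",
    "study_id",
    "subgroup",
    "n1",
    "mean1",
    "sd1",
    "n2",
    "mean2",
    "sd2",
    "outcome_type",
    "comparison_type",
    "medical_area",
]


class SchemaError(ValueError):
    """Malformed input table or invalid collection."""


@dataclass(frozen=True)
class ArmSummary:
    """Summary data for one intervention arm of a study."""

    n: int
    mean: float
    sd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise SchemaError(f"arm sample size must be >= 1, got {self.n}")
        if self.sd is not None and self.sd < 0:
            raise SchemaError(f"arm sd must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class StudyRecord:
    """One two-arm study; arm1 is the experimental arm by convention."""

    review_id: str
    comparison_id: str
    ma_id: str
    study_id: str
    arm1: ArmSummary
    arm2: ArmSummary
    subgroup_index: int = 1

    def __post_init__(self) -> None:
        for name in ("review_id", "comparison_id", "ma_id", "study_id"):
            if not getattr(self, name):
                raise SchemaError(f"{name} must be non-empty")

    @property
    def usable(self) -> bool:
        """True if both arms allow a standardized mean difference."""
        return all(
            a.sd is not None and a.sd > 0 and a.n >= 2 for a in (self.arm1, self.arm2)
        )


@dataclass(frozen=True)
class Setting:
    """Meta-analysis setting: the triple indexing the prior library."""

    outcome_type: str
    comparison_type: str
    medical_area: str

    def __post_init__(self) -> None:
        if self.outcome_type not in OUTCOME_TYPES:
            raise SchemaError(f"unknown outcome_type {self.outcome_type!r}")
        if self.comparison_type not in COMPARISON_TYPES:
            raise SchemaError(f"unknown comparison_type {self.comparison_type!r}")
        if self.medical_area not in MEDICAL_AREAS:
            raise SchemaError(f"unknown medical_area {self.medical_area!r}")


@dataclass(frozen=True)
class MetaAnalysis:
    """A filtered meta-analysis: >= 2 usable studies sharing one setting."""

    review_id: str
    comparison_id: str
    ma_id: str
    setting: Setting
    studies: tuple[StudyRecord, ...]

    def __post_init__(self) -> None:
        if len(self.studies) < 2:
            raise SchemaError(
                f"meta-analysis {self.ma_id!r} has {len(self.studies)} studies; need >= 2"
            )
        ids = [s.study_id for s in self.studies]
        if len(set(ids)) != len(ids):
            raise SchemaError(f"duplicated study_id within meta-analysis {self.ma_id!r}")

    def __len__(self) -> int:
        return len(self.studies)


@dataclass
class LoadReport:
    """Accounting of exclusions applied while assembling a collection.

    ``n_rows == n_retained + n_missing_sd + n_small_arm + n_duplicate +
    n_undersized_studies + n_other_outcome_studies + n_skipped`` always holds;
    each dropped study is attributed to exactly one rule, in rule order.
    """

    n_rows: int = 0
    n_retained: int = 0
    n_missing_sd: int = 0
    n_small_arm: int = 0
    n_duplicate: int = 0
    n_undersized_studies: int = 0
    n_undersized_mas: int = 0
    n_other_outcome_studies: int = 0
    n_other_outcome_mas: int = 0
    n_skipped: int = 0

    @property
    def empty(self) -> bool:
        return self.n_rows == self.n_retained

    def check(self) -> None:
        total = (
            self.n_retained
            + self.n_missing_sd
            + self.n_small_arm
            + self.n_duplicate
            + self.n_undersized_studies
            + self.n_other_outcome_studies
            + self.n_skipped
        )
        if total != self.n_rows:
            raise SchemaError(
                f"exclusion accounting broken: {total} != {self.n_rows} rows"
            )


@dataclass(frozen=True)
class _RawRow:
    study: StudyRecord
    setting_labels: tuple[str, str, str]  # may include the "other" outcome


def _parse_float(text: str, line: int, col: str) -> Optional[float]:
    text = text.strip()
    if text == "":
        return None
    try:
        return float(text)
    except ValueError:
        raise SchemaError(f"line {line}: column {col!r} is not numeric: {text!r}")


def _parse_int(text: str, line: int, col: str) -> int:
    value = _parse_float(text, line, col)
    if value is None or value != int(value):
        raise SchemaError(f"line {line}: column {col!r} must be an integer: {text!r}")
    return int(value)


def read_study_table(path, strict: bool = True):
    """Read a study-level CSV table and assemble filtered meta-analyses.

    Parameters
    ----------
    path
        CSV file with columns ``CSV_COLUMNS`` (UTF-8, ``""`` = missing).
    strict
        If True an unknown category label raises; otherwise the row is
        skipped with a warning and counted in the report.

    Returns
    -------
    (list of MetaAnalysis, LoadReport)
    """
    rows: list[_RawRow] = []
    report = LoadReport()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or list(reader.fieldnames) != CSV_COLUMNS:
            raise SchemaError(
                f"bad header: expected {CSV_COLUMNS}, got {reader.fieldnames}"
            )
        for i, rec in enumerate(reader, start=2):  # line 1 is the header
            if any(rec.get(c) is None for c in CSV_COLUMNS):
                raise SchemaError(f"line {i}: wrong number of fields")
            report.n_rows += 1
            outcome = rec["outcome_type"].strip()
            comparison = rec["comparison_type"].strip()
            area = rec["medical_area"].strip()
            known = (
                (outcome in OUTCOME_TYPES or outcome == OTHER_OUTCOME)
                and comparison in COMPARISON_TYPES
                and area in MEDICAL_AREAS
            )
            if not known:
                msg = (
                    f"line {i}: unknown category label(s): "
                    f"outcome={outcome!r} comparison={comparison!r} area={area!r}"
                )
                if strict:
                    raise SchemaError(msg)
                warnings.warn(msg + " (row skipped)", stacklevel=2)
                report.n_skipped += 1
                continue
            try:
                study = StudyRecord(
                    review_id=rec["review_id"].strip(),
                    comparison_id=rec["comparison_id"].strip(),
                    ma_id=rec["ma_id"].strip(),
                    study_id=rec["study_id"].strip(),
                    subgroup_index=_parse_int(rec["subgroup"], i, "subgroup"),
                    arm1=ArmSummary(
                        n=_parse_int(rec["n1"], i, "n1"),
                        mean=_require(_parse_float(rec["mean1"], i, "mean1"), i, "mean1"),
                        sd=_parse_float(rec["sd1"], i, "sd1"),
                    ),
                    arm2=ArmSummary(
                        n=_parse_int(rec["n2"], i, "n2"),
                        mean=_require(_parse_float(rec["mean2"], i, "mean2"), i, "mean2"),
                        sd=_parse_float(rec["sd2"], i, "sd2"),
                    ),
                )
            except SchemaError:
                raise
            except ValueError as exc:
                raise SchemaError(f"line {i}: malformed row: {exc}") from exc
            rows.append(_RawRow(study, (outcome, comparison, area)))

    collection = apply_filters(rows, report)
    report.check()
    return collection, report


def _require(value: Optional[float], line: int, col: str) -> float:
    if value is None:
        raise SchemaError(f"line {line}: column {col!r} is required")
    return value


def apply_filters(rows: Sequence[_RawRow], report: Optional[LoadReport] = None):
    """Apply the four inclusion rules, in order, to raw study rows.

    Shared by the CSV reader and the synthetic generator so that both
    paths produce identically filtered collections.
    """
    if report is None:
        report = LoadReport(n_rows=len(rows))

    # rule 1: unusable studies (missing/zero sd, or an arm with n < 2)
    usable: list[_RawRow] = []
    for row in rows:
        arms = (row.study.arm1, row.study.arm2)
        if any(a.sd is None or a.sd == 0 for a in arms):
            report.n_missing_sd += 1
        elif any(a.n < 2 for a in arms):
            report.n_small_arm += 1
        else:
            usable.append(row)

    # rule 2: first occurrence of each study within a meta-analysis
    seen: set[tuple[str, str, str, str]] = set()
    deduped: list[_RawRow] = []
    for row in usable:
        s = row.study
        key = (s.review_id, s.comparison_id, s.ma_id, s.study_id)
        if key in seen:
            report.n_duplicate += 1
        else:
            seen.add(key)
            deduped.append(row)

    # group by meta-analysis, preserving first-appearance order
    groups: dict[tuple[str, str, str], list[_RawRow]] = {}
    for row in deduped:
        s = row.study
        groups.setdefault((s.review_id, s.comparison_id, s.ma_id), []).append(row)

    collection: list[MetaAnalysis] = []
    for key, group in groups.items():
        labels = {r.setting_labels for r in group}
        if len(labels) != 1:
            raise SchemaError(
                f"meta-analysis {key[2]!r} carries inconsistent setting labels: {labels}"
            )
        # rule 3: at least two studies after the per-study rules
        if len(group) < 2:
            report.n_undersized_mas += 1
            report.n_undersized_studies += len(group)
            continue
        outcome, comparison, area = group[0].setting_labels
        # rule 4: outcome type "other" excluded from analysis
        if outcome == OTHER_OUTCOME:
            report.n_other_outcome_mas += 1
            report.n_other_outcome_studies += len(group)
            continue
        collection.append(
            MetaAnalysis(
                review_id=key[0],
                comparison_id=key[1],
                ma_id=key[2],
                setting=Setting(outcome, comparison, area),
                studies=tuple(r.study for r in group),
            )
        )
    report.n_retained = sum(len(ma) for ma in collection)
    return collection


def _format_float(x: Optional[float]) -> str:
    if x is None:
        return ""
    return repr(float(x))


def write_study_table(collection: Iterable[MetaAnalysis], path) -> None:
    """Write a collection back to CSV; ``read_study_table`` round-trips it."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for ma in collection:
            for s in ma.studies:
                writer.writerow(
                    [
                        s.review_id,
                        s.comparison_id,
                        s.ma_id,
                        s.study_id,
                        s.subgroup_index,
                        s.arm1.n,
                        _format_float(s.arm1.mean),
                        _format_float(s.arm1.sd),
                        s.arm2.n,
                        _format_float(s.arm2.mean),
                        _format_float(s.arm2.sd),
                        ma.setting.outcome_type,
                        ma.setting.comparison_type,
                        ma.setting.medical_area,
                    ]
                )
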