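"""Domain records, CSV I/O, validation and the risk-of-bias composite.

The unit of extraction is one randomized controlled trial (a *study*) with two
or more *arms* (exactly one mindfulness-intervention arm per comparison) and a
set of *measures*: per-arm pre/post means and SDs for one outcome instrument,
assigned to one of seven outcome categories. A three-file long-format CSV
schema (studies / arms / measures) keeps multi-arm, multi-measure studies
normalized.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import pydantic
from pydantic import BaseModel, ConfigDict, Field, model_validator

#: Outcome categories every measure must fall into.
CATEGORIES = (
    "mindfulness",
    "executive_function",
    "attention",
    "depression",
    "anxiety_stress",
    "negative_behaviour",
    "social_behaviour",
)

#: The five Cochrane risk-of-bias domains, in reporting order.
ROB_DOMAINS = (
    "random_sequencing",
    "allocation_concealment",
    "blinding_outcome",
    "incomplete_data",
    "selective_reporting",
)

Rating = Literal["low", "high", "unclear"]
Role = Literal["mbi", "control"]
ControlSubtype = Literal[
    "none", "no_contact", "wait_list", "attention_placebo", "active_intervention"
]
Direction = Literal["higher_better", "lower_better"]

#: Structured comparison conditions ("active controls").
ACTIVE_SUBTYPES = frozenset({"attention_placebo", "active_intervention"})
#: No-contact / wait-list conditions ("passive controls").
PASSIVE_SUBTYPES = frozenset({"no_contact", "wait_list"})
CONTROL_SUBTYPES = ("no_contact", "wait_list", "attention_placebo", "active_intervention")


class DatasetError(Exception):
    """Base class for dataset loading/validation failures."""


class SchemaError(DatasetError):
    """A CSV file does not conform to the expected column schema."""


class ReferentialError(DatasetError):
    """A record refers to a study/arm that does not exist."""


class RecordValidationError(DatasetError):
    """A record violates a field-level invariant."""


class RoBAssessment(BaseModel):
    """Cochrane risk-of-bias ratings for the five assessed domains."""

    model_config = ConfigDict(frozen=True)

    random_sequencing: Rating
    allocation_concealment: Rating
    blinding_outcome: Rating
    incomplete_data: Rating
    selective_reporting: Rating

    def ratings(self) -> tuple[Rating, ...]:
        return tuple(getattr(self, dom) for dom in ROB_DOMAINS)

    @property
    def composite(self) -> int:
        return rob_score(self)


def rob_score(rob: RoBAssessment) -> int:
    """Composite risk-of-bias score: +1 per low-risk domain, 0 per unclear,
    -1 per high-risk, summed over the five domains (range -5..5; lower means
    higher risk of bias)."""
    ratings = rob.ratings()
    return sum(r == "low" for r in ratings) - sum(r == "high" for r in ratings)


class ArmRecord(BaseModel):
    model_config = ConfigDict(frozen=True)

    arm_id: str
    role: Role
    control_subtype: ControlSubtype = "none"
    n: int = Field(ge=1)

    @model_validator(mode="after")
    def _role_subtype_consistent(self) -> "ArmRecord":
        if self.role == "mbi" and self.control_subtype != "none":
            raise ValueError("an mbi arm must have control_subtype='none'")
        if self.role == "control" and self.control_subtype == "none":
            raise ValueError("a control arm must declare its control_subtype")
        return self


class StudyRecord(BaseModel):
    model_config = ConfigDict(frozen=True)

    study_id: str
    age_mean: Optional[float] = Field(default=None, gt=0, lt=19)
    total_hours: Optional[float] = Field(default=None, gt=0)
    training_weeks: Optional[float] = Field(default=None, gt=0)
    mbi_name: str = ""
    arms: tuple[ArmRecord, ...] = Field(min_length=2)
    rob: RoBAssessment

    @model_validator(mode="after")
    def _arm_structure(self) -> "StudyRecord":
        ids = [a.arm_id for a in self.arms]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate arm_id in study {self.study_id!r}")
        roles = {a.role for a in self.arms}
        if roles != {"mbi", "control"}:
            raise ValueError(
                f"study {self.study_id!r} needs at least one mbi and one control arm"
            )
        return self

    def arm(self, arm_id: str) -> ArmRecord:
        for a in self.arms:
            if a.arm_id == arm_id:
                return a
        raise KeyError(arm_id)

    @property
    def rob_score(self) -> int:
        return rob_score(self.rob)


class MeasureRecord(BaseModel):
    """Pre/post summary statistics of one outcome measure for one
    (MBI arm, control arm) comparison."""

    model_config = ConfigDict(frozen=True)

    study_id: str
    comparison_id: str
    mbi_arm_id: str
    control_arm_id: str
    measure_name: str
    category: Literal[CATEGORIES]  # type: ignore[valid-type]
    direction: Direction
    mbi_pre_mean: float
    mbi_pre_sd: float = Field(gt=0)
    mbi_post_mean: float
    mbi_post_sd: float = Field(gt=0)
    mbi_n: int = Field(ge=1)
    ctl_pre_mean: float
    ctl_pre_sd: float = Field(gt=0)
    ctl_post_mean: float
    ctl_post_sd: float = Field(gt=0)
    ctl_n: int = Field(ge=1)


class EffectSize(BaseModel):
    """One oriented standardized mean difference with its sampling variance,
    at study x comparison x category level (possibly an average over several
    measures in the category)."""

    model_config = ConfigDict(frozen=True)

    study_id: str
    comparison_id: str
    category: str
    d: float
    variance: float = Field(gt=0)
    n_total: int = Field(ge=2)
    n_measures_averaged: int = Field(ge=1)

    @property
    def se(self) -> float:
        return math.sqrt(self.variance)


class Diagnostic(BaseModel):
    model_config = ConfigDict(frozen=True)

    severity: Literal["warning", "error"]
    code: str
    message: str


class Dataset(BaseModel):
    model_config = ConfigDict(frozen=True)

    studies: tuple[StudyRecord, ...]
    measures: tuple[MeasureRecord, ...]

    def study(self, study_id: str) -> StudyRecord:
        for s in self.studies:
            if s.study_id == study_id:
                return s
        raise KeyError(study_id)

    def comparison_arms(self, study_id: str, comparison_id: str) -> tuple[ArmRecord, ArmRecord]:
        """(mbi arm, control arm) referenced by a comparison."""
        for m in self.measures:
            if m.study_id == study_id and m.comparison_id == comparison_id:
                study = self.study(study_id)
                return study.arm(m.mbi_arm_id), study.arm(m.control_arm_id)
        raise KeyError((study_id, comparison_id))

    def control_subtype(self, study_id: str, comparison_id: str) -> str:
        return self.comparison_arms(study_id, comparison_id)[1].control_subtype

    def comparison_ids(self) -> list[tuple[str, str]]:
        """Distinct (study_id, comparison_id) pairs, in first-appearance order."""
        seen: list[tuple[str, str]] = []
        for m in self.measures:
            key = (m.study_id, m.comparison_id)
            if key not in seen:
                seen.append(key)
        return seen


STUDY_COLUMNS = (
    "study_id", "age_mean", "total_hours", "training_weeks", "mbi_name",
    "rob_random_sequencing", "rob_allocation", "rob_blinding",
    "rob_incomplete", "rob_selective",
)
_ROB_COLUMN_TO_DOMAIN = {
    "rob_random_sequencing": "random_sequencing",
    "rob_allocation": "allocation_concealment",
    "rob_blinding": "blinding_outcome",
    "rob_incomplete": "incomplete_data",
    "rob_selective": "selective_reporting",
}
ARM_COLUMNS = ("study_id", "arm_id", "role", "control_subtype", "n")
MEASURE_COLUMNS = (
    "study_id", "comparison_id", "mbi_arm_id", "control_arm_id",
    "measure_name", "category", "direction",
    "mbi_pre_mean", "mbi_pre_sd", "mbi_post_mean", "mbi_post_sd", "mbi_n",
    "ctl_pre_mean", "ctl_pre_sd", "ctl_post_mean", "ctl_post_sd", "ctl_n",
)


def _read_csv(path: Path | str, required: tuple[str, ...], label: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{label} file not found: {path}")
    df = pd.read_csv(path, dtype={"study_id": str}, float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{label} is missing required column(s): {', '.join(missing)}")
    return df


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def read_dataset(
    studies_path: Path | str,
    arms_path: Path | str,
    measures_path: Path | str,
) -> Dataset:
    """Load the three-file CSV schema into validated records.

    Raises :class:`SchemaError` for missing columns, :class:`ReferentialError`
    for unresolved study/arm references, and :class:`RecordValidationError`
    (naming the offending row) for invariant violations. Row order is
    preserved.
    """
    studies_df = _read_csv(studies_path, STUDY_COLUMNS, "studies.csv")
    arms_df = _read_csv(arms_path, ARM_COLUMNS, "arms.csv")
    measures_df = _read_csv(measures_path, MEASURE_COLUMNS, "measures.csv")

    arms_by_study: dict[str, list[ArmRecord]] = {}
    for i, row in arms_df.iterrows():
        subtype = row["control_subtype"]
        if subtype is None or (isinstance(subtype, float) and math.isnan(subtype)):
            subtype = "none"
        try:
            arm = ArmRecord(
                arm_id=str(row["arm_id"]), role=row["role"],
                control_subtype=subtype, n=int(row["n"]),
            )
        except (pydantic.ValidationError, ValueError) as exc:
            raise RecordValidationError(f"arms.csv row {i}: {exc}") from exc
        arms_by_study.setdefault(str(row["study_id"]), []).append(arm)

    studies: list[StudyRecord] = []
    for i, row in studies_df.iterrows():
        sid = str(row["study_id"])
        if sid not in arms_by_study:
            raise ReferentialError(f"studies.csv row {i}: study {sid!r} has no arms")
        try:
            rob = RoBAssessment(
                **{_ROB_COLUMN_TO_DOMAIN[c]: str(row[c]).strip() for c in _ROB_COLUMN_TO_DOMAIN}
            )
            studies.append(StudyRecord(
                study_id=sid,
                age_mean=_opt_float(row["age_mean"]),
                total_hours=_opt_float(row["total_hours"]),
                training_weeks=_opt_float(row["training_weeks"]),
                mbi_name="" if pd.isna(row["mbi_name"]) else str(row["mbi_name"]),
                arms=tuple(arms_by_study[sid]),
                rob=rob,
            ))
        except pydantic.ValidationError as exc:
            raise RecordValidationError(f"studies.csv row {i}: {exc}") from exc
    study_ids = {s.study_id for s in studies}
    if len(study_ids) != len(studies):
        raise RecordValidationError("studies.csv: duplicate study_id")
    for sid in arms_by_study:
        if sid not in study_ids:
            raise ReferentialError(f"arms.csv: study {sid!r} not present in studies.csv")
    by_id = {s.study_id: s for s in studies}

    measures: list[MeasureRecord] = []
    for i, row in measures_df.iterrows():
        sid = str(row["study_id"])
        if sid not in by_id:
            raise ReferentialError(
                f"measures.csv row {i}: study_id {sid!r} not found in studies.csv"
            )
        study = by_id[sid]
        kwargs = {c: row[c] for c in MEASURE_COLUMNS}
        kwargs["study_id"] = sid
        for key in ("comparison_id", "mbi_arm_id", "control_arm_id", "measure_name"):
            kwargs[key] = str(kwargs[key])
        # arm-level n is the default when the per-measure n is blank
        for n_col, arm_col in (("mbi_n", "mbi_arm_id"), ("ctl_n", "control_arm_id")):
            if pd.isna(kwargs[n_col]):
                try:
                    kwargs[n_col] = study.arm(kwargs[arm_col]).n
                except KeyError:
                    pass
        try:
            mbi_arm = study.arm(kwargs["mbi_arm_id"])
            ctl_arm = study.arm(kwargs["control_arm_id"])
        except KeyError as exc:
            raise ReferentialError(
                f"measures.csv row {i}: arm {exc.args[0]!r} not found in study {sid!r}"
            ) from exc
        if mbi_arm.role != "mbi" or ctl_arm.role != "control":
            raise ReferentialError(
                f"measures.csv row {i}: comparison arms have wrong roles "
                f"({mbi_arm.role!r} vs {ctl_arm.role!r})"
            )
        try:
            measures.append(MeasureRecord(**kwargs))
        except pydantic.ValidationError as exc:
            raise RecordValidationError(f"measures.csv row {i}: {exc}") from exc

    return Dataset(studies=tuple(studies), measures=tuple(measures))


def write_dataset(
    dataset: Dataset,
    studies_path: Path | str,
    arms_path: Path | str,
    measures_path: Path | str,
) -> None:
    """Write the three CSV files; a subsequent :func:`read_dataset` round-trips
    to an identical dataset."""

    def _fmt(value):
        # shortest-repr float serialization keeps the round-trip lossless
        if value is None:
            return ""
        if isinstance(value, float):
            return repr(value)
        return value

    srows = []
    for s in dataset.studies:
        srows.append({
            "study_id": s.study_id, "age_mean": _fmt(s.age_mean),
            "total_hours": _fmt(s.total_hours), "training_weeks": _fmt(s.training_weeks),
            "mbi_name": s.mbi_name,
            **{col: getattr(s.rob, dom) for col, dom in _ROB_COLUMN_TO_DOMAIN.items()},
        })
    pd.DataFrame(srows, columns=list(STUDY_COLUMNS)).to_csv(studies_path, index=False)

    arows = []
    for s in dataset.studies:
        for a in s.arms:
            arows.append({"study_id": s.study_id, "arm_id": a.arm_id, "role": a.role,
                          "control_subtype": a.control_subtype, "n": a.n})
    pd.DataFrame(arows, columns=list(ARM_COLUMNS)).to_csv(arms_path, index=False)

    mrows = [{c: _fmt(getattr(m, c)) for c in MEASURE_COLUMNS} for m in dataset.measures]
    pd.DataFrame(mrows, columns=list(MEASURE_COLUMNS)).to_csv(measures_path, index=False)


def validate_dataset(dataset: Dataset) -> list[Diagnostic]:
    """Non-mutating whole-dataset checks.

    Errors: duplicate (study, comparison, measure) rows; comparisons whose arm
    pair is inconsistent across rows. Warnings: outcome categories covered by
    fewer than two studies; studies with missing moderators.
    """
    out: list[Diagnostic] = []

    seen: set[tuple[str, str, str]] = set()
    for m in dataset.measures:
        key = (m.study_id, m.comparison_id, m.measure_name)
        if key in seen:
            out.append(Diagnostic(
                severity="error", code="duplicate_measure",
                message=f"duplicate measure row {key!r}",
            ))
        seen.add(key)

    pair_of: dict[tuple[str, str], tuple[str, str]] = {}
    for m in dataset.measures:
        key = (m.study_id, m.comparison_id)
        pair = (m.mbi_arm_id, m.control_arm_id)
        if key in pair_of and pair_of[key] != pair:
            out.append(Diagnostic(
                severity="error", code="inconsistent_comparison",
                message=f"comparison {key!r} maps to multiple arm pairs",
            ))
        pair_of.setdefault(key, pair)

    studies_per_cat: dict[str, set[str]] = {}
    for m in dataset.measures:
        studies_per_cat.setdefault(m.category, set()).add(m.study_id)
    for cat, sids in sorted(studies_per_cat.items()):
        if len(sids) < 2:
            out.append(Diagnostic(
                severity="warning", code="small_category",
                message=f"category {cat!r} has k < 2 studies (k={len(sids)})",
            ))

    for s in dataset.studies:
        missing = [name for name in ("age_mean", "total_hours", "training_weeks")
                   if getattr(s, name) is None]
        if missing:
            out.append(Diagnostic(
                severity="warning", code="missing_moderator",
                message=f"study {s.study_id!r} has missing moderator(s): {', '.join(missing)}",
            ))

    return out
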