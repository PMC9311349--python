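"""Cohort domain model: participants, assessments, treatment codes and plans.

A cohort bundles four record collections:

* :class:`Participant` — sociodemographics (age in months, gender, diagnosis tool);
* :class:`AssessmentProfile` — SRS-2 subscale/total T-scores and the VB-MAPP
  aggregate milestone score at a study timepoint (months 0, 4, 6);
* :class:`TreatmentPlan` — the clinician's plan as hierarchical treatment codes:
  integer Level-1 *domain* codes (skill domains / verbal operants) and Level-2
  *target* codes rendered ``"domain.target"`` (one teachable skill, ordered
  easy-to-complex within its domain);
* :class:`MasteryRecord` — whether and when a planned target was mastered.

Construction never validates; :func:`validate_cohort` reports invariant
violations as data so a pipeline can log them without dying mid-file.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .exceptions import CohortParseError

__all__ = [
    "Participant",
    "AssessmentProfile",
    "TreatmentCode",
    "TreatmentPlan",
    "MasteryRecord",
    "Cohort",
    "Violation",
    "validate_cohort",
    "read_cohort",
    "write_cohort",
    "AGE_RANGE_MONTHS",
    "TIMEPOINTS",
    "SRS2_SUBSCALES",
]

#: Inclusion criterion: children between 2 and 6 years of age.
AGE_RANGE_MONTHS = (24.0, 72.0)

#: Assessment timepoints (months from intake) used in the study design.
TIMEPOINTS = (0, 4, 6)

#: Standard SRS-2 treatment subscales, in instrument order.
SRS2_SUBSCALES = (
    "social_awareness",
    "social_cognition",
    "social_communication",
    "social_motivation",
    "restricted_repetitive_behavior",
)

DIAGNOSIS_TOOLS = ("DSM-V", "CARS-2", "ADOS", "INDT-ASD", "ISAA", "other")

T_SCORE_RANGE = (30.0, 100.0)
VBMAPP_RANGE = (0.0, 170.0)
STUDY_MONTHS = (1, 6)


@dataclass(frozen=True)
class Participant:
    id: str
    age_months: float
    gender: str  # "male" | "female"
    diagnosis_tool: Optional[str] = None


@dataclass(frozen=True)
class AssessmentProfile:
    participant_id: str
    timepoint_month: int
    srs2_subscale_t: tuple[float, ...]  # instrument order, see SRS2_SUBSCALES
    srs2_total_t: float
    vbmapp_aggregate: float


@dataclass(frozen=True, order=True)
class TreatmentCode:
    """Hierarchical treatment code: Level-1 domain, optional Level-2 target.

    Stored as an integer pair, never a float: ``"5.13"`` is target 13 of
    domain 5, which a float would conflate with ``5.1``/``5.10``.
    """

    domain: int
    target: Optional[int] = None

    @property
    def is_target(self) -> bool:
        return self.target is not None

    @property
    def parent(self) -> "TreatmentCode":
        """The domain-level code this code belongs to."""
        return TreatmentCode(self.domain)

    def render(self) -> str:
        if self.target is None:
            return str(self.domain)
        return f"{self.domain}.{self.target}"

    @classmethod
    def parse(cls, text: str) -> "TreatmentCode":
        text = text.strip()
        if "." in text:
            dom, _, tgt = text.partition(".")
            return cls(int(dom), int(tgt))
        return cls(int(text))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


@dataclass(frozen=True)
class TreatmentPlan:
    participant_id: str
    domain_codes: frozenset[TreatmentCode]
    target_codes: frozenset[TreatmentCode]
    window: tuple[int, int] = STUDY_MONTHS

    def codes(self, level: str) -> frozenset[TreatmentCode]:
        if level == "domain":
            return self.domain_codes
        if level == "target":
            return self.target_codes
        raise ValueError(f"unknown level {level!r}")


@dataclass(frozen=True)
class MasteryRecord:
    participant_id: str
    code: TreatmentCode
    mastered: bool
    days_to_mastery: Optional[float]
    month: int


@dataclass
class Cohort:
    participants: list[Participant]
    profiles: list[AssessmentProfile]
    plans: list[TreatmentPlan]
    mastery: list[MasteryRecord]

    def participant_ids(self) -> list[str]:
        return [p.id for p in self.participants]

    def profile_for(self, participant_id: str, timepoint: int = 0) -> Optional[AssessmentProfile]:
        for prof in self.profiles:
            if prof.participant_id == participant_id and prof.timepoint_month == timepoint:
                return prof
        return None

    def plan_for(self, participant_id: str) -> Optional[TreatmentPlan]:
        for plan in self.plans:
            if plan.participant_id == participant_id:
                return plan
        return None

    def mastery_for(self, participant_id: str) -> list[MasteryRecord]:
        return [m for m in self.mastery if m.participant_id == participant_id]

    def __len__(self) -> int:
        return len(self.participants)


@dataclass(frozen=True)
class Violation:
    """One invariant breach, reported as data rather than an exception."""

    kind: str
    participant_id: Optional[str]
    message: str


def _check(cond: bool, out: list, kind: str, pid: Optional[str], msg: str) -> None:
    if not cond:
        out.append(Violation(kind, pid, msg))


def validate_cohort(cohort: Cohort) -> list[Violation]:
    """Check every type invariant and referential link; return breaches.

    An empty list means the cohort is valid. Violations name the offending
    participant and the bound that was breached.
    """
    out: list[Violation] = []
    ids = set()
    for p in cohort.participants:
        if p.id in ids:
            out.append(Violation("duplicate_id", p.id, f"participant id {p.id!r} repeated"))
        ids.add(p.id)
        lo, hi = AGE_RANGE_MONTHS
        _check(lo <= p.age_months <= hi, out, "age_bounds", p.id,
               f"age_months={p.age_months} outside inclusion range [{lo}, {hi}]")
        _check(p.gender in ("male", "female"), out, "gender", p.id,
               f"gender={p.gender!r} not one of male/female")
        _check(p.diagnosis_tool is None or p.diagnosis_tool in DIAGNOSIS_TOOLS,
               out, "diagnosis_tool", p.id, f"unknown diagnosis tool {p.diagnosis_tool!r}")

    for prof in cohort.profiles:
        pid = prof.participant_id
        _check(pid in ids, out, "unknown_participant", pid,
               f"assessment references unknown participant {pid!r}")
        _check(prof.timepoint_month in TIMEPOINTS, out, "timepoint", pid,
               f"timepoint_month={prof.timepoint_month} not in {TIMEPOINTS}")
        _check(len(prof.srs2_subscale_t) == len(SRS2_SUBSCALES), out, "subscale_arity", pid,
               f"expected {len(SRS2_SUBSCALES)} SRS-2 subscales, got {len(prof.srs2_subscale_t)}")
        lo, hi = T_SCORE_RANGE
        for name, t in zip(SRS2_SUBSCALES, prof.srs2_subscale_t):
            _check(lo <= t <= hi, out, "t_score_bounds", pid,
                   f"SRS-2 {name} T-score {t} outside [{lo}, {hi}]")
        _check(lo <= prof.srs2_total_t <= hi, out, "t_score_bounds", pid,
               f"SRS-2 total T-score {prof.srs2_total_t} outside [{lo}, {hi}]")
        vlo, vhi = VBMAPP_RANGE
        _check(vlo <= prof.vbmapp_aggregate <= vhi, out, "vbmapp_bounds", pid,
               f"VB-MAPP aggregate {prof.vbmapp_aggregate} outside [{vlo}, {vhi}]")

    for plan in cohort.plans:
        pid = plan.participant_id
        _check(pid in ids, out, "unknown_participant", pid,
               f"plan references unknown participant {pid!r}")
        for c in plan.domain_codes:
            _check(not c.is_target, out, "level_mismatch", pid,
                   f"code {c.render()} in domain_codes has a target component")
            _check(c.domain > 0, out, "code_bounds", pid,
                   f"domain code {c.render()} must be a positive integer")
        for c in plan.target_codes:
            _check(c.is_target, out, "level_mismatch", pid,
                   f"code {c.render()} in target_codes lacks a target component")
            _check(c.parent in plan.domain_codes, out, "hierarchy", pid,
                   f"target {c.render()} has no parent domain {c.domain} in the plan")

    for rec in cohort.mastery:
        pid = rec.participant_id
        _check(pid in ids, out, "unknown_participant", pid,
               f"mastery record references unknown participant {pid!r}")
        _check(rec.code.is_target, out, "level_mismatch", pid,
               f"mastery code {rec.code.render()} is not target-level")
        _check((rec.days_to_mastery is not None) == rec.mastered, out, "mastery_days", pid,
               "days_to_mastery must be present iff mastered")
        if rec.days_to_mastery is not None:
            _check(rec.days_to_mastery >= 0, out, "mastery_days", pid,
                   f"days_to_mastery={rec.days_to_mastery} negative")
        _check(STUDY_MONTHS[0] <= rec.month <= STUDY_MONTHS[1], out, "month_bounds", pid,
               f"month={rec.month} outside study horizon {STUDY_MONTHS}")

    return out


# ---------------------------------------------------------------------------
# I/O — directory-of-CSVs schema, with a single-document JSON mirror.
# ---------------------------------------------------------------------------

_PARTICIPANT_COLS = ["id", "age_months", "gender", "diagnosis_tool"]
_ASSESSMENT_COLS = (["participant_id", "timepoint_month"]
                    + [f"srs2_sub{i + 1}" for i in range(len(SRS2_SUBSCALES))]
                    + ["srs2_total", "vbmapp"])
_PLAN_COLS = ["participant_id", "code", "level", "window_start", "window_end"]
_MASTERY_COLS = ["participant_id", "code", "mastered", "days_to_mastery", "month"]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], fname: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise CohortParseError(f"{fname}: missing column(s) {', '.join(missing)}")


def _read_csv(path: Path, cols: Sequence[str]) -> pd.DataFrame:
    if not path.exists():
        raise CohortParseError(f"{path.name}: file not found under {path.parent}")
    try:
        # codes must stay strings ("5.10" is not the float 5.1) and floats
        # must parse correctly rounded so write-then-read is the identity
        df = pd.read_csv(path, dtype={"code": str} if "code" in cols else None,
                         float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise CohortParseError(f"{path.name}: file is empty") from None
    except Exception as exc:  # malformed CSV
        raise CohortParseError(f"{path.name}: {exc}") from exc
    _require_columns(df, cols, path.name)
    return df


def read_cohort(path: str | Path) -> Cohort:
    """Read a cohort from a directory of CSVs or a single ``.json`` document.

    Empty files are rejected (a cohort with no participants is treated as a
    parse error so pipelines fail fast rather than silently producing empty
    reports).
    """
    path = Path(path)
    if path.suffix == ".json":
        return _read_cohort_json(path)

    parts = _read_csv(path / "participants.csv", _PARTICIPANT_COLS)
    if len(parts) == 0:
        raise CohortParseError("participants.csv: no participant rows")
    assess = _read_csv(path / "assessments.csv", _ASSESSMENT_COLS)
    plans = _read_csv(path / "plans.csv", _PLAN_COLS)
    mastery = _read_csv(path / "mastery.csv", _MASTERY_COLS)

    participants = [
        Participant(
            id=str(r.id),
            age_months=float(r.age_months),
            gender=str(r.gender),
            diagnosis_tool=None if pd.isna(r.diagnosis_tool) else str(r.diagnosis_tool),
        )
        for r in parts.itertuples()
    ]
    profiles = [
        AssessmentProfile(
            participant_id=str(r.participant_id),
            timepoint_month=int(r.timepoint_month),
            srs2_subscale_t=tuple(
                float(getattr(r, f"srs2_sub{i + 1}")) for i in range(len(SRS2_SUBSCALES))
            ),
            srs2_total_t=float(r.srs2_total),
            vbmapp_aggregate=float(r.vbmapp),
        )
        for r in assess.itertuples()
    ]

    plan_objs: list[TreatmentPlan] = []
    for pid, grp in plans.groupby("participant_id", sort=False):
        domains, targets = set(), set()
        win = (int(grp.window_start.iloc[0]), int(grp.window_end.iloc[0]))
        for r in grp.itertuples():
            try:
                code = TreatmentCode.parse(str(r.code))
            except ValueError as exc:
                raise CohortParseError(f"plans.csv: bad code {r.code!r}: {exc}") from exc
            if str(r.level) == "target":
                targets.add(code)
            elif str(r.level) == "domain":
                domains.add(code)
            else:
                raise CohortParseError(f"plans.csv: bad level {r.level!r} (domain/target)")
        plan_objs.append(TreatmentPlan(str(pid), frozenset(domains), frozenset(targets), win))

    mastery_objs = [
        MasteryRecord(
            participant_id=str(r.participant_id),
            code=TreatmentCode.parse(str(r.code)),
            mastered=bool(r.mastered),
            days_to_mastery=None if pd.isna(r.days_to_mastery) else float(r.days_to_mastery),
            month=int(r.month),
        )
        for r in mastery.itertuples()
    ]
    return Cohort(participants, profiles, plan_objs, mastery_objs)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort to ``path``: a ``.json`` document, or a directory of CSVs."""
    path = Path(path)
    if path.suffix == ".json":
        _write_cohort_json(cohort, path)
        return
    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {"id": p.id, "age_months": p.age_months, "gender": p.gender,
             "diagnosis_tool": p.diagnosis_tool}
            for p in cohort.participants
        ],
        columns=_PARTICIPANT_COLS,
    ).to_csv(path / "participants.csv", index=False)

    pd.DataFrame(
        [
            {
                "participant_id": a.participant_id,
                "timepoint_month": a.timepoint_month,
                **{f"srs2_sub{i + 1}": t for i, t in enumerate(a.srs2_subscale_t)},
                "srs2_total": a.srs2_total_t,
                "vbmapp": a.vbmapp_aggregate,
            }
            for a in cohort.profiles
        ],
        columns=_ASSESSMENT_COLS,
    ).to_csv(path / "assessments.csv", index=False)

    plan_rows = []
    for plan in cohort.plans:
        for level in ("domain", "target"):
            for code in sorted(plan.codes(level)):
                plan_rows.append(
                    {"participant_id": plan.participant_id, "code": code.render(),
                     "level": level, "window_start": plan.window[0],
                     "window_end": plan.window[1]}
                )
    pd.DataFrame(plan_rows, columns=_PLAN_COLS).to_csv(path / "plans.csv", index=False)

    pd.DataFrame(
        [
            {"participant_id": m.participant_id, "code": m.code.render(),
             "mastered": m.mastered, "days_to_mastery": m.days_to_mastery,
             "month": m.month}
            for m in cohort.mastery
        ],
        columns=_MASTERY_COLS,
    ).to_csv(path / "mastery.csv", index=False)


def _cohort_to_doc(cohort: Cohort) -> dict:
    return {
        "participants": [dataclasses.asdict(p) for p in cohort.participants],
        "profiles": [
            {**dataclasses.asdict(a), "srs2_subscale_t": list(a.srs2_subscale_t)}
            for a in cohort.profiles
        ],
        "plans": [
            {
                "participant_id": p.participant_id,
                "domain_codes": sorted(c.render() for c in p.domain_codes),
                "target_codes": sorted(c.render() for c in p.target_codes),
                "window": list(p.window),
            }
            for p in cohort.plans
        ],
        "mastery": [
            {**dataclasses.asdict(m), "code": m.code.render()} for m in cohort.mastery
        ],
    }


def _write_cohort_json(cohort: Cohort, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_cohort_to_doc(cohort), indent=1, sort_keys=True))


def _read_cohort_json(path: Path) -> Cohort:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise CohortParseError(f"{path.name}: invalid JSON: {exc}") from exc
    for key in ("participants", "profiles", "plans", "mastery"):
        if key not in doc:
            raise CohortParseError(f"{path.name}: missing section {key!r}")
    if not doc["participants"]:
        raise CohortParseError(f"{path.name}: no participants")
    try:
        participants = [Participant(**p) for p in doc["participants"]]
        profiles = [
            AssessmentProfile(
                participant_id=a["participant_id"],
                timepoint_month=a["timepoint_month"],
                srs2_subscale_t=tuple(a["srs2_subscale_t"]),
                srs2_total_t=a["srs2_total_t"],
                vbmapp_aggregate=a["vbmapp_aggregate"],
            )
            for a in doc["profiles"]
        ]
        plans = [
            TreatmentPlan(
                participant_id=p["participant_id"],
                domain_codes=frozenset(TreatmentCode.parse(c) for c in p["domain_codes"]),
                target_codes=frozenset(TreatmentCode.parse(c) for c in p["target_codes"]),
                window=tuple(p["window"]),
            )
            for p in doc["plans"]
        ]
        mastery = [
            MasteryRecord(
                participant_id=m["participant_id"],
                code=TreatmentCode.parse(m["code"]),
                mastered=m["mastered"],
                days_to_mastery=m["days_to_mastery"],
                month=m["month"],
            )
            for m in doc["mastery"]
        ]
    except (KeyError, TypeError, ValueError) as exc:
        raise CohortParseError(f"{path.name}: malformed record: {exc}") from exc
    return Cohort(participants, profiles, plans, mastery)
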