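"""CTCAE-style adverse-event handling for radiotherapy toxicity cohorts.

Events are graded 0-5 (grade 3 = severe) and assigned to one of three
follow-up phases relative to the end of radiotherapy: *early* (during
treatment), *acute* (1-6 months after the end of treatment) and *late*
(beyond 6 months).  Patients are split into two groups on the severity of
their pulmonary events: ``STox`` (at least one pulmonary event of grade >= 3
among cough, dyspnea, fibrosis, pneumonitis or a thromboembolic event, in any
phase) versus ``NoSTox`` (all pulmonary events grade <= 2; severe
non-pulmonary events do not qualify).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

PHASES = ("early", "acute", "late")

#: Pulmonary terms whose grade >=3 events define the severe-toxicity group.
PULMONARY_TERMS = frozenset(
    {"cough", "dyspnea", "fibrosis", "pneumonitis", "thromboembolic event"}
)

#: Non-pulmonary terms tracked in toxicity summaries.
NONPULMONARY_TERMS = frozenset(
    {
        "anemia",
        "chest wall pain",
        "dermatitis",
        "fatigue",
        "fracture",
        "GGT",
        "nausea/vomiting",
        "oesophagitis",
        "pericardial effusion",
    }
)

KNOWN_TERMS = PULMONARY_TERMS | NONPULMONARY_TERMS

#: Terms reported as a single row (no grade-band split) in summary tables.
UNBANDED_TERMS = frozenset({"fracture", "thromboembolic event"})

NOSTOX = "NoSTox"
STOX = "STox"

#: Pulmonary grade at or above which a patient is classified severe.
SEVERE_GRADE = 3


def _canonical_term(term: str) -> str:
    t = term.strip()
    if t == "GGT" or t.upper() == "GGT":
        return "GGT"
    return t.lower() if t.lower() in KNOWN_TERMS else t


@dataclass(frozen=True)
class ToxicityEvent:
    """One adverse event for one patient."""

    patient_id: str
    term: str
    grade: int
    phase: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "term", _canonical_term(self.term))
        if self.term not in KNOWN_TERMS:
            raise ValueError(f"unknown toxicity term: {self.term!r}")
        if not 0 <= int(self.grade) <= 5:
            raise ValueError(f"grade must be in [0, 5], got {self.grade}")
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")

    @property
    def pulmonary(self) -> bool:
        return self.term in PULMONARY_TERMS


@dataclass
class PatientRecord:
    """Clinical record for one patient; the toxicity group is derived."""

    patient_id: str
    sex: str = ""
    age: float | None = None
    laterality: str = ""
    histology: str = ""
    stage: str = ""
    events: list[ToxicityEvent] = field(default_factory=list)

    @property
    def group(self) -> str:
        return classify_patient_group(self.events)


def assign_phase(months_since_rt_end: float, during_treatment: bool = False) -> str:
    """Map a follow-up time to the early/acute/late phase.

    ``during_treatment`` forces *early*; otherwise events up to 6 months after
    the end of radiotherapy are *acute* and anything later is *late*.
    """
    if during_treatment:
        return "early"
    if months_since_rt_end < 0:
        raise ValueError("months_since_rt_end must be >= 0 after treatment end")
    return "acute" if months_since_rt_end <= 6 else "late"


def classify_patient_group(events: Iterable[ToxicityEvent]) -> str:
    """Severe-toxicity grouping rule.

    ``STox`` iff the patient has any pulmonary event of grade >= 3, in any
    phase; otherwise ``NoSTox``.  Grade >= 3 non-pulmonary events never
    qualify.  The maximum grade over all phases is used, so a patient with an
    acute grade-3 pneumonitis and otherwise mild events is severe.
    """
    for ev in events:
        if ev.pulmonary and ev.grade >= SEVERE_GRADE:
            return STOX
    return NOSTOX


def classify_groups(events: Iterable[ToxicityEvent]) -> dict[str, str]:
    """Per-patient group labels for a whole cohort's event list."""
    by_patient: dict[str, list[ToxicityEvent]] = {}
    for ev in events:
        by_patient.setdefault(ev.patient_id, []).append(ev)
    return {pid: classify_patient_group(evs) for pid, evs in by_patient.items()}


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def percentage(count: int, n_total: int) -> int:
    """Integer percentage, rounded half away from zero."""
    return _round_half_away(100.0 * count / n_total)


def summarize_toxicity(
    events: Iterable[ToxicityEvent],
    n_total: int,
    terms: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Phase x term x grade-band event counts with integer percentages.

    One row per (term, grade band), bands being grades 1-2 and grades >= 3,
    except for terms conventionally reported unbanded (fracture,
    thromboembolic event), which get a single ``any`` row.  Percentages are
    ``round(100 * count / n_total)``, half away from zero, matching the
    ``n (%)`` cells of a clinical toxicity table.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    events = list(events)
    if terms is None:
        present = {ev.term for ev in events}
        terms = sorted(NONPULMONARY_TERMS & present) + sorted(PULMONARY_TERMS & present)

    rows = []
    for term in terms:
        term = _canonical_term(term)
        bands = ("any",) if term in UNBANDED_TERMS else ("1-2", ">=3")
        for band in bands:
            row: dict[str, object] = {
                "term": term,
                "pulmonary": term in PULMONARY_TERMS,
                "grade_band": band,
            }
            for phase in PHASES:
                n = sum(
                    1
                    for ev in events
                    if ev.term == term
                    and ev.phase == phase
                    and ev.grade >= 1
                    and (
                        band == "any"
                        or (band == "1-2" and ev.grade <= 2)
                        or (band == ">=3" and ev.grade >= 3)
                    )
                )
                row[f"{phase}_n"] = n
                row[f"{phase}_pct"] = percentage(n, n_total)
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TSV i/o

TOXICITY_COLUMNS = ["patient_id", "term", "grade", "phase"]


def read_toxicity_table(path: str | Path) -> list[ToxicityEvent]:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    missing = set(TOXICITY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"toxicity table missing columns: {sorted(missing)}")
    return [
        ToxicityEvent(
            patient_id=str(r.patient_id),
            term=str(r.term),
            grade=int(r.grade),
            phase=str(r.phase),
        )
        for r in df.itertuples()
    ]


def write_toxicity_table(events: Iterable[ToxicityEvent], path: str | Path) -> None:
    df = pd.DataFrame(
        [(e.patient_id, e.term, e.grade, e.phase) for e in events],
        columns=TOXICITY_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def write_groups_table(groups: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        sorted(groups.items()), columns=["patient_id", "group"]
    ).to_csv(path, sep="\t", index=False)


def read_groups_table(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["patient_id"], df["group"]))
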