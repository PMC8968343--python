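"""Longitudinal exam tracking, progression detection and follow-up advice.

Exams are keyed by (patient id, eye) into date-ordered timelines. Progression
is defined as an increase in graded severity category relative to the
immediately preceding exam of the same key; a progressed eye always overrides
the category-based follow-up interval with the short "1-2 months" review. The
recommendation table lives in an editable YAML config
(``data/followup.yaml``); the store is a single versioned JSON file.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from datetime import date
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

from .records import VFRecord
from .rules import GradeLabel, Subtype

STORE_VERSION = 1


@dataclass(frozen=True)
class Recommendation:
    follow_up: str
    months_min: float
    months_max: float
    advice: str
    triggered_by: str  # "category" or "progression"


@dataclass
class PatientTimeline:
    """Date-ordered exams of one (patient, eye) with progression events."""

    key: tuple[str, str]
    exams: list[tuple[date, GradeLabel, float]] = field(default_factory=list)
    progression_events: list[date] = field(default_factory=list)


@lru_cache(maxsize=1)
def _followup_table() -> dict:
    with resources.files("vfgrade.data").joinpath("followup.yaml").open() as f:
        return yaml.safe_load(f)


class TimelineStore:
    """All timelines, persisted as one diffable JSON file."""

    def __init__(self):
        self.timelines: dict[tuple[str, str], PatientTimeline] = {}

    # -- persistence -------------------------------------------------------
    @classmethod
    def load(cls, path) -> "TimelineStore":
        store = cls()
        path = Path(path)
        if not path.exists():
            return store
        data = json.loads(path.read_text())
        if data.get("version") != STORE_VERSION:
            raise ValueError(f"unsupported store version: {data.get('version')}")
        for entry in data["timelines"]:
            key = (entry["patient_id"], entry["eye"])
            tl = PatientTimeline(key=key)
            for e in entry["exams"]:
                label = GradeLabel(e["category"],
                                   Subtype(e["subtype"]) if e["subtype"] else None)
                tl.exams.append((date.fromisoformat(e["date"]), label, e["md"]))
            store.timelines[key] = detect_progression(tl)
        return store

    def save(self, path) -> None:
        data = {"version": STORE_VERSION, "timelines": []}
        for (pid, eye), tl in sorted(self.timelines.items()):
            data["timelines"].append({
                "patient_id": pid, "eye": eye,
                "exams": [{"date": d.isoformat(), "category": l.category,
                           "subtype": l.subtype.value if l.subtype else None,
                           "md": md} for d, l, md in tl.exams],
                "progression_events": [d.isoformat()
                                       for d in tl.progression_events],
            })
        Path(path).write_text(json.dumps(data, indent=2))


def record_exam(store: TimelineStore, record: VFRecord, grade: GradeLabel,
                md: Optional[float] = None) -> PatientTimeline:
    """Insert one graded exam under (patient_id, eye), keeping date order.

    A duplicate (key, date) replaces the stored exam with a warning.
    Progression events are recomputed after insertion.
    """
    from .records import mean_deviation

    key = record.key()
    tl = store.timelines.setdefault(key, PatientTimeline(key=key))
    md = mean_deviation(record) if md is None else md
    entry = (record.exam_date, grade, float(md))
    for i, (d, _, _) in enumerate(tl.exams):
        if d == record.exam_date:
            warnings.warn(f"replacing exam {key} @ {d}", stacklevel=2)
            tl.exams[i] = entry
            break
    else:
        tl.exams.append(entry)
    tl.exams.sort(key=lambda e: e[0])
    return detect_progression(tl)


def detect_progression(timeline: PatientTimeline) -> PatientTimeline:
    """Flag every exam whose category exceeds the immediately preceding one.

    A category decrease (improvement) is not flagged as an event.
    """
    events = []
    for prev, cur in zip(timeline.exams, timeline.exams[1:]):
        if cur[1].category > prev[1].category:
            events.append(cur[0])
    timeline.progression_events = events
    return timeline


def recommend(current: GradeLabel, progressed: bool) -> Recommendation:
    """Table-driven follow-up and treatment advice.

    Progression overrides the category interval with the shorter "1-2
    months" review and escalation advice; the override never lengthens the
    interval.
    """
    table = _followup_table()
    if progressed:
        row = dict(table["progression"])
        cat_row = table["categories"][current.category]
        # never recommend a longer interval than the category alone would
        row["months_max"] = min(row["months_max"], cat_row["months_max"])
        row["months_min"] = min(row["months_min"], cat_row["months_min"])
        return Recommendation(row["follow_up"], row["months_min"],
                              row["months_max"], row["advice"], "progression")
    row = table["categories"][current.category]
    return Recommendation(row["follow_up"], row["months_min"],
                          row["months_max"], row["advice"], "category")
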