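"""Visual-field exam records: I/O, eye normalisation, pattern conversion,
reliability filtering and mean-deviation staging.

One :class:`VFRecord` is a single perimetry exam: identifiers, eye, date,
per-point deviations in dB (negative = sensitivity loss, HFA convention; the
negatives of the Octopus comparison graph are stored with the same sign
convention) and the reliability indices (false-positive, false-negative and
optional fixation-loss rates).

Deviation vectors are positional over the canonical point order of the exam's
:class:`~vfgrade.patterns.TestPattern`.
"""
from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, replace
from datetime import date
from enum import Enum
from typing import Iterable, Optional

import numpy as np

from .patterns import PatternId, TestPattern, get_pattern

#: deviations outside this window are clamped on load (device dynamic range)
DEVIATION_WINDOW = (-40.0, 10.0)

CSV_FIXED_COLUMNS = ["patient_id", "eye", "exam_date", "pattern_id",
                     "fp_rate", "fn_rate", "fl_rate"]


class Eye(str, Enum):
    L = "L"
    R = "R"


class HPAStage(Enum):
    """Hodapp-Parrish-Anderson MD-based stage; ordered mild < moderate < severe."""

    MILD = 1
    MODERATE = 2
    SEVERE = 3

    def __lt__(self, other):
        if isinstance(other, HPAStage):
            return self.value < other.value
        return NotImplemented

    def __le__(self, other):
        if isinstance(other, HPAStage):
            return self.value <= other.value
        return NotImplemented


class VFFormatError(ValueError):
    """Malformed visual-field CSV content."""


class MirrorError(ValueError):
    """Left-eye conversion requested on a pattern without mirror symmetry."""


@dataclass(frozen=True)
class VFRecord:
    """One visual-field exam."""

    patient_id: str
    eye: Eye
    exam_date: date
    pattern_id: PatternId
    deviations: np.ndarray
    fp_rate: float
    fn_rate: float
    fl_rate: Optional[float] = None
    #: True once the field has been brought to right-eye orientation
    right_eye_format: bool = False

    def __post_init__(self):
        dev = np.array(self.deviations, dtype=float)  # copy: callers keep theirs
        pattern = get_pattern(self.pattern_id)
        if dev.shape != (pattern.n_points,):
            raise VFFormatError(
                f"deviation vector has length {dev.size}, pattern "
                f"{self.pattern_id.value} has {pattern.n_points} points")
        lo, hi = DEVIATION_WINDOW
        if np.any(dev < lo) or np.any(dev > hi):
            warnings.warn(
                f"deviations outside [{lo}, {hi}] dB clamped "
                f"({self.patient_id} {self.exam_date})", stacklevel=2)
            dev = np.clip(dev, lo, hi)
        dev.setflags(write=False)
        object.__setattr__(self, "deviations", dev)
        for name in ("fp_rate", "fn_rate", "fl_rate"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise VFFormatError(f"{name}={v} outside [0, 1]")

    @property
    def pattern(self) -> TestPattern:
        return get_pattern(self.pattern_id)

    def key(self) -> tuple[str, str]:
        return (self.patient_id, self.eye.value)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _expected_header(pattern: TestPattern) -> list[str]:
    return CSV_FIXED_COLUMNS + [f"d{i + 1:03d}" for i in range(pattern.n_points)]


def load_vf_csv(path, pattern_id: PatternId | str) -> list[VFRecord]:
    """Read exam records from the canonical VF CSV layout.

    The header must carry the fixed columns followed by one ``dNNN`` column
    per test point of the declared pattern; deviation columns map positionally
    onto the pattern's canonical point order.
    """
    pattern_id = PatternId(pattern_id)
    pattern = get_pattern(pattern_id)
    expected = _expected_header(pattern)
    records = []
    with open(path, newline="") as f:
        reader = csv.reader(f)
        try:
            header = next(reader)
        except StopIteration:
            raise VFFormatError(f"{path}: empty file") from None
        n_dev = len(header) - len(CSV_FIXED_COLUMNS)
        if header != expected:
            if header[:len(CSV_FIXED_COLUMNS)] == CSV_FIXED_COLUMNS and n_dev != pattern.n_points:
                raise VFFormatError(
                    f"{path}: expected {pattern.n_points} deviation columns "
                    f"for pattern {pattern_id.value}, got {n_dev}")
            raise VFFormatError(f"{path}: header does not match canonical layout")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(expected):
                raise VFFormatError(
                    f"{path}:{lineno}: expected {len(expected)} fields, got {len(row)}")
            fixed = dict(zip(CSV_FIXED_COLUMNS, row))
            if fixed["pattern_id"] != pattern_id.value:
                raise VFFormatError(
                    f"{path}:{lineno}: row pattern {fixed['pattern_id']!r} "
                    f"does not match declared {pattern_id.value}")
            devs = []
            for col, cell in enumerate(row[len(CSV_FIXED_COLUMNS):]):
                try:
                    devs.append(float(cell))
                except ValueError:
                    raise VFFormatError(
                        f"{path}:{lineno}: non-numeric deviation in column "
                        f"d{col + 1:03d}: {cell!r}") from None
            try:
                records.append(VFRecord(
                    patient_id=fixed["patient_id"],
                    eye=Eye(fixed["eye"]),
                    exam_date=date.fromisoformat(fixed["exam_date"]),
                    pattern_id=pattern_id,
                    deviations=np.array(devs),
                    fp_rate=float(fixed["fp_rate"]),
                    fn_rate=float(fixed["fn_rate"]),
                    fl_rate=float(fixed["fl_rate"]) if fixed["fl_rate"] != "" else None,
                ))
            except (ValueError, VFFormatError) as e:
                raise VFFormatError(f"{path}:{lineno}: {e}") from None
    return records


def write_vf_csv(records: Iterable[VFRecord], path) -> None:
    """Write records in the canonical VF CSV layout (deviations to 0.01 dB)."""
    records = list(records)
    if not records:
        raise ValueError("no records to write")
    pattern = records[0].pattern
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(_expected_header(pattern))
        for r in records:
            if r.pattern_id != records[0].pattern_id:
                raise VFFormatError("mixed patterns in one CSV")
            w.writerow(
                [r.patient_id, r.eye.value, r.exam_date.isoformat(),
                 r.pattern_id.value, f"{r.fp_rate:g}", f"{r.fn_rate:g}",
                 "" if r.fl_rate is None else f"{r.fl_rate:g}"]
                + [f"{d:.2f}" for d in r.deviations])


# ---------------------------------------------------------------------------
# Eye normalisation and pattern conversion
# ---------------------------------------------------------------------------

def _mirror_permutation(pattern: TestPattern) -> np.ndarray:
    """perm[i] = index of the point at (-x_i, y_i); MirrorError if missing."""
    lookup = {(round(x, 6), round(y, 6)): i
              for i, (x, y) in enumerate(pattern.points)}
    perm = np.empty(pattern.n_points, dtype=int)
    missing = []
    for i, (x, y) in enumerate(pattern.points):
        j = lookup.get((round(-x, 6), round(y, 6)))
        if j is None:
            missing.append((x, y))
        else:
            perm[i] = j
    if missing:
        raise MirrorError(
            f"pattern {pattern.pattern_id.value} lacks mirror symmetry; "
            f"unmatched points: {missing}")
    return perm


def mirror_record(record: VFRecord) -> VFRecord:
    """Mirror the value-to-coordinate assignment about the vertical midline.

    The value at point (x, y) is re-assigned to the point at (-x, y); applying
    it twice restores the original assignment.
    """
    perm = _mirror_permutation(record.pattern)
    new_dev = np.empty_like(record.deviations)
    new_dev[perm] = record.deviations
    return replace(record, deviations=new_dev)


def to_right_eye(record: VFRecord) -> VFRecord:
    """Bring an exam to right-eye orientation.

    Right-eye records are returned unchanged. Left-eye records are mirrored
    about the vertical midline and flagged as converted; the deviation
    multiset is preserved. Raises :class:`MirrorError` on patterns whose point
    set is not mirror symmetric (the 24-2 grid, whose nasal extension points
    have no temporal counterpart).
    """
    if record.eye is Eye.R or record.right_eye_format:
        return replace(record, right_eye_format=True)
    return replace(mirror_record(record), right_eye_format=True)


def convert_30_2_to_24_2(record: VFRecord) -> VFRecord:
    """Restrict a 30-2 exam to the 24-2 point subset (no interpolation)."""
    if record.pattern_id is not PatternId.HFA30_2:
        raise VFFormatError(
            f"30-2 to 24-2 conversion requires pattern HFA30_2, got "
            f"{record.pattern_id.value}")
    src = record.pattern
    dst = get_pattern(PatternId.HFA24_2)
    idx = np.array([src.index_at(x, y) for x, y in dst.points])
    return replace(record, pattern_id=PatternId.HFA24_2,
                   deviations=record.deviations[idx])


# ---------------------------------------------------------------------------
# Reliability and staging
# ---------------------------------------------------------------------------

def reliability_filter(records: Iterable[VFRecord], max_fp: float = 0.30,
                       max_fn: float = 0.30,
                       max_fl: Optional[float] = 0.33,
                       ) -> tuple[list[VFRecord], list[tuple[VFRecord, list[str]]]]:
    """Partition records into (kept, rejected-with-reasons); bounds inclusive.

    A record is kept when fp_rate <= max_fp, fn_rate <= max_fn and, if both a
    fixation-loss bound and a fixation-loss rate are present,
    fl_rate <= max_fl.
    """
    kept, rejected = [], []
    for r in records:
        reasons = []
        if r.fp_rate > max_fp:
            reasons.append(f"false-positive rate > {max_fp:.2f}")
        if r.fn_rate > max_fn:
            reasons.append(f"false-negative rate > {max_fn:.2f}")
        if max_fl is not None and r.fl_rate is not None and r.fl_rate > max_fl:
            reasons.append(f"fixation loss rate > {max_fl:.2f}")
        (rejected.append((r, reasons)) if reasons else kept.append(r))
    return kept, rejected


def mean_deviation(record: VFRecord) -> float:
    """Arithmetic mean of deviations over non-blind-spot points (dB)."""
    return float(record.deviations[record.pattern.non_blind_spot].mean())


def hpa_stage(md: float) -> HPAStage:
    """Hodapp-Parrish-Anderson stage from MD.

    severe when MD <= -12 dB, moderate when -12 < MD <= -6 dB, mild otherwise;
    boundaries go to the worse stage.
    """
    if not math.isfinite(md):
        raise ValueError(f"MD must be finite, got {md}")
    if md <= -12:
        return HPAStage.SEVERE
    if md <= -6:
        return HPAStage.MODERATE
    return HPAStage.MILD
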