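"""Synthetic labelled visual fields for the ten defect subtypes.

Each generated field is a baseline of small relative dips (truncated normal
in [-5, +3] dB, emulating a non-glaucomatous field) on which one defect
archetype is imposed at an absolute-defect floor (default -32 dB):

* ``nasal_step`` -- an absolute sector in the nasal field respecting the
  horizontal meridian on one side, away from the blind spot;
* ``paracentral_scotoma`` -- a compact cluster within 10 deg of fixation,
  disconnected from the blind spot;
* ``temporal_wedge`` -- a wedge at the temporal periphery;
* ``partial_arcuate`` / ``arcuate`` -- a chain of points along a Bjerrum arc
  (the shortest adjacency path inside the 9-24 deg band from a
  blind-spot-adjacent point toward the nasal field; the partial form keeps
  the blind-spot half of the arc);
* ``altitudinal`` -- an entire hemifield at depth with a sharp
  horizontal-meridian edge;
* ``double_arcuate`` -- the superior and inferior arcs together, central
  island (within 8 deg) spared;
* ``tubular_vision`` -- everything beyond 8 deg at depth;
* ``diffuse_defect`` -- the whole field shifted by the depth except a spared
  temporal crescent (x > 20 deg);
* ``total_loss`` -- every point at the floor.

Per-point Gaussian noise is added last and the result clamped to the device
window and rounded to 0.1 dB. Labels are generative: they come from the
subtype, not from re-classification, so noise never changes a label.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from datetime import date, timedelta

import numpy as np
from scipy.stats import truncnorm

from .patterns import PatternId, TestPattern, get_pattern
from .records import DEVIATION_WINDOW, Eye, VFRecord
from .rules import CATEGORY_OF_SUBTYPE, SUBTYPES_OF_CATEGORY, GradeLabel, Subtype

#: baseline relative dips are truncated to this window (dB)
BASELINE_WINDOW = (-5.0, 3.0)
#: geometry constants of the defect selectors (degrees)
NASAL_X = -12.0
NASAL_Y_MAX = 14.0
PARACENTRAL_ECC = 10.0
WEDGE_X = 6.0
WEDGE_Y = 13.0
ARC_BAND = (9.0, 24.0)
ISLAND_RADIUS = 8.0
CRESCENT_X = 20.0
#: per-record seed scheme for generate_dataset
SEED_STRIDE = 1_000_003
SEED_MOD = 2 ** 31


@dataclass(frozen=True)
class DefectSpec:
    """Recipe for one synthetic field."""

    subtype: Subtype
    depth: float = -32.0
    noise_sd: float = 0.0
    relative_dip_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "subtype", Subtype(self.subtype))
        if self.subtype is not Subtype.CLEAR and self.depth > -20.0:
            raise ValueError(
                f"absolute-defect depth must be <= -20 dB, got {self.depth}")
        if self.noise_sd < 0 or self.relative_dip_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")

    @property
    def category(self) -> int:
        return CATEGORY_OF_SUBTYPE[self.subtype]


@dataclass(frozen=True)
class LabeledField:
    record: VFRecord
    label: GradeLabel

    def __post_init__(self):
        if self.label.subtype is not None and \
                CATEGORY_OF_SUBTYPE[self.label.subtype] != self.label.category:
            raise ValueError("label category inconsistent with subtype")


# ---------------------------------------------------------------------------
# defect geometry selectors (right-eye convention; side = +1 superior)
# ---------------------------------------------------------------------------

def _nasal_step(pattern: TestPattern, side: int) -> np.ndarray:
    x, y = pattern.points.T
    return np.flatnonzero((x <= NASAL_X) & (side * y > 0) & (side * y <= NASAL_Y_MAX))


def _paracentral(pattern: TestPattern, side: int) -> np.ndarray:
    x, y = pattern.points.T
    ecc = pattern.eccentricity()
    return np.flatnonzero((ecc <= PARACENTRAL_ECC) & (x <= 0) & (side * y > 0))


def _temporal_wedge(pattern: TestPattern, side: int) -> np.ndarray:
    x, y = pattern.points.T
    return np.flatnonzero((x >= WEDGE_X) & (side * y >= WEDGE_Y))


def _arc_path(pattern: TestPattern, side: int) -> list[int]:
    """Shortest adjacency path along the Bjerrum band, blind spot to nasal."""
    import networkx as nx

    pts = pattern.points
    ecc = pattern.eccentricity()
    bs = set(int(i) for i in pattern.blind_spot)
    band = [int(i) for i in range(pattern.n_points)
            if i not in bs and ARC_BAND[0] <= ecc[i] <= ARC_BAND[1]
            and side * pts[i, 1] > 0]
    G = nx.Graph()
    G.add_nodes_from(band)
    band_set = set(band)
    for a, b in pattern.adjacency:
        if a in band_set and b in band_set:
            G.add_edge(a, b, weight=float(np.linalg.norm(pts[a] - pts[b])))
    adj = pattern.adjacency_lists()
    sources = sorted(i for i in band if any(n in bs for n in adj[i]))
    target = min(band, key=lambda i: (pts[i, 0], abs(pts[i, 1]), i))
    best: tuple[float, list[int]] | None = None
    for src in sources:
        try:
            length, path = nx.single_source_dijkstra(G, src, target)
        except nx.NetworkXNoPath:
            continue
        if best is None or length < best[0]:
            best = (length, path)
    if best is None:
        raise RuntimeError(
            f"no Bjerrum arc path on pattern {pattern.pattern_id.value}")
    return best[1]


def _defect_indices(pattern: TestPattern, subtype: Subtype, side: int
                    ) -> np.ndarray:
    x, y = pattern.points.T
    ecc = pattern.eccentricity()
    if subtype is Subtype.CLEAR:
        return np.array([], dtype=int)
    if subtype is Subtype.NASAL_STEP:
        return _nasal_step(pattern, side)
    if subtype is Subtype.PARACENTRAL_SCOTOMA:
        return _paracentral(pattern, side)
    if subtype is Subtype.TEMPORAL_WEDGE:
        return _temporal_wedge(pattern, side)
    if subtype is Subtype.PARTIAL_ARCUATE:
        path = _arc_path(pattern, side)
        return np.array(path[:max(2, math.ceil(len(path) / 2))], dtype=int)
    if subtype is Subtype.ARCUATE:
        return np.array(_arc_path(pattern, side), dtype=int)
    if subtype is Subtype.ALTITUDINAL:
        return np.flatnonzero(side * y > 0)
    if subtype is Subtype.DOUBLE_ARCUATE:
        return np.array(sorted(set(_arc_path(pattern, +1))
                               | set(_arc_path(pattern, -1))), dtype=int)
    if subtype is Subtype.TUBULAR_VISION:
        return np.flatnonzero(ecc > ISLAND_RADIUS)
    if subtype is Subtype.DIFFUSE_DEFECT:
        return np.flatnonzero(x <= CRESCENT_X)
    if subtype is Subtype.TOTAL_LOSS:
        return np.arange(pattern.n_points)
    raise ValueError(f"unknown subtype: {subtype}")


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_field(spec: DefectSpec, pattern_id: PatternId | str,
                   patient_id: str | None = None,
                   exam_date: date = date(2020, 1, 1)) -> LabeledField:
    """Realise one labelled synthetic field; deterministic given spec.seed."""
    pattern = get_pattern(pattern_id)
    rng = np.random.default_rng(spec.seed)
    side = 1 if rng.random() < 0.5 else -1
    if spec.relative_dip_sd > 0:
        lo, hi = BASELINE_WINDOW
        a, b = lo / spec.relative_dip_sd, hi / spec.relative_dip_sd
        dev = truncnorm.rvs(a, b, scale=spec.relative_dip_sd,
                            size=pattern.n_points, random_state=rng)
    else:
        dev = np.zeros(pattern.n_points)
    idx = _defect_indices(pattern, spec.subtype, side)
    if spec.subtype is Subtype.DIFFUSE_DEFECT:
        dev[idx] += spec.depth
    else:
        dev[idx] = spec.depth
    if spec.noise_sd > 0:
        dev += rng.normal(0.0, spec.noise_sd, pattern.n_points)
    dev = np.round(np.clip(dev, *DEVIATION_WINDOW), 1)
    fp, fn, fl = np.round(rng.uniform(0.0, 0.25, 3), 2)
    record = VFRecord(
        patient_id=patient_id or f"sim-{spec.subtype.value}-{spec.seed}",
        eye=Eye.R, exam_date=exam_date, pattern_id=PatternId(pattern_id),
        deviations=dev, fp_rate=float(fp), fn_rate=float(fn), fl_rate=float(fl),
        right_eye_format=True)
    return LabeledField(record, GradeLabel(spec.category, spec.subtype))


def generate_dataset(n_per_class: int, pattern_id: PatternId | str,
                     noise_sd: float = 0.0, seed: int = 0,
                     depth: float = -32.0, relative_dip_sd: float = 1.0,
                     ) -> list[LabeledField]:
    """5 * n_per_class labelled fields, subtypes cycled within each category.

    Per-record seeds follow the counter scheme
    ``(seed + 1_000_003 * counter) mod 2**31``, so the whole dataset is
    reproducible bit-exactly from the master seed.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    fields = []
    counter = 0
    for category in range(1, 6):
        subs = SUBTYPES_OF_CATEGORY[category]
        for i in range(n_per_class):
            spec = DefectSpec(subtype=subs[i % len(subs)], depth=depth,
                              noise_sd=noise_sd,
                              relative_dip_sd=relative_dip_sd,
                              seed=(seed + SEED_STRIDE * counter) % SEED_MOD)
            lf = generate_field(
                spec, pattern_id, patient_id=f"P{counter:05d}",
                exam_date=date(2020, 1, 1) + timedelta(days=counter % 3650))
            fields.append(lf)
            counter += 1
    return fields


def labels_csv_rows(fields: list[LabeledField]) -> list[dict]:
    """Rows for the labels CSV (patient_id, eye, exam_date, category, subtype)."""
    return [{"patient_id": f.record.patient_id,
             "eye": f.record.eye.value,
             "exam_date": f.record.exam_date.isoformat(),
             "category": f.label.category,
             "subtype": f.label.subtype.value if f.label.subtype else ""}
            for f in fields]
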