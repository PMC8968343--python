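"""Morphological grading of visual-field defects.

A deterministic classifier over the five-category clinical scale:

1. clear field -- only relative defects;
2. mild defect -- spot/stroke/arcuate absolute defects with no connection to
   the blind spot (nasal step, paracentral scotoma, temporal wedge);
3. moderate defect -- arcuate absolute defects connected to the blind spot,
   with or without nasal breakthrough (partial arcuate, arcuate, altitudinal);
4. severe defect -- extensive ring or half-ring defects with a maintained
   central island (double arcuate, tubular vision);
5. diffuse defect -- central island collapse with at most the temporal
   crescent remaining (diffuse depression, total loss).

"Absolute" defect is operationalised as deviation <= -20 dB (well below
device noise); connectivity runs over the test pattern's adjacency graph,
with the physiologic blind-spot points excluded from the defect mask but
usable as connectivity anchors. All thresholds live in :class:`RuleConfig`.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np

from .patterns import TestPattern
from .records import Eye, VFRecord


class Subtype(str, Enum):
    CLEAR = "clear"
    NASAL_STEP = "nasal_step"
    PARACENTRAL_SCOTOMA = "paracentral_scotoma"
    TEMPORAL_WEDGE = "temporal_wedge"
    PARTIAL_ARCUATE = "partial_arcuate"
    ARCUATE = "arcuate"
    ALTITUDINAL = "altitudinal"
    DOUBLE_ARCUATE = "double_arcuate"
    TUBULAR_VISION = "tubular_vision"
    DIFFUSE_DEFECT = "diffuse_defect"
    TOTAL_LOSS = "total_loss"


CATEGORY_OF_SUBTYPE: dict[Subtype, int] = {
    Subtype.CLEAR: 1,
    Subtype.NASAL_STEP: 2,
    Subtype.PARACENTRAL_SCOTOMA: 2,
    Subtype.TEMPORAL_WEDGE: 2,
    Subtype.PARTIAL_ARCUATE: 3,
    Subtype.ARCUATE: 3,
    Subtype.ALTITUDINAL: 3,
    Subtype.DOUBLE_ARCUATE: 4,
    Subtype.TUBULAR_VISION: 4,
    Subtype.DIFFUSE_DEFECT: 5,
    Subtype.TOTAL_LOSS: 5,
}

SUBTYPES_OF_CATEGORY: dict[int, list[Subtype]] = {
    1: [Subtype.CLEAR],
    2: [Subtype.NASAL_STEP, Subtype.PARACENTRAL_SCOTOMA, Subtype.TEMPORAL_WEDGE],
    3: [Subtype.PARTIAL_ARCUATE, Subtype.ARCUATE, Subtype.ALTITUDINAL],
    4: [Subtype.DOUBLE_ARCUATE, Subtype.TUBULAR_VISION],
    5: [Subtype.DIFFUSE_DEFECT, Subtype.TOTAL_LOSS],
}


@dataclass(frozen=True)
class GradeLabel:
    """Severity category 1-5 with optional morphological subtype."""

    category: int
    subtype: Optional[Subtype] = None

    def __post_init__(self):
        if not 1 <= self.category <= 5:
            raise ValueError(f"category must be 1..5, got {self.category}")
        if self.subtype is not None and CATEGORY_OF_SUBTYPE[self.subtype] != self.category:
            raise ValueError(
                f"subtype {self.subtype.value} belongs to category "
                f"{CATEGORY_OF_SUBTYPE[self.subtype]}, not {self.category}")


@dataclass(frozen=True)
class RuleConfig:
    """Declared constants of the grading cascade (all in degrees / dB)."""

    threshold: float = -20.0          # absolute-defect depth
    island_radius: float = 8.0        # central island eccentricity
    crescent_x: float = 20.0          # temporal crescent beyond this x
    diffuse_fraction: float = 0.90    # mask fraction for central collapse
    deep_singleton_margin: float = 8.0  # lone point counts if <= threshold - margin
    hemifield_fraction: float = 0.90  # altitudinal: masked share of a hemifield
    nasal_reach_x: float = -10.0      # an arc reaching beyond this is "full"
    paracentral_ecc: float = 12.0     # category-2 cluster wholly inside this


DEFAULT_RULES = RuleConfig()


@dataclass(frozen=True)
class DefectGraph:
    """Connected components of the absolute-defect mask."""

    mask: np.ndarray                      # per-point bool, blind spot False
    components: tuple[tuple[int, ...], ...]
    blind_spot_connected: tuple[bool, ...]


def absolute_mask(record: VFRecord, threshold: float = DEFAULT_RULES.threshold
                  ) -> np.ndarray:
    """Per-point absolute-defect mask: deviation <= threshold.

    Blind-spot points are excluded from the mask (they act only as
    connectivity anchors).
    """
    mask = record.deviations <= threshold
    mask[record.pattern.blind_spot] = False
    return mask


def _bfs_components(indices: list[int], adj: list[list[int]]
                    ) -> list[list[int]]:
    """Connected components of the subgraph induced by ``indices`` (BFS)."""
    in_set = set(indices)
    seen: set[int] = set()
    comps = []
    for start in indices:
        if start in seen:
            continue
        comp = []
        queue = [start]
        seen.add(start)
        while queue:
            u = queue.pop()
            comp.append(u)
            for v in adj[u]:
                if v in in_set and v not in seen:
                    seen.add(v)
                    queue.append(v)
        comps.append(sorted(comp))
    return comps


def build_defect_graph(record: VFRecord,
                       threshold: float = DEFAULT_RULES.threshold) -> DefectGraph:
    """Mask the field and split it into adjacency-connected components."""
    pattern = record.pattern
    mask = absolute_mask(record, threshold)
    adj = pattern.adjacency_lists()
    comps = _bfs_components(sorted(np.flatnonzero(mask).tolist()), adj)
    bs = set(int(i) for i in pattern.blind_spot)
    bs_neigh = set()
    for b in bs:
        bs_neigh.update(adj[b])
    connected = tuple(any(p in bs_neigh or p in bs for p in comp) for comp in comps)
    return DefectGraph(mask, tuple(tuple(c) for c in comps), connected)


def _hemifield_arc(pattern: TestPattern, mask: np.ndarray, side: int,
                   cfg: RuleConfig) -> bool:
    """True if the masked points of one hemifield link the blind spot to the
    nasal field (a blind-spot-spanning arc)."""
    pts = pattern.points
    adj = pattern.adjacency_lists()
    hemi = [i for i in np.flatnonzero(mask) if side * pts[i, 1] > 0]
    if not hemi:
        return False
    bs = set(int(i) for i in pattern.blind_spot)
    bs_neigh = set()
    for b in bs:
        bs_neigh.update(adj[b])
    for comp in _bfs_components(hemi, adj):
        if any(p in bs_neigh for p in comp) and \
                min(pts[p, 0] for p in comp) <= cfg.nasal_reach_x:
            return True
    return False


def classify(record: VFRecord, threshold: float = DEFAULT_RULES.threshold,
             config: RuleConfig | None = None) -> GradeLabel:
    """Grade one right-eye-format field through the 5 -> 1 decision cascade."""
    cfg = config or DEFAULT_RULES
    if threshold != cfg.threshold:
        cfg = RuleConfig(**{**cfg.__dict__, "threshold": threshold})
    if record.eye is Eye.L and not record.right_eye_format:
        raise ValueError("record must be in right-eye format (run to_right_eye)")
    pattern = record.pattern
    pts = pattern.points
    nonbs = pattern.non_blind_spot
    graph = build_defect_graph(record, cfg.threshold)
    mask = graph.mask
    ecc = pattern.eccentricity()
    island = nonbs[ecc[nonbs] <= cfg.island_radius]
    temporal = nonbs[pts[nonbs, 0] > cfg.crescent_x]
    non_temporal = nonbs[pts[nonbs, 0] <= cfg.crescent_x]
    masked_frac = mask[nonbs].sum() / len(nonbs)

    # category 5: central island collapse, at most the temporal crescent left
    crescent_spared = len(temporal) > 0 and bool(np.any(~mask[temporal]))
    collapse = bool(np.all(mask[non_temporal])) and masked_frac >= cfg.diffuse_fraction
    diffuse = (float(np.median(record.deviations[nonbs])) <= cfg.threshold
               and not np.any(~mask[island]))
    if collapse or diffuse:
        sub = Subtype.DIFFUSE_DEFECT if crescent_spared else Subtype.TOTAL_LOSS
        return GradeLabel(5, sub)

    # category 4: ring/double-arc defects sparing the central island
    island_spared = len(island) > 0 and not np.any(mask[island])
    non_island = nonbs[ecc[nonbs] > cfg.island_radius]
    if island_spared and bool(np.all(mask[non_island])):
        return GradeLabel(4, Subtype.TUBULAR_VISION)
    if island_spared and _hemifield_arc(pattern, mask, +1, cfg) \
            and _hemifield_arc(pattern, mask, -1, cfg):
        return GradeLabel(4, Subtype.DOUBLE_ARCUATE)

    # category 3: any component connected to the blind spot
    if any(graph.blind_spot_connected):
        for side in (+1, -1):
            hemi = nonbs[side * pts[nonbs, 1] > 0]
            if len(hemi) and mask[hemi].sum() / len(hemi) >= cfg.hemifield_fraction:
                return GradeLabel(3, Subtype.ALTITUDINAL)
        reach = False
        for comp, bs_conn in zip(graph.components, graph.blind_spot_connected):
            if bs_conn and min(pts[p, 0] for p in comp) <= cfg.nasal_reach_x:
                reach = True
        return GradeLabel(3, Subtype.ARCUATE if reach else Subtype.PARTIAL_ARCUATE)

    # category 2: isolated absolute defects away from the blind spot
    deep = cfg.threshold - cfg.deep_singleton_margin
    qualifying = [c for c in graph.components
                  if len(c) >= 2 or record.deviations[c[0]] <= deep]
    if qualifying:
        primary = max(qualifying,
                      key=lambda c: (len(c), -float(record.deviations[list(c)].mean())))
        cpts = pts[list(primary)]
        if np.all(np.hypot(cpts[:, 0], cpts[:, 1]) <= cfg.paracentral_ecc):
            sub = Subtype.PARACENTRAL_SCOTOMA
        elif cpts[:, 0].mean() < 0:
            sub = Subtype.NASAL_STEP
        else:
            sub = Subtype.TEMPORAL_WEDGE
        return GradeLabel(2, sub)

    return GradeLabel(1, Subtype.CLEAR)
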