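"""Structure-function sector mapping.

Visual-field test points are grouped into 10 clusters, each associated with
an angular sector of the optic-nerve-head (ONH) circle; functional loss in a
cluster predicts rim damage in its ONH sector. The shipped cluster tables
(``clusters_<pattern>.csv``: point_index,cluster_id and ``onh_sectors.csv``:
cluster_id,angle_start_deg,angle_end_deg) are synthetic stand-ins built from
36-degree field wedges with an inverted field-to-disc arc correspondence;
the published cluster schemes are not reproduced verbatim, and the tables
are data fixtures meant to be edited.

A cluster counts as damaged when the mean deviation over its (non-blind-spot)
points is at or below the damage criterion (default -5 dB).
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .patterns import PatternId, get_pattern
from .records import VFRecord

N_CLUSTERS = 10
#: cluster mean deviation at or below this counts as damage (dB)
DAMAGE_CRITERION_DB = -5.0

_CLUSTER_FIXTURES = {
    PatternId.G1: "clusters_g1.csv",
    PatternId.HFA24_2: "clusters_hfa24_2.csv",
    PatternId.HFA30_2: "clusters_hfa30_2.csv",
}


@dataclass(frozen=True)
class SectorMap:
    """Per-point cluster ids (1-10) and per-cluster ONH angular arcs."""

    pattern_id: PatternId
    vf_cluster_of: np.ndarray                      # (k,) ints in 1..10
    onh_sector_of: dict[int, tuple[float, float]]  # cluster -> [start, end) deg

    def __post_init__(self):
        pattern = get_pattern(self.pattern_id)
        cl = np.asarray(self.vf_cluster_of, dtype=int)
        if cl.shape != (pattern.n_points,):
            raise ValueError("cluster table does not match the pattern")
        nonbs = pattern.non_blind_spot
        ids = set(cl[nonbs].tolist())
        if not ids <= set(range(1, N_CLUSTERS + 1)):
            raise ValueError(f"cluster ids outside 1..{N_CLUSTERS}: {ids}")
        if ids != set(range(1, N_CLUSTERS + 1)):
            raise ValueError(f"cluster ids must cover 1..{N_CLUSTERS}, got {ids}")
        cl.setflags(write=False)
        object.__setattr__(self, "vf_cluster_of", cl)


def load_sector_map(pattern_id: PatternId | str) -> SectorMap:
    pattern_id = PatternId(pattern_id)
    with resources.files("vfgrade.data").joinpath(
            _CLUSTER_FIXTURES[pattern_id]).open() as f:
        rows = list(csv.DictReader(f))
    clusters = np.full(len(rows), -1, dtype=int)
    for r in rows:
        clusters[int(r["point_index"])] = int(r["cluster_id"])
    with resources.files("vfgrade.data").joinpath("onh_sectors.csv").open() as f:
        arcs = {int(r["cluster_id"]):
                (float(r["angle_start_deg"]), float(r["angle_end_deg"]))
                for r in csv.DictReader(f)}
    return SectorMap(pattern_id, clusters, arcs)


def damaged_clusters(record: VFRecord, sector_map: SectorMap | None = None,
                     criterion_db: float = DAMAGE_CRITERION_DB
                     ) -> tuple[int, dict[int, bool]]:
    """Count damaged clusters and flag each one.

    A cluster is damaged iff the mean deviation over its non-blind-spot
    points is <= criterion_db.
    """
    sector_map = sector_map or load_sector_map(record.pattern_id)
    if sector_map.pattern_id != record.pattern_id:
        raise ValueError(
            f"sector map is for {sector_map.pattern_id.value}, record is "
            f"{record.pattern_id.value}")
    pattern = record.pattern
    nonbs = pattern.non_blind_spot
    flags = {}
    for c in range(1, N_CLUSTERS + 1):
        pts = nonbs[sector_map.vf_cluster_of[nonbs] == c]
        flags[c] = bool(record.deviations[pts].mean() <= criterion_db)
    return sum(flags.values()), flags


def expected_onh_sectors(flags: dict[int, bool] | list[bool],
                         sector_map: SectorMap) -> list[tuple[float, float]]:
    """ONH angular ranges predicted to show rim damage, from cluster flags."""
    if not isinstance(flags, dict):
        if len(flags) != N_CLUSTERS:
            raise ValueError(f"need {N_CLUSTERS} flags, got {len(flags)}")
        flags = {c: bool(v) for c, v in zip(range(1, N_CLUSTERS + 1), flags)}
    return [sector_map.onh_sector_of[c]
            for c in sorted(flags) if flags[c]]
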