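"""Delineation of the ventricular outer and inner curvature (OC / IC).

All constructions happen in the lateral-view plane, mirroring how specimens
are mounted flat on one side before landmarking.  Landmarks are placed by
fixed fractions of arc length:

48 hpf
    The OC-side arc runs from one cell diameter past the AVC (PB_OC) to the
    distal OFT boundary; DB_OC sits at 2/3 of that arc.  The OC is everything
    on the convex side of the cut through PB_OC and DB_OC.  The IC-side arc
    runs from the AVC (PB_IC) to its distal OFT boundary with DB_IC at 1/2;
    the IC is the surface region enclosed by PB_IC→Point II, Point II→Point
    III, Point III→DB_IC and the IC arc back to PB_IC, where Point I lies at
    1/2 of the PB_OC→DB_OC arc, Point II at 1/3 of the straight segment
    PB_IC→Point I and Point III halfway between DB_IC and DB_OC.

36–37 hpf
    Curvature contours are shallower, so both regions get explicit medial
    borders: Points I and II at 1/3 and 2/3 of segment PB_OC→PB_IC, Points
    III and IV at 1/3 and 2/3 of segment DB_OC→DB_IC.  OC is bounded by the
    OC arc and PB_OC→I, I→III, III→DB_OC; IC by the IC arc and PB_IC→II,
    II→IV, IV→DB_IC.  The strip between the two medial borders belongs to
    neither region.

Cells are assigned to a region when at least half of their (projected) apical
area falls inside it; OC cells are split into proximal and distal halves at
the arc midpoint of PB_OC→DB_OC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely import prepared
from shapely.geometry import LineString, Point, Polygon

from .geometry import HeartModel

__all__ = [
    "ArcLandmarks",
    "BoundarySegment",
    "RegionBoundaries",
    "locate_landmarks_48",
    "locate_landmarks_36",
    "locate_landmarks",
    "build_region_boundaries",
    "assign_cells",
    "select_mosaic_cells",
]

_ARC_SAMPLES = 400


@dataclass
class ArcLandmarks:
    """Arc positions (µm) and lateral-view points bounding the curvatures."""

    stage: str
    PB_OC: float
    DB_OC: float
    DB_OFT_OC: float
    PB_IC: float
    DB_IC: float
    DB_OFT_IC: float
    point_i: np.ndarray
    point_ii: np.ndarray
    point_iii: np.ndarray
    point_iv: np.ndarray | None
    # anchor points and sampled arcs, used to build region boundaries
    pb_oc_2d: np.ndarray = field(repr=False, default=None)
    db_oc_2d: np.ndarray = field(repr=False, default=None)
    pb_ic_2d: np.ndarray = field(repr=False, default=None)
    db_ic_2d: np.ndarray = field(repr=False, default=None)
    avc_2d: np.ndarray = field(repr=False, default=None)
    arc_center_2d: np.ndarray = field(repr=False, default=None)
    oc_arc_s: np.ndarray = field(repr=False, default=None)
    oc_arc_2d: np.ndarray = field(repr=False, default=None)
    ic_arc_s: np.ndarray = field(repr=False, default=None)
    ic_arc_2d: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if not (0 <= self.PB_OC < self.DB_OC <= self.DB_OFT_OC):
            raise ValueError("OC landmarks must satisfy 0 <= PB < DB <= DB_OFT")
        if not (0 <= self.PB_IC < self.DB_IC <= self.DB_OFT_IC):
            raise ValueError("IC landmarks must satisfy 0 <= PB < DB <= DB_OFT")


def _common_landmarks(heart: HeartModel, cell_diameter: float | None):
    d = heart.cell_diameter_typical if cell_diameter is None else float(cell_diameter)
    if d < 0:
        raise ValueError("cell_diameter must be >= 0")
    if d >= heart.oc_arc_length:
        raise ValueError(
            f"cell_diameter ({d} µm) must be smaller than the OC arc "
            f"({heart.oc_arc_length:.1f} µm)"
        )
    pb_oc = d
    db_oft_oc = heart.oc_arc_length
    db_oc = pb_oc + (2.0 / 3.0) * (db_oft_oc - pb_oc)
    pb_ic = 0.0
    db_oft_ic = heart.ic_arc_length
    db_ic = pb_ic + 0.5 * (db_oft_ic - pb_ic)
    return d, pb_oc, db_oc, db_oft_oc, pb_ic, db_ic, db_oft_ic


def _arc_fields(heart: HeartModel) -> dict:
    oc_s, oc_2d = heart.oc_arc_samples(_ARC_SAMPLES)
    ic_s, ic_2d = heart.ic_arc_samples(_ARC_SAMPLES)
    return dict(
        avc_2d=heart.oc_point_2d(0.0),
        arc_center_2d=heart.bend_center_2d(),
        oc_arc_s=oc_s,
        oc_arc_2d=oc_2d,
        ic_arc_s=ic_s,
        ic_arc_2d=ic_2d,
    )


def locate_landmarks_48(
    heart: HeartModel, cell_diameter: float | None = None
) -> ArcLandmarks:
    """48 hpf landmark rules (2/3 OC arc, 1/2 IC arc, Points I–III)."""
    _, pb_oc, db_oc, db_oft_oc, pb_ic, db_ic, db_oft_ic = _common_landmarks(
        heart, cell_diameter
    )
    pb_oc_2d = heart.oc_point_2d(pb_oc)
    db_oc_2d = heart.oc_point_2d(db_oc)
    pb_ic_2d = heart.ic_point_2d(pb_ic)
    db_ic_2d = heart.ic_point_2d(db_ic)
    point_i = heart.oc_point_2d(pb_oc + 0.5 * (db_oc - pb_oc))
    point_ii = pb_ic_2d + (point_i - pb_ic_2d) / 3.0
    point_iii = 0.5 * (db_ic_2d + db_oc_2d)
    return ArcLandmarks(
        stage="48",
        PB_OC=pb_oc, DB_OC=db_oc, DB_OFT_OC=db_oft_oc,
        PB_IC=pb_ic, DB_IC=db_ic, DB_OFT_IC=db_oft_ic,
        point_i=point_i, point_ii=point_ii, point_iii=point_iii, point_iv=None,
        pb_oc_2d=pb_oc_2d, db_oc_2d=db_oc_2d, pb_ic_2d=pb_ic_2d,
        db_ic_2d=db_ic_2d, **_arc_fields(heart),
    )


def locate_landmarks_36(
    heart: HeartModel, cell_diameter: float | None = None
) -> ArcLandmarks:
    """36–37 hpf landmark rules (thirds of the two inter-arc segments)."""
    _, pb_oc, db_oc, db_oft_oc, pb_ic, db_ic, db_oft_ic = _common_landmarks(
        heart, cell_diameter
    )
    pb_oc_2d = heart.oc_point_2d(pb_oc)
    db_oc_2d = heart.oc_point_2d(db_oc)
    pb_ic_2d = heart.ic_point_2d(pb_ic)
    db_ic_2d = heart.ic_point_2d(db_ic)
    point_i = pb_oc_2d + (pb_ic_2d - pb_oc_2d) / 3.0
    point_ii = pb_oc_2d + 2.0 * (pb_ic_2d - pb_oc_2d) / 3.0
    point_iii = db_oc_2d + (db_ic_2d - db_oc_2d) / 3.0
    point_iv = db_oc_2d + 2.0 * (db_ic_2d - db_oc_2d) / 3.0
    return ArcLandmarks(
        stage=heart.stage if heart.stage in ("36", "37") else "36",
        PB_OC=pb_oc, DB_OC=db_oc, DB_OFT_OC=db_oft_oc,
        PB_IC=pb_ic, DB_IC=db_ic, DB_OFT_IC=db_oft_ic,
        point_i=point_i, point_ii=point_ii, point_iii=point_iii,
        point_iv=point_iv,
        pb_oc_2d=pb_oc_2d, db_oc_2d=db_oc_2d, pb_ic_2d=pb_ic_2d,
        db_ic_2d=db_ic_2d, **_arc_fields(heart),
    )


def locate_landmarks(heart: HeartModel, cell_diameter: float | None = None):
    """Stage-dispatching wrapper."""
    if heart.stage == "48":
        return locate_landmarks_48(heart, cell_diameter)
    return locate_landmarks_36(heart, cell_diameter)


@dataclass
class BoundarySegment:
    role: str
    p0: np.ndarray
    p1: np.ndarray


@dataclass
class RegionBoundaries:
    """Region predicates and cut geometry derived from the landmarks."""

    stage: str
    segments: list
    oc_polygon: Polygon
    ic_polygon: Polygon
    oc_mid_arc: float
    landmarks: ArcLandmarks = field(repr=False, default=None)
    # half-plane cut (48 hpf): point on the cut and unit normal toward the OC
    cut_point: np.ndarray | None = field(repr=False, default=None)
    cut_normal: np.ndarray | None = field(repr=False, default=None)

    def __post_init__(self) -> None:
        self._oc_prep = prepared.prep(self.oc_polygon)
        self._ic_prep = prepared.prep(self.ic_polygon)

    def region_of(self, point) -> str:
        """OC/IC/neither classification of a lateral-view point."""
        p = Point(np.asarray(point, dtype=float))
        if self._oc_prep.covers(p):
            return "OC"
        if self._ic_prep.covers(p):
            return "IC"
        return "neither"

    def _arc_angle(self, point_2d: np.ndarray) -> float:
        """Sweep angle of a lateral-view point about the arc centre, from AVC."""
        lm = self.landmarks
        c = lm.arc_center_2d
        a0 = math.atan2(*(lm.avc_2d - c)[::-1])
        a = math.atan2(*(np.asarray(point_2d) - c)[::-1])
        return (a - a0) % (2 * math.pi)

    def subregion_of(self, point_2d) -> str:
        """proximal/distal split of the OC at the PB_OC→DB_OC arc midpoint."""
        lm = self.landmarks
        mid_2d = _oc_arc_point(lm, self.oc_mid_arc)
        return "proximal" if self._arc_angle(point_2d) < self._arc_angle(mid_2d) else "distal"


def _oc_arc_point(lm: ArcLandmarks, s: float) -> np.ndarray:
    x = np.interp(s, lm.oc_arc_s, lm.oc_arc_2d[:, 0])
    y = np.interp(s, lm.oc_arc_s, lm.oc_arc_2d[:, 1])
    return np.array([x, y])


def _arc_between(s: np.ndarray, pts: np.ndarray, s0: float, s1: float) -> np.ndarray:
    """Sampled arc points for arc positions in [s0, s1] (inclusive ends)."""
    inner = (s > s0) & (s < s1)
    p0 = np.array([np.interp(s0, s, pts[:, 0]), np.interp(s0, s, pts[:, 1])])
    p1 = np.array([np.interp(s1, s, pts[:, 0]), np.interp(s1, s, pts[:, 1])])
    return np.vstack([p0, pts[inner], p1])


def _checked_polygon(coords: np.ndarray, label: str) -> Polygon:
    poly = Polygon(coords)
    if not poly.is_valid or poly.area <= 0:
        raise ValueError(f"{label} boundary polygon is degenerate or self-intersecting")
    return poly


def build_region_boundaries(landmarks: ArcLandmarks) -> RegionBoundaries:
    """Turn landmarks into concrete boundary segments and region predicates."""
    lm = landmarks
    oc_mid_arc = lm.PB_OC + 0.5 * (lm.DB_OC - lm.PB_OC)
    if lm.stage == "48":
        return _boundaries_48(lm, oc_mid_arc)
    return _boundaries_36(lm, oc_mid_arc)


def _boundaries_48(lm: ArcLandmarks, oc_mid_arc: float) -> RegionBoundaries:
    a, b = lm.pb_oc_2d, lm.db_oc_2d
    chord = b - a
    normal = np.array([-chord[1], chord[0]])
    normal /= np.linalg.norm(normal)
    # orient the normal toward the convex side (where the OC arc bulges)
    ref = _oc_arc_point(lm, oc_mid_arc)
    if np.dot(ref - a, normal) < 0:
        normal = -normal
    # half-plane as a large polygon so area fractions can be intersected
    all_pts = np.vstack([lm.oc_arc_2d, lm.ic_arc_2d])
    span = float(np.ptp(all_pts, axis=0).max()) * 4.0 + 1.0
    d = chord / np.linalg.norm(chord)
    oc_poly = _checked_polygon(
        np.array([a - span * d, b + span * d,
                  b + span * d + span * normal, a - span * d + span * normal]),
        "OC",
    )
    ic_coords = np.vstack(
        [
            lm.pb_ic_2d,
            lm.point_ii,
            lm.point_iii,
            lm.db_ic_2d,
            _arc_between(lm.ic_arc_s, lm.ic_arc_2d, lm.PB_IC, lm.DB_IC)[::-1],
        ]
    )
    ic_poly = _checked_polygon(ic_coords, "IC")
    ic_poly = ic_poly.difference(oc_poly)  # enforce mutual exclusivity
    segments = [
        BoundarySegment("OC cut", a, b),
        BoundarySegment("IC proximal border", lm.pb_ic_2d, lm.point_ii),
        BoundarySegment("IC medial slicer", lm.point_ii, lm.point_iii),
        BoundarySegment("IC distal border", lm.point_iii, lm.db_ic_2d),
    ]
    return RegionBoundaries(
        stage="48", segments=segments, oc_polygon=oc_poly, ic_polygon=ic_poly,
        oc_mid_arc=oc_mid_arc, landmarks=lm, cut_point=a, cut_normal=normal,
    )


def _boundaries_36(lm: ArcLandmarks, oc_mid_arc: float) -> RegionBoundaries:
    oc_coords = np.vstack(
        [
            _arc_between(lm.oc_arc_s, lm.oc_arc_2d, lm.PB_OC, lm.DB_OC),
            lm.point_iii,
            lm.point_i,
        ]
    )
    ic_coords = np.vstack(
        [
            _arc_between(lm.ic_arc_s, lm.ic_arc_2d, lm.PB_IC, lm.DB_IC)[::-1],
            lm.point_ii,
            lm.point_iv,
        ]
    )
    oc_poly = _checked_polygon(oc_coords, "OC")
    ic_poly = _checked_polygon(ic_coords, "IC")
    ic_poly = ic_poly.difference(oc_poly)
    segments = [
        BoundarySegment("OC proximal border", lm.pb_oc_2d, lm.point_i),
        BoundarySegment("OC medial border", lm.point_i, lm.point_iii),
        BoundarySegment("OC distal border", lm.point_iii, lm.db_oc_2d),
        BoundarySegment("IC proximal border", lm.pb_ic_2d, lm.point_ii),
        BoundarySegment("IC medial border", lm.point_ii, lm.point_iv),
        BoundarySegment("IC distal border", lm.point_iv, lm.db_ic_2d),
    ]
    return RegionBoundaries(
        stage=lm.stage, segments=segments, oc_polygon=oc_poly,
        ic_polygon=ic_poly, oc_mid_arc=oc_mid_arc, landmarks=lm,
    )


def _valid_projection(poly: Polygon):
    """Region covered by a projected outline, robust to projection folds.

    A cell straddling the crest of the tube projects to a self-overlapping
    polygon whose signed (shoelace) area can cancel; ``make_valid`` recovers
    the actually covered region instead.
    """
    if poly.is_valid:
        return poly
    from shapely import make_valid
    from shapely.ops import unary_union

    valid = make_valid(poly)
    parts = [g for g in getattr(valid, "geoms", [valid])
             if g.geom_type in ("Polygon", "MultiPolygon")]
    return unary_union(parts) if parts else valid


def assign_cells(cells, boundaries: RegionBoundaries) -> pd.DataFrame:
    """Assign each cell to OC/IC/neither by projected apical-area overlap.

    A cell joins a region when at least half of its lateral-view apical area
    lies inside that region's boundary (ties at exactly one half count as
    inside).  Returns a table with one row per cell: ``cell_id``, ``region``,
    ``subregion`` (proximal/distal for OC cells, "none" otherwise) and
    ``in_region_area_fraction``.
    """
    rows = []
    for cell in cells:
        poly = _valid_projection(cell.apical_polygon_2d())
        if poly.area <= 0:
            raise ValueError(f"zero projected apical area for cell {cell.cell_id!r}")
        frac_oc = poly.intersection(boundaries.oc_polygon).area / poly.area
        frac_ic = poly.intersection(boundaries.ic_polygon).area / poly.area
        if frac_oc >= 0.5:
            region, frac = "OC", frac_oc
        elif frac_ic >= 0.5:
            region, frac = "IC", frac_ic
        else:
            region, frac = "neither", max(frac_oc, frac_ic)
        sub = "none"
        if region == "OC":
            centroid = np.asarray(poly.centroid.coords[0])
            sub = boundaries.subregion_of(centroid)
        rows.append(
            dict(cell_id=cell.cell_id, embryo_id=cell.embryo_id, region=region,
                 subregion=sub, in_region_area_fraction=frac)
        )
    return pd.DataFrame(rows)


def select_mosaic_cells(
    cells, assignment: pd.DataFrame, max_distance: int = 2
) -> tuple[set, set]:
    """Mosaic-analysis cell selection.

    Donor-derived cells are analysed whenever they fall inside the OC or IC.
    Host-derived cells are analysed when inside the OC or IC *and* within
    ``max_distance`` steps of a donor cell on the cell-contact graph (direct
    contact = 1, one cell-distance = 2).
    """
    region = dict(zip(assignment["cell_id"], assignment["region"]))
    by_id = {c.cell_id: c for c in cells}
    donors = [c.cell_id for c in cells if c.clone_label == "donor"]
    donor_set = {cid for cid in donors if region.get(cid, "neither") != "neither"}
    # multi-source BFS from every donor cell
    dist = {cid: 0 for cid in donors}
    frontier = list(donors)
    while frontier:
        nxt = []
        for cid in frontier:
            if dist[cid] >= max_distance:
                continue
            for nb in by_id[cid].neighbors:
                if nb not in dist:
                    dist[nb] = dist[cid] + 1
                    nxt.append(nb)
        frontier = nxt
    host_set = {
        c.cell_id
        for c in cells
        if c.clone_label == "host"
        and region.get(c.cell_id, "neither") != "neither"
        and dist.get(c.cell_id, max_distance + 1) <= max_distance
    }
    return donor_set, host_set
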