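"""Per-cell 3D shape metrics.

Four metrics describe each cardiomyocyte, mirroring how flat-mounted
confocal reconstructions are measured by hand:

* **apical surface area** — the apical outline is projected to its best-fit
  plane; outlines that curve out of plane beyond a threshold are first split
  at the plane of greatest curvature (perpendicular to the cell's long axis),
  each part projected to its own tangent plane, and the parts rejoined at the
  cut before tracing ("snapshot stitching");
* **circularity** — ``4*pi*A / P**2``, 1 for a circle;
* **apicobasal length** — the mean of the four lateral-wall lengths read
  from two cross-sections through the cell, one along each principal axis of
  the apical outline;
* **volume** — the product ``mean basal width x mean apical width x mean
  apicobasal length``.  This is deliberately the box estimator used on the
  cross-section measurements, not a mesh integral: for tapered (frustum)
  cells it undercounts the true volume by h/3*(w_basal - w_apical)^2 in the
  square-frustum family (documented estimator bias).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .geometry import (
    fit_plane,
    polygon_area_perimeter,
    polygon_plane_intersections,
    principal_axes_2d,
    project_to_plane,
)
from .model import Cardiomyocyte

__all__ = [
    "ApicalTrace",
    "CrossSectionMeasure",
    "MorphometricsRecord",
    "StitchingError",
    "trace_apical",
    "compute_circularity",
    "cross_section_measures",
    "apicobasal_length",
    "estimate_volume",
    "measure_cell",
    "measure_cells",
]


class StitchingError(RuntimeError):
    """Snapshot stitching produced a self-intersecting or split outline."""


@dataclass
class ApicalTrace:
    """Stitched, flattened apical outline with its area and perimeter."""

    outline_2d: np.ndarray  # (M, 2) closed polygon, vertices listed once
    n_segments: int
    area: float
    perimeter: float

    def __post_init__(self) -> None:
        if not (self.area > 0 and self.perimeter > 0):
            raise ValueError("trace must have positive area and perimeter")
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")


@dataclass
class CrossSectionMeasure:
    """Widths and lateral-wall lengths read from one cell cross-section."""

    axis: str
    basal_width: float
    apical_width: float
    lateral_lengths: tuple[float, float]

    def __post_init__(self) -> None:
        vals = (self.basal_width, self.apical_width, *self.lateral_lengths)
        if any(v < 0 for v in vals):
            raise ValueError("cross-section measures must be >= 0")
        if len(self.lateral_lengths) != 2:
            raise ValueError("exactly two lateral lengths per section")


@dataclass
class MorphometricsRecord:
    cell_id: str
    embryo_id: str
    apical_area: float
    circularity: float
    apicobasal_length: float
    mean_basal_width: float
    mean_apical_width: float
    volume: float
    region: str = "none"
    subregion: str = "none"
    genotype_label: str = "WT"
    clone_label: str = "host"


# ---------------------------------------------------------------------------
# Apical tracing with stitching
# ---------------------------------------------------------------------------

def _max_plane_deviation(loop: np.ndarray) -> float:
    centroid, _, normal = fit_plane(loop)
    return float(np.max(np.abs((loop - centroid) @ normal)))


def _split_loop(loop: np.ndarray, axis: np.ndarray, origin: np.ndarray,
                t_cut: float):
    """Split a closed 3D loop by the plane ``axis . (x - origin) = t_cut``.

    Returns ``(low_loop, high_loop, cut_points)`` or None when the plane does
    not cut the loop in exactly two edges.
    """
    t = (loop - origin) @ axis - t_cut
    n = len(loop)
    crossings = [i for i in range(n) if (t[i] < 0) != (t[(i + 1) % n] < 0)]
    if len(crossings) != 2:
        return None
    pts = {}
    for i in crossings:
        j = (i + 1) % n
        lam = t[i] / (t[i] - t[j])
        pts[i] = loop[i] + lam * (loop[j] - loop[i])
    i0, i1 = crossings
    seg_a = [pts[i0]] + [loop[k % n] for k in range(i0 + 1, i1 + 1)] + [pts[i1]]
    seg_b = [pts[i1]] + [loop[k % n] for k in range(i1 + 1, i0 + n + 1)] + [pts[i0]]
    loop_a, loop_b = np.array(seg_a), np.array(seg_b)
    if t[(i0 + 1) % n] < 0:
        low, high = loop_a, loop_b
    else:
        low, high = loop_b, loop_a
    return low, high, (pts[i0], pts[i1])


def _best_split(loop: np.ndarray, axis: np.ndarray, origin: np.ndarray):
    """Cut position minimising the worse of the two halves' plane deviations."""
    t = (loop - origin) @ axis
    lo, hi = np.quantile(t, [0.15, 0.85])
    best = None
    for t_cut in np.linspace(lo, hi, 17):
        parts = _split_loop(loop, axis, origin, t_cut)
        if parts is None:
            continue
        low, high, cut = parts
        cost = max(_max_plane_deviation(low), _max_plane_deviation(high))
        if best is None or cost < best[0]:
            best = (cost, low, high, cut)
    if best is None:
        raise StitchingError("no valid cut perpendicular to the long axis")
    return best[1], best[2], best[3]


def _flatten_piece(loop: np.ndarray, cut_pts):
    """Project a loop to its tangent plane; return 2D polygon + cut images."""
    centroid, basis, _ = fit_plane(loop)
    poly2d = project_to_plane(loop, centroid, basis)
    cuts2d = [project_to_plane(np.asarray(p)[None, :], centroid, basis)[0]
              for p in cut_pts]
    return poly2d, cuts2d


def _chord_transform(src_a, src_b, target_a, target_b, reflect: bool):
    """Rigid 2D map taking chord (src_a, src_b) onto (target_a, target_b).

    With ``reflect`` the source is first mirrored across its own chord, which
    flips which side of the chord the piece lands on.  Chord lengths match by
    construction; no rescaling is applied.
    """
    src_a, src_b = np.asarray(src_a), np.asarray(src_b)
    target_a, target_b = np.asarray(target_a), np.asarray(target_b)

    def transform(points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points) - src_a
        if reflect:
            d = src_b - src_a
            nrm = np.array([-d[1], d[0]]) / np.linalg.norm(d)
            pts = pts - 2.0 * np.outer(pts @ nrm, nrm)
        sv = src_b - src_a
        tv = target_b - target_a
        ang = math.atan2(tv[1], tv[0]) - math.atan2(sv[1], sv[0])
        c, s = math.cos(ang), math.sin(ang)
        rot = np.array([[c, -s], [s, c]])
        return pts @ rot.T + target_a

    return transform


def _chord_side(points: np.ndarray, a, b) -> float:
    """Mean signed side of points relative to chord a->b."""
    a, b = np.asarray(a), np.asarray(b)
    d = b - a
    normal = np.array([-d[1], d[0]])
    return float(np.mean((points - a) @ normal))


def trace_apical(
    cell, curvature_threshold: float = 1.0, max_segments: int = 2
) -> ApicalTrace:
    """Flatten a (possibly Z-curved) apical outline and trace its border.

    ``cell`` may be a Cardiomyocyte or an (N, 3) outline array.  When the
    outline's maximum deviation from its best-fit plane exceeds
    ``curvature_threshold`` (µm), it is split perpendicular to its long axis
    at the cut minimising residual curvature, each side projected to its own
    tangent plane, and the sides rejoined at the cut; up to
    ``max_segments - 1`` splits are applied, worst piece first.
    """
    outline = np.asarray(
        cell.apical_outline if isinstance(cell, Cardiomyocyte) else cell,
        dtype=float,
    )
    if outline.ndim != 2 or outline.shape[1] != 3 or len(outline) < 3:
        raise ValueError("outline must be an (N>=3, 3) array")
    if max_segments < 1:
        raise ValueError("max_segments must be >= 1")

    centroid, basis, _ = fit_plane(outline)
    major2d, _, _ = principal_axes_2d(project_to_plane(outline, centroid, basis))
    axis3d = major2d @ basis
    axis3d /= np.linalg.norm(axis3d)

    # pieces ordered along the long axis; cut chords between consecutive pieces
    pieces: list[np.ndarray] = [outline]
    cuts: list = []  # cuts[k] joins pieces[k] and pieces[k+1]
    while len(pieces) < max_segments:
        devs = [_max_plane_deviation(p) for p in pieces]
        worst = int(np.argmax(devs))
        if devs[worst] <= curvature_threshold:
            break
        low, high, cut = _best_split(pieces[worst], axis3d, centroid)
        pieces[worst: worst + 1] = [low, high]
        cuts.insert(worst, cut)

    if len(pieces) == 1:
        poly2d = project_to_plane(outline, centroid, basis)
        merged = Polygon(poly2d)
        if not merged.is_valid:
            raise StitchingError("projected outline is self-intersecting")
        area, perim = polygon_area_perimeter(poly2d)
        return ApicalTrace(outline_2d=poly2d, n_segments=1, area=area,
                           perimeter=perim)

    # flatten each piece, then chain-align across the shared cut chords
    flat0, cut_imgs = _flatten_piece(pieces[0], cuts[0])
    placed: list[np.ndarray] = [flat0]
    prev_chord = cut_imgs  # images of the chord joining piece k-1 and k
    for k in range(1, len(pieces)):
        this_cuts = [cuts[k - 1][0], cuts[k - 1][1]]
        if k < len(cuts):
            this_cuts += [cuts[k][0], cuts[k][1]]
        flat, imgs = _flatten_piece(pieces[k], this_cuts)
        prev_side = _chord_side(placed[-1], prev_chord[0], prev_chord[1])
        moved = None
        for reflect in (False, True):
            tf = _chord_transform(imgs[0], imgs[1], prev_chord[0],
                                  prev_chord[1], reflect)
            cand = tf(flat)
            # the new piece must sit on the opposite side of the shared chord
            if _chord_side(cand, prev_chord[0], prev_chord[1]) * prev_side <= 0:
                moved = cand
                fwd = tf(np.asarray(imgs[2:])) if k < len(cuts) else None
                break
        if moved is None:
            raise StitchingError("could not place a stitched segment")
        placed.append(moved)
        if k < len(cuts):
            prev_chord = [fwd[0], fwd[1]]

    if len(placed) == 2:
        # each piece's 2D chain runs cut-point to cut-point, so the rejoined
        # border is the two chains concatenated (dropping duplicate cut points)
        xy = np.vstack([placed[0], placed[1][1:-1]])
        merged = Polygon(xy)
        if not merged.is_valid:
            raise StitchingError(
                "rejoined outline is self-intersecting; inspect the cut "
                "position and segment projections"
            )
    else:
        scale = math.sqrt(sum(abs(polygon_area_perimeter(a)[0]) for a in placed))
        eps = 1e-4 * max(scale, 1.0)
        merged = unary_union([Polygon(a).buffer(eps) for a in placed]).buffer(-eps)
        if merged.geom_type != "Polygon" or not merged.is_valid:
            raise StitchingError(
                f"stitched outline is not a single simple polygon "
                f"({merged.geom_type}, {len(pieces)} segments)"
            )
        xy = np.asarray(merged.exterior.coords)[:-1]
    area, perim = polygon_area_perimeter(xy)
    return ApicalTrace(outline_2d=xy, n_segments=len(pieces), area=area,
                       perimeter=perim)


def compute_circularity(trace) -> float:
    """``4*pi*A/P**2`` of a trace (or an ``(area, perimeter)`` pair)."""
    if isinstance(trace, ApicalTrace):
        area, perim = trace.area, trace.perimeter
    else:
        area, perim = trace
    if not (np.isfinite(area) and np.isfinite(perim)):
        raise ValueError("non-finite area/perimeter")
    if perim <= 0:
        raise ValueError("perimeter must be > 0")
    return 4.0 * math.pi * area / perim**2


# ---------------------------------------------------------------------------
# Cross-sections, apicobasal length, volume
# ---------------------------------------------------------------------------

def cross_section_measures(
    cell, symmetric_tol: float = 1e-6
) -> tuple[CrossSectionMeasure, CrossSectionMeasure]:
    """Widths and lateral lengths from two orthogonal cross-sections.

    Cutting planes pass through the apical-outline centroid, perpendicular
    to the apical surface, one containing each principal axis of the outline
    (X: major, Y: minor).  For circularly symmetric outlines the axes are
    ambiguous; fixed in-plane axes are used and a warning emitted.
    """
    apical = np.asarray(cell.apical_outline, dtype=float)
    basal = np.asarray(cell.basal_outline, dtype=float)
    centroid, basis, normal = fit_plane(apical)
    coords2d = project_to_plane(apical, centroid, basis)
    major2d, minor2d, ratio = principal_axes_2d(coords2d)
    if ratio > 1.0 - symmetric_tol:
        warnings.warn(
            "apical outline is circularly symmetric; falling back to fixed "
            "X/Y section axes", stacklevel=2,
        )
        major2d, minor2d = np.array([1.0, 0.0]), np.array([0.0, 1.0])
    sections = []
    for label, axis2d in (("X", major2d), ("Y", minor2d)):
        u = axis2d @ basis
        u /= np.linalg.norm(u)
        m = np.cross(u, normal)
        m /= np.linalg.norm(m)
        a_pts = polygon_plane_intersections(apical, centroid, m)
        b_pts = polygon_plane_intersections(basal, centroid, m)
        if len(b_pts) < 2:
            # very narrow or strongly curved cells: the basal outline can sit
            # entirely to one side of the apical-centroid plane; read it with
            # the parallel plane through its own centroid instead
            b_pts = polygon_plane_intersections(basal, basal.mean(axis=0), m)
        if len(a_pts) < 2 or len(b_pts) < 2:
            raise ValueError(
                f"{label} section plane does not cut cell {getattr(cell, 'cell_id', '?')!r}"
            )
        ta = (a_pts - centroid) @ u
        tb = (b_pts - centroid) @ u
        a_lo, a_hi = a_pts[np.argmin(ta)], a_pts[np.argmax(ta)]
        b_lo, b_hi = b_pts[np.argmin(tb)], b_pts[np.argmax(tb)]
        sections.append(
            CrossSectionMeasure(
                axis=label,
                basal_width=float(np.linalg.norm(b_hi - b_lo)),
                apical_width=float(np.linalg.norm(a_hi - a_lo)),
                lateral_lengths=(
                    float(np.linalg.norm(a_lo - b_lo)),
                    float(np.linalg.norm(a_hi - b_hi)),
                ),
            )
        )
    return sections[0], sections[1]


def apicobasal_length(sections) -> float:
    """Mean of the four lateral-wall lengths from the two cross-sections."""
    sections = tuple(sections)
    if len(sections) != 2 or any(s is None for s in sections):
        raise ValueError("need exactly two cross-sections")
    lats = [v for s in sections for v in s.lateral_lengths]
    return float(np.mean(lats))


def estimate_volume(sections, length: float) -> float:
    """Box volume estimator: mean basal width x mean apical width x length.

    Matches the spreadsheet calculation applied to the hand measurements;
    it equals the true volume only for a cuboid and undercounts tapered
    (frustum-like) cells.
    """
    if length < 0:
        raise ValueError("length must be >= 0")
    sections = tuple(sections)
    if len(sections) != 2:
        raise ValueError("need exactly two cross-sections")
    bw = [s.basal_width for s in sections]
    aw = [s.apical_width for s in sections]
    if any(v < 0 for v in bw + aw):
        raise ValueError("widths must be >= 0")
    return float(np.mean(bw) * np.mean(aw) * length)


def measure_cell(
    cell: Cardiomyocyte, curvature_threshold: float = 1.0, max_segments: int = 2,
    region: str = "none", subregion: str = "none",
) -> MorphometricsRecord:
    """All four shape metrics for one cell."""
    trace = trace_apical(cell, curvature_threshold, max_segments)
    sx, sy = cross_section_measures(cell)
    length = apicobasal_length((sx, sy))
    bw = float(np.mean([sx.basal_width, sy.basal_width]))
    aw = float(np.mean([sx.apical_width, sy.apical_width]))
    return MorphometricsRecord(
        cell_id=cell.cell_id,
        embryo_id=cell.embryo_id,
        apical_area=trace.area,
        circularity=compute_circularity(trace),
        apicobasal_length=length,
        mean_basal_width=bw,
        mean_apical_width=aw,
        volume=estimate_volume((sx, sy), length),
        region=region,
        subregion=subregion,
        genotype_label=cell.genotype_label,
        clone_label=cell.clone_label,
    )


def measure_cells(
    cells, assignment: pd.DataFrame | None = None,
    curvature_threshold: float = 1.0, max_segments: int = 2,
) -> pd.DataFrame:
    """Morphometrics table for a cell list, joined with region labels."""
    labels = {}
    if assignment is not None:
        labels = {
            row.cell_id: (row.region, row.subregion)
            for row in assignment.itertuples()
        }
    records = []
    for cell in cells:
        region, subregion = labels.get(cell.cell_id, ("none", "none"))
        rec = measure_cell(cell, curvature_threshold, max_segments,
                           region=region, subregion=subregion)
        records.append(rec.__dict__)
    return pd.DataFrame(records)
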