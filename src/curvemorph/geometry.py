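"""Parametric heart-tube geometry.

The embryonic ventricle is modelled as a planar-bent tube: a circle of radius
``tube_radius`` swept around a bend of radius ``bend_radius`` through
``bend_angle`` radians (a torus sector).  The convex sweep side of the tube is
the prospective outer curvature (OC); the concave side is the inner curvature
(IC).  The bend lies in the z = 0 plane, which doubles as the lateral mounting
plane of the specimen: projecting along +z gives the lateral view used for all
landmark and boundary constructions.

Surface coordinates are ``(phi, theta)``: ``phi`` is the sweep angle from the
atrioventricular canal (AVC, ``phi = 0``) toward the outflow tract (OFT,
``phi = bend_angle``) and ``theta`` the circumferential angle around the tube
(``theta = 0`` points radially outward, onto the OC midline; ``theta = pi``
onto the IC midline).  Arc-length parameterizations along the OC-side and
IC-side surface curves (``s = phi * (bend_radius +/- tube_radius)``) are the
coordinates in which all landmarks are stated.

Units are micrometres throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "HeartModel",
    "fit_plane",
    "project_to_plane",
    "polygon_area_perimeter",
    "principal_axes_2d",
    "polygon_plane_intersections",
    "rotate_2d",
]


def rotate_2d(points: np.ndarray, angle: float) -> np.ndarray:
    """Rotate 2D point(s) by ``angle`` radians about the origin."""
    c, s = math.cos(angle), math.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    return np.asarray(points, dtype=float) @ rot.T


@dataclass(frozen=True)
class HeartModel:
    """Planar-bent tube model of the embryonic ventricle.

    Parameters
    ----------
    stage:
        Developmental stage label, one of ``"36"``, ``"37"``, ``"48"`` (hpf).
    bend_radius:
        Radius of the sweep circle (distance from bend centre to the tube
        centreline), µm.  Must exceed ``tube_radius`` so the surface is
        injective.
    tube_radius:
        Radius of the swept tube cross-section, µm.
    bend_angle:
        Angular extent of the sweep (AVC plane to distal OFT boundary), rad.
    cell_diameter_typical:
        Typical cardiomyocyte diameter, µm; used for the "one cell diameter
        from the AVC" landmark rule.
    frame_rotation, frame_offset:
        Optional rigid motion within the lateral-view plane (rotation about
        the view axis, then translation).  The canonical frame puts the bend
        centre at the origin with the AVC at polar angle zero.
    """

    stage: str = "48"
    bend_radius: float = 80.0
    tube_radius: float = 40.0
    bend_angle: float = 2.4
    cell_diameter_typical: float = 13.0
    frame_rotation: float = 0.0
    frame_offset: tuple[float, float] = (0.0, 0.0)
    #: unit vector of the lateral-view projection axis (out of the mount plane)
    lateral_view_axis: tuple[float, float, float] = field(
        default=(0.0, 0.0, 1.0), repr=False
    )

    def __post_init__(self) -> None:
        if self.stage not in {"36", "37", "48"}:
            raise ValueError(f"unsupported stage {self.stage!r}")
        if not (self.bend_radius > self.tube_radius > 0):
            raise ValueError(
                "need bend_radius > tube_radius > 0 for an injective midsurface"
            )
        if not (0 < self.bend_angle < 2 * math.pi):
            raise ValueError("bend_angle must lie in (0, 2*pi)")
        if self.cell_diameter_typical < 0:
            raise ValueError("cell_diameter_typical must be >= 0")

    # -- arc lengths ------------------------------------------------------
    @property
    def oc_arc_length(self) -> float:
        return self.bend_angle * (self.bend_radius + self.tube_radius)

    @property
    def ic_arc_length(self) -> float:
        return self.bend_angle * (self.bend_radius - self.tube_radius)

    @property
    def centerline_length(self) -> float:
        return self.bend_angle * self.bend_radius

    @property
    def landmarks_raw(self) -> dict[str, float]:
        """Raw anatomical anchors: AVC at s=0, distal OFT boundaries."""
        return {
            "AVC": 0.0,
            "DB_OFT_OC": self.oc_arc_length,
            "DB_OFT_IC": self.ic_arc_length,
        }

    # -- frame ------------------------------------------------------------
    def _frame_2d(self, q: np.ndarray) -> np.ndarray:
        return rotate_2d(q, self.frame_rotation) + np.asarray(self.frame_offset)

    def with_frame(self, rotation: float, offset: tuple[float, float]) -> "HeartModel":
        return replace(self, frame_rotation=rotation, frame_offset=tuple(offset))

    # -- surface maps -----------------------------------------------------
    def projected_radius(self, theta):
        """Distance of the surface point from the bend centre in lateral view."""
        return self.bend_radius + self.tube_radius * np.cos(theta)

    def surface_point(self, phi, theta) -> np.ndarray:
        """Map ``(phi, theta)`` to 3D, broadcasting over array inputs."""
        phi = np.asarray(phi, dtype=float)
        theta = np.asarray(theta, dtype=float)
        rho = self.projected_radius(theta)
        xy = np.stack([rho * np.cos(phi), rho * np.sin(phi)], axis=-1)
        xy = self._frame_2d(xy)
        z = np.broadcast_to(self.tube_radius * np.sin(theta), phi.shape if phi.shape else theta.shape)
        return np.concatenate([xy, np.asarray(z)[..., None]], axis=-1)

    def midsurface(self, s, theta) -> np.ndarray:
        """Spec-facing map: ``s`` is centreline arc length from the AVC plane."""
        return self.surface_point(np.asarray(s, dtype=float) / self.bend_radius, theta)

    # -- lateral-view arcs -------------------------------------------------
    def bend_center_2d(self) -> np.ndarray:
        return self._frame_2d(np.zeros(2))

    def oc_point_2d(self, s_oc) -> np.ndarray:
        """Lateral-view position of the OC-side surface curve at arc length s."""
        phi = np.asarray(s_oc, dtype=float) / (self.bend_radius + self.tube_radius)
        rho = self.bend_radius + self.tube_radius
        return self._frame_2d(np.stack([rho * np.cos(phi), rho * np.sin(phi)], axis=-1))

    def ic_point_2d(self, s_ic) -> np.ndarray:
        phi = np.asarray(s_ic, dtype=float) / (self.bend_radius - self.tube_radius)
        rho = self.bend_radius - self.tube_radius
        return self._frame_2d(np.stack([rho * np.cos(phi), rho * np.sin(phi)], axis=-1))

    def oc_arc_samples(self, n: int = 256) -> tuple[np.ndarray, np.ndarray]:
        """(arc positions, 2D points) sampled along the full OC-side curve."""
        s = np.linspace(0.0, self.oc_arc_length, n)
        return s, self.oc_point_2d(s)

    def ic_arc_samples(self, n: int = 256) -> tuple[np.ndarray, np.ndarray]:
        s = np.linspace(0.0, self.ic_arc_length, n)
        return s, self.ic_point_2d(s)

    # -- areas ------------------------------------------------------------
    def patch_surface_area(
        self, phi0: float, phi1: float, theta0: float, theta1: float
    ) -> float:
        """Exact area of the surface patch ``[phi0,phi1] x [theta0,theta1]``.

        The torus area element is ``r (R + r cos(theta)) dphi dtheta``.
        """
        r, big_r = self.tube_radius, self.bend_radius
        return r * (phi1 - phi0) * (
            big_r * (theta1 - theta0) + r * (math.sin(theta1) - math.sin(theta0))
        )


# ---------------------------------------------------------------------------
# Generic 3D/2D helpers shared by the morphometrics and rendering code.
# ---------------------------------------------------------------------------

def fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares plane through 3D points.

    Returns ``(centroid, basis, normal)`` where ``basis`` is a (2, 3) array of
    orthonormal in-plane directions and ``normal`` the unit plane normal.
    """
    pts = np.asarray(points, dtype=float)
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    return centroid, vt[:2], vt[2]


def project_to_plane(
    points: np.ndarray, centroid: np.ndarray, basis: np.ndarray
) -> np.ndarray:
    """In-plane (u, v) coordinates of 3D points for a plane from fit_plane."""
    return (np.asarray(points, dtype=float) - centroid) @ np.asarray(basis).T


def polygon_area_perimeter(coords: np.ndarray) -> tuple[float, float]:
    """Shoelace area (absolute) and perimeter of a closed 2D polygon.

    ``coords`` lists the vertices once (no repeated closing vertex).
    """
    xy = np.asarray(coords, dtype=float)
    x, y = xy[:, 0], xy[:, 1]
    x2, y2 = np.roll(x, -1), np.roll(y, -1)
    area = 0.5 * abs(np.sum(x * y2 - x2 * y))
    perim = float(np.sum(np.hypot(x2 - x, y2 - y)))
    return float(area), perim


def principal_axes_2d(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Principal axes of a 2D vertex set from its second moments.

    Returns ``(major, minor, anisotropy)`` with unit axis vectors and the
    eigenvalue ratio ``lambda_minor / lambda_major`` (1 means circularly
    symmetric second moments, i.e. no well-defined axes).
    """
    xy = np.asarray(coords, dtype=float)
    centred = xy - xy.mean(axis=0)
    cov = centred.T @ centred / len(centred)
    evals, evecs = np.linalg.eigh(cov)
    # eigh sorts ascending: column 1 is the major axis
    major, minor = evecs[:, 1], evecs[:, 0]
    ratio = float(evals[0] / evals[1]) if evals[1] > 0 else 1.0
    return major, minor, ratio


def polygon_plane_intersections(
    vertices: np.ndarray, plane_point: np.ndarray, plane_normal: np.ndarray
) -> np.ndarray:
    """Intersection points of a closed 3D polygon's edges with a plane.

    Vertices exactly on the plane are counted once.  Returns an (m, 3) array.
    """
    verts = np.asarray(vertices, dtype=float)
    n = np.asarray(plane_normal, dtype=float)
    d = (verts - np.asarray(plane_point, dtype=float)) @ n
    pts = []
    m = len(verts)
    for i in range(m):
        j = (i + 1) % m
        di, dj = d[i], d[j]
        if di == 0.0:
            pts.append(verts[i])
        elif (di < 0) != (dj < 0) and dj != 0.0:
            t = di / (di - dj)
            pts.append(verts[i] + t * (verts[j] - verts[i]))
    if not pts:
        return np.empty((0, 3))
    out = np.array(pts)
    # drop duplicates from vertices lying exactly on the plane
    keep = [0]
    for k in range(1, len(out)):
        if np.all(np.linalg.norm(out[keep] - out[k], axis=1) > 1e-9):
            keep.append(k)
    return out[keep]
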