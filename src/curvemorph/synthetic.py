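"""Seeded synthetic ventricles: geometry, cells, intensities, images.

The generator lays cardiomyocytes onto the bent-tube surface as a row-based
brick tiling in ``(phi, theta)`` parameters: rows run along the long axis of
the ventricle and are filled circumferentially, each cell's angular width
solved so that the *flat area of its apical outline polygon* equals an
apical-area value drawn from the configured (truncated-at-zero normal)
distribution.  Thin inter-cell gaps absorb the mismatch between drawn areas
and region area, so outlines never overlap.  OC cells are wider
circumferentially than longitudinally (elongated along theta); IC cells are
nearly isotropic and taller apicobasally.

Placement domains are insets of the same lateral-view region boundaries the
delineation stage reconstructs, so generation truth and downstream assignment
agree except for deliberate boundary cases.

Per-membrane channel intensities follow a per-region fraction triplet
(basal, lateral, apical): each cell gets one lognormal overall scale and
domain means proportional to the triplet, so renormalizing any cell's truth
recovers the configured triplet exactly.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import replace

import numpy as np
from shapely.geometry import LineString, Polygon

from .config import GeneratorConfig
from .geometry import HeartModel, fit_plane, polygon_area_perimeter, project_to_plane
from .model import CHANNELS, Cardiomyocyte, CrossSectionImage
from .regions import RegionBoundaries, build_region_boundaries, locate_landmarks

__all__ = [
    "InfeasibleTilingError",
    "generate_heart",
    "generate_population",
    "render_cross_section",
]

_EDGE_SUBDIV = 4  # boundary points per outline edge (16-gon cells)
_BAND_PX = 3.0  # rendered intensity band thickness, px
_LATERAL_DOMAINS = {
    "X": ("lateral-x-left", "lateral-x-right"),
    "Y": ("lateral-y-left", "lateral-y-right"),
}


class InfeasibleTilingError(RuntimeError):
    """Requested cell count does not fit the available region surface."""


def _heart_from_config(cfg: GeneratorConfig) -> HeartModel:
    return HeartModel(
        stage=cfg.stage,
        bend_radius=cfg.bend_radius,
        tube_radius=cfg.tube_radius,
        bend_angle=cfg.bend_angle,
        cell_diameter_typical=cfg.cell_diameter_typical,
    )


def _draw_positive(rng: np.random.Generator, mean: float, sd: float, n: int,
                   floor: float = 0.0) -> np.ndarray:
    """Normal draws truncated at > floor by redraw."""
    out = rng.normal(mean, sd, n)
    for _ in range(1000):
        bad = out <= floor
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    raise RuntimeError("could not draw positive values; check mean/sd")


def _surface_xyz(cfg: GeneratorConfig, phi, theta, radial: float) -> np.ndarray:
    """Point at tube-radial distance ``radial`` from the tube centreline."""
    rho = cfg.bend_radius + radial * np.cos(theta)
    return np.stack(
        [rho * np.cos(phi), rho * np.sin(phi), radial * np.sin(theta)], axis=-1
    )


def _box_outline(cfg: GeneratorConfig, phi0, phi1, th0, th1, radial) -> np.ndarray:
    """16-gon outline of a parameter box on the surface at ``radial``."""
    k = _EDGE_SUBDIV
    phis = np.concatenate([
        np.full(k, phi0), np.linspace(phi0, phi1, k, endpoint=False),
        np.full(k, phi1), np.linspace(phi1, phi0, k, endpoint=False),
    ])
    thetas = np.concatenate([
        np.linspace(th0, th1, k, endpoint=False), np.full(k, th1),
        np.linspace(th1, th0, k, endpoint=False), np.full(k, th0),
    ])
    return _surface_xyz(cfg, phis, thetas, radial)


def _flat_area(outline: np.ndarray) -> float:
    centroid, basis, _ = fit_plane(outline)
    area, _ = polygon_area_perimeter(project_to_plane(outline, centroid, basis))
    return area


def _solve_theta_width(cfg: GeneratorConfig, phi0: float, phi1: float,
                       th0: float, area: float) -> float:
    """theta-width such that the flat apical polygon area equals ``area``."""
    r, big_r = cfg.tube_radius, cfg.bend_radius
    dphi = phi1 - phi0
    # smooth-patch initial guess, then two Newton steps on the patch formula
    dth = area / (r * dphi * (big_r + r * math.cos(th0)))
    for _ in range(2):
        f = big_r * dth + r * (math.sin(th0 + dth) - math.sin(th0)) - area / (r * dphi)
        dth -= f / (big_r + r * math.cos(th0 + dth))
    # correct for flat-polygon vs curved-patch area (few-percent effect)
    for _ in range(3):
        flat = _flat_area(_box_outline(cfg, phi0, phi1, th0, th0 + dth, r))
        dth *= area / flat
    return dth


def _ray_rho(polygon: Polygon, center: np.ndarray, angle: float,
             reach: float) -> np.ndarray:
    """Radii at which a ray from ``center`` traverses ``polygon`` (sorted)."""
    far = center + reach * np.array([math.cos(angle), math.sin(angle)])
    seg = LineString([center, far]).intersection(polygon)
    if seg.is_empty:
        return np.empty(0)
    coords = []
    geoms = getattr(seg, "geoms", [seg])
    for g in geoms:
        coords.extend(np.asarray(g.coords))
    if not coords:
        return np.empty(0)
    return np.sort(np.linalg.norm(np.asarray(coords) - center, axis=1))


def _theta_halfwidth(cfg: GeneratorConfig, polygon: Polygon, phi: float,
                     side: str, margin: float) -> float:
    """Admissible half-width of theta around the region midline at sweep phi.

    ``side`` is "outer" (OC, theta around 0: surface radius must stay above
    the region's inner boundary radius) or "inner" (IC, theta around pi:
    radius must stay below the region's outer boundary radius).
    """
    r, big_r = cfg.tube_radius, cfg.bend_radius
    reach = (big_r + r) * 2.0
    rho = _ray_rho(polygon, np.zeros(2), phi, reach)
    if rho.size < 2:
        return 0.0
    if side == "outer":
        limit = rho[0] + margin  # innermost crossing = region cut
        c = (limit - big_r) / r
        if c >= 1.0:
            return 0.0
        return math.acos(max(c, -1.0))
    limit = rho[-1] - margin  # outermost crossing
    c = (limit - big_r) / r
    if c <= -1.0:
        return 0.0
    return math.pi - math.acos(min(c, 1.0))


def _tile_region(cfg: GeneratorConfig, polygon: Polygon, side: str,
                 phi_lo: float, phi_hi: float, areas: np.ndarray,
                 elongation: float, label: str) -> list[tuple[float, float, float, float, float]]:
    """Fill a region with parameter boxes of exact flat areas.

    Returns one ``(phi0, phi1, th0, th1, area)`` tuple per cell, in draw
    order.  Raises InfeasibleTilingError when the draws do not fit.
    """
    r, big_r = cfg.tube_radius, cfg.bend_radius
    th_mid = 0.0 if side == "outer" else math.pi
    rho_mid = big_r + r * math.cos(th_mid)
    n = len(areas)
    mean_area = float(np.mean(areas))
    row_height = math.sqrt(mean_area / elongation)  # longitudinal extent, µm
    dphi_row = row_height / rho_mid
    gap_phi = cfg.gap / rho_mid
    gap_th = cfg.gap / r

    # candidate rows across the full admissible span
    rows = []
    phi = phi_lo
    while phi + dphi_row <= phi_hi + 1e-12:
        phi1 = phi + dphi_row
        half = min(
            _theta_halfwidth(cfg, polygon, phi, side, cfg.margin),
            _theta_halfwidth(cfg, polygon, phi1, side, cfg.margin),
        )
        rows.append((phi, phi1, half))
        phi = phi1 + gap_phi

    def fill_row(phi0, phi1, half, start, stop, draws):
        """Greedy sequential fill; returns placed boxes."""
        placed = []
        cursor = start
        for a in draws:
            dth = _solve_theta_width(cfg, phi0, phi1, cursor, a)
            if cursor + dth > stop:
                break
            placed.append((phi0, phi1, cursor, cursor + dth, float(a)))
            cursor += dth + gap_th
        return placed

    # phase 1: per-row capacity from one continuous greedy pass with the
    # draw sequence recycled (restarting the sequence per row would let one
    # large early draw depress every row's estimate)
    caps = []
    seq = np.resize(areas, 6 * n)
    ptr = 0
    for phi0, phi1, half in rows:
        sim = fill_row(phi0, phi1, half, th_mid - half, th_mid + half,
                       seq[ptr:])
        caps.append(len(sim))
        ptr += len(sim)
    total = sum(caps)
    if total < n:
        raise InfeasibleTilingError(
            f"{label}: region fits ~{total} cells but {n} were requested "
            f"(counts too high for the configured geometry)"
        )

    # phase 2: apportion cells to rows by capacity (largest remainder),
    # then fill each row centred on the region midline
    shares = [n * c / total for c in caps]
    quotas = [min(int(s), c) for s, c in zip(shares, caps)]
    remainder = n - sum(quotas)
    order = sorted(range(len(rows)), key=lambda k: shares[k] - int(shares[k]),
                   reverse=True)
    for k in order:
        if remainder == 0:
            break
        if quotas[k] < caps[k]:
            quotas[k] += 1
            remainder -= 1
    if remainder:
        raise InfeasibleTilingError(
            f"{label}: could not apportion {n} cells over {len(rows)} rows"
        )

    boxes: list[tuple[float, float, float, float, float]] = []
    idx = 0
    backlog = 0  # cells that did not fit their apportioned row
    for (phi0, phi1, half), quota in zip(rows, quotas):
        target = quota + backlog
        if target == 0:
            continue
        draws = areas[idx: idx + target]
        # dry run from the left edge to learn the block width, then centre it
        dry = fill_row(phi0, phi1, half, th_mid - half, th_mid + half, draws)
        if len(dry) == len(draws):
            width = dry[-1][3] - dry[0][2]
            start = th_mid - 0.5 * width
            centred = fill_row(phi0, phi1, half, start, th_mid + half, draws)
            if len(centred) == len(draws):
                dry = centred
        boxes.extend(dry)
        idx += len(dry)
        backlog = target - len(dry)
    if idx < n:
        raise InfeasibleTilingError(
            f"{label}: only {idx} of {n} cells fit the region surface "
            f"(counts too high for the configured geometry)"
        )
    return boxes


def _neighbor_lists(boxes: list, gap_phi: float, gap_th: float) -> list[list[int]]:
    """Edge-sharing adjacency from parameter boxes.

    Two cells are neighbours when their boxes touch (up to the inter-cell
    gap) along one axis while properly overlapping — by more than a quarter
    of the smaller extent — along the other, i.e. they share an edge rather
    than a corner.
    """
    n = len(boxes)
    arr = np.array([b[:4] for b in boxes])
    out: list[list[int]] = [[] for _ in range(n)]
    eps_p, eps_t = gap_phi * 1.5, gap_th * 1.5
    for i in range(n):
        p0, p1, t0, t1 = arr[i]
        ov_p = np.minimum(arr[:, 1], p1) - np.maximum(arr[:, 0], p0)
        ov_t = np.minimum(arr[:, 3], t1) - np.maximum(arr[:, 2], t0)
        min_p = np.minimum(arr[:, 1] - arr[:, 0], p1 - p0)
        min_t = np.minimum(arr[:, 3] - arr[:, 2], t1 - t0)
        share = ((ov_p > -eps_p) & (ov_t > 0.25 * min_t)) | (
            (ov_t > -eps_t) & (ov_p > 0.25 * min_p)
        )
        share[i] = False
        out[i] = list(np.nonzero(share)[0])
    return out


def _membrane_truth(rng: np.random.Generator, cfg: GeneratorConfig,
                    region: str) -> dict:
    scale = cfg.intensity_scale * math.exp(rng.normal(0.0, cfg.intensity_jitter))
    truth: dict = {}
    for chan in CHANNELS:
        if region in ("OC", "IC"):
            f_b, f_l, f_a = cfg.fractions(region, chan)
        else:
            f_b = f_l = f_a = 1.0 / 3.0
        truth[chan] = {
            "basal": f_b * scale,
            "apical": f_a * scale,
            "lateral-x-left": f_l * scale,
            "lateral-x-right": f_l * scale,
            "lateral-y-left": f_l * scale,
            "lateral-y-right": f_l * scale,
        }
    return truth


def generate_heart(
    config: GeneratorConfig, embryo_id: str = "e0"
) -> tuple[HeartModel, list[Cardiomyocyte]]:
    """Generate one seeded synthetic ventricle.

    Returns the tube model and the cell list (OC cells first, then IC, then
    unassigned flank cells).  Deterministic for a given config.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    heart = _heart_from_config(cfg)
    landmarks = locate_landmarks(heart)
    boundaries = build_region_boundaries(landmarks)

    r, big_r = cfg.tube_radius, cfg.bend_radius
    rho_oc, rho_ic = big_r + r, big_r - r
    margin_phi_oc = cfg.margin / rho_oc
    margin_phi_ic = cfg.margin / rho_ic

    plan = [
        ("OC", cfg.n_oc, cfg.oc_area_mean, cfg.oc_area_sd, cfg.oc_elongation,
         cfg.oc_height_mean, cfg.oc_height_sd, boundaries.oc_polygon, "outer",
         landmarks.PB_OC / rho_oc + margin_phi_oc,
         landmarks.DB_OC / rho_oc - margin_phi_oc),
        ("IC", cfg.n_ic, cfg.ic_area_mean, cfg.ic_area_sd, cfg.ic_elongation,
         cfg.ic_height_mean, cfg.ic_height_sd, boundaries.ic_polygon, "inner",
         margin_phi_ic, landmarks.DB_IC / rho_ic - margin_phi_ic),
    ]

    cells: list[Cardiomyocyte] = []
    all_boxes: list = []
    meta: list[tuple[str, float]] = []  # (region, height) per box
    for (region, n, a_mean, a_sd, elong, h_mean, h_sd, poly, side,
         phi_lo, phi_hi) in plan:
        areas = _draw_positive(rng, a_mean, a_sd, n, floor=1.0)
        heights = _draw_positive(rng, h_mean, h_sd, n, floor=0.5)
        boxes = _tile_region(cfg, poly, side, phi_lo, phi_hi, areas, elong, region)
        all_boxes.extend(boxes)
        meta.extend((region, float(h)) for h in heights[: len(boxes)])

    _place_flank_cells(cfg, rng, boundaries, all_boxes, meta)

    gap_phi = cfg.gap / big_r
    gap_th = cfg.gap / r
    neighbor_idx = _neighbor_lists(all_boxes, gap_phi, gap_th)

    n_cells = len(all_boxes)
    donor = np.zeros(n_cells, dtype=bool)
    if cfg.donor_fraction > 0:
        donor = rng.random(n_cells) < cfg.donor_fraction

    for i, ((phi0, phi1, th0, th1, area), (region, height)) in enumerate(
        zip(all_boxes, meta)
    ):
        apical = _box_outline(cfg, phi0, phi1, th0, th1, r)
        basal = _box_outline(cfg, phi0, phi1, th0, th1, r - height)
        th_c = 0.5 * (th0 + th1)
        phi_c = 0.5 * (phi0 + phi1)
        center_2d = heart.projected_radius(th_c) * np.array(
            [math.cos(phi_c), math.sin(phi_c)]
        )
        circ = r * (th1 - th0)
        lon = (big_r + r * math.cos(th_c)) * (phi1 - phi0)
        orientation = (
            ("circumferential", th_c) if circ >= lon else ("longitudinal", phi_c)
        )
        cells.append(
            Cardiomyocyte(
                cell_id=f"{embryo_id}_c{i:03d}",
                embryo_id=embryo_id,
                true_region=boundaries.region_of(center_2d),
                center=(phi_c * big_r, th_c),
                apical_outline=apical,
                basal_outline=basal,
                wall_heights=np.full(4, height),
                orientation=orientation,
                clone_label="donor" if donor[i] else "host",
                genotype_label=cfg.genotype,
                membrane_truth=_membrane_truth(rng, cfg, region),
                true_area=float(_flat_area(apical)),
                param_box=(phi0, phi1, th0, th1),
            )
        )
    for i, cell in enumerate(cells):
        cell.neighbors = [cells[j].cell_id for j in neighbor_idx[i]]
    return heart, cells


def _place_flank_cells(cfg: GeneratorConfig, rng: np.random.Generator,
                       boundaries: RegionBoundaries, all_boxes: list,
                       meta: list) -> None:
    """Opportunistically fill part of the distal flank with unassigned cells.

    Placement is best-effort: candidates whose projected corners touch either
    region are dropped, so the final count may fall short of ``n_neither``.
    """
    if cfg.n_neither == 0:
        return
    r, big_r = cfg.tube_radius, cfg.bend_radius
    areas = _draw_positive(rng, cfg.neither_area_mean, cfg.neither_area_sd,
                           cfg.n_neither, floor=1.0)
    heights = _draw_positive(rng, cfg.neither_height_mean,
                             cfg.neither_height_sd, cfg.n_neither, floor=0.5)
    lm = boundaries.landmarks
    phi_lo = lm.DB_OC / (big_r + r) + 3.0 * cfg.margin / (big_r + r)
    phi_hi = cfg.bend_angle - cfg.margin / (big_r + r)
    if phi_hi <= phi_lo:
        return
    row_h = math.sqrt(float(np.mean(areas)))
    dphi_row = row_h / (big_r + r)
    gap_th = cfg.gap / r
    idx = 0
    phi = phi_lo
    while idx < len(areas) and phi + dphi_row <= phi_hi:
        phi1 = phi + dphi_row
        th_cursor, th_stop = -0.9, 0.9
        while idx < len(areas) and th_cursor < th_stop:
            dth = _solve_theta_width(cfg, phi, phi1, th_cursor, areas[idx])
            if th_cursor + dth > th_stop:
                break
            corners_ok = all(
                boundaries.region_of(
                    (big_r + r * math.cos(t)) * np.array([math.cos(p), math.sin(p)])
                )
                == "neither"
                for p in (phi, phi1)
                for t in (th_cursor, th_cursor + dth)
            )
            if corners_ok:
                all_boxes.append((phi, phi1, th_cursor, th_cursor + dth,
                                  float(areas[idx])))
                meta.append(("neither", float(heights[idx])))
            th_cursor += dth + gap_th
            idx += 1
        phi = phi1 + cfg.gap / (big_r + r)


def generate_population(
    config: GeneratorConfig, n_cells: int, region: str = "OC",
    max_embryos: int = 64,
) -> list[Cardiomyocyte]:
    """Pool cells of one region from as many seeded hearts as needed.

    Embryo seeds are derived deterministically from ``config.seed``; cells are
    taken in generation order, so the first ``n_cells`` apical areas are iid
    draws from the configured distribution.  Mirrors how published group
    sizes pool a few hundred cells over a handful of embryos.
    """
    pooled: list[Cardiomyocyte] = []
    ss = np.random.SeedSequence(config.seed)
    for k, child in enumerate(ss.spawn(max_embryos)):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        _, cells = generate_heart(config.replace(seed=sub_seed), embryo_id=f"e{k}")
        pooled.extend(c for c in cells if c.true_region == region)
        if len(pooled) >= n_cells:
            return pooled[:n_cells]
    raise RuntimeError(f"could not pool {n_cells} {region} cells from "
                       f"{max_embryos} embryos")


# ---------------------------------------------------------------------------
# Cross-section rendering
# ---------------------------------------------------------------------------

def _section_frame(cell: Cardiomyocyte, axis: str):
    """(origin, in-section unit axes (u along cut, v apicobasal), cut normal)."""
    from .geometry import principal_axes_2d  # local import to avoid cycles

    centroid, basis, normal = fit_plane(cell.apical_outline)
    coords2d = project_to_plane(cell.apical_outline, centroid, basis)
    major2d, minor2d, _ = principal_axes_2d(coords2d)
    axis2d = major2d if axis == "X" else minor2d
    u = axis2d @ basis
    u /= np.linalg.norm(u)
    v = centroid - cell.basal_outline.mean(axis=0)  # basal -> apical direction
    v = v - (v @ u) * u
    nv = np.linalg.norm(v)
    if nv < 1e-9:
        v = normal.copy()
        nv = 1.0
    v /= nv
    m = np.cross(u, v)
    m /= np.linalg.norm(m)
    return centroid, u, v, m


def _section_tips(outline: np.ndarray, origin: np.ndarray, m: np.ndarray,
                  u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    from .geometry import polygon_plane_intersections

    pts = polygon_plane_intersections(outline, origin, m)
    if len(pts) < 2:
        raise ValueError("section plane misses the outline")
    t = (pts - origin) @ u
    return pts[np.argmin(t)], pts[np.argmax(t)]


def _segment_point_distance(px: np.ndarray, py: np.ndarray, a, b) -> np.ndarray:
    ax, ay = a
    bx, by = b
    dx, dy = bx - ax, by - ay
    den = dx * dx + dy * dy
    if den == 0:
        return np.hypot(px - ax, py - ay)
    t = np.clip(((px - ax) * dx + (py - ay) * dy) / den, 0.0, 1.0)
    return np.hypot(px - (ax + t * dx), py - (ay + t * dy))


def render_cross_section(
    cell: Cardiomyocyte, axis: str, config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> CrossSectionImage:
    """Rasterize one cross-section of a cell into a multi-channel image.

    The section quad (basal edge, apical edge, two lateral walls) is drawn in
    the membrane channel; each fluorescence channel places the cell's true
    per-domain intensity in a 3-px band just inside the corresponding
    membrane, on top of a uniform background, with optional Gaussian noise.
    Ground-truth membrane polylines are returned in pixel coordinates.
    """
    if axis not in ("X", "Y"):
        raise ValueError("axis must be 'X' or 'Y'")
    if rng is None:
        entropy = zlib.crc32(f"{cell.cell_id}:{axis}".encode())
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, entropy])
        )
    origin, u, v, m = _section_frame(cell, axis)
    a_lo, a_hi = _section_tips(cell.apical_outline, origin, m, u)
    b_lo, b_hi = _section_tips(cell.basal_outline, origin, m, u)

    def to_uv(p):
        return np.array([(p - origin) @ u, (p - origin) @ v])

    quad_um = np.array([to_uv(b_lo), to_uv(b_hi), to_uv(a_hi), to_uv(a_lo)])
    area, _ = polygon_area_perimeter(quad_um)
    if area < 1e-6:
        raise ValueError(f"degenerate (zero-area) section for cell {cell.cell_id!r}")

    ps = config.pixel_size
    pad = 2.0  # µm of background around the section
    mins = quad_um.min(axis=0) - pad
    quad_px = (quad_um - mins) / ps
    shape_xy = np.ceil(quad_px.max(axis=0) + pad / ps).astype(int) + 1
    w, h = int(shape_xy[0]), int(shape_xy[1])

    bl, br, ar, al = quad_px
    lat_l, lat_r = _LATERAL_DOMAINS[axis]
    polylines = {
        "basal": np.array([bl, br]),
        "apical": np.array([al, ar]),
        "lateral-left": np.array([bl, al]),
        "lateral-right": np.array([br, ar]),
    }
    edge_domains = {
        "basal": "basal", "apical": "apical",
        "lateral-left": lat_l, "lateral-right": lat_r,
    }

    ys, xs = np.mgrid[0:h, 0:w]
    xs = xs.astype(float)
    ys = ys.astype(float)
    from matplotlib.path import Path as MplPath

    inside = MplPath(quad_px).contains_points(
        np.column_stack([xs.ravel(), ys.ravel()]), radius=1e-9
    ).reshape(h, w)
    dists = np.stack([
        _segment_point_distance(xs, ys, line[0], line[1])
        for line in polylines.values()
    ])
    nearest = np.argmin(dists, axis=0)
    in_band = inside & (np.min(dists, axis=0) < _BAND_PX)

    channels: dict[str, np.ndarray] = {}
    membrane = np.zeros((h, w))
    membrane[np.min(dists, axis=0) < 1.0] = config.membrane_value
    channels["membrane"] = membrane
    domain_order = list(polylines.keys())
    for chan in cell.membrane_truth:
        img = np.full((h, w), float(config.background))
        for k, edge in enumerate(domain_order):
            sel = in_band & (nearest == k)
            img[sel] = cell.membrane_truth[chan][edge_domains[edge]] + config.background
        if config.noise_sd > 0:
            img = img + rng.normal(0.0, config.noise_sd, img.shape)
        channels[chan] = np.clip(img, 0.0, None)
    return CrossSectionImage(
        cell_id=cell.cell_id, axis=axis, pixel_size=ps,
        channels=channels, polylines=polylines,
    )
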