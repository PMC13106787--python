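"""Membrane-domain intensity profiling and whole-myocardium summaries.

Channel intensities are measured along a ~1 µm-wide band traced just inside
each membrane of a cell cross-section, skipping ~1 µm at each corner so that
lateral signal never bleeds into the basal/apical readings (and vice versa).
Eight band means per channel (2 basal, 2 apical, 4 lateral across the X and
Y sections) reduce to three domain means, the percentage of signal at each
domain, and the basal polarity ratio ``basal / (apical + lateral)``.

Whole-ventricle summaries are masked myocardium means per embryo, screened
for outliers (Tukey fences by default) and rescaled per experimental
replicate to 1–10 relative fluorescence units (rfu) by min–max
normalization, which preserves ordering and relative spacing between
embryos.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Polygon
from shapely.ops import polygonize, substring, unary_union

from .model import DOMAINS, CrossSectionImage

__all__ = [
    "MembraneBand",
    "BandMean",
    "ChannelProfile",
    "MembraneProfile",
    "VentricleIntensitySummary",
    "band_mean",
    "profile_cell",
    "profile_cells",
    "profiles_to_frame",
    "masked_mean",
    "myocardium_summary",
    "normalize_summaries",
    "screen_outliers",
    "minmax_rfu",
]


@dataclass
class MembraneBand:
    """A measurement band along one membrane of a cross-section image."""

    polyline: np.ndarray  # (K, 2) pixel coordinates (x, y)
    domain: str  # basal | apical | lateral-left | lateral-right
    width: float = 1.0  # µm
    corner_exclusion: float = 1.0  # µm trimmed from each end

    def __post_init__(self) -> None:
        self.polyline = np.asarray(self.polyline, dtype=float)
        if self.width <= 0:
            raise ValueError("band width must be > 0")
        if self.corner_exclusion < 0:
            raise ValueError("corner_exclusion must be >= 0")
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}")


@dataclass
class BandMean:
    value: float
    pixels: np.ndarray  # (n, 2) integer (row, col) indices used — audit trail


def _cell_polygon(image: CrossSectionImage) -> Polygon:
    """Closed cell contour assembled from the four membrane polylines."""
    lines = [LineString(np.asarray(p)) for p in image.polylines.values()]
    polys = list(polygonize(unary_union(lines)))
    if not polys:
        raise ValueError(
            f"membrane polylines of cell {image.cell_id!r} do not close"
        )
    return max(polys, key=lambda p: p.area)


def band_mean(
    image: CrossSectionImage, band: MembraneBand, channel: str,
    background: float = 0.0, cell_polygon: Polygon | None = None,
) -> BandMean:
    """Mean channel intensity over the band's interior-side pixels.

    Pixels count when their centre lies within ``width/2`` of the
    corner-trimmed polyline *and* inside the cell contour (the interior
    side).  The sampled pixel set is returned for auditing.
    """
    if channel not in image.channels:
        raise KeyError(f"channel {channel!r} not in image")
    ps = image.pixel_size
    line = LineString(band.polyline)
    trim = band.corner_exclusion / ps
    if line.length - 2 * trim <= 0:
        raise ValueError(
            f"corner exclusion ({band.corner_exclusion} µm) consumes the whole "
            f"{band.domain} membrane"
        )
    trimmed = substring(line, trim, line.length - trim)
    region = trimmed.buffer(0.5 * band.width / ps, cap_style="flat")
    poly = cell_polygon if cell_polygon is not None else _cell_polygon(image)
    region = region.intersection(poly)
    if region.is_empty:
        raise ValueError(f"empty {band.domain} band after trimming")
    minx, miny, maxx, maxy = region.bounds
    h, w = image.shape
    x0, x1 = max(0, int(np.floor(minx))), min(w - 1, int(np.ceil(maxx)))
    y0, y1 = max(0, int(np.floor(miny))), min(h - 1, int(np.ceil(maxy)))
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    # intersects (not contains) so that centres exactly on the band or cell
    # boundary still count
    hit = shapely.intersects_xy(region, xs.ravel(), ys.ravel()).reshape(xs.shape)
    if not hit.any():
        raise ValueError(f"no pixels fall inside the {band.domain} band")
    rows, cols = ys[hit], xs[hit]
    vals = np.asarray(image.channels[channel])[rows, cols]
    return BandMean(
        value=float(vals.mean() - background),
        pixels=np.column_stack([rows, cols]),
    )


@dataclass
class ChannelProfile:
    mean_basal: float
    mean_lateral: float
    mean_apical: float
    pct_basal: float
    pct_lateral: float
    pct_apical: float
    basal_ratio: float
    flagged: bool = False


@dataclass
class MembraneProfile:
    cell_id: str
    channels: dict = field(default_factory=dict)

    @property
    def flagged(self) -> bool:
        return any(c.flagged for c in self.channels.values())


def _reduce_channel(basal, apical, lateral) -> ChannelProfile:
    mb = max(float(np.mean(basal)), 0.0)
    ma = max(float(np.mean(apical)), 0.0)
    ml = max(float(np.mean(lateral)), 0.0)
    total = mb + ma + ml
    if total <= 0:
        return ChannelProfile(mb, ml, ma, np.nan, np.nan, np.nan, np.nan,
                              flagged=True)
    ratio = mb / (ma + ml) if (ma + ml) > 0 else np.nan
    return ChannelProfile(
        mean_basal=mb, mean_lateral=ml, mean_apical=ma,
        pct_basal=100.0 * mb / total, pct_lateral=100.0 * ml / total,
        pct_apical=100.0 * ma / total, basal_ratio=ratio,
        flagged=not np.isfinite(ratio),
    )


def profile_cell(
    image_x: CrossSectionImage, image_y: CrossSectionImage,
    width: float = 1.0, corner_exclusion: float = 1.0,
    background: float = 0.0, channels=None,
) -> MembraneProfile:
    """Per-domain means, percentages, and basal ratio for one cell.

    Needs both cross-sections; each contributes one basal, one apical and two
    lateral band means per channel.  Cells whose domain means are all zero
    are flagged (percentages undefined) and excluded from group statistics
    downstream, never silently dropped.
    """
    if image_x is None or image_y is None:
        raise ValueError("both X and Y cross-sections are required")
    if image_x.cell_id != image_y.cell_id:
        raise ValueError("cross-sections belong to different cells")
    if channels is None:
        channels = [c for c in image_x.channels if c != "membrane"]
    per_channel: dict[str, ChannelProfile] = {}
    for chan in channels:
        basal, apical, lateral = [], [], []
        for img in (image_x, image_y):
            missing = [d for d in DOMAINS if d not in img.polylines]
            if missing:
                raise ValueError(f"image {img.axis} lacks polylines {missing}")
            poly = _cell_polygon(img)
            for dom in DOMAINS:
                bm = band_mean(
                    img,
                    MembraneBand(img.polylines[dom], dom, width, corner_exclusion),
                    chan, background=background, cell_polygon=poly,
                )
                if dom == "basal":
                    basal.append(bm.value)
                elif dom == "apical":
                    apical.append(bm.value)
                else:
                    lateral.append(bm.value)
        per_channel[chan] = _reduce_channel(basal, apical, lateral)
    return MembraneProfile(cell_id=image_x.cell_id, channels=per_channel)


def profile_cells(images_by_cell, **kwargs) -> list[MembraneProfile]:
    """Profile ``{cell_id: {"X": image, "Y": image}}`` mappings."""
    return [
        profile_cell(pair["X"], pair["Y"], **kwargs)
        for pair in images_by_cell.values()
    ]


def profiles_to_frame(profiles, extra: dict | None = None) -> pd.DataFrame:
    """Long-format table: one row per cell x channel."""
    rows = []
    for prof in profiles:
        for chan, cp in prof.channels.items():
            row = dict(cell_id=prof.cell_id, channel=chan, **cp.__dict__)
            if extra and prof.cell_id in extra:
                row.update(extra[prof.cell_id])
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Whole-myocardium summaries
# ---------------------------------------------------------------------------

@dataclass
class VentricleIntensitySummary:
    embryo_id: str
    replicate_id: str
    channel: str
    raw_mean: float
    rfu: float = float("nan")
    outlier_flag: bool = False


def masked_mean(image: np.ndarray, mask: np.ndarray) -> float:
    """Mean intensity over the masked myocardium pixels/voxels."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if not mask.any():
        raise ValueError("empty myocardium mask")
    return float(image[mask].mean())


def myocardium_summary(
    embryos, channel: str, replicate_id: str = "r1"
) -> list[VentricleIntensitySummary]:
    """Masked myocardium mean per embryo.

    ``embryos`` maps embryo_id -> (image, mask) for the given channel.
    """
    return [
        VentricleIntensitySummary(
            embryo_id=eid, replicate_id=replicate_id, channel=channel,
            raw_mean=masked_mean(img, mask),
        )
        for eid, (img, mask) in embryos.items()
    ]


def screen_outliers(values, k: float = 1.5) -> np.ndarray:
    """Tukey-fence outlier flags: outside [Q1 - k*IQR, Q3 + k*IQR].

    Fewer than three values cannot be screened; a warning is emitted and
    nothing is flagged.  Flagged values are meant to be excluded from later
    statistics but must never be deleted from outputs.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        warnings.warn("fewer than 3 values; outlier screening skipped",
                      stacklevel=2)
        return np.zeros(values.shape, dtype=bool)
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return (values < q1 - k * iqr) | (values > q3 + k * iqr)


def minmax_rfu(values) -> np.ndarray:
    """Min–max rescale to the 1–10 rfu scale: ``1 + 9 (x - min)/(max - min)``."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two values for min-max normalization")
    lo, hi = values.min(), values.max()
    if hi == lo:
        raise ValueError("min-max normalization undefined for constant values")
    return 1.0 + 9.0 * (values - lo) / (hi - lo)


def normalize_summaries(
    summaries, outlier_k: float = 1.5
) -> list[VentricleIntensitySummary]:
    """Screen outliers and fill rfu values per (replicate, channel) group.

    rfu is computed over the non-outlier embryos of each group; outliers keep
    NaN rfu but stay in the output.
    """
    groups: dict[tuple[str, str], list[VentricleIntensitySummary]] = {}
    for s in summaries:
        groups.setdefault((s.replicate_id, s.channel), []).append(s)
    for members in groups.values():
        raw = np.array([m.raw_mean for m in members])
        flags = screen_outliers(raw, k=outlier_k) if len(members) >= 3 else (
            np.zeros(len(members), dtype=bool)
        )
        for m, f in zip(members, flags):
            m.outlier_flag = bool(f)
        kept = [m for m in members if not m.outlier_flag]
        if len(kept) >= 2 and len({m.raw_mean for m in kept}) >= 2:
            rfu = minmax_rfu([m.raw_mean for m in kept])
            for m, v in zip(kept, rfu):
                m.rfu = float(v)
    return list(summaries)
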