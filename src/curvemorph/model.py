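"""Core domain records: cells and rendered cross-section images."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

#: membrane-domain labels used for cross-section polylines and bands
DOMAINS = ("basal", "apical", "lateral-left", "lateral-right")
#: default fluorescence channels carried by the synthetic data
CHANNELS = ("F-actin", "pMyosin")


@dataclass
class Cardiomyocyte:
    """A labelled prism cell on the myocardial surface.

    ``apical_outline`` is a closed 3D polygon (vertices listed once) on the
    outer tube surface; ``basal_outline`` the matching polygon on the inner
    surface.  ``membrane_truth`` maps channel -> domain -> true mean intensity
    (arbitrary units), with one value per lateral wall
    (``lateral-x-left`` … ``lateral-y-right``).
    """

    cell_id: str
    apical_outline: np.ndarray
    basal_outline: np.ndarray
    embryo_id: str = "e0"
    true_region: str = "neither"  # OC | IC | neither (generation truth)
    center: tuple[float, float] = (0.0, 0.0)  # (s along centreline, theta)
    wall_heights: np.ndarray = field(default_factory=lambda: np.ones(4))
    orientation: tuple[str, float] = ("circumferential", 0.0)
    clone_label: str = "host"
    genotype_label: str = "WT"
    membrane_truth: dict = field(default_factory=dict)
    neighbors: list = field(default_factory=list)
    true_area: float = float("nan")  # area of the flat apical polygon, µm²
    param_box: tuple[float, float, float, float] | None = None  # (phi0,phi1,th0,th1)

    def __post_init__(self) -> None:
        self.apical_outline = np.asarray(self.apical_outline, dtype=float)
        self.basal_outline = np.asarray(self.basal_outline, dtype=float)
        self.wall_heights = np.asarray(self.wall_heights, dtype=float)
        if self.apical_outline.ndim != 2 or self.apical_outline.shape[1] != 3:
            raise ValueError("apical_outline must be an (N, 3) array")
        if np.any(self.wall_heights <= 0):
            raise ValueError("wall_heights must be > 0")
        for chan, doms in self.membrane_truth.items():
            for dom, val in doms.items():
                if val < 0:
                    raise ValueError(
                        f"negative membrane_truth for {chan}/{dom} in {self.cell_id}"
                    )

    def apical_polygon_2d(self) -> Polygon:
        """Lateral-view (z-dropped) projection of the apical outline."""
        return Polygon(self.apical_outline[:, :2])


@dataclass
class CrossSectionImage:
    """Single-cell cross-section: channel rasters plus ground-truth polylines.

    ``channels`` maps channel name -> 2D float array (row = y, col = x);
    ``polylines`` maps the four membrane-domain labels to (K, 2) arrays of
    (x, y) pixel coordinates tracing each membrane.  ``axis`` records which
    principal axis the section runs along (``"X"`` major, ``"Y"`` minor).
    """

    cell_id: str
    axis: str
    pixel_size: float
    channels: dict
    polylines: dict

    def __post_init__(self) -> None:
        if self.axis not in ("X", "Y"):
            raise ValueError("axis must be 'X' or 'Y'")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError("all channels must share one image shape")
        (self.shape,) = shapes
        h, w = self.shape
        for name, arr in self.channels.items():
            if np.any(np.asarray(arr) < 0):
                raise ValueError(f"negative intensities in channel {name!r}")
        for dom, line in self.polylines.items():
            line = np.asarray(line, dtype=float)
            if np.any(line[:, 0] < -0.5) or np.any(line[:, 0] > w - 0.5) or np.any(
                line[:, 1] < -0.5
            ) or np.any(line[:, 1] > h - 0.5):
                raise ValueError(f"polyline {dom!r} leaves the image bounds")
            self.polylines[dom] = line
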