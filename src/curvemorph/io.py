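"""Readers/writers for the pipeline's table, geometry and image formats.

Tables are UTF-8 CSV with a ``# key = value`` metadata header (tool version,
seed, config hash) so every artefact is self-describing and reruns are
byte-comparable.  Geometry travels as JSON, per-cell cross-sections as
multi-page TIFF (channel-major) with a JSON sidecar holding pixel size,
channel order and the ground-truth membrane polylines.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .config import GeneratorConfig, config_hash
from .geometry import HeartModel
from .model import Cardiomyocyte, CrossSectionImage

__all__ = [
    "SchemaError",
    "write_table",
    "read_table",
    "cells_to_frame",
    "frame_to_cells",
    "write_heart_json",
    "read_heart_json",
    "write_cross_section",
    "read_cross_section",
    "validate_morphometrics",
    "validate_cells",
]


class SchemaError(ValueError):
    """A table violates its declared schema."""


def _meta_lines(meta: dict) -> str:
    lines = [f"# {k} = {v}" for k, v in sorted(meta.items())]
    return "\n".join(lines) + ("\n" if lines else "")


def default_meta(seed=None, cfg=None) -> dict:
    meta = {"curvemorph-version": __version__}
    if seed is not None:
        meta["seed"] = seed
    if cfg is not None:
        meta["config-sha256"] = config_hash(cfg)
    return meta


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        if meta:
            fh.write(_meta_lines(meta))
        df.to_csv(fh, index=False)
    return path


def read_table(path, validate=None) -> tuple[pd.DataFrame, dict]:
    """Read a metadata-headed CSV; returns (frame, metadata)."""
    path = Path(path)
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line.lstrip("# ").partition(" = ")
            meta[key.strip()] = value.strip()
    df = pd.read_csv(path, comment="#")
    if validate is not None:
        validate(df)
    return df, meta


# ---------------------------------------------------------------------------
# Cells
# ---------------------------------------------------------------------------

def _pack_outline(arr: np.ndarray) -> str:
    return json.dumps(np.asarray(arr).round(6).tolist())


def cells_to_frame(cells) -> pd.DataFrame:
    rows = []
    for c in cells:
        row = dict(
            cell_id=c.cell_id,
            embryo_id=c.embryo_id,
            true_region=c.true_region,
            center_s=c.center[0],
            center_theta=c.center[1],
            orientation_axis=c.orientation[0],
            orientation_angle=c.orientation[1],
            clone_label=c.clone_label,
            genotype_label=c.genotype_label,
            true_area=c.true_area,
            wall_heights=json.dumps(np.round(c.wall_heights, 6).tolist()),
            apical_outline=_pack_outline(c.apical_outline),
            basal_outline=_pack_outline(c.basal_outline),
            membrane_truth=json.dumps(
                {k: {d: round(v, 6) for d, v in doms.items()}
                 for k, doms in c.membrane_truth.items()},
                sort_keys=True,
            ),
            neighbors=json.dumps(list(c.neighbors)),
        )
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_cells(df: pd.DataFrame) -> list[Cardiomyocyte]:
    cells = []
    for row in df.itertuples():
        cells.append(
            Cardiomyocyte(
                cell_id=row.cell_id,
                embryo_id=row.embryo_id,
                true_region=row.true_region,
                center=(float(row.center_s), float(row.center_theta)),
                apical_outline=np.array(json.loads(row.apical_outline)),
                basal_outline=np.array(json.loads(row.basal_outline)),
                wall_heights=np.array(json.loads(row.wall_heights)),
                orientation=(row.orientation_axis, float(row.orientation_angle)),
                clone_label=row.clone_label,
                genotype_label=row.genotype_label,
                membrane_truth=json.loads(row.membrane_truth),
                neighbors=json.loads(row.neighbors),
                true_area=float(row.true_area),
            )
        )
    return cells


def validate_cells(df: pd.DataFrame) -> None:
    required = {"cell_id", "embryo_id", "true_region", "apical_outline",
                "basal_outline", "wall_heights"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"cells table is missing columns {sorted(missing)}")
    bad = df.index[df["true_area"] <= 0].tolist() if "true_area" in df else []
    if bad:
        raise SchemaError(f"non-positive true_area in rows {bad}")


def validate_morphometrics(df: pd.DataFrame) -> None:
    required = {"cell_id", "embryo_id", "apical_area", "circularity",
                "apicobasal_length", "volume"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(
            f"morphometrics table is missing columns {sorted(missing)}"
        )
    problems = []
    if (df["apical_area"] <= 0).any():
        problems.append(
            f"apical_area <= 0 in rows {df.index[df['apical_area'] <= 0].tolist()}"
        )
    if ((df["circularity"] <= 0) | (df["circularity"] > 1 + 1e-6)).any():
        bad = df.index[(df["circularity"] <= 0) | (df["circularity"] > 1 + 1e-6)]
        problems.append(f"circularity out of (0, 1] in rows {bad.tolist()}")
    if (df["volume"] < 0).any():
        problems.append("negative volume")
    if problems:
        raise SchemaError("; ".join(problems))


# ---------------------------------------------------------------------------
# Geometry JSON
# ---------------------------------------------------------------------------

def write_heart_json(heart: HeartModel, path, config: GeneratorConfig | None = None,
                     landmarks=None) -> Path:
    payload = {
        "heart": {
            "stage": heart.stage,
            "bend_radius": heart.bend_radius,
            "tube_radius": heart.tube_radius,
            "bend_angle": heart.bend_angle,
            "cell_diameter_typical": heart.cell_diameter_typical,
            "frame_rotation": heart.frame_rotation,
            "frame_offset": list(heart.frame_offset),
            "oc_arc_length": heart.oc_arc_length,
            "ic_arc_length": heart.ic_arc_length,
            "landmarks_raw": heart.landmarks_raw,
        },
    }
    if landmarks is not None:
        payload["landmarks"] = {
            k: float(getattr(landmarks, k))
            for k in ("PB_OC", "DB_OC", "DB_OFT_OC", "PB_IC", "DB_IC", "DB_OFT_IC")
        }
        for name in ("point_i", "point_ii", "point_iii", "point_iv"):
            val = getattr(landmarks, name)
            payload["landmarks"][name] = None if val is None else [float(v) for v in val]
    if config is not None:
        payload["config"] = json.loads(
            json.dumps(asdict(config), default=lambda o: list(o))
        )
        payload["config-sha256"] = config_hash(config)
    path = Path(path)
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path


def read_heart_json(path) -> tuple[HeartModel, dict]:
    payload = json.loads(Path(path).read_text())
    h = payload["heart"]
    heart = HeartModel(
        stage=h["stage"], bend_radius=h["bend_radius"],
        tube_radius=h["tube_radius"], bend_angle=h["bend_angle"],
        cell_diameter_typical=h["cell_diameter_typical"],
        frame_rotation=h.get("frame_rotation", 0.0),
        frame_offset=tuple(h.get("frame_offset", (0.0, 0.0))),
    )
    return heart, payload


# ---------------------------------------------------------------------------
# Cross-section TIFF + sidecar
# ---------------------------------------------------------------------------

def write_cross_section(image: CrossSectionImage, path) -> Path:
    """Channel-major multi-page TIFF plus a JSON sidecar."""
    path = Path(path)
    order = sorted(image.channels)
    stack = np.stack([np.asarray(image.channels[c], dtype=np.float32)
                      for c in order])
    tifffile.imwrite(path, stack, photometric="minisblack")
    sidecar = {
        "cell_id": image.cell_id,
        "axis": image.axis,
        "pixel_size": image.pixel_size,
        "channels": order,
        "polylines": {k: np.asarray(v).round(4).tolist()
                      for k, v in image.polylines.items()},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, sort_keys=True))
    return path


def read_cross_section(path, expected_channels=None) -> CrossSectionImage:
    path = Path(path)
    stack = tifffile.imread(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    names = sidecar["channels"]
    if stack.ndim == 2:
        stack = stack[None]
    if len(names) != stack.shape[0]:
        raise SchemaError(
            f"TIFF {path.name} has {stack.shape[0]} pages but the sidecar "
            f"declares channels {names} (expected channel-major layout)"
        )
    if expected_channels is not None and set(expected_channels) != set(names):
        raise SchemaError(
            f"TIFF {path.name} carries channels {names}, expected "
            f"{sorted(expected_channels)}"
        )
    return CrossSectionImage(
        cell_id=sidecar["cell_id"], axis=sidecar["axis"],
        pixel_size=sidecar["pixel_size"],
        channels={n: stack[i].astype(float) for i, n in enumerate(names)},
        polylines={k: np.asarray(v, dtype=float)
                   for k, v in sidecar["polylines"].items()},
    )
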