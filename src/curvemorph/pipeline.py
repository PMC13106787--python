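"""Top-level pipeline: generate → delineate → measure → profile → stats.

A run synthesizes a cohort of control embryos (plus, optionally, an
experimental arm with a different genotype), delineates the curvatures on
each heart, measures every cell, profiles membrane-domain intensities from
rendered cross-sections, and writes the comparison and normalization tables.
Every output CSV carries a metadata header (tool version, seed, config hash)
and a rerun with the same config reproduces identical files.
"""

from __future__ import annotations

import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .config import GeneratorConfig, PipelineConfig, config_hash
from .intensity import (
    VentricleIntensitySummary,
    normalize_summaries,
    profile_cell,
    profiles_to_frame,
    screen_outliers,
)
from .model import CHANNELS
from .morphometrics import measure_cells
from .regions import assign_cells, build_region_boundaries, locate_landmarks
from .synthetic import _heart_from_config, generate_heart, render_cross_section

__all__ = ["PipelineStageError", "run_pipeline", "OUTPUT_TABLES"]

log = logging.getLogger("curvemorph")

OUTPUT_TABLES = (
    "cells.csv",
    "assignment.csv",
    "morphometrics.csv",
    "profiles.csv",
    "ventricle_summary.csv",
    "comparisons.csv",
    "normalized_means.csv",
)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _embryo_seed(base_seed: int, index: int) -> int:
    ss = np.random.SeedSequence([base_seed, index])
    return int(ss.generate_state(1)[0] % (2**31))


def _cohort(cfg: GeneratorConfig, base_seed: int, n_embryos: int, tag: str):
    hearts, cells = [], []
    tag_salt = zlib.crc32(tag.encode()) % 1000
    for k in range(n_embryos):
        eid = f"{tag}{k}"
        h, cs = generate_heart(
            cfg.replace(seed=_embryo_seed(base_seed, tag_salt + k)),
            embryo_id=eid,
        )
        hearts.append((eid, h))
        cells.extend(cs)
    return hearts, cells


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Execute all stages; returns the output directory.

    On stage failure, partial outputs are kept next to a ``FAILED`` marker
    naming the stage, and a PipelineStageError is raised.
    """
    cfg = config
    out = Path(out_dir)
    if not out.parent.exists():
        raise FileNotFoundError(f"output location does not exist: {out.parent}")
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level, logging.INFO))
    meta = io.default_meta(seed=cfg.seed, cfg=cfg)
    stage = "generate"
    try:
        gen = cfg.generator.replace(stage=cfg.stage) if (
            cfg.generator.stage != cfg.stage
        ) else cfg.generator
        hearts, cells = _cohort(gen, cfg.seed, cfg.n_embryos, "ctrl")
        cohorts = {"control": (gen, cells)}
        if cfg.experiment is not None:
            exp_gen = cfg.experiment.generator(gen)
            _, exp_cells = _cohort(exp_gen, cfg.seed + 1,
                                   cfg.experiment.n_embryos, "exp")
            cohorts["experiment"] = (exp_gen, exp_cells)
            cells = cells + exp_cells
        for eid, h in hearts:
            io.write_heart_json(h, out / f"heart_{eid}.json", config=gen)
        io.write_table(io.cells_to_frame(cells), out / "cells.csv", meta)

        stage = "delineate"
        assignments = []
        for label, (gcfg, ccells) in cohorts.items():
            heart = _heart_from_config(gcfg)
            boundaries = build_region_boundaries(locate_landmarks(heart))
            assignments.append(assign_cells(ccells, boundaries))
        assignment = pd.concat(assignments, ignore_index=True)
        io.write_table(assignment, out / "assignment.csv", meta)

        stage = "measure"
        morpho = measure_cells(cells, assignment)
        io.write_table(morpho, out / "morphometrics.csv", meta)

        stage = "profile"
        profiles, extra = [], {}
        summaries: list[VentricleIntensitySummary] = []
        pixel_sums: dict[tuple[str, str], list[np.ndarray]] = {}
        a_by_id = dict(zip(assignment["cell_id"], assignment["region"]))
        for label, (gcfg, ccells) in cohorts.items():
            bg = gcfg.background if cfg.subtract_background else 0.0
            for cell in ccells:
                if a_by_id.get(cell.cell_id, "neither") == "neither":
                    continue
                imgs = {
                    ax: render_cross_section(cell, ax, gcfg) for ax in ("X", "Y")
                }
                if cfg.write_images:
                    for ax, img in imgs.items():
                        io.write_cross_section(
                            img, out / f"section_{cell.cell_id}_{ax}.tif"
                        )
                try:
                    profiles.append(
                        profile_cell(imgs["X"], imgs["Y"], width=cfg.band_width,
                                     corner_exclusion=cfg.corner_exclusion,
                                     background=bg)
                    )
                except ValueError as err:
                    # e.g. sliver cells whose membranes vanish after corner
                    # trimming; they are skipped, not fatal
                    log.warning("profiling skipped for %s: %s",
                                cell.cell_id, err)
                    continue
                extra[cell.cell_id] = dict(
                    embryo_id=cell.embryo_id,
                    region=a_by_id[cell.cell_id],
                    genotype_label=cell.genotype_label,
                )
                # pool in-cell pixels for the per-embryo myocardium summary
                for chan in CHANNELS:
                    for img in imgs.values():
                        key = (cell.embryo_id, chan)
                        pixel_sums.setdefault(key, []).append(
                            np.asarray(img.channels[chan]).ravel()
                        )
        prof_df = profiles_to_frame(profiles, extra)
        io.write_table(prof_df, out / "profiles.csv", meta)

        for (eid, chan), chunks in sorted(pixel_sums.items()):
            allpix = np.concatenate(chunks)
            summaries.append(
                VentricleIntensitySummary(
                    embryo_id=eid, replicate_id="r1", channel=chan,
                    raw_mean=float(allpix.mean()),
                )
            )
        normalize_summaries(summaries, outlier_k=cfg.outlier_k)
        io.write_table(
            pd.DataFrame([s.__dict__ for s in summaries]),
            out / "ventricle_summary.csv", meta,
        )

        stage = "stats"
        _write_stats(cfg, morpho, prof_df, out, meta)
    except Exception as exc:  # noqa: BLE001 - annotate and re-raise
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise PipelineStageError(stage, exc) from exc

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config-sha256": config_hash(cfg),
        "outputs": sorted(p.name for p in out.iterdir() if p.name != "FAILED"),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      sort_keys=True))
    return out


def _write_stats(cfg: PipelineConfig, morpho: pd.DataFrame,
                 prof_df: pd.DataFrame, out: Path, meta: dict) -> None:
    from .stats import cross_experiment_normalize, superplot_summarize, wilcoxon_compare

    morpho = morpho[morpho["region"].isin(["OC", "IC"])].copy()
    ctrl = morpho[morpho["genotype_label"] == cfg.generator.genotype]
    comparisons, normalized = [], []

    def compare(sub_a, sub_b, la, lb, metric, level):
        if level == "embryo":
            va = sub_a.groupby("embryo_id")[metric].mean().to_numpy()
            vb = sub_b.groupby("embryo_id")[metric].mean().to_numpy()
        else:
            va, vb = sub_a[metric].to_numpy(), sub_b[metric].to_numpy()
        if len(va) == 0 or len(vb) == 0:
            return
        res = wilcoxon_compare(va, vb, la, lb)
        comparisons.append(dict(metric=metric, level=level, **res.__dict__))

    for metric in cfg.metrics:
        for level in ("cell", "embryo"):
            compare(ctrl[ctrl.region == "OC"], ctrl[ctrl.region == "IC"],
                    "control-OC", "control-IC", metric, level)
        exp = morpho[morpho["genotype_label"] != cfg.generator.genotype]
        if len(exp):
            for region in ("OC", "IC"):
                for level in ("cell", "embryo"):
                    compare(exp[exp.region == region],
                            ctrl[ctrl.region == region],
                            f"{exp['genotype_label'].iloc[0]}-{region}",
                            f"control-{region}", metric, level)
                ctrl_vals = ctrl.loc[ctrl.region == region, metric].to_numpy()
                exp_vals = exp.loc[exp.region == region, metric].to_numpy()
                if len(exp_vals) and len(ctrl_vals) >= 2:
                    ref = cfg.reference_stats.get(
                        metric,
                        (float(ctrl_vals.mean()), float(ctrl_vals.std(ddof=1))),
                    )
                    nm = cross_experiment_normalize(
                        ref[0], ref[1], exp_vals, ctrl_vals, metric=metric
                    )
                    normalized.append(dict(region=region, **nm.__dict__))
    io.write_table(pd.DataFrame(comparisons), out / "comparisons.csv", meta)
    io.write_table(pd.DataFrame(normalized), out / "normalized_means.csv", meta)

    if cfg.make_plots:
        import matplotlib

        matplotlib.use("Agg", force=True)
        import matplotlib.pyplot as plt

        plt.rcParams["svg.hashsalt"] = meta.get("config-sha256", "curvemorph")
        from .stats import superplot

        for metric in cfg.metrics:
            table = superplot_summarize(
                morpho.assign(
                    group=morpho["genotype_label"] + "-" + morpho["region"]
                ),
                "group", metric,
            )
            ax = superplot(table)
            ax.figure.savefig(out / f"superplot_{metric}.svg",
                              metadata={"Date": None})
            plt.close(ax.figure)
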