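"""Group comparisons, SuperPlot summaries, and cross-experiment normalization.

Comparisons use the two-sided Wilcoxon rank-sum (Mann–Whitney) test — exact
enumeration for small tie-free samples, normal approximation with tie
correction otherwise — with the usual star thresholds (* p<0.05, ** p<0.01,
*** p<0.001).  SuperPlot summaries keep cell-level values while overlaying
per-embryo means, so biological replication stays visible; comparisons are
made at cell level by default with an embryo-level mode available.

Experiments run on different days are brought onto a common reference scale
by the mean-Z normalization

    mean_norm = mean_ref + SD_ref * mean(Z_exp),

where each experimental cell's Z-score is taken against its within-experiment
control group's mean and sample SD.  No multiple-testing correction is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SuperPlotTable",
    "ComparisonResult",
    "NormalizedMean",
    "star_label",
    "superplot_summarize",
    "superplot",
    "wilcoxon_compare",
    "cross_experiment_normalize",
    "normalized_mean",
]


def star_label(p: float) -> str:
    """Significance stars: most extreme applicable threshold."""
    if not np.isfinite(p):
        return "ns"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# SuperPlots
# ---------------------------------------------------------------------------

@dataclass
class SuperPlotTable:
    """Cell-level values with per-embryo means and group grand means."""

    metric: str
    cells: pd.DataFrame  # columns: group, embryo_id, cell_id?, value
    embryo_means: pd.DataFrame  # group, embryo_id, mean, n_cells
    group_summary: pd.DataFrame  # group, grand_mean, cell_mean, n_cells, n_embryos

    def legend_text(self) -> str:
        lines = []
        for row in self.group_summary.itertuples():
            lines.append(
                f"{row.group}: N = {row.n_embryos} embryos, n = {row.n_cells} cells"
            )
        return "\n".join(lines)


def superplot_summarize(
    records: pd.DataFrame, group_by, metric: str, embryo_col: str = "embryo_id"
) -> SuperPlotTable:
    """Hierarchical summary of a long-format table.

    ``group_by`` may be one column or a list (joined with '/').  Every record
    must carry an embryo identifier; the grand mean of a group is the mean of
    its per-embryo means.
    """
    df = records.copy()
    if embryo_col not in df.columns or df[embryo_col].isna().any():
        raise ValueError(f"records are missing {embryo_col!r} identifiers")
    if metric not in df.columns:
        raise ValueError(f"metric column {metric!r} not found")
    if isinstance(group_by, str):
        df["group"] = df[group_by].astype(str)
    else:
        df["group"] = df[list(group_by)].astype(str).agg("/".join, axis=1)
    cells = df[["group", embryo_col, metric]].rename(
        columns={embryo_col: "embryo_id", metric: "value"}
    )
    if "cell_id" in df.columns:
        cells.insert(1, "cell_id", df["cell_id"])
    embryo_means = (
        cells.groupby(["group", "embryo_id"], sort=True)["value"]
        .agg(mean="mean", n_cells="size")
        .reset_index()
    )
    group_summary = (
        embryo_means.groupby("group", sort=True)
        .agg(grand_mean=("mean", "mean"), n_embryos=("embryo_id", "nunique"),
             n_cells=("n_cells", "sum"))
        .reset_index()
    )
    cell_means = cells.groupby("group", sort=True)["value"].mean().rename("cell_mean")
    group_summary = group_summary.merge(cell_means, on="group")
    cells = cells.sort_values(["group", "embryo_id"]).reset_index(drop=True)
    return SuperPlotTable(
        metric=metric, cells=cells, embryo_means=embryo_means,
        group_summary=group_summary,
    )


def superplot(table: SuperPlotTable, ax=None, rng_seed: int = 0):
    """Draw a SuperPlot: jittered cells, embryo means, cell-level mean bar."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 + 1.1 * table.group_summary.shape[0], 3.2))
    rng = np.random.default_rng(rng_seed)
    groups = list(table.group_summary["group"])
    cmap = plt.get_cmap("tab10")
    for gi, group in enumerate(groups):
        vals = table.cells.loc[table.cells["group"] == group, "value"].to_numpy()
        x = gi + rng.uniform(-0.18, 0.18, size=len(vals))
        ax.plot(x, vals, ".", color="0.6", ms=3, zorder=1)
        ax.hlines(vals.mean(), gi - 0.28, gi + 0.28, color="k", lw=1.8, zorder=3)
        em = table.embryo_means[table.embryo_means["group"] == group]
        for k, row in enumerate(em.itertuples()):
            ax.plot(gi + 0.22, row.mean, "o", ms=7, zorder=4,
                    color=cmap(k % 10), mec="k", mew=0.5)
    ax.set_xticks(range(len(groups)), groups, rotation=20, ha="right")
    ax.set_ylabel(table.metric)
    ax.set_title(table.legend_text(), fontsize=7, loc="left")
    return ax


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum comparison
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    statistic: float  # Mann-Whitney U of group A
    rank_sum: float  # rank sum W of group A
    p_value: float
    stars: str
    method: str  # exact | asymptotic

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value out of [0, 1]")


_EXACT_MAX_N = 8


def wilcoxon_compare(
    values_a, values_b, label_a: str = "A", label_b: str = "B"
) -> ComparisonResult:
    """Two-sided Wilcoxon rank-sum test between two groups.

    Uses exact enumeration when both groups have at most 8 tie-free values,
    otherwise the normal approximation with mid-ranks and tie-corrected
    variance.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (a.size <= _EXACT_MAX_N and b.size <= _EXACT_MAX_N and not has_ties)
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided",
        method="exact" if exact else "asymptotic",
    )
    ranks = sps.rankdata(pooled)
    rank_sum = float(ranks[: a.size].sum())
    p = float(min(res.pvalue, 1.0))
    return ComparisonResult(
        group_a=label_a, group_b=label_b, n_a=int(a.size), n_b=int(b.size),
        statistic=float(res.statistic), rank_sum=rank_sum, p_value=p,
        stars=star_label(p), method="exact" if exact else "asymptotic",
    )


# ---------------------------------------------------------------------------
# Cross-experiment normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizedMean:
    mean_ref: float
    sd_ref: float
    mean_ctrl: float
    sd_ctrl: float
    mean_exp: float
    mean_z: float
    mean_norm: float
    n_exp: int
    n_ctrl: int
    metric: str = ""


def normalized_mean(mean_ref: float, sd_ref: float, mean_z: float) -> float:
    """Core reference-scale formula: ``mean_ref + SD_ref * mean_z``."""
    return float(mean_ref + sd_ref * mean_z)


def cross_experiment_normalize(
    mean_ref: float, sd_ref: float, exp_values, ctrl_values, metric: str = ""
) -> NormalizedMean:
    """Project an experimental group onto a reference dataset's scale.

    Each experimental value is Z-scored against the within-experiment control
    group (control mean, sample SD with n-1 denominator); the group's mean Z
    then scales the reference SD:  ``mean_norm = mean_ref + SD_ref * mean_z``.
    Exactly affine-equivariant: transforming exp and ctrl together leaves
    ``mean_z`` (and hence ``mean_norm``) unchanged.
    """
    exp = np.asarray(exp_values, dtype=float)
    ctrl = np.asarray(ctrl_values, dtype=float)
    if exp.size == 0:
        raise ValueError("experimental group is empty")
    if ctrl.size < 2:
        raise ValueError("need at least two control values")
    if sd_ref < 0:
        raise ValueError("SD_ref must be >= 0")
    mean_ctrl = float(ctrl.mean())
    sd_ctrl = float(ctrl.std(ddof=1))
    if sd_ctrl == 0:
        raise ValueError("control SD is zero; Z-scores undefined")
    z = (exp - mean_ctrl) / sd_ctrl
    mean_z = float(z.mean())
    return NormalizedMean(
        mean_ref=float(mean_ref), sd_ref=float(sd_ref), mean_ctrl=mean_ctrl,
        sd_ctrl=sd_ctrl, mean_exp=float(exp.mean()), mean_z=mean_z,
        mean_norm=normalized_mean(mean_ref, sd_ref, mean_z),
        n_exp=int(exp.size), n_ctrl=int(ctrl.size), metric=metric,
    )
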