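"""Orchestration of the full grain-size experiment and its summaries.

For every quadrat side length in the sampling design and every repetition,
quadrats are redrawn, the 22-predictor feature table is rebuilt, and the
complete modelling protocol (Boruta screen, mtry/ntree tuning, 70/30
evaluation) is run from a repetition-specific seed.  Medians over
repetitions are the headline per-scale summaries; the minimum adequate
sampling scale is the smallest side length whose median R2 and rRMSE clear
the configured accuracy requirements.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .biomass import AllometryTable
from .config import SamplingDesign, TuningProtocol
from .indices import CATEGORIES, CATEGORY_MAP, PREDICTOR_NAMES, build_feature_table
from .modeling import METRIC_NAMES, run_protocol
from .sampling import InfeasibleScaleError, sample_quadrats, scale_series
from .synthetic import ElevationGrid
from .topography import TrendSurface, fit_kriging_surface

logger = logging.getLogger(__name__)

RESULT_META = ["scale_m", "rep", "mtry", "ntree", "n_selected"]
IMPORTANCE_COLUMNS = [f"imp_{n}" for n in PREDICTOR_NAMES]


def run_scale_experiment(stems: pd.DataFrame, grid: ElevationGrid,
                         design: SamplingDesign, allometry: AllometryTable,
                         protocol: TuningProtocol | None = None,
                         interval_yr: float = 5.0,
                         surface: TrendSurface | None = None) -> pd.DataFrame:
    """Long results table with one row per scale x repetition.

    Repetitions are seeded independently (from ``design.seed``) so results
    do not depend on execution order; infeasible scales are skipped with a
    warning.
    """
    protocol = protocol or TuningProtocol()
    if surface is None:
        surface = fit_kriging_surface(grid)
    plot_x = (grid.nx - 1) * grid.spacing
    plot_y = (grid.ny - 1) * grid.spacing

    rows = []
    for side in scale_series(design):
        if side > min(plot_x, plot_y):
            logger.warning("scale %.0f m infeasible for %sx%s plot; skipped",
                           side, plot_x, plot_y)
            continue
        for rep in range(design.repetitions):
            # seeded by (seed, scale, rep): results are independent of which
            # design a scale is embedded in and of execution order
            ss = np.random.SeedSequence([design.seed, int(round(side * 1000)), rep])
            rng = np.random.default_rng(ss)
            quadrats = sample_quadrats(plot_x, plot_y, side,
                                       design.quadrats_per_scale, rng)
            features = build_feature_table(stems, quadrats, surface, allometry,
                                           interval_yr=interval_yr)
            result = run_protocol(features, protocol, rng)
            row = {
                "scale_m": side, "rep": rep, "mtry": result.mtry,
                "ntree": result.ntree,
                "n_selected": len(result.selected_features),
            }
            row.update(result.metrics)
            row.update({f"imp_{k}": v for k, v in result.importance.items()})
            rows.append(row)
        logger.info("scale %.0f m: %d repetitions done", side, design.repetitions)
    return pd.DataFrame(rows, columns=RESULT_META + METRIC_NAMES + IMPORTANCE_COLUMNS)


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Per-scale medians and SDs of the metrics and importances.

    Includes median absolute ME and MRE (the headline values reported for
    the signed criteria).  Per-category importance medians are renormalised
    to sum to 100% at each scale.
    """
    if results.empty:
        raise ValueError("results table is empty")
    out = []
    for scale, grp in results.groupby("scale_m"):
        row: dict[str, float] = {"scale_m": scale, "n_reps": len(grp)}
        for m in METRIC_NAMES:
            row[f"{m}_median"] = float(grp[m].median())
            row[f"{m}_sd"] = float(grp[m].std(ddof=0))
        row["absME_median"] = float(grp["ME"].abs().median())
        row["absMRE_median"] = float(grp["MRE"].abs().median())
        for c in IMPORTANCE_COLUMNS:
            row[f"{c}_median"] = float(grp[c].median())
        cat_median = {}
        for cat in CATEGORIES:
            members = [f"imp_{n}" for n in PREDICTOR_NAMES if CATEGORY_MAP[n] == cat]
            cat_median[cat] = float(grp[members].sum(axis=1).median())
        total = sum(cat_median.values())
        for cat in CATEGORIES:
            row[f"cat_{cat}"] = 100.0 * cat_median[cat] / total if total > 0 else 0.0
        out.append(row)
    return pd.DataFrame(out).sort_values("scale_m").reset_index(drop=True)


def minimum_adequate_scale(summary: pd.DataFrame, r2_min: float = 0.7,
                           rrmse_max: float = 20.0) -> float | None:
    """Smallest scale with median R2 > r2_min and median rRMSE < rrmse_max."""
    qualifying = summary[(summary["R2_median"] > r2_min)
                         & (summary["rRMSE_median"] < rrmse_max)]
    if qualifying.empty:
        return None
    return float(qualifying["scale_m"].min())


def export_report(summary: pd.DataFrame, outdir: str | Path,
                  make_plots: bool = False) -> dict[str, Path]:
    """Write summary tables (and optional plots) under ``outdir``.

    ``scale_summary.csv`` holds the full per-scale summary;
    ``importance_by_scale.csv`` the 22 x n_scales median-importance matrix.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}

    summary_path = outdir / "scale_summary.csv"
    summary.to_csv(summary_path, index=False)
    files["summary"] = summary_path

    imp = pd.DataFrame(
        {f"{scale:g}m": summary.loc[i, [f"{c}_median" for c in IMPORTANCE_COLUMNS]].to_numpy()
         for i, scale in zip(summary.index, summary["scale_m"])},
        index=PREDICTOR_NAMES,
    )
    imp_path = outdir / "importance_by_scale.csv"
    imp.to_csv(imp_path, index_label="feature")
    files["importance"] = imp_path

    if make_plots:
        files.update(_plots(summary, imp, outdir))
    return files


def _plots(summary: pd.DataFrame, imp: pd.DataFrame, outdir: Path) -> dict[str, Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    files = {}
    scales = summary["scale_m"]

    fig, axes = plt.subplots(2, 3, figsize=(12, 7), sharex=True)
    for ax, m in zip(axes.ravel(), METRIC_NAMES):
        ax.errorbar(scales, summary[f"{m}_median"], yerr=summary[f"{m}_sd"],
                    marker="o", capsize=3)
        ax.set_ylabel(m)
        ax.set_xlabel("quadrat side (m)")
    fig.tight_layout()
    p = outdir / "metrics_vs_scale.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    files["metrics_plot"] = p

    fig, ax = plt.subplots(figsize=(10, 6))
    im = ax.imshow(imp.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_yticks(range(len(imp.index)), imp.index, fontsize=7)
    ax.set_xticks(range(len(imp.columns)), imp.columns, rotation=45)
    fig.colorbar(im, label="median relative importance (%)")
    fig.tight_layout()
    p = outdir / "importance_heatmap.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    files["heatmap"] = p

    fig, ax = plt.subplots(figsize=(7, 5))
    for cat in CATEGORIES:
        ax.plot(scales, summary[f"cat_{cat}"], marker="o", label=cat)
    ax.set_xlabel("quadrat side (m)")
    ax.set_ylabel("category importance (%)")
    ax.legend()
    fig.tight_layout()
    p = outdir / "category_importance.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    files["category_plot"] = p
    return files
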