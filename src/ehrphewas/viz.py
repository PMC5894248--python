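"""Manhattan-style PheWAS plots and tabular output.

Conventions follow the field's standard PheWAS figure: phecodes grouped
and color-coded by organ-system category on the x axis, −log10 of the
unadjusted p-value on the y axis, one triangle per phecode whose
orientation encodes the direction of effect relative to the reference
group, and a horizontal red line at the significance level implied by
the FDR threshold (the largest unadjusted p whose BH-adjusted p is
below alpha).  Every plot returns a marker manifest (phecode, x, y,
orientation, color, category, label) so tests assert on data, never on
pixels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .phewas import RESULT_COLUMNS

logger = logging.getLogger(__name__)

DEFAULT_CATEGORY_ORDER = [
    "infectious diseases",
    "circulatory system",
    "respiratory",
    "genitourinary",
    "dermatologic",
    "musculoskeletal",
]

_PALETTE = plt.get_cmap("tab10")


@dataclass
class PlotSpec:
    results: pd.DataFrame
    fdr_alpha: float = 0.05
    reference_group_label: str = "reference"
    category_order: list[str] = field(default_factory=lambda: list(DEFAULT_CATEGORY_ORDER))
    output_path: str | Path = "phewas_manhattan.png"
    image_format: str = "png"
    #: "up" means triangles point up when the phenotype is more common in
    #: the comparison (non-reference) group; "down" flips the convention.
    comparison_direction: str = "up"
    labels_per_category: int = 1


def fdr_threshold_p(results: pd.DataFrame, alpha: float) -> float | None:
    """Largest unadjusted p among results with BH-adjusted p <= alpha."""
    sig = results[(results["fdr_p"].notna()) & (results["fdr_p"] <= alpha)]
    if len(sig) == 0:
        return None
    return float(sig["p"].max())


def phewas_manhattan(spec: PlotSpec) -> pd.DataFrame:
    """Render the plot and return the marker manifest.

    The manifest has one row per plotted phecode with columns phecode,
    x, y (−log10 p), orientation (up/down), color (hex), category, and
    label (bool: annotated on the figure).  Rows without a finite p are
    dropped with a log note.
    """
    res = spec.results
    if len(res) == 0:
        raise ValueError("results are empty; nothing to plot")
    res = res[np.isfinite(res["p"].astype(float))].copy()
    if len(res) == 0:
        raise ValueError("no finite p-values to plot")

    order = list(spec.category_order)
    for cat in sorted(set(res["category"]) - set(order)):
        order.append(cat)
    cat_rank = {c: i for i, c in enumerate(order)}
    res["__cat_rank"] = res["category"].map(cat_rank)
    res["__code_val"] = res["phecode"].astype(float)
    res = res.sort_values(["__cat_rank", "__code_val"], kind="stable").reset_index(drop=True)

    up_for_positive = spec.comparison_direction == "up"
    orientation = np.where(
        (res["beta"].astype(float) > 0) == up_for_positive, "up", "down"
    )
    colors = [
        matplotlib.colors.to_hex(_PALETTE(cat_rank[c] % 10)) for c in res["category"]
    ]
    y = -np.log10(np.clip(res["p"].astype(float), 1e-300, None))
    x = np.arange(len(res), dtype=float)

    label_flag = np.zeros(len(res), dtype=bool)
    for _, grp in res.groupby("category", sort=False):
        top = grp.nsmallest(spec.labels_per_category, "p").index
        label_flag[[res.index.get_loc(i) for i in top]] = True

    fig, ax = plt.subplots(figsize=(max(6, len(res) * 0.3), 4.5))
    for orient, marker in (("up", "^"), ("down", "v")):
        m = orientation == orient
        ax.scatter(x[m], y[m], marker=marker, c=[c for c, f in zip(colors, m) if f], s=40)
    thr = fdr_threshold_p(res, spec.fdr_alpha)
    if thr is not None:
        ax.axhline(-np.log10(thr), color="red", lw=1)
    else:
        logger.info("no result passes FDR %.3g; threshold line omitted", spec.fdr_alpha)
    for xi, yi, lab, f in zip(x, y, res["phecode"], label_flag):
        if f:
            ax.annotate(str(lab), (xi, yi), fontsize=7, rotation=45,
                        xytext=(0, 4), textcoords="offset points")
    ticks, tick_labels = [], []
    for cat, grp in res.groupby("category", sort=False):
        ticks.append(x[[res.index.get_loc(i) for i in grp.index]].mean())
        tick_labels.append(cat)
    ax.set_xticks(ticks)
    ax.set_xticklabels(tick_labels, rotation=30, ha="right", fontsize=8)
    ax.set_ylabel(r"$-\log_{10}(p)$")
    ax.set_xlabel(f"phecode (reference: {spec.reference_group_label})")
    fig.tight_layout()
    fig.savefig(spec.output_path, format=spec.image_format, dpi=150)
    plt.close(fig)

    manifest = pd.DataFrame(
        {
            "phecode": res["phecode"].to_numpy(),
            "x": x,
            "y": y.to_numpy(),
            "orientation": orientation,
            "color": colors,
            "category": res["category"].to_numpy(),
            "label": label_flag,
        }
    )
    return manifest


def forest_plot(results: pd.DataFrame, output_path, title: str = "") -> None:
    """Simple OR-with-CI panel for conditional-model results."""
    res = results.dropna(subset=["odds_ratio"]).reset_index(drop=True)
    fig, ax = plt.subplots(figsize=(6, max(2, 0.4 * len(res))))
    ypos = np.arange(len(res))[::-1]
    ax.errorbar(
        res["odds_ratio"], ypos,
        xerr=[res["odds_ratio"] - res["ci_low"], res["ci_high"] - res["odds_ratio"]],
        fmt="s", color="black", ecolor="gray", capsize=3,
    )
    ax.axvline(1.0, color="red", lw=1, ls="--")
    ax.set_yticks(ypos)
    ax.set_yticklabels(res["phecode"].astype(str))
    ax.set_xscale("log")
    ax.set_xlabel("odds ratio (95% CI)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(output_path, dpi=150)
    plt.close(fig)


def write_results(results: pd.DataFrame, path) -> None:
    """Write PheWAS results with a fixed column order and 17-significant-
    digit floats so the file round-trips bit-exactly through
    :func:`read_results`."""
    out = results.reindex(columns=RESULT_COLUMNS)
    out.to_csv(path, index=False, float_format="%.17g")


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"phecode": str}, float_precision="round_trip")
    for col in ("description", "category"):
        df[col] = df[col].fillna("")
    df["converged"] = df["converged"].astype(bool)
    return df.reindex(columns=RESULT_COLUMNS)


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, index=False, float_format="%.17g")


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"phecode": str}, float_precision="round_trip")
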