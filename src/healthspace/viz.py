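"""Plots: the anchored health space and the response-clustering heatmap.

All functions are pure readers — they never mutate their inputs — and
write static images (PNG/SVG/PDF by file extension).  The health space is
drawn as one 3-D view plus every pairwise 2-D projection; axes are shown
orthogonal for display even though the underlying processes are
statistically interdependent.
"""

from __future__ import annotations

import itertools
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .datamodel import ARM_CONTROL, ARM_TREATED
from .response import Dendrogram, ResponseSet
from .space import ScoreSet

#: colour-blind-safe group colours
ARM_COLORS = {ARM_TREATED: "#0072B2", ARM_CONTROL: "#D55E00"}


def _check_axes(scores: ScoreSet, axes: Sequence[str] | None) -> list:
    names = list(axes) if axes is not None else list(scores.axis_names)
    unknown = [a for a in names if a not in scores.axis_names]
    if unknown:
        raise ValueError(f"unknown axis name(s): {unknown}")
    if not names or scores.scores.empty:
        raise ValueError("no scores to plot")
    return names


def _scatter_2d(ax, scores: ScoreSet, x: str, y: str, vectors: bool) -> None:
    df = scores.scores
    for arm, color in ARM_COLORS.items():
        mask = df["arm"] == arm
        ax.scatter(df.loc[mask, x], df.loc[mask, y], c=color, label=arm, s=24)
    if vectors:
        for _, sub in df.groupby("subject_id"):
            if set(sub["arm"]) >= {ARM_TREATED, ARM_CONTROL}:
                c = sub[sub["arm"] == ARM_CONTROL].iloc[0]
                t = sub[sub["arm"] == ARM_TREATED].iloc[0]
                ax.plot([c[x], t[x]], [c[y], t[y]], color="grey", lw=0.6, alpha=0.6)
    for anchor, style in ((0.0, "-"), (1.0, "--")):
        ax.axvline(anchor, color="k", lw=0.5, ls=style, alpha=0.4)
        ax.axhline(anchor, color="k", lw=0.5, ls=style, alpha=0.4)
    ax.set_xlabel(x)
    ax.set_ylabel(y)


def plot_health_space(
    scores: ScoreSet,
    out_prefix: str | Path,
    axes: Sequence[str] | None = None,
    vectors: bool = True,
    fmt: str = "png",
    dpi: int = 150,
) -> list:
    """Write one 3-D view (if >= 3 axes) plus all pairwise 2-D projections.

    Returns the list of written paths.  Subject vectors connect each
    subject's control point to their treated point; reference lines mark
    the 0 (treated mean) and 1 (control mean) anchors.
    """
    names = _check_axes(scores, axes)
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if len(names) >= 3:
        x, y, z = names[:3]
        fig = plt.figure(figsize=(6, 5))
        ax = fig.add_subplot(projection="3d")
        df = scores.scores
        for arm, color in ARM_COLORS.items():
            mask = df["arm"] == arm
            ax.scatter(
                df.loc[mask, x], df.loc[mask, y], df.loc[mask, z],
                c=color, label=arm, s=24,
            )
        if vectors:
            for _, sub in df.groupby("subject_id"):
                if set(sub["arm"]) >= {ARM_TREATED, ARM_CONTROL}:
                    c = sub[sub["arm"] == ARM_CONTROL].iloc[0]
                    t = sub[sub["arm"] == ARM_TREATED].iloc[0]
                    ax.plot(
                        [c[x], t[x]], [c[y], t[y]], [c[z], t[z]],
                        color="grey", lw=0.6, alpha=0.6,
                    )
        ax.set_xlabel(x)
        ax.set_ylabel(y)
        ax.set_zlabel(z)
        ax.legend()
        path = out_prefix.with_name(out_prefix.name + f"_3d.{fmt}")
        fig.savefig(path, dpi=dpi)
        plt.close(fig)
        written.append(path)

    for x, y in itertools.combinations(names, 2):
        fig, ax = plt.subplots(figsize=(5, 4))
        _scatter_2d(ax, scores, x, y, vectors)
        ax.legend()
        fig.tight_layout()
        path = out_prefix.with_name(out_prefix.name + f"_{x}_vs_{y}.{fmt}")
        fig.savefig(path, dpi=dpi)
        plt.close(fig)
        written.append(path)
    return written


def plot_response_clustering(
    responses: ResponseSet,
    dendrogram: Dendrogram,
    out_path: str | Path,
    dpi: int = 150,
) -> Path:
    """Heatmap of per-subject responses ordered by dendrogram leaf order.

    The dendrogram is drawn alongside; outlier subjects (not part of the
    tree) are appended below the heatmap with an ``(outlier)`` annotation
    and no cluster band.
    """
    table = responses.table
    in_tree = set(dendrogram.leaf_names)
    missing = in_tree - set(table["subject_id"])
    if missing:
        raise ValueError(f"dendrogram leaves not in responses: {sorted(missing)}")

    leaf_order = dendrogram.leaf_order()
    outliers = [s for s in table.loc[table["outlier"], "subject_id"] if s not in in_tree]
    order = leaf_order + outliers

    mat = (
        table.set_index("subject_id")
        .loc[order, responses.axis_names]
        .to_numpy(dtype=float)
    )
    clusters = table.set_index("subject_id")["cluster"]

    fig, (ax_d, ax_h) = plt.subplots(
        1, 2, figsize=(8, 0.35 * len(order) + 2),
        gridspec_kw={"width_ratios": [1, 2]},
    )
    hierarchy.dendrogram(
        dendrogram.linkage,
        labels=dendrogram.leaf_names,
        orientation="left",
        ax=ax_d,
        color_threshold=0,
        above_threshold_color="k",
    )
    ax_d.set_xlabel("height")

    vmax = np.nanmax(np.abs(mat)) or 1.0
    im = ax_h.imshow(mat, aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    labels = []
    for s in order:
        tag = " (outlier)" if s in set(outliers) else f"  [c{int(clusters[s])}]" if not pd.isna(clusters[s]) else ""
        labels.append(f"{s}{tag}")
    ax_h.set_yticks(range(len(order)), labels=labels, fontsize=7)
    ax_h.set_xticks(range(len(responses.axis_names)), labels=responses.axis_names)
    fig.colorbar(im, ax=ax_h, label="response (control - treated)")
    fig.tight_layout()
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=dpi)
    plt.close(fig)
    return out_path
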