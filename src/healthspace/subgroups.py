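"""Characterization of responder clusters by interaction-first two-way ANOVA.

For every parameter of the table, a fixed-effects two-way ANOVA with
factors *cluster* (responder subgroup from the hierarchical clustering) and
*treatment* (arm) is fitted on per-subject-arm means — one value per
subject per arm, so timepoints are never pseudo-replicated.  The
cluster x treatment interaction is tested first: a significant interaction
(after BH correction across parameters) means the treatment effect on that
parameter differs between responder subgroups.  Only for parameters with a
non-significant interaction are the main effects interpreted.

Cluster sizes are naturally unbalanced, so sums of squares are Type II by
default (each effect adjusted for the other main effect, the interaction
ignored when testing mains — matching the interaction-first logic);
Type III is available as an option.  The F statistics come from
residual-sum-of-squares comparisons of nested least-squares fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ARM_CONTROL, ARM_TREATED, SampleTable
from .exceptions import InsufficientDataError
from .response import ResponseSet
from .screen import bh_adjust

EFFECTS = ("interaction", "cluster", "treatment")

_RSS_TOL = 1e-12


def _dummy(levels_idx: np.ndarray, n_levels: int) -> np.ndarray:
    """Drop-first dummy coding, shape (n, n_levels - 1)."""
    out = np.zeros((len(levels_idx), n_levels - 1))
    for j in range(1, n_levels):
        out[levels_idx == j, j - 1] = 1.0
    return out


def _effect_coding(levels_idx: np.ndarray, n_levels: int) -> np.ndarray:
    """Sum-to-zero coding (used for Type III)."""
    out = np.zeros((len(levels_idx), n_levels - 1))
    for j in range(n_levels - 1):
        out[levels_idx == j, j] = 1.0
    out[levels_idx == n_levels - 1, :] = -1.0
    return out


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _interaction_cols(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    cols = [A[:, i] * B[:, j] for i in range(A.shape[1]) for j in range(B.shape[1])]
    return np.column_stack(cols) if cols else np.empty((len(A), 0))


def two_way_anova(
    values: Sequence[float],
    cluster: Sequence,
    treatment: Sequence,
    ss_type: int = 2,
) -> dict:
    """Fixed-effects two-way ANOVA with interaction.

    Returns ``{"interaction": (F, p), "cluster": (F, p), "treatment":
    (F, p), "df": {...}}``.  Unbalanced designs use Type II sums of squares
    by default (``ss_type=3`` switches to Type III with sum-to-zero
    coding).  An empty cluster x treatment cell is an error; zero residual
    variance yields ``p = nan`` with a warning.
    """
    y = np.asarray(values, dtype=float)
    cl = np.asarray([str(c) for c in cluster], dtype=object)
    tr = np.asarray([str(t) for t in treatment], dtype=object)
    if not (len(y) == len(cl) == len(tr)):
        raise ValueError("values, cluster, treatment must have equal length")

    cl_levels = sorted(set(cl))
    tr_levels = sorted(set(tr))
    a, b = len(cl_levels), len(tr_levels)
    if a < 2 or b < 2:
        raise InsufficientDataError("both factors need >= 2 levels")
    cl_idx = np.array([cl_levels.index(c) for c in cl])
    tr_idx = np.array([tr_levels.index(t) for t in tr])

    for i, ci in enumerate(cl_levels):
        for j, tj in enumerate(tr_levels):
            if not np.any((cl_idx == i) & (tr_idx == j)):
                raise InsufficientDataError(
                    f"empty cell: cluster={ci!r} x treatment={tj!r}"
                )

    n = len(y)
    df_res = n - a * b
    if df_res < 1:
        raise InsufficientDataError("no residual degrees of freedom")

    code = _effect_coding if ss_type == 3 else _dummy
    A = code(cl_idx, a)
    B = code(tr_idx, b)
    AB = _interaction_cols(A, B)
    ones = np.ones((n, 1))

    rss_full = _rss(np.hstack([ones, A, B, AB]), y)
    rss_add = _rss(np.hstack([ones, A, B]), y)
    if ss_type == 3:
        ss_cl = _rss(np.hstack([ones, B, AB]), y) - rss_full
        ss_tr = _rss(np.hstack([ones, A, AB]), y) - rss_full
    else:  # Type II: each main adjusted for the other main, not the interaction
        ss_cl = _rss(np.hstack([ones, B]), y) - rss_add
        ss_tr = _rss(np.hstack([ones, A]), y) - rss_add
    ss_int = rss_add - rss_full

    df = {"interaction": (a - 1) * (b - 1), "cluster": a - 1, "treatment": b - 1}
    ss = {"interaction": ss_int, "cluster": ss_cl, "treatment": ss_tr}
    ms_res = rss_full / df_res

    scale = max(float(y @ y), 1.0)
    out: dict = {"df": {**df, "residual": df_res}}
    for eff in EFFECTS:
        ss_eff = max(ss[eff], 0.0)  # guard tiny negative round-off
        if ms_res < _RSS_TOL * scale:
            warnings.warn("zero residual variance; p-values undefined")
            out[eff] = (float("nan"), float("nan"))
            continue
        F = (ss_eff / df[eff]) / ms_res
        p = float(stats.f.sf(F, df[eff], df_res))
        out[eff] = (float(F), p)
    return out


@dataclass
class AnovaRecord:
    """Per-parameter ANOVA outcome under the interaction-first rule."""

    parameter_id: str
    interaction_F: float
    interaction_p: float
    cluster_F: float
    cluster_p: float
    treatment_F: float
    treatment_p: float
    interaction_q: float = float("nan")
    cluster_q: float = float("nan")
    treatment_q: float = float("nan")
    verdict: str = "none"


def _subject_arm_means(table: SampleTable) -> pd.DataFrame:
    """One row per (subject, arm): parameter means over timepoints."""
    grouped = table.values.groupby(
        [table.meta["subject_id"], table.meta["arm"]]
    ).mean()
    return grouped.reset_index()


def characterize_clusters(
    table: SampleTable,
    responses: ResponseSet,
    alpha: float = 0.05,
    ss_type: int = 2,
) -> pd.DataFrame:
    """Interaction-first ANOVA screen of all parameters against the clusters.

    Unit of analysis: per-subject-arm means.  Outlier and unlabelled
    subjects are excluded.  BH correction is applied across parameters
    within the interaction family; parameters with a non-significant
    interaction form the families for the two main effects.  The verdict
    per parameter is ``interaction`` when the interaction survives FDR at
    ``alpha``; otherwise the most significant surviving main effect
    (``cluster_main`` / ``treatment_main``), else ``none``.
    """
    t = responses.table
    labelled = t[~t["outlier"] & t["cluster"].notna()]
    cluster_of = dict(zip(labelled["subject_id"], labelled["cluster"].astype(int)))
    if len(set(cluster_of.values())) < 2:
        raise InsufficientDataError(
            "characterization needs >= 2 clusters of labelled subjects"
        )

    means = _subject_arm_means(table)
    means = means[means["subject_id"].isin(cluster_of)]
    cl = [cluster_of[s] for s in means["subject_id"]]
    tr = list(means["arm"])

    records: list[AnovaRecord] = []
    for p in table.parameter_ids:
        y = means[p].to_numpy(dtype=float)
        if np.isnan(y).any() or np.std(y) == 0.0:
            warnings.warn(f"parameter {p!r}: constant or incomplete values; verdict none")
            records.append(
                AnovaRecord(p, *(float("nan"),) * 6)
            )
            continue
        res = two_way_anova(y, cl, tr, ss_type=ss_type)
        records.append(
            AnovaRecord(
                p,
                res["interaction"][0],
                res["interaction"][1],
                res["cluster"][0],
                res["cluster"][1],
                res["treatment"][0],
                res["treatment"][1],
            )
        )

    df = pd.DataFrame([r.__dict__ for r in records])

    testable = df["interaction_p"].notna()
    if testable.any():
        df.loc[testable, "interaction_q"] = bh_adjust(
            df.loc[testable, "interaction_p"]
        )
    sig_int = testable & (df["interaction_q"] <= alpha)
    df.loc[sig_int, "verdict"] = "interaction"

    # main effects are interpreted only where the interaction is not significant
    mains = testable & ~sig_int
    for eff in ("cluster", "treatment"):
        if mains.any():
            df.loc[mains, f"{eff}_q"] = bh_adjust(df.loc[mains, f"{eff}_p"])
    for idx in df.index[mains]:
        qc = df.at[idx, "cluster_q"]
        qt = df.at[idx, "treatment_q"]
        candidates = [
            (q, name)
            for q, name in ((qc, "cluster_main"), (qt, "treatment_main"))
            if np.isfinite(q) and q <= alpha
        ]
        if candidates:
            df.at[idx, "verdict"] = min(candidates)[1]
    return df


def summary_report(anova_table: pd.DataFrame, top: int = 10) -> str:
    """Plain-text report of the parameters driving the cluster separation."""
    lines = ["Cluster characterization (interaction-first two-way ANOVA)", ""]
    counts = anova_table["verdict"].value_counts()
    for verdict in ("interaction", "cluster_main", "treatment_main", "none"):
        lines.append(f"  {verdict:>15}: {int(counts.get(verdict, 0))} parameter(s)")
    inter = anova_table[anova_table["verdict"] == "interaction"].sort_values(
        "interaction_q"
    )
    if len(inter):
        lines += ["", "Top interaction parameters (treatment effect differs by cluster):"]
        for _, row in inter.head(top).iterrows():
            lines.append(
                f"  {row.parameter_id}: F={row.interaction_F:.2f},"
                f" q={row.interaction_q:.3g}"
            )
    return "\n".join(lines) + "\n"


def save_anova_table(anova_table: pd.DataFrame, path: str | Path) -> None:
    anova_table.to_csv(path, sep="\t", index=False)
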