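"""Per-subject treatment-response vectors and responder-subgroup clustering.

A subject's *response vector* is the per-axis difference between their
control-arm and treated-arm anchored scores.  With the anchors at
treated = 0 and control = 1, a positive component means the treatment moved
the subject toward the healthy origin on that axis.  Response vectors are
clustered by agglomerative hierarchical clustering with Euclidean distance
and average (UPGMA) linkage, on the raw vectors — no additional scaling —
and the tree is cut into ``k`` clusters (default 2).

Outliers — subjects whose response is so extreme that they sit alone on a
long branch at the top of the tree — are flagged before clustering and
excluded from cluster labels but kept in all exports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator

from .datamodel import ARM_CONTROL, ARM_TREATED
from .exceptions import InsufficientDataError
from .space import ScoreSet

#: a top-split singleton is an outlier when its merge height exceeds this
#: multiple of the median pairwise distance
OUTLIER_HEIGHT_FACTOR = 3.0


@dataclass
class ResponseSet:
    """Per-subject response vectors with cluster labels and outlier flags.

    ``table`` columns: ``subject_id``, one column per axis, ``cluster``
    (nullable integer) and ``outlier`` (bool).
    """

    table: pd.DataFrame
    axis_names: list

    @property
    def subject_ids(self) -> list:
        return list(self.table["subject_id"])

    def vectors(self, include_outliers: bool = True) -> np.ndarray:
        t = self.table if include_outliers else self.table[~self.table["outlier"]]
        return t[self.axis_names].to_numpy(dtype=float)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class Dendrogram:
    """Merge list of an agglomerative clustering.

    ``linkage`` is the scipy linkage matrix (merges in non-decreasing height
    order for average linkage on Euclidean input); ``leaf_names`` maps leaf
    indices to subject ids.
    """

    linkage: np.ndarray
    leaf_names: list

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def leaf_order(self) -> list:
        return [self.leaf_names[i] for i in hierarchy.leaves_list(self.linkage)]

    def to_merge_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            self.linkage, columns=["node_a", "node_b", "height", "size"]
        )
        df.to_csv(path, sep="\t", index=False)

    def to_newick(self, path: str | Path | None = None) -> str:
        """Newick string with leaf names and height-derived branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def render(node, parent_height):
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                return f"{self.leaf_names[node.id]}:{parent_height:.10g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        body = render(tree, tree.dist).rsplit(":", 1)[0]
        newick = body + ";"
        if path is not None:
            Path(path).write_text(newick + "\n")
        return newick


def response_vectors(scores: ScoreSet, sign: str = "control_minus_treated") -> ResponseSet:
    """Per-subject per-axis arm difference (default: control - treated).

    Subjects lacking either arm are dropped with a warning.  No rescaling
    is applied to the vectors.
    """
    if sign not in ("control_minus_treated", "treated_minus_control"):
        raise ValueError("sign must be 'control_minus_treated' or 'treated_minus_control'")
    df = scores.scores
    wide = df.pivot_table(
        index="subject_id", columns="arm", values=scores.axis_names, aggfunc="mean"
    )
    rows = []
    dropped = []
    for subject in sorted(df["subject_id"].unique()):
        try:
            control = np.array(
                [wide.loc[subject, (a, ARM_CONTROL)] for a in scores.axis_names]
            )
            treated = np.array(
                [wide.loc[subject, (a, ARM_TREATED)] for a in scores.axis_names]
            )
        except KeyError:
            dropped.append(subject)
            continue
        if np.isnan(control).any() or np.isnan(treated).any():
            dropped.append(subject)
            continue
        vec = control - treated if sign == "control_minus_treated" else treated - control
        rows.append([subject, *vec])
    if dropped:
        warnings.warn(f"dropping subjects without both arms: {dropped}")
    if not rows:
        raise InsufficientDataError("no subject has scores under both arms")
    table = pd.DataFrame(rows, columns=["subject_id", *scores.axis_names])
    table["cluster"] = pd.array([pd.NA] * len(table), dtype="Int64")
    table["outlier"] = False
    return ResponseSet(table=table, axis_names=list(scores.axis_names))


def _linkage(vectors: np.ndarray) -> np.ndarray:
    return hierarchy.linkage(vectors, method="average", metric="euclidean")


def flag_outliers(
    responses: ResponseSet, height_factor: float = OUTLIER_HEIGHT_FACTOR
) -> ResponseSet:
    """Flag dendrogram-singleton outliers.

    A subject is an outlier when it forms a singleton branch at the top
    split of the (average-linkage, Euclidean) tree *and* that top merge
    height exceeds ``height_factor`` times the median pairwise distance of
    the current vectors.  Applied iteratively, so several successive
    extreme subjects can be peeled off.  With fewer than 4 subjects the
    rule is inapplicable (warning, no flags).
    """
    table = responses.table.copy()
    table["outlier"] = False
    if len(table) < 4:
        warnings.warn("outlier rule needs >= 4 subjects; no flags set")
        return ResponseSet(table=table, axis_names=list(responses.axis_names))

    active = list(table.index)
    while len(active) >= 4:
        vecs = table.loc[active, responses.axis_names].to_numpy(dtype=float)
        Z = _linkage(vecs)
        top = Z[-1]
        median_dist = float(np.median(pdist(vecs)))
        if median_dist == 0.0:
            break
        n = len(active)
        singleton_leaf = None
        for node in (int(top[0]), int(top[1])):
            if node < n:  # a leaf at the very top split
                singleton_leaf = node
        if singleton_leaf is None or top[2] <= height_factor * median_dist:
            break
        idx = active[singleton_leaf]
        table.loc[idx, "outlier"] = True
        active.remove(idx)
    return ResponseSet(table=table, axis_names=list(responses.axis_names))


def _auto_k(heights: np.ndarray, k_max: int = 6) -> int:
    """Number of clusters at the largest relative merge-height gap.

    Cutting between merge ``n-k`` and ``n-k+1`` (1-based from the top)
    yields ``k`` clusters; the gap is scored relative to the higher merge.
    """
    n_merges = len(heights)
    best_k, best_gap = 2, -np.inf
    for k in range(2, min(k_max, n_merges) + 1):
        hi = heights[n_merges - k + 1] if k > 1 else np.inf
        lo = heights[n_merges - k]
        if hi <= 0:
            continue
        gap = (hi - lo) / hi
        if gap > best_gap + 1e-12:
            best_gap, best_k = gap, k
    return best_k


def cluster_responses(
    responses: ResponseSet, k: int | str = 2
) -> tuple[Dendrogram, ResponseSet]:
    """Cluster non-outlier response vectors; label clusters 1..k.

    Euclidean distance, average (UPGMA) linkage, raw vectors.  ``k`` may be
    an integer or ``"auto"`` (largest relative height gap; never overrides
    an explicit integer).  Cluster labels are renumbered by first
    appearance in subject order, so the labelling is deterministic.
    """
    table = responses.table.copy()
    keep = ~table["outlier"].to_numpy(dtype=bool)
    vecs = table.loc[keep, responses.axis_names].to_numpy(dtype=float)
    names = list(table.loc[keep, "subject_id"])
    n = len(names)
    if n < 3:
        raise InsufficientDataError(
            f"clustering needs >= 3 non-outlier subjects, got {n}"
        )
    Z = _linkage(vecs)
    if k == "auto":
        k_eff = _auto_k(Z[:, 2])
    else:
        k_eff = int(k)
        if k_eff > n:
            raise ValueError(f"k={k_eff} exceeds the {n} available subjects")
    raw_labels = hierarchy.fcluster(Z, t=k_eff, criterion="maxclust")
    # renumber by order of first appearance for determinism
    remap: dict[int, int] = {}
    for lab in raw_labels:
        if lab not in remap:
            remap[lab] = len(remap) + 1
    labels = [remap[lab] for lab in raw_labels]

    table["cluster"] = pd.array([pd.NA] * len(table), dtype="Int64")
    table.loc[keep, "cluster"] = labels
    dendro = Dendrogram(linkage=Z, leaf_names=names)
    return dendro, ResponseSet(table=table, axis_names=list(responses.axis_names))


class ResponseClustering(BaseEstimator):
    """Estimator wrapper: outlier flagging + UPGMA clustering of responses.

    ``fit`` takes a :class:`ScoreSet`; attributes afterwards:
    ``responses_`` (labelled :class:`ResponseSet`), ``dendrogram_``,
    ``labels_`` (per non-outlier subject, in table order) and
    ``outliers_`` (subject ids).
    """

    def __init__(
        self,
        n_clusters: int | str = 2,
        flag_outliers: bool = True,
        height_factor: float = OUTLIER_HEIGHT_FACTOR,
        sign: str = "control_minus_treated",
        exclude_subjects: Sequence[str] = (),
    ):
        self.n_clusters = n_clusters
        self.flag_outliers = flag_outliers
        self.height_factor = height_factor
        self.sign = sign
        self.exclude_subjects = tuple(exclude_subjects)

    def fit(self, scores: ScoreSet) -> "ResponseClustering":
        responses = response_vectors(scores, sign=self.sign)
        if self.exclude_subjects:
            mask = responses.table["subject_id"].isin(self.exclude_subjects)
            responses.table.loc[mask, "outlier"] = True
        if self.flag_outliers:
            flagged = flag_outliers(responses, height_factor=self.height_factor)
            # manual exclusions stay flagged regardless of the rule
            if self.exclude_subjects:
                mask = flagged.table["subject_id"].isin(self.exclude_subjects)
                flagged.table.loc[mask, "outlier"] = True
            responses = flagged
        self.dendrogram_, self.responses_ = cluster_responses(
            responses, k=self.n_clusters
        )
        t = self.responses_.table
        self.labels_ = t.loc[~t["outlier"], "cluster"].to_numpy(dtype=int)
        self.outliers_ = list(t.loc[t["outlier"], "subject_id"])
        return self

    def fit_predict(self, scores: ScoreSet) -> np.ndarray:
        return self.fit(scores).labels_
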