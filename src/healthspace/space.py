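"""Assembly of per-axis PLS-DA scores into an anchored health space.

Each axis is fitted independently (feature construction -> double-CV
PLS-DA -> out-of-fold prediction scores) and the scores are then mapped by
the anchor transform

    s' = (s - mean_treated) / (mean_control - mean_treated)

applied simultaneously to all samples of the axis, so the treated-group
mean lands exactly at 0 ("health", the average state after the active
intervention) and the control-group mean at 1.  The transform makes scores
comparable *within* an axis; the axes remain mutually non-comparable and
non-orthogonal (processes share parameters and are biologically coupled) —
no operation here forms cross-axis ratios.

A fitted :class:`HealthSpace` keeps, per axis, the refit all-data PLS model
together with the anchor means, so new subjects can later be projected into
the same space without re-estimating anything.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datamodel import (
    ARM_CONTROL,
    ARM_TREATED,
    AxisDefinition,
    SampleTable,
    build_feature_matrix,
)
from .exceptions import DegenerateAxisError, MissingParameterError
from .plsda import DcvResult, DoubleCV, PLSDA

#: anchor means below this separation make an axis un-anchorable
DEGENERACY_TOL = 1e-12
#: oof misclassification at or above this triggers an "uninformative axis" warning
UNINFORMATIVE_MISCLS = 0.4

SCHEMA_VERSION = 1


@dataclass
class ScoreSet:
    """Per-sample anchored scores on every axis.

    ``scores`` has columns ``subject_id``, ``arm`` and one column per axis;
    after construction, per axis the treated mean is 0 and the control mean
    is 1 (to numerical precision).
    """

    scores: pd.DataFrame
    axis_names: list

    def axis_values(self, axis: str) -> np.ndarray:
        return self.scores[axis].to_numpy()

    def arm_mask(self, arm: str) -> np.ndarray:
        return (self.scores["arm"] == arm).to_numpy()

    def to_tsv(self, path: str | Path) -> None:
        self.scores.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ScoreSet":
        df = pd.read_csv(path, sep="\t")
        axes = [c for c in df.columns if c not in ("subject_id", "arm")]
        df["subject_id"] = df["subject_id"].astype(str)
        return cls(scores=df, axis_names=axes)


@dataclass
class AxisModel:
    """Everything needed to score one axis: definition, refit PLS, anchors."""

    definition: AxisDefinition
    pls: PLSDA
    treated_anchor: float
    control_anchor: float
    column_ids: list
    dcv: DcvResult | None = None
    refit_anchor_offset: tuple = (0.0, 0.0)  # (treated, control) refit - oof anchor


def scale_scores(
    raw_scores: np.ndarray, treated_mask: np.ndarray, control_mask: np.ndarray
) -> np.ndarray:
    """Anchor transform sending the treated mean to 0, the control mean to 1.

    Applied to every score of the axis (both groups simultaneously).  The
    map is affine, so an axis whose raw control mean lies *below* the
    treated mean simply has its sign flipped — orientation becomes
    canonical as a side effect.
    """
    raw_scores = np.asarray(raw_scores, dtype=float)
    treated_mask = np.asarray(treated_mask, dtype=bool)
    control_mask = np.asarray(control_mask, dtype=bool)
    if not treated_mask.any() or not control_mask.any():
        raise DegenerateAxisError("both groups must be non-empty for anchoring")
    m_t = raw_scores[treated_mask].mean()
    m_c = raw_scores[control_mask].mean()
    span = m_c - m_t
    if abs(span) < DEGENERACY_TOL * max(1.0, abs(m_t), abs(m_c)):
        raise DegenerateAxisError(
            f"treated and control mean scores coincide ({m_t:.3g}); axis cannot be anchored"
        )
    return (raw_scores - m_t) / span


class HealthSpace(BaseEstimator):
    """Fit a multi-axis health space on a cross-over sample table.

    Parameters
    ----------
    outer_folds, inner_folds : int
        Fold counts of the double cross-validation (subject-grouped).
    max_components : int
        Upper bound for the number of PLS latent variables per axis.
    anchor_source : {"oof", "refit"}
        Whether the 0/1 anchors are the group means of the out-of-fold
        scores (default; unbiased) or of the refit all-data scores.
    score_source : {"oof", "refit"}
        Which scores populate the returned :class:`ScoreSet`.  The default
        out-of-fold scores are the unbiased coordinates; ``refit`` scores
        come from the final all-data model.
    random_state : int, optional
        Seed for all fold assignment.

    Attributes (after ``fit``)
    --------------------------
    axis_models_ : dict of axis name -> :class:`AxisModel`
    scores_      : :class:`ScoreSet` of the training samples
    provenance_  : dict with settings and a config hash
    """

    def __init__(
        self,
        outer_folds: int = 7,
        inner_folds: int = 5,
        max_components: int = 5,
        anchor_source: str = "oof",
        score_source: str = "oof",
        random_state: int | None = None,
    ):
        self.outer_folds = outer_folds
        self.inner_folds = inner_folds
        self.max_components = max_components
        self.anchor_source = anchor_source
        self.score_source = score_source
        self.random_state = random_state

    def fit(self, table: SampleTable, axes: Sequence[AxisDefinition]) -> "HealthSpace":
        if not axes:
            raise ValueError("at least one axis is required")
        if self.anchor_source not in ("oof", "refit") or self.score_source not in (
            "oof",
            "refit",
        ):
            raise ValueError("anchor_source/score_source must be 'oof' or 'refit'")

        axis_models: dict[str, AxisModel] = {}
        score_cols: dict[str, np.ndarray] = {}
        base_index = None
        rng = np.random.default_rng(self.random_state)
        for axis in axes:
            fm = build_feature_matrix(table, axis)
            index = list(zip(fm.subject_ids, fm.arms))
            if base_index is None:
                base_index = index
                subject_ids, arms = fm.subject_ids, fm.arms
            elif index != base_index:
                raise ValueError(
                    f"axis {axis.axis_name!r} yields a different sample grid"
                )
            axis_seed = int(rng.integers(0, 2**31 - 1))
            use_dcv = self.anchor_source == "oof" or self.score_source == "oof"
            dcv = None
            if use_dcv:
                dcv = DoubleCV(
                    outer_folds=self.outer_folds,
                    inner_folds=self.inner_folds,
                    max_components=self.max_components,
                    random_state=axis_seed,
                ).fit(fm.X, fm.y, groups=fm.subject_ids)
                if dcv.misclassification_rate_ >= UNINFORMATIVE_MISCLS:
                    warnings.warn(
                        f"axis {axis.axis_name!r} may be uninformative: out-of-fold "
                        f"misclassification {dcv.misclassification_rate_:.2f}"
                    )
                refit_components = int(round(np.median(dcv.chosen_components_)))
            else:
                refit_components = self.max_components
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                refit = PLSDA(n_components=max(1, refit_components), scale=True).fit(
                    fm.X, fm.y
                )
            refit_scores = refit.predict(fm.X)
            treated = np.asarray([a == ARM_TREATED for a in fm.arms])
            control = ~treated

            anchor_raw = dcv.oof_scores_ if self.anchor_source == "oof" else refit_scores
            m_t = float(anchor_raw[treated].mean())
            m_c = float(anchor_raw[control].mean())
            span = m_c - m_t
            if abs(span) < DEGENERACY_TOL * max(1.0, abs(m_t), abs(m_c)):
                raise DegenerateAxisError(
                    f"axis {axis.axis_name!r} is degenerate: treated and control "
                    f"mean scores coincide"
                )
            raw = dcv.oof_scores_ if self.score_source == "oof" else refit_scores
            score_cols[axis.axis_name] = scale_scores(raw, treated, control)
            axis_models[axis.axis_name] = AxisModel(
                definition=axis,
                pls=refit,
                treated_anchor=m_t,
                control_anchor=m_c,
                column_ids=fm.column_ids,
                dcv=dcv.result_ if dcv is not None else None,
                refit_anchor_offset=(
                    float(refit_scores[treated].mean()) - m_t,
                    float(refit_scores[control].mean()) - m_c,
                ),
            )

        frame = pd.DataFrame({"subject_id": subject_ids, "arm": arms})
        for name, col in score_cols.items():
            frame[name] = col
        self.axis_models_ = axis_models
        self.axis_names_ = [a.axis_name for a in axes]
        self.scores_ = ScoreSet(scores=frame, axis_names=self.axis_names_)
        self.provenance_ = self._provenance(axes)
        return self

    def _provenance(self, axes: Sequence[AxisDefinition]) -> dict:
        cfg = {
            "outer_folds": self.outer_folds,
            "inner_folds": self.inner_folds,
            "max_components": self.max_components,
            "anchor_source": self.anchor_source,
            "score_source": self.score_source,
            "random_state": self.random_state,
            "axes": {
                a.axis_name: [list(f) for f in a.features] for a in axes
            },
        }
        digest = hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest()[:16]
        return {"settings": cfg, "config_hash": digest}

    # -- projection ------------------------------------------------------
    def transform(self, table: SampleTable) -> ScoreSet:
        """Project a table into the fitted space using stored constants.

        Applies the stored autoscaling, refit PLS coefficients and anchor
        means; nothing is re-estimated.  Projecting the training table
        reproduces the anchor means only approximately when anchors came
        from out-of-fold scores (the refit-vs-oof offset is available per
        axis as a diagnostic).
        """
        if not hasattr(self, "axis_models_"):
            raise ValueError("HealthSpace is not fitted")
        needed = sorted(
            {
                p
                for m in self.axis_models_.values()
                for p, _ in m.column_ids
            }
        )
        missing = [p for p in needed if p not in table.values.columns]
        if missing:
            raise MissingParameterError(missing)

        frame = None
        for name in self.axis_names_:
            m = self.axis_models_[name]
            fm = build_feature_matrix(
                table,
                AxisDefinition(axis_name=name, features=tuple(m.column_ids)),
            )
            raw = m.pls.predict(fm.X)
            scaled = (raw - m.treated_anchor) / (m.control_anchor - m.treated_anchor)
            if frame is None:
                frame = pd.DataFrame(
                    {"subject_id": fm.subject_ids, "arm": fm.arms}
                )
            frame[name] = scaled
        return ScoreSet(scores=frame, axis_names=list(self.axis_names_))

    def fit_transform(self, table: SampleTable, axes: Sequence[AxisDefinition]) -> ScoreSet:
        return self.fit(table, axes).scores_

    # -- serialisation ---------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        doc = {"schema_version": SCHEMA_VERSION, "provenance": self.provenance_, "axes": {}}
        for name in self.axis_names_:
            m = self.axis_models_[name]
            pls = m.pls
            doc["axes"][name] = {
                "features": [list(f) for f in m.column_ids],
                "treated_anchor": m.treated_anchor,
                "control_anchor": m.control_anchor,
                "refit_anchor_offset": list(m.refit_anchor_offset),
                "pls": {
                    "x_mean": pls.x_mean_.tolist(),
                    "x_std": pls.x_std_.tolist(),
                    "coef": pls.coef_.tolist(),
                    "y_mean": pls.y_mean_,
                    "n_components": pls.n_components_,
                },
            }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "HealthSpace":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported model schema version {doc.get('schema_version')}"
            )
        settings = doc["provenance"]["settings"]
        model = cls(
            outer_folds=settings["outer_folds"],
            inner_folds=settings["inner_folds"],
            max_components=settings["max_components"],
            anchor_source=settings["anchor_source"],
            score_source=settings["score_source"],
            random_state=settings["random_state"],
        )
        model.axis_models_ = {}
        model.axis_names_ = list(doc["axes"])
        for name, entry in doc["axes"].items():
            pls = PLSDA.__new__(PLSDA)
            pls.n_components = entry["pls"]["n_components"]
            pls.scale = True
            pls.x_mean_ = np.asarray(entry["pls"]["x_mean"], dtype=float)
            pls.x_std_ = np.asarray(entry["pls"]["x_std"], dtype=float)
            pls.coef_ = np.asarray(entry["pls"]["coef"], dtype=float)
            pls.y_mean_ = float(entry["pls"]["y_mean"])
            pls.n_components_ = int(entry["pls"]["n_components"])
            features = tuple((p, k) for p, k in entry["features"])
            model.axis_models_[name] = AxisModel(
                definition=AxisDefinition(axis_name=name, features=features),
                pls=pls,
                treated_anchor=float(entry["treated_anchor"]),
                control_anchor=float(entry["control_anchor"]),
                column_ids=list(features),
                dcv=None,
                refit_anchor_offset=tuple(entry.get("refit_anchor_offset", (0.0, 0.0))),
            )
        model.provenance_ = doc["provenance"]
        return model


def build_health_space(
    table: SampleTable,
    axes: Sequence[AxisDefinition],
    outer_folds: int = 7,
    inner_folds: int = 5,
    max_components: int = 5,
    anchor_source: str = "oof",
    score_source: str = "oof",
    seed: int | None = None,
) -> tuple[HealthSpace, ScoreSet]:
    """Functional wrapper: fit a :class:`HealthSpace` and return its scores."""
    model = HealthSpace(
        outer_folds=outer_folds,
        inner_folds=inner_folds,
        max_components=max_components,
        anchor_source=anchor_source,
        score_source=score_source,
        random_state=seed,
    ).fit(table, axes)
    return model, model.scores_


def project(model: HealthSpace, table: SampleTable) -> ScoreSet:
    """Score new subjects in an existing space (stored constants only)."""
    return model.transform(table)
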