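"""Core typed containers for cross-over study data and process-axis definitions.

A :class:`SampleTable` holds a wide matrix of plasma parameter values
(samples x parameters) together with per-sample metadata: which subject the
sample came from, which study arm (``treated`` receives the active
intervention, ``control`` the placebo) and, optionally, the timepoint within
that arm's period.  In a cross-over design every subject contributes samples
under both arms, which is what makes within-subject contrasts possible.

An :class:`AxisDefinition` names one biological process (e.g. oxidation,
inflammation, metabolism) and lists the parameters that parameterize it.
Each parameter enters as one or two *features*: its value at the start of
the period (``baseline``) and/or its arithmetic mean over all timepoints of
the period (``mean_over_time``).

:func:`build_feature_matrix` turns a table plus an axis into the
(subject, arm)-indexed design matrix consumed by the PLS-DA stage, with the
class vector coded treated = 0, control = 1 — the same orientation used for
the health-space anchors, so PLS-DA score signs are canonical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import (
    ConfigurationError,
    MissingDataError,
    MissingParameterError,
)

ARM_TREATED = "treated"
ARM_CONTROL = "control"
ARMS = (ARM_TREATED, ARM_CONTROL)
#: class code per arm: treated = 0 anchors the "healthy" origin, control = 1
ARM_CODE = {ARM_TREATED: 0, ARM_CONTROL: 1}

META_COLUMNS = ("subject_id", "arm", "timepoint")

FEATURE_KINDS = ("baseline", "mean_over_time")

#: a parameter column with more than this fraction of missing entries is
#: dropped from feature construction (with a warning) instead of imputed
MAX_MISSING_FRACTION = 0.2


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate_sample_table`."""

    rule: str
    message: str
    rows: tuple = ()

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.rule}] {self.message}"


class SampleTable:
    """Wide sample x parameter value matrix with per-sample metadata.

    Parameters
    ----------
    values : pandas.DataFrame
        Numeric matrix, one row per sample, one column per parameter.
    meta : pandas.DataFrame
        Per-row metadata with columns ``subject_id``, ``arm`` and
        (optionally) ``timepoint``; must have the same length as ``values``.
    """

    def __init__(self, values: pd.DataFrame, meta: pd.DataFrame):
        values = values.reset_index(drop=True)
        meta = meta.reset_index(drop=True)
        if len(values) != len(meta):
            raise ConfigurationError(
                f"values has {len(values)} rows but meta has {len(meta)}"
            )
        missing = [c for c in ("subject_id", "arm") if c not in meta.columns]
        if missing:
            raise ConfigurationError(f"meta lacks required columns: {missing}")
        if "timepoint" not in meta.columns:
            meta = meta.assign(timepoint="t0")
        meta = meta.astype({"subject_id": str, "arm": str, "timepoint": str})
        self.values = values.apply(pd.to_numeric, errors="coerce")
        self.meta = meta[list(META_COLUMNS)]

    # -- basic accessors -------------------------------------------------
    @property
    def parameter_ids(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def subject_ids(self) -> list[str]:
        return sorted(self.meta["subject_id"].unique())

    @property
    def n_samples(self) -> int:
        return len(self.values)

    def timepoint_order(self) -> list[str]:
        """Ordered timepoint labels (lexicographic; ``t0`` < ``t1`` < ...)."""
        return sorted(self.meta["timepoint"].unique())

    def complete_subjects(self) -> list[str]:
        """Subjects with samples under both arms."""
        arms_per_subject = self.meta.groupby("subject_id")["arm"].agg(set)
        return sorted(
            s for s, arms in arms_per_subject.items() if set(ARMS) <= arms
        )

    # -- I/O -------------------------------------------------------------
    @classmethod
    def from_csv(cls, path: str | Path, sep: str = ",") -> "SampleTable":
        """Read a wide table whose first columns are the metadata columns."""
        df = pd.read_csv(path, sep=sep, na_values=["NA", ""])
        meta_cols = [c for c in META_COLUMNS if c in df.columns]
        if "subject_id" not in meta_cols or "arm" not in meta_cols:
            raise ConfigurationError(
                f"{path}: expected metadata columns subject_id, arm"
                " (and optionally timepoint) before the parameter columns"
            )
        param_cols = [c for c in df.columns if c not in META_COLUMNS]
        return cls(df[param_cols], df[meta_cols])

    def to_csv(self, path: str | Path, sep: str = ",") -> None:
        out = pd.concat([self.meta, self.values], axis=1)
        out.to_csv(path, sep=sep, index=False, na_rep="NA")

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"SampleTable({self.n_samples} samples, "
            f"{len(self.parameter_ids)} parameters, "
            f"{len(self.subject_ids)} subjects)"
        )


@dataclass(frozen=True)
class AxisDefinition:
    """One health-space axis: a named process and its feature list.

    ``features`` is a sequence of ``(parameter_id, feature_kind)`` pairs with
    ``feature_kind`` in :data:`FEATURE_KINDS`.  A parameter may appear on
    several axes — biological processes overlap — but a given
    (parameter, kind) pair may appear only once within an axis.
    """

    axis_name: str
    features: tuple = ()

    def __post_init__(self):
        feats = tuple((str(p), str(k)) for p, k in self.features)
        for _, kind in feats:
            if kind not in FEATURE_KINDS:
                raise ConfigurationError(
                    f"axis {self.axis_name!r}: unknown feature kind {kind!r}"
                )
        if len(set(feats)) != len(feats):
            dupes = sorted(
                {f for f in feats if feats.count(f) > 1}
            )
            raise ConfigurationError(
                f"axis {self.axis_name!r}: duplicate features {dupes}"
            )
        object.__setattr__(self, "features", feats)

    @property
    def parameter_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for p, _ in self.features:
            seen.setdefault(p, None)
        return list(seen)

    def __len__(self) -> int:
        return len(self.features)


def load_axis_definitions(path: str | Path) -> list[AxisDefinition]:
    """Load axes from a YAML/JSON document.

    Schema::

        axes:
          - name: oxidation
            features:
              - {parameter: GSH, kind: baseline}
              - {parameter: GSSG, kind: both}   # expands to both kinds

    ``kind`` defaults to ``mean_over_time``; ``both`` expands to a
    ``baseline`` plus a ``mean_over_time`` feature.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return axis_definitions_from_dict(doc)


def axis_definitions_from_dict(doc: dict) -> list[AxisDefinition]:
    if not isinstance(doc, dict) or "axes" not in doc:
        raise ConfigurationError("axis config must be a mapping with an 'axes' list")
    axes = []
    for entry in doc["axes"]:
        name = entry.get("name")
        if not name:
            raise ConfigurationError("each axis needs a 'name'")
        features = []
        for feat in entry.get("features", []):
            if isinstance(feat, str):
                feat = {"parameter": feat}
            param = feat.get("parameter")
            if not param:
                raise ConfigurationError(
                    f"axis {name!r}: feature entries need a 'parameter'"
                )
            kind = feat.get("kind", "mean_over_time")
            if kind == "both":
                features.append((param, "baseline"))
                features.append((param, "mean_over_time"))
            else:
                features.append((param, kind))
        axes.append(AxisDefinition(axis_name=str(name), features=tuple(features)))
    return axes


def axis_definitions_to_dict(axes: Sequence[AxisDefinition]) -> dict:
    return {
        "axes": [
            {
                "name": ax.axis_name,
                "features": [
                    {"parameter": p, "kind": k} for p, k in ax.features
                ],
            }
            for ax in axes
        ]
    }


def save_axis_definitions(axes: Sequence[AxisDefinition], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(axis_definitions_to_dict(axes), fh, sort_keys=False)


@dataclass
class FeatureMatrix:
    """(subject, arm)-level design matrix for one axis.

    Rows are ordered arm-major — all treated rows first, then all control
    rows, subjects sorted within each arm — so downstream fold assignment and
    score export are deterministic.  ``y`` codes treated = 0, control = 1.
    """

    X: np.ndarray
    y: np.ndarray
    subject_ids: list[str]
    arms: list[str]
    column_ids: list[tuple]
    dropped_features: list[tuple] = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return len(set(self.subject_ids))


def validate_sample_table(table: SampleTable, crossover: bool = True) -> list[Violation]:
    """Check :class:`SampleTable` invariants; return a list of violations.

    An empty list means the table is valid.  Rules checked:

    * parameter names unique,
    * at most one sample per (subject, arm, timepoint),
    * in cross-over mode, every subject has samples under both arms.
    """
    violations: list[Violation] = []

    params = table.parameter_ids
    dupes = sorted({p for p in params if params.count(p) > 1})
    for p in dupes:
        violations.append(
            Violation("unique-parameters", f"duplicate parameter_id {p!r}")
        )

    bad_arms = sorted(set(table.meta["arm"]) - set(ARMS))
    if bad_arms:
        violations.append(
            Violation("arm-labels", f"unknown arm labels {bad_arms}; expected {ARMS}")
        )

    key = ["subject_id", "arm", "timepoint"]
    counts = table.meta.groupby(key).size()
    for idx, n in counts[counts > 1].items():
        violations.append(
            Violation(
                "one-sample-per-cell",
                f"subject {idx[0]!r} has {n} samples for arm={idx[1]!r},"
                f" timepoint={idx[2]!r}",
                rows=tuple(
                    table.meta.index[
                        (table.meta[key] == pd.Series(idx, index=key)).all(axis=1)
                    ]
                ),
            )
        )

    if crossover:
        arms_per_subject = table.meta.groupby("subject_id")["arm"].agg(set)
        for subject, arms in arms_per_subject.items():
            missing = sorted(set(ARMS) - arms)
            if missing:
                violations.append(
                    Violation(
                        "crossover-complete",
                        f"subject {subject!r} missing arm(s) {missing}",
                    )
                )
    return violations


def _prepare_columns(table: SampleTable, parameters: Iterable[str]):
    """Missing-value policy for feature construction.

    Columns with more than :data:`MAX_MISSING_FRACTION` missing entries are
    dropped (warning); remaining missing entries are imputed with the column
    mean computed within the same arm.
    """
    usable: dict[str, pd.Series] = {}
    dropped: list[str] = []
    for p in parameters:
        col = table.values[p]
        frac = float(col.isna().mean())
        if frac > MAX_MISSING_FRACTION:
            dropped.append(p)
            continue
        if frac > 0:
            filled = col.copy()
            for arm in ARMS:
                mask = table.meta["arm"] == arm
                arm_mean = col[mask].mean()
                filled[mask] = filled[mask].fillna(arm_mean)
            if filled.isna().any():
                raise MissingDataError(
                    f"parameter {p!r}: no values available to impute from"
                )
            col = filled
        usable[p] = col
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} parameter(s) with >"
            f"{MAX_MISSING_FRACTION:.0%} missing values: {dropped}",
            stacklevel=3,
        )
    return usable, dropped


def build_feature_matrix(table: SampleTable, axis: AxisDefinition) -> FeatureMatrix:
    """Build the (subject, arm) x feature design matrix for one axis.

    ``baseline`` features take the subject's value at the earliest timepoint
    of that arm's period (each cross-over period has its own baseline);
    ``mean_over_time`` features average over all of that subject-arm's
    timepoints.  Only subjects with both arms are retained.
    """
    unknown = [p for p in axis.parameter_ids if p not in table.values.columns]
    if unknown:
        raise MissingParameterError(unknown)

    usable, dropped_params = _prepare_columns(table, axis.parameter_ids)
    features = [(p, k) for p, k in axis.features if p in usable]
    dropped_features = [(p, k) for p, k in axis.features if p not in usable]
    if not features:
        raise MissingDataError(
            f"axis {axis.axis_name!r}: no usable features after missing-value filtering"
        )

    subjects = table.complete_subjects()
    incomplete = sorted(set(table.subject_ids) - set(subjects))
    if incomplete:
        warnings.warn(
            f"dropping {len(incomplete)} subject(s) without both arms: {incomplete}",
            stacklevel=2,
        )
    if not subjects:
        raise MissingDataError("no subject has samples under both arms")

    meta = table.meta
    rows = []
    subject_col: list[str] = []
    arm_col: list[str] = []
    # arm-major ordering: treated block first, subjects sorted within arm
    for arm in ARMS:
        for subject in subjects:
            mask = (meta["subject_id"] == subject) & (meta["arm"] == arm)
            sub = meta[mask].sort_values("timepoint")
            if sub.empty:  # pragma: no cover - excluded by complete_subjects
                raise MissingDataError(f"subject {subject!r} has no {arm} samples")
            idx = sub.index
            first_idx = idx[0]
            row = []
            for p, kind in features:
                col = usable[p]
                if kind == "baseline":
                    row.append(float(col.loc[first_idx]))
                else:
                    row.append(float(col.loc[idx].mean()))
            rows.append(row)
            subject_col.append(subject)
            arm_col.append(arm)

    X = np.asarray(rows, dtype=float)
    y = np.asarray([ARM_CODE[a] for a in arm_col], dtype=float)
    return FeatureMatrix(
        X=X,
        y=y,
        subject_ids=subject_col,
        arms=arm_col,
        column_ids=list(features),
        dropped_features=dropped_features,
    )
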