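"""Univariate screening of treatment-responsive parameters.

Axes of a health space are built from parameters that changed significantly
under treatment.  When no curated parameter lists are available, this module
provides the default screen: a two-sided paired t-test per parameter on
subject-matched arm means, Benjamini-Hochberg FDR correction across the
whole parameter family, and a significance flag at the configured alpha.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import ARM_CONTROL, ARM_TREATED, AxisDefinition, SampleTable
from .exceptions import InsufficientDataError

DEFAULT_ALPHA = 0.05


def paired_test(treated: np.ndarray, control: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t-test on subject-matched values.

    Values must be aligned by subject.  Requires at least 3 complete pairs.
    Zero variance of the differences makes the statistic undefined; by
    convention the test then reports p = 1 with a warning (no evidence of a
    within-subject effect beyond a constant shift is attributable to chance
    under the model, and a constant nonzero shift with zero variance does
    not occur in continuous data).
    """
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if treated.shape != control.shape:
        raise ValueError("treated and control must be subject-aligned")
    mask = ~(np.isnan(treated) | np.isnan(control))
    diffs = treated[mask] - control[mask]
    if diffs.size < 3:
        raise InsufficientDataError(
            f"paired test needs >= 3 complete pairs, got {diffs.size}"
        )
    if np.std(diffs, ddof=1) == 0.0:
        warnings.warn("zero variance of paired differences; p set to 1")
        return float("nan"), 1.0
    stat, p = stats.ttest_rel(treated[mask], control[mask])
    return float(stat), float(p)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, in [0, 1])."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def screen_parameters(
    table: SampleTable,
    alpha: float = DEFAULT_ALPHA,
    parameters: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Screen every parameter for a paired treatment effect.

    Per parameter, each subject contributes one treated and one control
    value (the mean over that arm's timepoints); a paired t-test is applied
    and BH correction is carried out across all tested parameters as a
    single family.  Returns a DataFrame with columns ``parameter_id``,
    ``mean_difference`` (treated - control), ``p_value``, ``q_value`` and
    ``significant``.  Parameters that cannot be tested (too few pairs) are
    skipped with a warning.
    """
    params = list(parameters) if parameters is not None else table.parameter_ids
    subjects = table.complete_subjects()
    if len(subjects) < 3:
        raise InsufficientDataError(
            f"screening needs >= 3 complete subjects, got {len(subjects)}"
        )

    meta = table.meta
    arm_means = {}
    for arm in (ARM_TREATED, ARM_CONTROL):
        mask = meta["arm"] == arm
        arm_means[arm] = (
            table.values[mask]
            .groupby(meta.loc[mask, "subject_id"])
            .mean()
            .reindex(subjects)
        )

    records = []
    for p in params:
        treated = arm_means[ARM_TREATED][p].to_numpy()
        control = arm_means[ARM_CONTROL][p].to_numpy()
        try:
            _, pval = paired_test(treated, control)
        except InsufficientDataError as exc:
            warnings.warn(f"parameter {p!r} skipped: {exc}")
            continue
        records.append(
            {
                "parameter_id": p,
                "mean_difference": float(np.nanmean(treated - control)),
                "p_value": pval,
            }
        )

    result = pd.DataFrame.from_records(
        records, columns=["parameter_id", "mean_difference", "p_value"]
    )
    if len(result):
        result["q_value"] = bh_adjust(result["p_value"])
    else:
        result["q_value"] = pd.Series(dtype=float)
    result["significant"] = result["q_value"] <= alpha
    return result


def axis_from_screen(
    screen_result: pd.DataFrame,
    axis_name: str,
    parameters: Sequence[str] | None = None,
    kind: str = "mean_over_time",
) -> AxisDefinition:
    """Build an axis from the significant parameters of a screen.

    ``parameters`` optionally restricts the axis to a process-specific
    subset (process membership is domain knowledge the screen itself does
    not have).  ``kind`` may be ``baseline``, ``mean_over_time`` or
    ``both``.
    """
    sig = screen_result.loc[screen_result["significant"], "parameter_id"]
    selected = [p for p in sig if parameters is None or p in set(parameters)]
    if kind == "both":
        feats = [(p, k) for p in selected for k in ("baseline", "mean_over_time")]
    else:
        feats = [(p, kind) for p in selected]
    return AxisDefinition(axis_name=axis_name, features=tuple(feats))


def save_screen_result(result: pd.DataFrame, path: str | Path) -> None:
    result.to_csv(path, sep="\t", index=False)
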