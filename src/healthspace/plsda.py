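"""Two-class PLS-DA with autoscaling and double (nested) cross-validation.

Each health-space axis is parameterized by a partial least squares
discriminant analysis: a PLS1 regression of the binary arm code
(treated = 0, control = 1) on the autoscaled axis features.  A sample's
*prediction score* — its predicted class value — is the coordinate plotted
on the axis.

Model complexity (the number of latent variables) is chosen by double
cross-validation: an outer loop over subject folds produces out-of-fold
prediction scores from models that never saw the held-out subject, while an
inner loop within each outer-training set selects the component count.
Both arms of a subject always travel together between folds, and the
autoscaling constants are re-estimated inside every training partition, so
no information about a held-out subject leaks into the model that scores it.

The NIPALS PLS1 fit is implemented here directly; with as many components
as the rank of the (centred) design it reproduces the ordinary
least-squares solution, which the test suite uses as an oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import InsufficientDataError

#: components whose score variance falls below this are treated as exhausted
RANK_TOL = 1e-12


def autoscale(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-column standardization to mean 0, unit sample sd (ddof = 1).

    Returns ``(scaled, centers, scales, constant_flags)``.  Zero-variance
    columns are centred but divided by 1, and flagged rather than failed —
    a constant feature carries no class information but must not poison the
    rest of the axis.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("autoscale needs a 2-D matrix with >= 2 rows")
    centers = X.mean(axis=0)
    scales = X.std(axis=0, ddof=1)
    constant = scales == 0.0
    scales = np.where(constant, 1.0, scales)
    return (X - centers) / scales, centers, scales, constant


class PLSDA(BaseEstimator, RegressorMixin):
    """NIPALS PLS1 regression against a binary class code.

    Parameters
    ----------
    n_components : int
        Number of latent variables to extract.  Capped (with a warning) at
        the effective rank of the centred training matrix.
    scale : bool
        Autoscale features on ``fit`` (and apply the same constants in
        ``predict``).  The double-CV driver leaves this on so every
        training partition owns its scaling constants.

    Attributes (after ``fit``)
    --------------------------
    x_mean_, x_std_ : per-feature autoscaling constants
    x_weights_      : W, shape (p, A)
    x_loadings_     : P, shape (p, A)
    y_loadings_     : q, shape (A,)
    x_scores_       : training score vectors T, shape (n, A), mutually orthogonal
    coef_           : regression vector on the autoscaled scale, shape (p,)
    intercept_      : scalar so that ``predict(x) = intercept_ + x_scaled @ coef_``
    n_components_   : effective number of extracted components
    """

    def __init__(self, n_components: int = 2, scale: bool = True):
        self.n_components = n_components
        self.scale = scale

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PLSDA":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        n, p = X.shape
        if self.scale:
            Xs, self.x_mean_, self.x_std_, self.constant_features_ = autoscale(X)
        else:
            Xs = X - X.mean(axis=0)
            self.x_mean_ = X.mean(axis=0)
            self.x_std_ = np.ones(p)
            self.constant_features_ = np.zeros(p, dtype=bool)
        self.y_mean_ = y.mean()

        max_rank = min(n - 1, p)
        A = int(self.n_components)
        if A > max_rank:
            warnings.warn(
                f"n_components={A} exceeds max rank {max_rank}; capped"
            )
            A = max_rank
        if A < 1:
            raise ValueError("n_components must be >= 1")

        Xr = Xs.copy()
        yr = y - self.y_mean_
        W, P, Q, T = [], [], [], []
        for _ in range(A):
            w = Xr.T @ yr
            norm_w = np.linalg.norm(w)
            if norm_w < RANK_TOL:  # no covariance left (e.g. constant y)
                break
            w = w / norm_w
            t = Xr @ w
            tt = float(t @ t)
            if tt < RANK_TOL:  # rank exhausted
                break
            pvec = Xr.T @ t / tt
            q = float(yr @ t / tt)
            Xr = Xr - np.outer(t, pvec)
            yr = yr - q * t
            W.append(w)
            P.append(pvec)
            Q.append(q)
            T.append(t)

        self.n_components_ = len(W)
        if self.n_components_:
            self.x_weights_ = np.column_stack(W)
            self.x_loadings_ = np.column_stack(P)
            self.y_loadings_ = np.asarray(Q)
            self.x_scores_ = np.column_stack(T)
            self.coef_ = self._coef(self.n_components_)
        else:  # degenerate: constant y or zero-rank X
            self.x_weights_ = np.zeros((p, 0))
            self.x_loadings_ = np.zeros((p, 0))
            self.y_loadings_ = np.zeros(0)
            self.x_scores_ = np.zeros((n, 0))
            self.coef_ = np.zeros(p)
        self.intercept_ = float(self.y_mean_ - self.x_mean_ / self.x_std_ @ self.coef_)
        return self

    def _coef(self, a: int) -> np.ndarray:
        """Regression vector using the first ``a`` components: B = W (P'W)^-1 q."""
        W = self.x_weights_[:, :a]
        P = self.x_loadings_[:, :a]
        q = self.y_loadings_[:a]
        return W @ np.linalg.solve(P.T @ W, q)

    def _scale_X(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.x_mean_) / self.x_std_

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Continuous prediction score (predicted class value)."""
        return self.y_mean_ + self._scale_X(X) @ self.coef_

    def predict_components(self, X: np.ndarray) -> np.ndarray:
        """Prediction scores for every truncation 1..n_components_.

        Returns shape ``(n_samples, n_components_)``; column ``a-1`` is the
        prediction of the model truncated to its first ``a`` components.
        Used by the inner CV to score all candidate complexities from a
        single fit.
        """
        Xs = self._scale_X(X)
        if self.n_components_ == 0:
            return np.full((Xs.shape[0], 1), self.y_mean_)
        out = np.empty((Xs.shape[0], self.n_components_))
        for a in range(1, self.n_components_ + 1):
            out[:, a - 1] = self.y_mean_ + Xs @ self._coef(a)
        return out

    def predict_class(self, X: np.ndarray) -> np.ndarray:
        """Hard class assignment: score >= 0.5 -> class 1 (control)."""
        return (self.predict(X) >= 0.5).astype(int)


def fit_pls(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSDA:
    """Fit PLS1 on an already-autoscaled matrix (centering only)."""
    return PLSDA(n_components=n_components, scale=False).fit(X, y)


@dataclass
class FoldRecord:
    """Per-outer-fold diagnostics, also used by leakage tests."""

    fold: int
    test_subjects: list
    train_subjects: list
    chosen_components: int
    x_mean: np.ndarray
    x_std: np.ndarray


@dataclass
class DcvResult:
    """Outcome of double cross-validation for one axis.

    ``oof_scores[i]`` is sample ``i``'s prediction score from the outer
    model whose training folds excluded that sample's subject.
    """

    oof_scores: np.ndarray
    chosen_components: list
    misclassification_rate: float
    fold_of_sample: np.ndarray
    folds: list = field(default_factory=list)


def _partition(items: list, n_folds: int, rng: np.random.Generator) -> list:
    order = list(np.asarray(items, dtype=object)[rng.permutation(len(items))])
    return [list(chunk) for chunk in np.array_split(np.asarray(order, dtype=object), n_folds)]


def _select_components(
    X: np.ndarray,
    y: np.ndarray,
    subject_rows: dict,
    subjects: list,
    inner_folds: int,
    max_components: int,
    rng: np.random.Generator,
    criterion: str,
) -> int:
    """Inner CV over subjects: component count with minimal validation loss.

    Ties are broken toward fewer components (parsimony).
    """
    n_folds = min(inner_folds, len(subjects))
    parts = _partition(subjects, n_folds, rng)
    losses = np.zeros(max_components)
    counts = np.zeros(max_components)
    for part in parts:
        val = set(part)
        train_rows = np.concatenate([subject_rows[s] for s in subjects if s not in val])
        val_rows = np.concatenate([subject_rows[s] for s in part])
        y_train = y[train_rows]
        if len(np.unique(y_train)) < 2 or len(train_rows) < 3:
            continue
        a_max = min(max_components, len(train_rows) - 1, X.shape[1])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = PLSDA(n_components=a_max, scale=True).fit(X[train_rows], y_train)
        preds = model.predict_components(X[val_rows])  # (n_val, a_eff)
        a_eff = preds.shape[1]
        y_val = y[val_rows]
        for a in range(max_components):
            col = preds[:, min(a, a_eff - 1)]
            if criterion == "rmse":
                losses[a] += float(np.sum((col - y_val) ** 2))
            else:
                losses[a] += float(np.sum((col >= 0.5).astype(int) != y_val))
            counts[a] += len(val_rows)
    if not counts.any():
        return 1
    # argmin with ties to the smallest component count
    return int(np.argmin(losses / np.maximum(counts, 1))) + 1


def double_cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    subject_ids: Sequence,
    outer_folds: int = 7,
    inner_folds: int = 5,
    max_components: int = 5,
    seed: int | None = None,
    criterion: str = "misclassification",
) -> DcvResult:
    """Nested subject-grouped CV producing out-of-fold prediction scores.

    The outer loop partitions *subjects* (both arms of a subject always land
    in the same fold); the inner loop selects the number of latent
    variables by minimum inner-CV loss.  Autoscaling constants are computed
    on each training partition only.  Deterministic given the seed.
    """
    dcv = DoubleCV(
        outer_folds=outer_folds,
        inner_folds=inner_folds,
        max_components=max_components,
        criterion=criterion,
        random_state=seed,
    ).fit(X, y, groups=subject_ids)
    return dcv.result_


class DoubleCV(BaseEstimator):
    """Estimator wrapper around :func:`double_cross_validate`.

    After ``fit(X, y, groups)`` exposes ``oof_scores_``,
    ``chosen_components_``, ``misclassification_rate_`` and a full
    :class:`DcvResult` under ``result_``.
    """

    def __init__(
        self,
        outer_folds: int = 7,
        inner_folds: int = 5,
        max_components: int = 5,
        criterion: str = "misclassification",
        random_state: int | None = None,
    ):
        self.outer_folds = outer_folds
        self.inner_folds = inner_folds
        self.max_components = max_components
        self.criterion = criterion
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray, groups: Sequence) -> "DoubleCV":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        groups = np.asarray([str(g) for g in groups], dtype=object)
        if not (len(X) == len(y) == len(groups)):
            raise ValueError("X, y and groups must have equal length")
        if len(np.unique(y)) != 2:
            raise ValueError("exactly two classes required")

        subjects = sorted(set(groups))
        if len(subjects) < self.outer_folds:
            raise InsufficientDataError(
                f"double CV needs >= {self.outer_folds} subjects "
                f"(outer_folds), got {len(subjects)}"
            )
        subject_rows = {s: np.flatnonzero(groups == s) for s in subjects}
        rng = np.random.default_rng(self.random_state)

        outer_parts = _partition(subjects, self.outer_folds, rng)
        oof = np.full(len(y), np.nan)
        fold_of_sample = np.full(len(y), -1, dtype=int)
        chosen: list[int] = []
        folds: list[FoldRecord] = []
        for k, part in enumerate(outer_parts):
            held = set(part)
            train_subjects = [s for s in subjects if s not in held]
            train_rows = np.concatenate([subject_rows[s] for s in train_subjects])
            test_rows = np.concatenate([subject_rows[s] for s in part])
            if len(np.unique(y[train_rows])) < 2:
                raise InsufficientDataError(
                    f"outer fold {k}: training partition lacks both classes"
                )
            a = _select_components(
                X,
                y,
                subject_rows,
                train_subjects,
                self.inner_folds,
                min(self.max_components, len(train_rows) - 1, X.shape[1]),
                rng,
                self.criterion,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = PLSDA(n_components=a, scale=True).fit(X[train_rows], y[train_rows])
            oof[test_rows] = model.predict(X[test_rows])
            fold_of_sample[test_rows] = k
            chosen.append(model.n_components_ if model.n_components_ else a)
            folds.append(
                FoldRecord(
                    fold=k,
                    test_subjects=list(part),
                    train_subjects=train_subjects,
                    chosen_components=chosen[-1],
                    x_mean=model.x_mean_,
                    x_std=model.x_std_,
                )
            )

        miscls = float(np.mean((oof >= 0.5).astype(int) != y))
        self.result_ = DcvResult(
            oof_scores=oof,
            chosen_components=chosen,
            misclassification_rate=miscls,
            fold_of_sample=fold_of_sample,
            folds=folds,
        )
        self.oof_scores_ = oof
        self.chosen_components_ = chosen
        self.misclassification_rate_ = miscls
        return self
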