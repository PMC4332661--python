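"""Sparse linear classification of subset feature vectors.

Two evaluation protocols:

* Experiment 1 — the pooled feature matrix is randomly split into train
  and test rows; the same subjects may contribute to both sides.
* Experiment 2 — disjoint subject pools are drawn per cohort first and
  train/test rows are generated only from their own pool, so no subject
  contributes to feature vectors on both sides of the split.

The classifier is an L1-penalized linear decision function (logistic loss
by default, hinge loss optionally) on standardized features, with the
penalty constant chosen by stratified cross-validation maximizing mean
validation AUC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from cortsep.corrfeat import FeatureMatrix, FeatureSet, build_feature_matrix
from cortsep.io_atlas import CASE, CONTROL, ThicknessTable

logger = logging.getLogger(__name__)

DEFAULT_PENALTY_GRID = np.logspace(-3, 2, 20)


@dataclass
class SplitPlan:
    """Row partition of a feature matrix, plus subject pools for experiment 2."""

    train_rows: tuple[int, ...]
    test_rows: tuple[int, ...]
    experiment: int
    seed: int
    train_subject_pool: frozenset[str] | None = None
    test_subject_pool: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if set(self.train_rows) & set(self.test_rows):
            raise ValueError("train and test rows overlap")
        if self.experiment not in (1, 2):
            raise ValueError("experiment must be 1 or 2")
        if self.experiment == 2:
            if self.train_subject_pool is None or self.test_subject_pool is None:
                raise ValueError("experiment 2 requires subject pools")
            if self.train_subject_pool & self.test_subject_pool:
                raise ValueError("train and test subject pools overlap")


def split_experiment1(
    matrix: FeatureMatrix, n_train: int = 700, n_test: int = 300, seed: int = 0
) -> SplitPlan:
    """Random stratified row partition with overlapping subjects allowed."""
    if n_train <= 0 or n_test <= 0:
        raise ValueError("n_train and n_test must be positive")
    if n_train + n_test != matrix.n_rows:
        raise ValueError(
            f"n_train + n_test = {n_train + n_test} does not match {matrix.n_rows} rows"
        )
    rng = np.random.default_rng(seed)
    labels = matrix.label_array()
    train_frac = n_train / matrix.n_rows
    train_idx: list[int] = []
    leftover: list[tuple[float, int]] = []
    for lab in sorted(set(matrix.labels)):
        rows = np.flatnonzero(labels == lab)
        rows = rng.permutation(rows)
        want = train_frac * len(rows)
        take = int(np.floor(want))
        train_idx.extend(int(r) for r in rows[:take])
        leftover.append((want - take, int(rows[take]) if take < len(rows) else -1))
    # distribute rounding remainder, largest fractional part first
    deficit = n_train - len(train_idx)
    for _, row in sorted(leftover, reverse=True)[:deficit]:
        train_idx.append(row)
    train_set = set(train_idx)
    test_idx = [i for i in range(matrix.n_rows) if i not in train_set]
    return SplitPlan(tuple(sorted(train_idx)), tuple(test_idx), experiment=1, seed=seed)


def _allocate_rows(total: int) -> tuple[int, int]:
    """Split a row count evenly across cohorts, odd remainder to the case cohort."""
    control = total // 2
    return total - control, control


def split_experiment2(
    case_table: ThicknessTable,
    control_table: ThicknessTable,
    features: FeatureSet,
    n_train_case_subjects: int = 40,
    n_train_control_subjects: int = 24,
    n_train_rows: int = 700,
    n_test_rows: int = 300,
    g: int = 6,
    seed: int = 0,
) -> tuple[FeatureMatrix, FeatureMatrix, SplitPlan]:
    """Subject-disjoint train/test feature matrices.

    Per cohort, a random training pool is drawn (defaults 40 of the cases,
    24 of the controls); the remaining subjects form the test pool.  Train
    rows are generated only from training-pool subjects and test rows only
    from test-pool subjects.  The disjointness audit is a hard assertion.
    """
    pools: dict[str, tuple[list[str], list[str]]] = {}
    rng = np.random.default_rng(seed)
    for table, cohort, n_pool in (
        (case_table, CASE, n_train_case_subjects),
        (control_table, CONTROL, n_train_control_subjects),
    ):
        ids = list(table.subject_ids)
        if n_pool >= len(ids):
            raise ValueError(
                f"{cohort} training pool ({n_pool}) must leave test subjects "
                f"(cohort size {len(ids)})"
            )
        if n_pool < g or len(ids) - n_pool < g:
            raise ValueError(f"{cohort} pools must each hold at least g={g} subjects")
        chosen = rng.choice(len(ids), size=n_pool, replace=False)
        train_ids = [ids[c] for c in sorted(chosen)]
        test_ids = [s for s in ids if s not in set(train_ids)]
        pools[cohort] = (train_ids, test_ids)

    n_train_case, n_train_control = _allocate_rows(n_train_rows)
    n_test_case, n_test_control = _allocate_rows(n_test_rows)

    def build(which: int, n_case_rows: int, n_control_rows: int, sub_seed: int) -> FeatureMatrix:
        case_sub = case_table.subset(pools[CASE][which])
        control_sub = control_table.subset(pools[CONTROL][which])
        fm = build_feature_matrix(
            case_sub, control_sub, features, max(n_case_rows, n_control_rows), g, seed=sub_seed
        )
        labels = fm.label_array()
        keep = list(np.flatnonzero(labels == CASE)[:n_case_rows]) + list(
            np.flatnonzero(labels == CONTROL)[:n_control_rows]
        )
        return fm.rows(keep)

    ss = np.random.SeedSequence(seed).spawn(2)
    train_fm = build(0, n_train_case, n_train_control, ss[0].generate_state(1)[0])
    test_fm = build(1, n_test_case, n_test_control, ss[1].generate_state(1)[0])

    train_pool = frozenset(pools[CASE][0]) | frozenset(pools[CONTROL][0])
    test_pool = frozenset(pools[CASE][1]) | frozenset(pools[CONTROL][1])
    plan = SplitPlan(
        tuple(range(train_fm.n_rows)),
        tuple(range(train_fm.n_rows, train_fm.n_rows + test_fm.n_rows)),
        experiment=2,
        seed=seed,
        train_subject_pool=train_pool,
        test_subject_pool=test_pool,
    )
    audit_subject_disjoint(train_fm, test_fm, plan)
    return train_fm, test_fm, plan


def audit_subject_disjoint(
    train_fm: FeatureMatrix, test_fm: FeatureMatrix, plan: SplitPlan
) -> None:
    """Hard assertion that no subject crosses the experiment-2 split."""
    train_used = train_fm.subjects_used()
    test_used = test_fm.subjects_used()
    if train_used & test_used:
        raise AssertionError(f"subject leakage across split: {sorted(train_used & test_used)}")
    if plan.train_subject_pool is not None and not train_used <= plan.train_subject_pool:
        raise AssertionError("training rows use subjects outside the training pool")
    if plan.test_subject_pool is not None and not test_used <= plan.test_subject_pool:
        raise AssertionError("test rows use subjects outside the test pool")
    logger.info(
        "subject-disjointness audit passed: %d train / %d test subjects, no overlap",
        len(train_used),
        len(test_used),
    )


@dataclass
class SparseLinearModel:
    """L1-penalized linear decision function on standardized features."""

    weights: np.ndarray
    intercept: float
    penalty: float
    cv_folds: int
    center: np.ndarray
    scale: np.ndarray
    loss: str = "logistic"
    cv_scores: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("non-finite model weights")

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Linear scores; larger means more case-like."""
        Z = (np.asarray(X, dtype=float) - self.center) / self.scale
        return Z @ self.weights + self.intercept

    @property
    def n_active_features(self) -> int:
        return int(np.sum(self.weights != 0))


def _label_vector(labels: np.ndarray) -> np.ndarray:
    """case -> 1 (positive class), control -> 0."""
    return (np.asarray(labels) == CASE).astype(int)


def _make_estimator(loss: str, penalty: float, seed: int):
    if loss == "logistic":
        return LogisticRegression(
            penalty="l1", C=penalty, solver="liblinear", max_iter=2000, random_state=seed
        )
    if loss == "hinge":
        return LinearSVC(
            penalty="l1", loss="squared_hinge", dual=False, C=penalty, max_iter=5000
        )
    raise ValueError(f"unknown loss {loss!r}")


def fit_sparse_linear(
    X: np.ndarray,
    labels: np.ndarray,
    penalty_grid: np.ndarray | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    loss: str = "logistic",
) -> SparseLinearModel:
    """Fit the sparse linear classifier with CV-selected penalty.

    Features are standardized with training means/sds (constant features
    are dropped with a warning, i.e. given zero weight).  For each penalty
    in the grid, mean validation AUC over stratified folds is computed;
    the best penalty (ties to the smallest, sparsest value) is refit on
    the full training data.
    """
    X = np.asarray(X, dtype=float)
    y = _label_vector(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    if np.bincount(y).min() < 2:
        raise ValueError("need at least 2 rows per class")
    grid = DEFAULT_PENALTY_GRID if penalty_grid is None else np.asarray(penalty_grid, float)
    if grid.size == 0:
        raise ValueError("empty penalty grid")

    center = X.mean(axis=0)
    scale = X.std(axis=0)
    constant = scale == 0
    if constant.any():
        logger.warning("dropping %d constant feature(s)", int(constant.sum()))
        scale = np.where(constant, 1.0, scale)
    Z = (X - center) / scale
    Z[:, constant] = 0.0

    n_folds = min(cv_folds, int(np.bincount(y).min()))
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(cv.split(Z, y))
    mean_auc = np.empty(grid.size)
    for gi, penalty in enumerate(grid):
        aucs = []
        for tr, va in folds:
            est = _make_estimator(loss, penalty, seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(Z[tr], y[tr])
            scores = est.decision_function(Z[va])
            if np.allclose(scores, scores[0]):
                aucs.append(0.5)  # fully shrunk model: chance level
            else:
                aucs.append(roc_auc_score(y[va], scores))
        mean_auc[gi] = np.mean(aucs)
    best = int(np.flatnonzero(mean_auc == mean_auc.max())[0])
    penalty = float(grid[best])

    est = _make_estimator(loss, penalty, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(Z, y)
    weights = np.asarray(est.coef_).ravel().copy()
    weights[constant] = 0.0
    return SparseLinearModel(
        weights=weights,
        intercept=float(np.asarray(est.intercept_).ravel()[0]),
        penalty=penalty,
        cv_folds=n_folds,
        center=center,
        scale=scale,
        loss=loss,
        cv_scores={"penalty_grid": grid.tolist(), "mean_auc": mean_auc.tolist()},
    )


@dataclass
class ROCResult:
    """Operating curve with bootstrap confidence bounds."""

    fpr_grid: np.ndarray
    tpr_values: np.ndarray
    auc: float
    n_boot: int
    tpr_lower: np.ndarray
    tpr_upper: np.ndarray

    def __post_init__(self) -> None:
        self.fpr_grid = np.asarray(self.fpr_grid, float)
        self.tpr_values = np.asarray(self.tpr_values, float)
        if np.any(np.diff(self.tpr_values) < -1e-12):
            raise ValueError("ROC curve must be non-decreasing")
        if not (self.fpr_grid[0] == 0 and self.fpr_grid[-1] == 1):
            raise ValueError("FPR grid must span [0, 1]")
        if not 0 <= self.auc <= 1:
            raise ValueError("AUC outside [0, 1]")

    def tpr_at_fpr(self, q: float) -> float:
        """Linear interpolation of the TPR at false-positive rate q."""
        return float(np.interp(q, self.fpr_grid, self.tpr_values))


def _tpr_on_grid(y: np.ndarray, scores: np.ndarray, grid: np.ndarray) -> tuple[np.ndarray, float]:
    fpr, tpr, _ = roc_curve(y, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return np.interp(grid, fpr, tpr), auc


def roc_with_bootstrap(
    model: SparseLinearModel,
    test: FeatureMatrix,
    n_boot: int = 100,
    seed: int = 0,
    n_grid: int = 201,
) -> ROCResult:
    """ROC of the model on test rows with stratified bootstrap bounds."""
    y = _label_vector(test.label_array())
    if len(np.unique(y)) < 2:
        raise ValueError("test rows contain a single class")
    scores = model.decision_scores(test.values)
    grid = np.linspace(0, 1, n_grid)
    tpr, auc = _tpr_on_grid(y, scores, grid)

    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    boot = np.empty((n_boot, n_grid))
    for b in range(n_boot):
        idx = np.r_[rng.choice(pos, pos.size, replace=True), rng.choice(neg, neg.size, replace=True)]
        boot[b], _ = _tpr_on_grid(y[idx], scores[idx], grid)
    lower = np.minimum(np.percentile(boot, 2.5, axis=0), tpr)
    upper = np.maximum(np.percentile(boot, 97.5, axis=0), tpr)
    return ROCResult(grid, tpr, auc, n_boot, lower, upper)


def pca_embed(values: np.ndarray, dims: int = 2) -> np.ndarray:
    """Projection onto the top principal axes of the row covariance."""
    X = np.asarray(values, dtype=float)
    if dims > X.shape[1]:
        raise ValueError(f"dims={dims} exceeds feature count {X.shape[1]}")
    if dims > X.shape[0]:
        raise ValueError(f"dims={dims} exceeds row count {X.shape[0]}")
    Xc = X - X.mean(axis=0)
    # SVD with deterministic sign convention (largest-|loading| positive)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    for c in range(dims):
        lead = np.argmax(np.abs(Vt[c]))
        if Vt[c, lead] < 0:
            Vt[c] *= -1
            U[:, c] *= -1
    return U[:, :dims] * s[:dims]
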