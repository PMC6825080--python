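"""Machine-learning pipeline: standardization, balanced binary
sub-datasets, patient-disjoint splitting, RBF-SVM grid search and
recursive feature elimination.

The four-class feature table is turned into two balanced binary tasks:

* ``lesion_vs_normal``    — {malignant, benign} vs {fat, glandular};
* ``malignant_vs_benign`` — malignant vs benign.

Balancing removes whole patients from the majority side (seeded) until
image counts agree as closely as whole patients allow; no oversampling
is ever applied.  Train/validation splitting, cross-validation folds and
feature elimination are all grouped by patient so no patient contributes
to both sides of any fit/evaluate boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.feature_selection import RFE, RFECV
from sklearn.model_selection import StratifiedGroupKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ParameterError
from .features import FEATURE_NAMES

__all__ = [
    "TASKS",
    "DEFAULT_C_GRID",
    "DEFAULT_GAMMA_GRID",
    "StandardizedTable",
    "SubDataset",
    "SplitPlan",
    "SVMParams",
    "GridSearchResult",
    "RFECVResult",
    "standardize",
    "make_subsets",
    "split_train_validation",
    "grid_search_svm",
    "train_and_predict",
    "rfecv_select",
]

# positive label listed first
TASKS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "lesion_vs_normal": (("malignant", "benign"), ("fat", "glandular")),
    "malignant_vs_benign": (("malignant",), ("benign",)),
}

# logarithmic grids, endpoints 1e-5..1e-3 and 1..1000
DEFAULT_GAMMA_GRID: tuple[float, ...] = (1e-5, 1e-4, 1e-3)
DEFAULT_C_GRID: tuple[float, ...] = (1.0, 10.0, 100.0, 1000.0)


@dataclass(frozen=True)
class SVMParams:
    """Hyperparameters of the RBF-kernel support vector classifier."""

    C: float
    gamma: float

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ParameterError("C and gamma must be positive")


@dataclass
class StandardizedTable:
    """Feature matrix standardized with training-set mean/scale only."""

    X_train: np.ndarray
    X_other: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    constant_columns: tuple[str, ...]
    feature_names: tuple[str, ...]
    train_meta: pd.DataFrame
    other_meta: pd.DataFrame


@dataclass
class SubDataset:
    """One balanced binary task with image rows and a 0/1 label column ``y``."""

    task_id: str
    frame: pd.DataFrame
    balance_report: dict[str, dict[str, int]]


@dataclass(frozen=True)
class SplitPlan:
    """Patient-disjoint stratified train/validation partition."""

    train_image_ids: tuple[str, ...]
    val_image_ids: tuple[str, ...]
    train_patients: tuple[str, ...]
    val_patients: tuple[str, ...]
    val_fraction: float
    seed: int


@dataclass
class GridSearchResult:
    """CV-accuracy heatmap over the (C, gamma) grid and the winning cell."""

    c_grid: tuple[float, ...]
    gamma_grid: tuple[float, ...]
    heatmap: np.ndarray  # len(c_grid) x len(gamma_grid), mean CV accuracy
    fold_accuracies: np.ndarray  # c x gamma x folds
    best: SVMParams

    def heatmap_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.heatmap, index=list(self.c_grid), columns=list(self.gamma_grid))


@dataclass
class RFECVResult:
    """Feature ranking by elimination order and the optimal reduced set."""

    elimination_order: tuple[str, ...]  # first element eliminated first
    selected: tuple[str, ...]
    cv_accuracy_by_size: np.ndarray  # index k -> mean CV accuracy with k+1 features


def standardize(
    train_rows: pd.DataFrame,
    other_rows: pd.DataFrame | None = None,
    feature_names: tuple[str, ...] = FEATURE_NAMES,
) -> StandardizedTable:
    """Remove the mean and scale to unit variance, fitted on training rows only.

    A constant training column gets scale 1 (so it passes through
    centred but unscaled) and is flagged.
    """
    if len(train_rows) < 2:
        raise ParameterError("need at least 2 training rows")
    cols = list(feature_names)
    scaler = StandardScaler().fit(train_rows[cols].to_numpy(dtype=np.float64))
    constant = tuple(np.asarray(cols)[scaler.var_ == 0.0])
    meta_cols = [c for c in train_rows.columns if c not in cols]
    other = other_rows if other_rows is not None else train_rows.iloc[0:0]
    return StandardizedTable(
        X_train=scaler.transform(train_rows[cols].to_numpy(dtype=np.float64)),
        X_other=scaler.transform(other[cols].to_numpy(dtype=np.float64)) if len(other) else
        np.empty((0, len(cols))),
        center=scaler.mean_.copy(),
        scale=scaler.scale_.copy(),
        constant_columns=constant,
        feature_names=tuple(cols),
        train_meta=train_rows[meta_cols].reset_index(drop=True),
        other_meta=other[meta_cols].reset_index(drop=True),
    )


def _patient_image_counts(frame: pd.DataFrame) -> pd.Series:
    return frame.groupby("patient_id", sort=True).size()


def _balance_sides(frame: pd.DataFrame, rng: np.random.Generator) -> tuple[pd.DataFrame, dict]:
    """Down-sample the majority side patient-by-patient until image counts
    balance as closely as whole patients allow."""
    report: dict[str, dict[str, int]] = {"before": {}, "after": {}}
    for side in (0, 1):
        report["before"][str(side)] = int((frame["y"] == side).sum())
    removed: set[str] = set()
    while True:
        counts = {s: int(((frame["y"] == s) & (~frame["patient_id"].isin(removed))).sum())
                  for s in (0, 1)}
        diff = counts[1] - counts[0]
        if diff == 0:
            break
        maj = 1 if diff > 0 else 0
        adiff = abs(diff)
        side_frame = frame[(frame["y"] == maj) & (~frame["patient_id"].isin(removed))]
        per_patient = _patient_image_counts(side_frame)
        # removing c images changes |diff| to |adiff - c|; keep strict improvements
        candidates = per_patient[abs(adiff - per_patient) < adiff]
        if candidates.empty or len(per_patient) <= 1:
            break
        best_gap = int(abs(adiff - candidates).min())
        pool = sorted(candidates[abs(adiff - candidates) == best_gap].index)
        removed.add(str(rng.choice(pool)))
    balanced = frame[~frame["patient_id"].isin(removed)].reset_index(drop=True)
    for side in (0, 1):
        report["after"][str(side)] = int((balanced["y"] == side).sum())
    report["removed_patients"] = sorted(removed)
    return balanced, report


def make_subsets(table: pd.DataFrame, seed: int) -> dict[str, SubDataset]:
    """Build the two balanced binary sub-datasets from the 4-class table."""
    present = set(table["class_label"])
    missing = set(c for pair in TASKS.values() for c in pair[0] + pair[1]) - present
    if missing:
        raise ParameterError(f"classes absent from the table: {sorted(missing)}")
    out: dict[str, SubDataset] = {}
    for k, (task_id, (pos, neg)) in enumerate(TASKS.items()):
        sel = table[table["class_label"].isin(pos + neg)].copy()
        sel["y"] = sel["class_label"].isin(pos).astype(int)
        rng = np.random.default_rng((seed + 7919 * k) % (2**31))
        balanced, report = _balance_sides(sel, rng)
        out[task_id] = SubDataset(task_id=task_id, frame=balanced, balance_report=report)
    return out


def split_train_validation(sub: SubDataset, val_fraction: float = 0.2, seed: int = 0) -> SplitPlan:
    """Patient-disjoint stratified split with a target validation image fraction.

    Within each class, whole patients are moved into validation (in
    seeded random order) while doing so brings the validation image
    count closer to the target fraction.
    """
    if not 0.0 < val_fraction < 1.0:
        raise ParameterError("val_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    val_patients: list[str] = []
    for side in (0, 1):
        side_frame = sub.frame[sub.frame["y"] == side]
        per_patient = _patient_image_counts(side_frame)
        patients = list(per_patient.index)
        if len(patients) < 2:
            raise ParameterError(
                f"task {sub.task_id}: class {side} has < 2 patients; cannot stratify"
            )
        rng.shuffle(patients)
        target = val_fraction * per_patient.sum()
        current = 0.0
        chosen: list[str] = []
        for p in patients:
            c = per_patient[p]
            if abs(current + c - target) <= abs(current - target) and len(chosen) < len(patients) - 1:
                chosen.append(p)
                current += c
            if current >= target:
                break
        if not chosen:
            chosen = [patients[0]]
        val_patients.extend(chosen)
    is_val = sub.frame["patient_id"].isin(val_patients)
    train_patients = sorted(set(sub.frame.loc[~is_val, "patient_id"]))
    return SplitPlan(
        train_image_ids=tuple(sub.frame.loc[~is_val, "image_id"]),
        val_image_ids=tuple(sub.frame.loc[is_val, "image_id"]),
        train_patients=tuple(train_patients),
        val_patients=tuple(sorted(set(val_patients))),
        val_fraction=val_fraction,
        seed=seed,
    )


def _grouped_stratified_folds(y: np.ndarray, groups: np.ndarray, folds: int, seed: int):
    skf = StratifiedGroupKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros((len(y), 1)), y, groups))
    for tr, te in splits:
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            raise ParameterError("a CV fold contains a single class; use more patients")
    return splits


def grid_search_svm(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    c_grid: tuple[float, ...] = DEFAULT_C_GRID,
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID,
    folds: int = 5,
    seed: int = 0,
) -> GridSearchResult:
    """Exhaustive (C, gamma) search by mean patient-grouped stratified
    k-fold CV accuracy of the RBF-SVM.

    Ties break towards the smallest C, then the smallest gamma (the
    smoother model).
    """
    splits = _grouped_stratified_folds(np.asarray(y), np.asarray(groups), folds, seed)
    heat = np.zeros((len(c_grid), len(gamma_grid)))
    fold_acc = np.zeros((len(c_grid), len(gamma_grid), len(splits)))
    for ci, C in enumerate(c_grid):
        for gi, gamma in enumerate(gamma_grid):
            for fi, (tr, te) in enumerate(splits):
                clf = SVC(kernel="rbf", C=C, gamma=gamma)
                clf.fit(X[tr], np.asarray(y)[tr])
                fold_acc[ci, gi, fi] = clf.score(X[te], np.asarray(y)[te])
            heat[ci, gi] = fold_acc[ci, gi].mean()
    best_ci, best_gi = 0, 0
    for ci in range(len(c_grid)):
        for gi in range(len(gamma_grid)):
            if heat[ci, gi] > heat[best_ci, best_gi] + 1e-12:
                best_ci, best_gi = ci, gi
    return GridSearchResult(
        c_grid=tuple(c_grid),
        gamma_grid=tuple(gamma_grid),
        heatmap=heat,
        fold_accuracies=fold_acc,
        best=SVMParams(C=c_grid[best_ci], gamma=gamma_grid[best_gi]),
    )


def train_and_predict(
    train_X: np.ndarray,
    train_y: np.ndarray,
    val_X: np.ndarray,
    params: SVMParams,
    seed: int = 0,
    feature_names: tuple[str, ...] | None = None,
    val_feature_names: tuple[str, ...] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit the RBF-SVM on the training partition and score the validation rows.

    Returns ``(scores, labels)`` where ``scores`` are calibrated
    positive-class probabilities (Platt scaling on internal training
    folds) and the hard label is ``score >= 0.5``.
    """
    if feature_names is not None and val_feature_names is not None:
        if tuple(feature_names) != tuple(val_feature_names):
            raise ParameterError("validation feature names differ from training feature names")
    from sklearn.calibration import CalibratedClassifierCV
    from sklearn.model_selection import StratifiedKFold

    train_y = np.asarray(train_y)
    n_cal = min(5, int(np.bincount(train_y).min()))
    clf = CalibratedClassifierCV(
        SVC(kernel="rbf", C=params.C, gamma=params.gamma),
        method="sigmoid",
        ensemble=False,
        cv=StratifiedKFold(n_splits=n_cal, shuffle=True, random_state=seed),
    )
    clf.fit(train_X, train_y)
    pos_col = int(np.flatnonzero(clf.classes_ == 1)[0])
    scores = clf.predict_proba(val_X)[:, pos_col]
    return scores, (scores >= 0.5).astype(int)


def rfecv_select(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    folds: int = 5,
    seed: int = 0,
    feature_names: tuple[str, ...] = FEATURE_NAMES,
) -> RFECVResult:
    """Recursive feature elimination with cross-validation.

    A linear-kernel SVM supplies the per-feature importances (|weight|);
    one feature is dropped per iteration, CV accuracy is recorded for
    every subset size and the optimal size is the accuracy argmax (ties
    resolved towards the smaller set).  The reduced set is intended to
    be refit with the RBF-SVM by the caller.
    """
    if X.shape[1] < 2:
        raise ParameterError("need at least 2 features")
    y = np.asarray(y)
    cv = _grouped_stratified_folds(y, np.asarray(groups), folds, seed)
    ranker = SVC(kernel="linear", C=1.0)
    selector = RFECV(ranker, step=1, cv=cv, scoring="accuracy", min_features_to_select=1)
    selector.fit(X, y)
    # full elimination order from a parallel RFE down to a single feature
    full = RFE(SVC(kernel="linear", C=1.0), n_features_to_select=1, step=1).fit(X, y)
    order = np.argsort(-full.ranking_, kind="stable")  # highest rank eliminated first
    names = np.asarray(feature_names)
    return RFECVResult(
        elimination_order=tuple(names[order]),
        selected=tuple(names[selector.support_]),
        cv_accuracy_by_size=np.asarray(selector.cv_results_["mean_test_score"]),
    )
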