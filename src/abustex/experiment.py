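"""End-to-end two-task experiment orchestration.

One config + one seed drives: cohort simulation (or manifest loading),
feature extraction, sub-dataset construction, patient-disjoint
splitting, grid-searched RBF-SVM training on the full feature set
(FFS), recursive feature elimination to the reduced feature set (RFS),
re-tuned RFS training, validation metrics for every task x feature set,
and a paired DeLong comparison of the FFS and RFS validation ROC
curves.  The base seed fans out to per-stage sub-seeds through
:func:`abustex.seeding.derive_seed`, so any stage can be rerun in
isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AbustexError
from .features import FEATURE_NAMES, FeatureConfig, extract_table
from .io import read_cohort, write_feature_table
from .pipeline import (
    DEFAULT_C_GRID,
    DEFAULT_GAMMA_GRID,
    SubDataset,
    grid_search_svm,
    make_subsets,
    rfecv_select,
    split_train_validation,
    standardize,
    train_and_predict,
)
from .seeding import derive_seed
from .stats import confusion_metrics, delong_compare, roc_with_ci
from .synthetic import default_class_params, CohortSpec, generate_cohort

__all__ = ["ExperimentConfig", "run_experiment", "run_task"]


@dataclass(frozen=True)
class ExperimentConfig:
    """Fully serialisable description of one experiment."""

    seed: int = 0
    manifest: str | None = None  # load this cohort instead of simulating
    n_patients_per_class: int = 20
    images_per_lesion: tuple[int, int] = (2, 16)
    images_per_tissue: int = 2
    image_shape: tuple[int, int] = (128, 128)
    lesion_radius_px: tuple[int, int] = (16, 28)
    separation: float = 1.0
    n_grey_levels: int = 64
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    folds: int = 5
    val_fraction: float = 0.2
    out_dir: str | None = None
    make_plots: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        kwargs = dict(d)
        for k in ("images_per_lesion", "image_shape", "lesion_radius_px", "c_grid", "gamma_grid"):
            if k in kwargs and kwargs[k] is not None:
                kwargs[k] = tuple(kwargs[k])
        return cls(**kwargs)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(
            class_params=default_class_params(self.separation),
            n_patients_per_class=self.n_patients_per_class,
            images_per_lesion=self.images_per_lesion,
            images_per_tissue=self.images_per_tissue,
            image_shape=self.image_shape,
            lesion_radius_px=self.lesion_radius_px,
            seed=derive_seed(self.seed, "cohort"),
        )


def _log(msg: str, t0: float) -> None:
    print(f"[abustex +{time.perf_counter() - t0:7.1f}s] {msg}", file=sys.stderr)


def run_task(
    sub: SubDataset,
    config: ExperimentConfig,
    seed: int,
    out_dir: Path | None = None,
) -> dict:
    """Train/evaluate one binary task for both FFS and RFS."""
    plan = split_train_validation(sub, config.val_fraction, seed=derive_seed(seed, "split"))
    frame = sub.frame.set_index("image_id", drop=False)
    train = frame.loc[list(plan.train_image_ids)]
    val = frame.loc[list(plan.val_image_ids)]
    result: dict = {
        "task": sub.task_id,
        "n_train_images": len(train),
        "n_val_images": len(val),
        "n_train_patients": len(plan.train_patients),
        "n_val_patients": len(plan.val_patients),
        "balance_report": sub.balance_report,
    }

    def _evaluate(feature_names: tuple[str, ...], tag: str) -> tuple[dict, np.ndarray]:
        st = standardize(train, val, feature_names=feature_names)
        y_tr = train["y"].to_numpy()
        groups = train["patient_id"].to_numpy()
        gs = grid_search_svm(
            st.X_train, y_tr, groups,
            c_grid=config.c_grid, gamma_grid=config.gamma_grid,
            folds=config.folds, seed=derive_seed(seed, tag, "grid"),
        )
        scores, labels = train_and_predict(
            st.X_train, y_tr, st.X_other, gs.best,
            seed=derive_seed(seed, tag, "fit"),
            feature_names=st.feature_names, val_feature_names=st.feature_names,
        )
        y_val = val["y"].to_numpy()
        cm = confusion_metrics(labels, y_val)
        roc = roc_with_ci(scores, y_val)
        block = {
            "n_features": len(feature_names),
            "best_C": gs.best.C,
            "best_gamma": gs.best.gamma,
            "train_cv_accuracy": float(gs.heatmap.max()),
            "confusion": {"tp": cm.tp, "fn": cm.fn, "fp": cm.fp, "tn": cm.tn},
            "accuracy": cm.accuracy,
            "sensitivity": cm.sensitivity,
            "specificity": cm.specificity,
            "auc": roc.auc,
            "auc_ci95": list(roc.ci95),
        }
        if out_dir is not None:
            gs.heatmap_frame().to_csv(out_dir / f"{sub.task_id}_{tag}_heatmap.csv")
            pd.DataFrame(
                {"image_id": val["image_id"], "y": y_val, "score": scores, "label": labels}
            ).to_csv(out_dir / f"{sub.task_id}_{tag}_scores.csv", index=False)
            if config.make_plots:
                _save_plots(gs, roc, out_dir / f"{sub.task_id}_{tag}")
        return block, scores

    ffs_block, ffs_scores = _evaluate(FEATURE_NAMES, "ffs")

    st_full = standardize(train, feature_names=FEATURE_NAMES)
    rfecv = rfecv_select(
        st_full.X_train,
        train["y"].to_numpy(),
        train["patient_id"].to_numpy(),
        folds=config.folds,
        seed=derive_seed(seed, "rfecv"),
        feature_names=FEATURE_NAMES,
    )
    rfs_block, rfs_scores = _evaluate(rfecv.selected, "rfs")
    rfs_block["selected_features"] = list(rfecv.selected)

    dl = delong_compare(ffs_scores, rfs_scores, val["y"].to_numpy(), paired=True)
    result["ffs"] = ffs_block
    result["rfs"] = rfs_block
    result["delong_ffs_vs_rfs"] = {
        "auc_ffs": dl.auc_a, "auc_rfs": dl.auc_b, "delta": dl.delta,
        "variance": dl.variance, "z": dl.z, "p_value": dl.p_value,
    }
    return result


def _save_plots(gs, roc, prefix: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    im = ax.imshow(gs.heatmap, cmap="viridis", aspect="auto")
    ax.set_xticks(range(len(gs.gamma_grid)), [f"{g:g}" for g in gs.gamma_grid])
    ax.set_yticks(range(len(gs.c_grid)), [f"{c:g}" for c in gs.c_grid])
    ax.set_xlabel("gamma")
    ax.set_ylabel("C")
    fig.colorbar(im, label="mean CV accuracy")
    fig.savefig(f"{prefix}_heatmap.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots()
    ax.plot(roc.one_minus_specificity, roc.sensitivity)
    ax.plot([0, 1], [0, 1], "k--", lw=0.5)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"AUC = {roc.auc:.3f}")
    fig.savefig(f"{prefix}_roc.png", dpi=120)
    plt.close(fig)


def run_experiment(config: ExperimentConfig, feature_table: pd.DataFrame | None = None) -> dict:
    """Run the full two-task x {FFS, RFS} experiment.

    A precomputed feature table may be supplied to skip simulation and
    extraction (e.g. when reusing cached features).  Returns the report
    dict; when ``config.out_dir`` is set all artifacts (report JSON,
    feature CSV, heatmaps, per-sample scores) are written there.
    """
    t0 = time.perf_counter()
    out_dir: Path | None = None
    if config.out_dir is not None:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
    try:
        if feature_table is None:
            if config.manifest is not None:
                _log(f"loading cohort from {config.manifest}", t0)
                samples = read_cohort(config.manifest)
            else:
                _log("simulating cohort", t0)
                samples = generate_cohort(config.cohort_spec())
            _log(f"extracting features from {len(samples)} images", t0)
            feature_table = extract_table(
                samples, FeatureConfig(n_grey_levels=config.n_grey_levels)
            )
    except AbustexError as exc:
        raise AbustexError(f"stage 'simulate/extract' failed: {exc}") from exc
    if out_dir is not None:
        write_feature_table(feature_table, out_dir / "features.csv")

    report: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_images": len(feature_table),
        "tasks": {},
    }
    try:
        subsets = make_subsets(feature_table, seed=derive_seed(config.seed, "balance"))
    except AbustexError as exc:
        raise AbustexError(f"stage 'subsets' failed: {exc}") from exc
    for task_id, sub in subsets.items():
        _log(f"task {task_id}: train/evaluate", t0)
        try:
            report["tasks"][task_id] = run_task(
                sub, config, seed=derive_seed(config.seed, task_id), out_dir=out_dir
            )
        except AbustexError as exc:
            raise AbustexError(f"stage 'task:{task_id}' failed: {exc}") from exc
    if out_dir is not None:
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    _log("done", t0)
    return report
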