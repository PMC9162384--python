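"""Per-region multimodal feature fusion and nested-LOOCV SVM evaluation.

For every atlas region a feature vector is assembled from (a) each regional
metric (GMV, WMV, FA, MD, fiber count, in that fixed order) whose group
contrast survives FDR at the feature-gate alpha (0.05), and (b) if the region
belongs to a significant NBS component, the component's functional-connectivity
edges incident to the region.  Regions with no surviving feature are marked
unclassifiable.

Evaluation is nested leave-one-out cross-validation: the outer loop holds out
each subject once; for each outer fold an inner leave-one-out loop scores every
C in the hyperparameter grid, the best C is chosen (ties to the smallest C),
the model is refit on all inner subjects and applied to the held-out subject.
Features are standardized (x - mean) / sd with parameters estimated from the
training fold only, so the held-out subject never influences the scaler or the
C choice; ``global_scaling=True`` reproduces the single global
standardization pass instead (leaky by construction, provided for
comparability).  Patients are the positive class: sensitivity = TP / (TP+FN)
counts patients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve

from .nbs import NBSResult
from .svm import DEFAULT_C_GRID, fit_linear_svm, svm_grid_path
from .synthetic import METRICS

__all__ = [
    "RegionFeatureSet",
    "ScalerParams",
    "FoldResult",
    "ClassificationReport",
    "assemble_features",
    "standardize",
    "nested_loocv_svm",
    "compute_metrics",
    "roc_auc",
    "rank_regions",
]


@dataclass
class RegionFeatureSet:
    region: int
    region_label: str
    feature_names: list[str]
    X: np.ndarray
    y: np.ndarray  # 1 = patient
    subject_ids: list[str]

    @property
    def unclassifiable(self) -> bool:
        return len(self.feature_names) == 0


@dataclass
class ScalerParams:
    mean: np.ndarray
    scale: np.ndarray
    kept: np.ndarray  # boolean mask of retained (non-constant) features


@dataclass
class FoldResult:
    subject_id: str
    true_label: int
    predicted_label: int
    decision_value: float
    selected_C: float


@dataclass
class ClassificationReport:
    region: int
    region_label: str
    feature_names: list[str]
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    confusion: dict[str, int]
    folds: list[FoldResult] = field(repr=False)
    roc_fpr: np.ndarray = field(repr=False, default=None)
    roc_tpr: np.ndarray = field(repr=False, default=None)


def assemble_features(
    region: int,
    stat_results: dict[str, "RegionStatsResult"],
    tables: dict[str, pd.DataFrame],
    nbs_result: NBSResult | None,
    fc: np.ndarray | None,
    alpha: float = 0.05,
) -> RegionFeatureSet:
    """Fuse significant modality features and incident component edges.

    Metric features keep the fixed order GMV, WMV, FA, MD, FIBER_COUNT; edge
    features follow, sorted by (i, j) ascending.  The subject ordering of all
    tables (and the FC stack) must agree.
    """
    ref_metric = next(iter(tables))
    subject_ids = list(tables[ref_metric]["subject_id"])
    groups = tables[ref_metric]["group"].to_numpy()
    for metric, table in tables.items():
        if list(table["subject_id"]) != subject_ids:
            raise ValueError(
                f"subject sets differ between {ref_metric} and {metric} tables"
            )
    region_label = [c for c in tables[ref_metric].columns
                    if c not in ("subject_id", "group")][region]

    names: list[str] = []
    columns: list[np.ndarray] = []
    for metric in METRICS:
        result = stat_results.get(metric)
        if result is None:
            continue
        p_adj = result.p_fdr[region]
        if not np.isnan(p_adj) and p_adj < alpha:
            names.append(metric)
            columns.append(tables[metric][region_label].to_numpy(float))

    if nbs_result is not None:
        if fc is None:
            raise ValueError("fc stack required when an NBS result is supplied")
        if fc.shape[0] != len(subject_ids):
            raise ValueError("FC stack does not match the cohort's subject set")
        edges = []
        for comp in nbs_result.significant_components():
            if region in comp.nodes:
                for i, j, _sign, _t in comp.edges:
                    if region in (i, j):
                        edges.append((min(i, j), max(i, j)))
        for i, j in sorted(set(edges)):
            li = nbs_result.region_labels[i]
            lj = nbs_result.region_labels[j]
            names.append(f"FC({li},{lj})")
            columns.append(fc[:, i, j])

    X = np.column_stack(columns) if columns else np.empty((len(subject_ids), 0))
    y = (groups == "patient").astype(int)
    return RegionFeatureSet(region, region_label, names, X, y, subject_ids)


def standardize(
    train: np.ndarray, apply: np.ndarray
) -> tuple[ScalerParams, np.ndarray, np.ndarray]:
    """Center and scale to unit variance using TRAIN statistics only.

    Sample standard deviation (n-1 denominator).  Constant training columns
    are dropped from both matrices with a warning.
    """
    train = np.asarray(train, float)
    apply = np.asarray(apply, float)
    if train.shape[0] < 2:
        raise ValueError("need at least 2 training rows to standardize")
    mean = train.mean(axis=0)
    scale = train.std(axis=0, ddof=1)
    kept = scale > 0
    if not kept.all():
        warnings.warn(
            f"dropping {int((~kept).sum())} constant feature(s) before scaling",
            stacklevel=2,
        )
    params = ScalerParams(mean=mean, scale=scale, kept=kept)
    train_t = (train[:, kept] - mean[kept]) / scale[kept]
    apply_t = (apply[:, kept] - mean[kept]) / scale[kept]
    return params, train_t, apply_t


def compute_metrics(tp: int, tn: int, fp: int, fn: int) -> dict[str, float]:
    """Accuracy, sensitivity and specificity from confusion counts."""
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    if tp + tn + fp + fn == 0 or tp + fn == 0 or tn + fp == 0:
        raise ValueError("zero denominator in confusion counts")
    return {
        "accuracy": (tp + tn) / (tp + tn + fp + fn),
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
    }


def roc_auc(decision_values, labels) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve (pooled decision values) and trapezoidal AUC.

    Ties in decision values follow the midpoint (rank) convention.  Constant
    decision values yield AUC 0.5 with a warning.
    """
    decision_values = np.asarray(decision_values, float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present for ROC analysis")
    if np.ptp(decision_values) == 0:
        warnings.warn("all decision values identical; AUC set to 0.5", stacklevel=2)
        return np.array([0.0, 1.0]), np.array([0.0, 1.0]), 0.5
    fpr, tpr, _ = roc_curve(labels, decision_values)
    area = float(_auc(fpr, tpr))
    return fpr, tpr, area


def nested_loocv_svm(
    fs: RegionFeatureSet,
    c_grid=DEFAULT_C_GRID,
    global_scaling: bool = False,
) -> ClassificationReport:
    """Nested leave-one-out evaluation of the linear SVM on one region."""
    if fs.unclassifiable:
        raise ValueError(f"region {fs.region_label} has no features")
    X = np.asarray(fs.X, float)
    y = np.asarray(fs.y, int)
    n = len(y)
    if (y == 1).sum() < 3 or (y == 0).sum() < 3:
        raise ValueError("need at least 3 subjects per class")
    c_grid = np.sort(np.asarray(c_grid, float))  # ascending => ties pick smallest C

    if global_scaling:
        _, X_all, _ = standardize(X, X)
        if X_all.shape[1] == 0:
            raise ValueError("all features constant; nothing to classify")

    folds: list[FoldResult] = []
    decisions = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        train = idx[idx != i]
        y_tr = y[train]
        if len(np.unique(y_tr)) < 2:
            raise ValueError(f"training fold {i} collapsed to one class")
        if global_scaling:
            Xs_tr = X_all[train]
            x_test = X_all[i]
        else:
            _, Xs_tr, x_test_m = standardize(X[train], X[i][None, :])
            if Xs_tr.shape[1] == 0:
                raise ValueError(
                    f"all features constant in training fold {i}; cannot classify"
                )
            x_test = x_test_m[0]
        y_pm = np.where(y_tr == 1, 1.0, -1.0)

        # inner LOOCV: per-C validation accuracy over the training subjects
        n_tr = len(train)
        correct = np.zeros(len(c_grid), dtype=int)
        inner_idx = np.arange(n_tr)
        for j in range(n_tr):
            inner = inner_idx[inner_idx != j]
            if len(np.unique(y_tr[inner])) < 2:
                raise ValueError(f"inner training fold {i}/{j} collapsed to one class")
            betas = svm_grid_path(Xs_tr[inner], y_pm[inner], c_grid)
            dec = betas[:, :-1] @ Xs_tr[j] + betas[:, -1]
            correct += (dec > 0) == (y_pm[j] > 0)
        best = int(np.argmax(correct))  # first max = smallest C (grid ascending)
        C_sel = float(c_grid[best])

        beta = fit_linear_svm(Xs_tr, y_pm, C_sel)
        d = float(x_test @ beta[:-1] + beta[-1])
        pred = 1 if d > 0 else 0
        decisions[i] = d
        folds.append(FoldResult(fs.subject_ids[i], int(y[i]), pred, d, C_sel))

    pred = np.array([f.predicted_label for f in folds])
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    metrics = compute_metrics(tp, tn, fp, fn)
    fpr, tpr, area = roc_auc(decisions, y)
    return ClassificationReport(
        region=fs.region,
        region_label=fs.region_label,
        feature_names=list(fs.feature_names),
        accuracy=metrics["accuracy"],
        sensitivity=metrics["sensitivity"],
        specificity=metrics["specificity"],
        auc=area,
        confusion={"TP": tp, "TN": tn, "FP": fp, "FN": fn},
        folds=folds,
        roc_fpr=fpr,
        roc_tpr=tpr,
    )


def rank_regions(
    reports: list[ClassificationReport], cutoff: float = 0.90
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank classifiable regions by accuracy (ties: AUC, then region index).

    Returns the full ranking and the strict ``accuracy > cutoff`` view.
    """
    if not reports:
        raise ValueError("no classifiable regions to rank")
    rows = [
        {
            "region": r.region,
            "region_label": r.region_label,
            "features": ", ".join(r.feature_names),
            "auc": r.auc,
            "accuracy": r.accuracy,
            "sensitivity": r.sensitivity,
            "specificity": r.specificity,
        }
        for r in reports
    ]
    table = pd.DataFrame(rows).sort_values(
        by=["accuracy", "auc", "region"], ascending=[False, False, True]
    ).reset_index(drop=True)
    return table, table[table["accuracy"] > cutoff].reset_index(drop=True)
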