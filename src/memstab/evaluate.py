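"""Validation protocol: repeated stratified group k-fold CV, metrics, and
the Fisher r-to-z comparison of correlations.

The protocol is stratified 10-fold cross-validation repeated 10 times with
independent re-randomised fold assignments ("bootstrap repetitions");
forward/reverse mutation pairs share a grouping key and are never split
across folds.  Per repetition, held-out predictions are pooled over the k
folds and a single set of metrics computed, then summarised as mean ± sd
across repetitions — so a repetition contributes one correlation, not ten.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (
    f1_score,
    matthews_corrcoef,
    recall_score,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import StratifiedGroupKFold

from .dataset import ClassThresholds, classify_ddg
from .learn import PathogenicityClassifier, StabilityRegressor

__all__ = [
    "CrossValProtocol",
    "EvaluationReport",
    "make_folds",
    "regression_metrics",
    "classification_metrics",
    "fisher_r_to_z",
    "roc_points",
    "run_protocol",
]


@dataclass(frozen=True)
class CrossValProtocol:
    n_folds: int = 10
    repetitions: int = 10

    def __post_init__(self) -> None:
        if self.n_folds < 2 or self.repetitions < 1:
            raise ValueError("need at least 2 folds and 1 repetition")


@dataclass
class EvaluationReport:
    """Per-repetition metrics with provenance (seeds and fold assignments)."""

    task: str
    protocol: CrossValProtocol
    per_repetition: list[dict] = field(default_factory=list)
    fold_assignments: list[np.ndarray] = field(default_factory=list)
    seeds: list[int] = field(default_factory=list)

    @property
    def summary(self) -> dict[str, tuple[float, float]]:
        """Metric → (mean, sd) across repetitions."""
        keys = [k for k in self.per_repetition[0] if isinstance(self.per_repetition[0][k], float)]
        out = {}
        for k in keys:
            vals = np.array([rep[k] for rep in self.per_repetition])
            out[k] = (float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_repetition)


def make_folds(labels, groups, n_folds: int = 10, seed: int = 0) -> np.ndarray:
    """Group-aware stratified fold assignment (deterministic per seed).

    ``labels`` stratify (ΔΔG class or pathogenicity label); ``groups`` are
    pair keys that must stay within one fold.
    """
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    n_groups = len(np.unique(groups))
    if n_groups < n_folds:
        raise ValueError(f"only {n_groups} groups for {n_folds} folds")
    splitter = StratifiedGroupKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignment = np.full(len(labels), -1, dtype=int)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(len(labels)), labels, groups)):
        assignment[test_idx] = fold
    if (assignment < 0).any():
        raise RuntimeError("fold assignment did not cover every record")
    return assignment


def regression_metrics(y_true, y_pred) -> dict[str, float]:
    """Pearson r, Spearman ρ, Kendall τ-b and RMSE (kcal/mol)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_true) != len(y_pred) or len(y_true) < 3:
        raise ValueError("need two equal-length vectors of at least 3 values")
    if not (np.all(np.isfinite(y_true)) and np.all(np.isfinite(y_pred))):
        raise ValueError("non-finite values in inputs")
    if np.ptp(y_true) == 0 or np.ptp(y_pred) == 0:
        raise ValueError("correlation undefined: an input vector has zero variance")
    return {
        "pearson": float(stats.pearsonr(y_true, y_pred).statistic),
        "spearman": float(stats.spearmanr(y_true, y_pred).statistic),
        "kendall": float(stats.kendalltau(y_true, y_pred).statistic),  # τ-b
        "rmse": float(np.sqrt(np.mean((y_true - y_pred) ** 2))),
    }


def classification_metrics(
    labels_true, labels_pred, scores=None, positive_label=None
) -> dict:
    """MCC, F1 (positive class), trapezoidal ROC AUC and per-class recall."""
    labels_true = np.asarray(labels_true)
    labels_pred = np.asarray(labels_pred)
    classes = np.unique(labels_true)
    if len(classes) < 2:
        raise ValueError("MCC undefined: ground truth contains a single class")
    if positive_label is None:
        positive_label = classes[-1]
    out = {
        "mcc": float(matthews_corrcoef(labels_true, labels_pred)),
        "f1": float(f1_score(labels_true, labels_pred, pos_label=positive_label)),
        "recall": {
            str(c): float(r)
            for c, r in zip(classes, recall_score(labels_true, labels_pred, labels=classes, average=None))
        },
    }
    if scores is not None and len(classes) == 2:
        out["auc"] = float(roc_auc_score(labels_true == positive_label, np.asarray(scores)))
    return out


def roc_points(labels_true, scores, positive_label) -> pd.DataFrame:
    """ROC curve points (FPR, TPR, threshold) for plotting/export."""
    fpr, tpr, thr = roc_curve(np.asarray(labels_true) == positive_label, scores)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def fisher_r_to_z(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Two-sided test for a difference between two Pearson correlations.

    z = (atanh r1 − atanh r2) / sqrt(1/(n1−3) + 1/(n2−3)), p from N(0, 1).
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("|r| must be < 1 (the transform diverges at ±1)")
    for n in (n1, n2):
        if n <= 3:
            raise ValueError("sample sizes must exceed 3")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def run_protocol(
    X: pd.DataFrame,
    y,
    groups,
    task: str = "stability",
    protocol: CrossValProtocol | None = None,
    seed: int = 0,
    hyperparams: dict | None = None,
    thresholds: ClassThresholds | None = None,
    positive_label=None,
) -> EvaluationReport:
    """Run the repeated stratified group k-fold protocol end to end.

    For ``task='stability'`` ``y`` holds ΔΔG values; stratification uses the
    three-way ΔΔG class and the report carries correlation/RMSE metrics plus
    classification-by-regression MCC/F1 over the stabilising/destabilising
    subset.  For ``task='pathogenicity'`` ``y`` holds labels and the report
    carries MCC/F1/AUC/recalls.
    """
    if protocol is None:
        protocol = CrossValProtocol()
    if task not in ("stability", "pathogenicity"):
        raise ValueError(f"unknown task {task!r}")
    y = np.asarray(y)
    groups = np.asarray(groups)
    if thresholds is None:
        thresholds = ClassThresholds()
    if task == "stability":
        strat = np.asarray([classify_ddg(float(v), thresholds) for v in y])
    else:
        strat = y

    report = EvaluationReport(task=task, protocol=protocol)
    for rep in range(protocol.repetitions):
        rep_seed = int(seed + rep) % (2**31 - 1)
        folds = make_folds(strat, groups, n_folds=protocol.n_folds, seed=rep_seed)
        # grouping audit: a pair key must map to exactly one fold
        for g in np.unique(groups):
            if len(np.unique(folds[groups == g])) != 1:
                raise RuntimeError(f"grouping violation: group {g!r} spans folds")
        pooled = np.empty(len(y), dtype=object if task == "pathogenicity" else float)
        pooled_scores = np.empty(len(y), dtype=float)
        seen = np.zeros(len(y), dtype=bool)
        for fold in range(protocol.n_folds):
            test_mask = folds == fold
            train_mask = ~test_mask
            if task == "stability":
                model = StabilityRegressor(random_state=rep_seed, **(hyperparams or {}))
                model.fit(X[train_mask], y[train_mask].astype(float))
                pooled[test_mask] = model.predict(X[test_mask])
            else:
                model = PathogenicityClassifier(random_state=rep_seed, **(hyperparams or {}))
                model.fit(X[train_mask], y[train_mask])
                proba = model.predict_proba(X[test_mask])
                labels = model.classes_[np.argmax(proba, axis=1)]
                pooled[test_mask] = labels
                pos = positive_label if positive_label is not None else model.classes_[-1]
                pos_col = list(model.classes_).index(pos)
                pooled_scores[test_mask] = proba[:, pos_col]
            seen |= test_mask
        if not seen.all():
            raise RuntimeError("pooled predictions do not cover every record")

        if task == "stability":
            metrics = regression_metrics(y.astype(float), pooled.astype(float))
            true_cls = strat
            pred_cls = np.asarray([classify_ddg(float(v), thresholds) for v in pooled])
            polar = np.isin(true_cls, ["stabilising", "destabilising"])
            if len(np.unique(true_cls[polar])) == 2:
                # MCC/F1 over the stabilising/destabilising subset, with
                # neutral predictions counting as misclassifications
                binary_pred = pred_cls[polar]
                metrics["class_mcc"] = float(matthews_corrcoef(true_cls[polar], binary_pred))
                metrics["class_f1"] = float(
                    f1_score(true_cls[polar], binary_pred, labels=["destabilising"], average="macro")
                )
                rec = {}
                for c in ("stabilising", "destabilising"):
                    mask = true_cls[polar] == c
                    rec[c] = float(np.mean(binary_pred[mask] == c)) if mask.any() else np.nan
                metrics["recall_stabilising"] = rec["stabilising"]
                metrics["recall_destabilising"] = rec["destabilising"]
        else:
            cls = classification_metrics(
                y, pooled, scores=pooled_scores, positive_label=positive_label
            )
            metrics = {k: v for k, v in cls.items() if isinstance(v, float)}
            for c, r in cls["recall"].items():
                metrics[f"recall_{c}"] = r
        report.per_repetition.append(metrics)
        report.fold_assignments.append(folds)
        report.seeds.append(rep_seed)
    return report
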