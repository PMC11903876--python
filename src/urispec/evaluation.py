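"""Performance metrics and 5-fold cross-validated optimism correction.

The global model is selected and fitted on the full dataset, so its
training-set ("inner") AUC/BAC are optimistic.  A correction term is
estimated by 5-fold CV: in each fold the whole procedure (best-subset
selection + fit) is repeated on the 4/5 training part, inner and
held-out performance are measured, and the mean inner-minus-out
difference across folds is subtracted from the global model's inner
performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold

from .exceptions import DegenerateOutcomeError, EvaluationError
from .models import BestSubsetResults, best_subset


@dataclass(frozen=True)
class PerformanceMetrics:
    auc: float
    bac: float
    sensitivity: float
    specificity: float
    threshold: float

    def __post_init__(self):
        assert abs(self.bac - (self.sensitivity + self.specificity) / 2) < 1e-12


def roc_auc(scores, labels) -> float:
    """AUC via the Mann-Whitney formulation; ties contribute 1/2."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise DegenerateOutcomeError("AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def balanced_accuracy(scores, labels, threshold: float = 0.5) -> PerformanceMetrics:
    """Sensitivity/specificity at ``score > threshold``; BAC is their mean."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if np.unique(labels).size < 2:
        raise DegenerateOutcomeError("BAC needs both classes present")
    pred = (scores > threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return PerformanceMetrics(auc=roc_auc(scores, labels),
                              bac=(sens + spec) / 2.0, sensitivity=sens,
                              specificity=spec, threshold=threshold)


def make_folds(n: int, k: int = 5, seed: int = 0) -> np.ndarray:
    """Random partition of n samples into k folds with sizes differing <= 1."""
    if n < k:
        raise ValueError(f"cannot split n={n} into k={k} folds")
    assignment = np.empty(n, dtype=int)
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (_, test_idx) in enumerate(kf.split(np.arange(n))):
        assignment[test_idx] = fold
    return assignment


def correct_metric(global_inner: float, correction: float) -> float:
    """Optimism-corrected estimate: inner-sample value minus correction term."""
    return global_inner - correction


@dataclass
class CVReport:
    """Per-fold metrics, correction terms and corrected global performance."""

    marker: str
    kind: str
    k: int
    seed: int
    fold_assignment: np.ndarray
    inner: list[PerformanceMetrics]
    outer: list[PerformanceMetrics]
    fold_features: list[tuple[str, ...]]
    global_inner: PerformanceMetrics
    global_selection: BestSubsetResults
    rebuilds: int = 0

    @property
    def correction_auc(self) -> float:
        return float(np.mean([i.auc - o.auc for i, o in zip(self.inner, self.outer)]))

    @property
    def correction_bac(self) -> float:
        return float(np.mean([i.bac - o.bac for i, o in zip(self.inner, self.outer)]))

    @property
    def corrected_auc(self) -> float:
        return float(np.clip(correct_metric(self.global_inner.auc,
                                            self.correction_auc), 0.0, 1.0))

    @property
    def corrected_bac(self) -> float:
        return float(np.clip(correct_metric(self.global_inner.bac,
                                            self.correction_bac), 0.0, 1.0))

    @property
    def n_covariates(self) -> int:
        return len(self.global_selection.selected_features)

    def summary_row(self) -> dict:
        return {"marker": self.marker, "model": self.kind.upper(),
                "corrected_auc": round(self.corrected_auc, 3),
                "corrected_bac": round(self.corrected_bac, 3),
                "inner_auc": round(self.global_inner.auc, 3),
                "inner_bac": round(self.global_inner.bac, 3),
                "correction_auc": round(self.correction_auc, 3),
                "correction_bac": round(self.correction_bac, 3),
                "n_covariates": self.n_covariates,
                "features": "+".join(self.global_selection.selected_features),
                "status": "ok"}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f, (i, o) in enumerate(zip(self.inner, self.outer)):
            rows.append({"fold": f, "inner_auc": i.auc, "outer_auc": o.auc,
                         "inner_bac": i.bac, "outer_bac": o.bac,
                         "features": "+".join(self.fold_features[f])})
        return pd.DataFrame(rows)


def _fold_seed(seed: int, attempt: int) -> int:
    return (seed + 1_000_003 * attempt) % (2 ** 31 - 1)


def _splittable(y: np.ndarray, assignment: np.ndarray, k: int) -> bool:
    for fold in range(k):
        test = y[assignment == fold]
        train = y[assignment != fold]
        if np.unique(test).size < 2 or np.unique(train).size < 2:
            return False
    return True


def cv_optimism(X: pd.DataFrame, y, groups=None, kind: str = "lr",
                k: int = 5, seed: int = 0, max_size: int | None = None,
                threshold: float = 0.5, n_quadrature: int = 15,
                inner_mode: str = "conditional", outer_mode: str = "marginal",
                grouped_folds: bool = False, max_attempts: int = 20,
                include_baseline: bool = True, marker: str = "") -> CVReport:
    """Run the full optimism-correction procedure for one marker/model kind.

    Folds are drawn at the sample level by default (a patient may span
    training and test, matching the validated procedure); set
    ``grouped_folds=True`` to keep each patient within one fold.  Folds
    whose training or test part is single-class are redrawn with a
    derived seed (counted in ``rebuilds``).
    """
    y = np.asarray(y).astype(int)
    groups_arr = None if groups is None else np.asarray(groups)
    n = y.size

    assignment = None
    rebuilds = 0
    for attempt in range(max_attempts):
        s = _fold_seed(seed, attempt)
        if grouped_folds:
            if groups_arr is None:
                raise ValueError("grouped_folds requires groups")
            uniq = np.unique(groups_arr)
            ga = make_folds(uniq.size, k, s)
            lut = dict(zip(uniq, ga))
            cand = np.array([lut[g] for g in groups_arr])
        else:
            cand = make_folds(n, k, s)
        if _splittable(y, cand, k):
            assignment = cand
            rebuilds = attempt
            break
    if assignment is None:
        raise EvaluationError(
            f"marker {marker or '?'}: could not build {k} folds with both "
            f"classes after {max_attempts} attempts")

    def predict(sel: BestSubsetResults, Xp, gp, mode):
        if kind == "lrre":
            return sel.best.predict(Xp[list(sel.selected_features)]
                                    if sel.selected_features else
                                    Xp[[]], groups=gp, mode=mode)
        return sel.best.predict(Xp[list(sel.selected_features)]
                                if sel.selected_features else Xp[[]])

    inner_metrics, outer_metrics, fold_features = [], [], []
    for fold in range(k):
        tr = assignment != fold
        te = ~tr
        g_tr = None if groups_arr is None else groups_arr[tr]
        g_te = None if groups_arr is None else groups_arr[te]
        sel = best_subset(X.loc[tr], y[tr], groups=g_tr, kind=kind,
                          max_size=max_size, n_quadrature=n_quadrature,
                          include_baseline=include_baseline)
        p_in = predict(sel, X.loc[tr], g_tr,
                       inner_mode if kind == "lrre" else "marginal")
        p_out = predict(sel, X.loc[te], g_te,
                        outer_mode if kind == "lrre" else "marginal")
        inner_metrics.append(balanced_accuracy(p_in, y[tr], threshold))
        outer_metrics.append(balanced_accuracy(p_out, y[te], threshold))
        fold_features.append(sel.selected_features)

    global_sel = best_subset(X, y, groups=groups_arr, kind=kind,
                             max_size=max_size, n_quadrature=n_quadrature,
                             include_baseline=include_baseline)
    p_global = predict(global_sel, X, groups_arr,
                       inner_mode if kind == "lrre" else "marginal")
    global_inner = balanced_accuracy(p_global, y, threshold)

    return CVReport(marker=marker, kind=kind, k=k, seed=seed,
                    fold_assignment=assignment, inner=inner_metrics,
                    outer=outer_metrics, fold_features=fold_features,
                    global_inner=global_inner, global_selection=global_sel,
                    rebuilds=rebuilds)


def roc_coordinates(scores, labels) -> pd.DataFrame:
    """FPR/TPR pairs of the empirical ROC curve (for plotting exports)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    order = np.argsort(-scores, kind="stable")
    y = labels[order]
    tpr = np.concatenate([[0], np.cumsum(y) / max(y.sum(), 1)])
    fpr = np.concatenate([[0], np.cumsum(1 - y) / max((1 - y).sum(), 1)])
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})
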