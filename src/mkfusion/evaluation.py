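"""Evaluation machinery: LOOCV, nested kernel-weight search, metrics.

The study protocol replicated here is:

* outer loop: leave-one-out cross-validation (LOOCV) over subjects;
* inner loop: stratified 5-fold CV on each outer training set, scoring every
  candidate (kernel weights beta, C) pair by pooled inner AUC;
* the winning pair is refit on the full outer training set and scores the
  held-out subject; pooled held-out scores give the reported ROC/AUC and
  confusion metrics.

All kernel standardisation statistics are recomputed inside every training
portion, so no fold sees its held-out subjects.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .cohort import MultimodalDataset
from .kernels import (
    KernelMatrix,
    KernelSpec,
    KernelWeights,
    combine_kernels,
    compute_kernel,
    normalize_kernel,
)
from .svm import decision_function, fit_svm

__all__ = [
    "ConfusionMatrix",
    "CVResult",
    "WeightGrid",
    "simplex_grid",
    "confusion_metrics",
    "roc_auc",
    "feature_screen",
    "loocv_fixed_weights",
    "nested_weight_search",
    "baseline_harness",
]

@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with the case group (label +1) as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(
            tp=int(((y_true > 0) & (y_pred > 0)).sum()),
            fn=int(((y_true > 0) & (y_pred < 0)).sum()),
            fp=int(((y_true < 0) & (y_pred > 0)).sum()),
            tn=int(((y_true < 0) & (y_pred < 0)).sum()),
        )


def confusion_metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) as percentages, 1 decimal.

    Sensitivity = TP/(TP+FN) over cases, specificity = TN/(TN+FP) over
    controls; either is undefined (raises) when its denominator is zero.
    """
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    if cm.tp + cm.fn == 0:
        raise ValueError("sensitivity undefined: no positive-class subjects")
    if cm.tn + cm.fp == 0:
        raise ValueError("specificity undefined: no negative-class subjects")
    acc = 100.0 * (cm.tp + cm.tn) / cm.n
    sens = 100.0 * cm.tp / (cm.tp + cm.fn)
    spec = 100.0 * cm.tn / (cm.tn + cm.fp)
    return round(acc, 1), round(sens, 1), round(spec, 1)


def roc_auc(y_true, scores) -> tuple[pd.DataFrame, float]:
    """ROC points and AUC from raw decision scores.

    The AUC equals the Mann-Whitney concordance probability: the fraction of
    (case, control) pairs where the case scores higher, counting ties 1/2.
    """
    y_true = np.asarray(y_true, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if (y_true > 0).all() or (y_true < 0).all():
        raise ValueError("ROC requires both classes")
    fpr, tpr, thr = roc_curve(y_true, scores, pos_label=1)
    auc = float(roc_auc_score(y_true, scores))
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return points, auc


@dataclass
class CVResult:
    """Held-out predictions and summaries from one cross-validated run."""

    subject_ids: tuple[str, ...]
    y_true: np.ndarray
    scores: np.ndarray
    y_pred: np.ndarray
    modalities: tuple[str, ...] = ()
    fold_weights: np.ndarray | None = None  # (n_folds, M)
    fold_C: np.ndarray | None = None
    method: str = "mk_svm"
    meta: dict = field(default_factory=dict)

    @property
    def confusion(self) -> ConfusionMatrix:
        return ConfusionMatrix.from_predictions(self.y_true, self.y_pred)

    @property
    def metrics(self) -> dict:
        acc, sens, spec = confusion_metrics(self.confusion)
        _, auc = roc_auc(self.y_true, self.scores)
        return {"accuracy": acc, "sensitivity": sens, "specificity": spec,
                "auc": round(auc, 3)}

    @property
    def auc(self) -> float:
        return roc_auc(self.y_true, self.scores)[1]

    def weights_summary(self) -> pd.DataFrame:
        """Mean +/- sample SD of the selected weights over outer folds."""
        if self.fold_weights is None:
            raise ValueError("this run selected no kernel weights")
        w = np.asarray(self.fold_weights, dtype=float)
        sd = w.std(axis=0, ddof=1) if w.shape[0] > 1 else np.zeros(w.shape[1])
        return pd.DataFrame({"mean": w.mean(axis=0), "sd": sd},
                            index=list(self.modalities))

    def to_dict(self) -> dict:
        out = {
            "method": self.method,
            "subject_ids": list(self.subject_ids),
            "y_true": self.y_true.tolist(),
            "scores": self.scores.tolist(),
            "y_pred": self.y_pred.tolist(),
            "confusion": vars(self.confusion),
            "metrics": self.metrics,
            "modalities": list(self.modalities),
            "meta": self.meta,
        }
        if self.fold_weights is not None:
            out["fold_weights"] = np.asarray(self.fold_weights).tolist()
            ws = self.weights_summary()
            out["weights_mean"] = ws["mean"].tolist()
            out["weights_sd"] = ws["sd"].tolist()
        if self.fold_C is not None:
            out["fold_C"] = np.asarray(self.fold_C).tolist()
        return out


# ---------------------------------------------------------------------------
# Simplex grid


@dataclass(frozen=True)
class WeightGrid:
    """All weight vectors with entries that are multiples of ``step``."""

    step: float
    points: tuple[tuple[float, ...], ...]

    @property
    def M(self) -> int:
        return len(self.points[0])

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)


def simplex_grid(M: int, step: float) -> WeightGrid:
    """Exhaustive grid on the probability simplex, lexicographic order.

    ``step`` must be 1/k for integer k >= 1; the grid has C(k+M-1, M-1)
    points (compositions of k into M non-negative parts).
    """
    if M < 1:
        raise ValueError(f"need at least one modality, got M={M}")
    k = 1.0 / step
    if abs(k - round(k)) > 1e-9:
        raise ValueError(f"step must be 1/k for an integer k, got {step}")
    k = int(round(k))
    points = []
    for cuts in itertools.combinations(range(k + M - 1), M - 1):
        prev = -1
        parts = []
        for c in cuts:
            parts.append(c - prev - 1)
            prev = c
        parts.append(k + M - 2 - prev)
        points.append(tuple(p / k for p in parts))
    points.sort()
    return WeightGrid(step=step, points=tuple(points))


# ---------------------------------------------------------------------------
# Feature screening


def feature_screen(dataset: MultimodalDataset, alpha: float = 0.05) -> pd.DataFrame:
    """Welch two-sample t-test per feature with per-modality Bonferroni flags.

    Returns a table with one row per feature: modality, feature, Welch t and
    p, -log10(p) (for Manhattan-style plotting), the modality-wise Bonferroni
    threshold ``alpha / p_m`` and a significance flag.  Features with zero
    variance in both groups get ``t = 0`` and an undefined (NaN) p value.
    """
    case_mask = dataset.y > 0
    rows = []
    for modality, block in dataset.blocks.items():
        X = block.to_numpy(dtype=float)
        case, ctrl = X[case_mask], X[~case_mask]
        p_m = X.shape[1]
        bonf = alpha / p_m
        with np.errstate(divide="ignore", invalid="ignore"):
            t, p = stats.ttest_ind(case, ctrl, equal_var=False)
        for j, name in enumerate(block.columns):
            tj, pj = float(t[j]), float(p[j])
            degenerate = case[:, j].var() == 0 and ctrl[:, j].var() == 0
            if degenerate:
                tj, pj = 0.0, np.nan
            rows.append({
                "modality": modality,
                "feature": str(name),
                "t": tj,
                "p": pj,
                "neg_log10_p": -np.log10(pj) if pj == pj and pj > 0 else np.nan,
                "bonferroni_alpha": bonf,
                "significant_bonferroni": bool(pj == pj and pj < bonf),
                "degenerate": degenerate,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Kernel CV plumbing


def default_kernel_specs(dataset: MultimodalDataset) -> dict[str, KernelSpec]:
    """Linear kernel on z-scored features for every modality (the default)."""
    return {m: KernelSpec(family="linear", standardize=True) for m in dataset.modalities}


def _modality_kernels(
    dataset: MultimodalDataset,
    kernel_specs: Mapping[str, KernelSpec],
    rows: np.ndarray,
    train_rows_local: np.ndarray,
) -> list[KernelMatrix]:
    """Normalized per-modality kernels over ``rows`` (absolute indices),
    standardised on ``train_rows_local`` (positions within ``rows``)."""
    kernels = []
    for m in dataset.modalities:
        X = dataset.blocks[m].iloc[rows]
        K = compute_kernel(X, kernel_specs[m], train_rows=train_rows_local, modality=m)
        kernels.append(normalize_kernel(K))
    return kernels


def _fit_and_score(kernels: Sequence[KernelMatrix], beta: KernelWeights,
                   y: np.ndarray, train: np.ndarray, test: np.ndarray,
                   C: float) -> np.ndarray:
    # convex combinations of verified PSD kernels stay PSD; skip the re-check
    K = combine_kernels(kernels, beta)
    model = fit_svm(K.submatrix(train), y[train], C=C, check_psd=False)
    return decision_function(model, K.submatrix(test, train))


def _fast_auc(y: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC via average ranks (ties counted 1/2)."""
    ranks = stats.rankdata(scores)
    pos = y > 0
    n_pos = int(pos.sum())
    n_neg = y.size - n_pos
    return (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def loocv_fixed_weights(
    dataset: MultimodalDataset,
    kernel_specs: Mapping[str, KernelSpec] | None = None,
    weights: KernelWeights | Sequence[float] | None = None,
    C: float = 1.0,
) -> CVResult:
    """Plain LOOCV of the multiple-kernel SVM with frozen weights.

    This is the protocol behind the study's reported confusion matrices:
    fix the fold-averaged weights, then leave-one-out over all subjects.
    """
    kernel_specs = dict(kernel_specs or default_kernel_specs(dataset))
    M = len(dataset.modalities)
    if weights is None:
        weights = KernelWeights(tuple([1.0 / M] * M), dataset.modalities)
    elif not isinstance(weights, KernelWeights):
        weights = KernelWeights(tuple(weights), dataset.modalities)
    n = dataset.n
    y = dataset.y
    scores = np.empty(n)
    all_rows = np.arange(n)
    for i in range(n):
        train = np.delete(all_rows, i)
        kernels = _modality_kernels(dataset, kernel_specs, all_rows, train)
        scores[i] = _fit_and_score(kernels, weights, y, train, np.array([i]), C)[0]
    y_pred = np.where(scores >= 0, 1.0, -1.0)
    return CVResult(
        subject_ids=dataset.subject_ids, y_true=y.copy(), scores=scores,
        y_pred=y_pred, modalities=dataset.modalities,
        fold_weights=np.tile(weights.as_array(), (n, 1)),
        fold_C=np.full(n, C), method="mk_svm_fixed_weights",
        meta={"C": C, "weights": list(weights.beta)},
    )


def nested_weight_search(
    dataset: MultimodalDataset,
    kernel_specs: Mapping[str, KernelSpec] | None = None,
    grid: WeightGrid | None = None,
    C_options: Sequence[float] = (1.0,),
    inner_folds: int = 5,
    seed: int = 0,
    tie_break: str = "centroid",
) -> CVResult:
    """Nested CV: LOOCV outer loop, stratified k-fold inner grid search.

    For every outer fold, each candidate (beta, C) is scored by the AUC of
    the pooled inner validation scores; the winner is refit on the outer
    training set and scores the held-out subject.  Inner splits are
    stratified and seeded from ``seed`` plus the outer-fold index, so the
    whole run is reproducible.

    With only ~n pooled validation scores the inner AUC is coarse and often
    ties at its maximum across many candidates.  ``tie_break`` controls the
    resolution: ``"centroid"`` (default) refits at the average of all tied
    weight vectors — deterministic and symmetric in the modalities — while
    ``"first"`` takes the lexicographically first tied grid point.  C ties
    resolve to the smallest C either way.
    """
    if tie_break not in ("centroid", "first"):
        raise ValueError(f"tie_break must be 'centroid' or 'first', got {tie_break!r}")
    n = dataset.n
    if n < 10:
        raise ValueError(f"nested CV needs at least 10 subjects, got {n}")
    if (dataset.y > 0).sum() < 2 or (dataset.y < 0).sum() < 2:
        raise ValueError("each class needs at least 2 subjects")
    kernel_specs = dict(kernel_specs or default_kernel_specs(dataset))
    modalities = dataset.modalities
    M = len(modalities)
    if grid is None:
        grid = simplex_grid(M, 0.05)
    if grid.M != M:
        raise ValueError(f"grid is over {grid.M} modalities, dataset has {M}")
    C_options = tuple(float(c) for c in C_options)
    y = dataset.y
    n_candidates = len(grid) * len(C_options)

    scores = np.empty(n)
    chosen_beta = np.empty((n, M))
    chosen_C = np.empty(n)
    all_rows = np.arange(n)

    for i in range(n):
        outer_train = np.delete(all_rows, i)
        y_tr = y[outer_train]
        skf = StratifiedKFold(n_splits=inner_folds, shuffle=True,
                              random_state=(seed + i) % (2**31 - 1))
        pooled_scores = [[] for _ in range(n_candidates)]
        pooled_labels: list[float] = []
        for tr_loc, va_loc in skf.split(np.zeros(y_tr.size), y_tr):
            rows = outer_train  # restrict all kernels to the outer training set
            kernels = _modality_kernels(dataset, kernel_specs, rows, tr_loc)
            pooled_labels.extend(y_tr[va_loc])
            c_idx = 0
            for beta in grid:
                bw = KernelWeights(beta, modalities)
                K = combine_kernels(kernels, bw)
                K_tr = K.submatrix(tr_loc)
                K_va = K.submatrix(va_loc, tr_loc)
                for C in C_options:
                    model = fit_svm(K_tr, y_tr[tr_loc], C=C, check_psd=False)
                    pooled_scores[c_idx].extend(decision_function(model, K_va))
                    c_idx += 1
        labels_arr = np.asarray(pooled_labels)
        aucs = np.array([_fast_auc(labels_arr, np.asarray(s)) for s in pooled_scores])
        tied = np.flatnonzero(aucs >= aucs.max() - 1e-12)
        if tie_break == "first":
            best = int(tied[0])  # grid is lexicographically ordered
            beta = np.asarray(grid.points[best // len(C_options)])
            C = C_options[best % len(C_options)]
        else:
            beta = np.mean([grid.points[t // len(C_options)] for t in tied], axis=0)
            C = min(C_options[t % len(C_options)] for t in tied)
        chosen_beta[i] = beta
        chosen_C[i] = C

        kernels = _modality_kernels(dataset, kernel_specs, all_rows, outer_train)
        scores[i] = _fit_and_score(
            kernels, KernelWeights(beta, modalities), y, outer_train,
            np.array([i]), C,
        )[0]

    y_pred = np.where(scores >= 0, 1.0, -1.0)
    return CVResult(
        subject_ids=dataset.subject_ids, y_true=y.copy(), scores=scores,
        y_pred=y_pred, modalities=modalities, fold_weights=chosen_beta,
        fold_C=chosen_C, method="mk_svm_nested",
        meta={"grid_step": grid.step, "C_options": list(C_options),
              "inner_folds": inner_folds, "seed": seed},
    )


# ---------------------------------------------------------------------------
# Baseline harness


BASELINE_METHODS = ("svm", "svm_stacked", "random_forest", "gradient_boosting", "mlp")
BASELINE_MODALITIES = ("clinical", "eeg", "pet", "all_stacked")


def _make_baseline(method: str, seed: int, C: float):
    from sklearn.neural_network import MLPClassifier
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.svm import SVC

    if method in ("svm", "svm_stacked"):
        return SVC(kernel="linear", C=C)
    if method == "random_forest":
        return RandomForestClassifier(n_estimators=200, random_state=seed)
    if method == "gradient_boosting":
        from xgboost import XGBClassifier
        return XGBClassifier(n_estimators=100, max_depth=3, learning_rate=0.3,
                             random_state=seed, verbosity=0, eval_metric="logloss")
    if method == "mlp":
        return MLPClassifier(hidden_layer_sizes=(32,), early_stopping=True,
                             random_state=seed, max_iter=1000)
    raise ValueError(f"unknown method {method!r}; options: {BASELINE_METHODS}")


def baseline_harness(
    dataset: MultimodalDataset,
    method: str = "svm_stacked",
    modality: str = "all_stacked",
    C: float = 1.0,
    seed: int = 0,
) -> CVResult:
    """LOOCV of a conventional classifier on one modality or stacked features.

    The stacked mode concatenates every block into a single long feature
    vector — the conventional fusion the kernel combination is compared
    against.  Classifiers are the established scikit-learn / xgboost
    implementations; features are z-scored on each training fold.
    """
    if method not in BASELINE_METHODS:
        raise ValueError(f"unknown method {method!r}; options: {BASELINE_METHODS}")
    if modality == "all_stacked":
        X = dataset.stacked().to_numpy(dtype=float)
    elif modality in dataset.blocks:
        X = dataset.blocks[modality].to_numpy(dtype=float)
    else:
        raise ValueError(
            f"unknown modality {modality!r}; options: "
            f"{tuple(dataset.modalities) + ('all_stacked',)}"
        )
    y = dataset.y
    y01 = (y > 0).astype(int)
    n = dataset.n
    scores = np.empty(n)
    for i in range(n):
        train = np.delete(np.arange(n), i)
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0)
        sd[sd == 0] = 1.0
        Z = (X - mu) / sd
        clf = _make_baseline(method, seed, C)
        clf.fit(Z[train], y01[train])
        if hasattr(clf, "decision_function"):
            scores[i] = float(clf.decision_function(Z[[i]])[0])
        else:
            scores[i] = float(clf.predict_proba(Z[[i]])[0, 1]) - 0.5
    y_pred = np.where(scores >= 0, 1.0, -1.0)
    return CVResult(
        subject_ids=dataset.subject_ids, y_true=y.copy(), scores=scores,
        y_pred=y_pred, modalities=dataset.modalities,
        method=f"{method}:{modality}", meta={"seed": seed, "C": C},
    )
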