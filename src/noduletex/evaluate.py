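"""RBF-kernel SVM evaluation with the seven assessment criteria.

The classifier is a soft-margin SVM with Gaussian radial basis kernel
``K(x, z) = exp(-gamma ||x - z||^2)``.  Performance is summarised by seven
criteria: sensitivity, specificity, accuracy, precision, Youden index,
F-measure and ROC AUC, computed from confusion counts pooled over the
held-out folds of a stratified k-fold cross-validation.

The ROC ranking variable ("malignant rate") is the classifier's continuous
decision value mapped monotonically to [0, 1]; AUC is invariant under any
strictly monotone transform of the scores, so this choice is canonical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import expit, ndtr
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from noduletex.smote import Dataset, smote_oversample

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "KernelConfig",
    "SmoteProfile",
    "compute_metrics",
    "roc_auc",
    "auc_pvalue",
    "train_rbf_svm",
    "cross_validate",
    "stratified_eval",
    "DIAMETER_GROUPS",
]


@dataclass
class ConfusionCounts:
    """Binary confusion counts; malignant is the positive class.

    ``a_tp``: malignant called malignant, ``b_fn``: malignant called benign,
    ``c_tn``: benign called benign, ``d_fp``: benign called malignant.
    """

    a_tp: int
    b_fn: int
    c_tn: int
    d_fp: int

    def __post_init__(self) -> None:
        if min(self.a_tp, self.b_fn, self.c_tn, self.d_fp) < 0:
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return self.a_tp + self.b_fn + self.c_tn + self.d_fp


@dataclass
class MetricsReport:
    sensitivity: float
    specificity: float
    accuracy: float
    precision: float
    youden: float
    f_measure: float
    auc: Optional[float] = None
    n_folds: Optional[int] = None
    per_fold: Optional[List[dict]] = None
    n: Optional[int] = None

    def as_dict(self) -> dict:
        out = {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "youden": self.youden,
            "f_measure": self.f_measure,
        }
        if self.auc is not None:
            out["auc"] = self.auc
        return out


@dataclass(frozen=True)
class KernelConfig:
    """Gaussian RBF kernel hyper-parameters.

    ``gamma=None`` uses 1 / (d * var(X)) on the training fold (the common
    heuristic); ``cost`` is the soft-margin penalty C.
    """

    gamma: Optional[float] = None
    cost: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.cost <= 0:
            raise ValueError("cost must be positive")


@dataclass(frozen=True)
class SmoteProfile:
    """How to rebalance inside cross-validation.

    ``mode='within-fold'`` applies SMOTE to each training fold only;
    ``mode='whole-dataset'`` reproduces the study-style application to all
    data before splitting (optimistic; retained for comparison);
    ``mode='off'`` disables balancing.
    """

    mode: str = "within-fold"
    amount_pct: int = 300
    k: int = 5

    def __post_init__(self) -> None:
        if self.mode not in ("off", "within-fold", "whole-dataset"):
            raise ValueError(f"unknown SMOTE mode {self.mode!r}")


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        raise ZeroDivisionError(f"{name} undefined: zero denominator")
    return num / den


def compute_metrics(c: ConfusionCounts, beta: float = 1.0) -> MetricsReport:
    """Sensitivity, specificity, accuracy, precision, Youden and F-measure.

    Raises on any undefined ratio rather than silently reporting 0.
    """
    sens = _ratio(c.a_tp, c.a_tp + c.b_fn, "sensitivity")
    spec = _ratio(c.c_tn, c.c_tn + c.d_fp, "specificity")
    acc = _ratio(c.a_tp + c.c_tn, c.total, "accuracy")
    prec = _ratio(c.a_tp, c.a_tp + c.d_fp, "precision")
    youden = sens + spec - 1.0
    f = _ratio((1 + beta ** 2) * prec * sens,
               beta ** 2 * prec + sens, "f_measure")
    return MetricsReport(sensitivity=sens, specificity=spec, accuracy=acc,
                         precision=prec, youden=youden, f_measure=f,
                         n=c.total)


def roc_auc(scores: Sequence[float], labels: Sequence[int]
            ) -> Tuple[float, np.ndarray]:
    """ROC curve and trapezoidal AUC by sweeping score thresholds.

    Tie groups are handled by the trapezoid across each distinct score,
    which equals the pair-counting (Mann-Whitney) estimator with ties
    counted one half.  Returns ``(auc, points)`` with points as an array of
    (fpr, tpr) rows from (0,0) to (1,1).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == labels.max()
    n_pos = int(pos.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0 or len(np.unique(labels)) != 2:
        raise ValueError("both classes required")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    p = pos[order]
    # counts per distinct score, descending
    boundaries = np.flatnonzero(np.diff(s)) + 1
    tp_cum = np.add.reduceat(p.astype(float),
                             np.concatenate([[0], boundaries])).cumsum()
    fp_cum = np.add.reduceat((~p).astype(float),
                             np.concatenate([[0], boundaries])).cumsum()
    tpr = np.concatenate([[0.0], tp_cum / n_pos])
    fpr = np.concatenate([[0.0], fp_cum / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return auc, np.column_stack([fpr, tpr])


def auc_pvalue(auc: float, n_pos: int, n_neg: int) -> float:
    """Two-sided p for AUC != 0.5 via the Mann-Whitney normal approximation
    (no-tie variance)."""
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("counts must be positive")
    u = auc * n_pos * n_neg
    mu = n_pos * n_neg / 2.0
    sigma = math.sqrt(n_pos * n_neg * (n_pos + n_neg + 1) / 12.0)
    z = (u - mu) / sigma
    return float(2.0 * (1.0 - ndtr(abs(z))))


class FittedSVM:
    """Fitted classifier handle: hard labels plus continuous malignancy
    scores (decision value and its monotone [0,1] map)."""

    def __init__(self, svc: SVC, scaler: StandardScaler, positive_label):
        self._svc = svc
        self._scaler = scaler
        self.positive_label = positive_label

    def decision(self, X: np.ndarray) -> np.ndarray:
        return self._svc.decision_function(self._scaler.transform(X))

    def malignant_rate(self, X: np.ndarray) -> np.ndarray:
        return expit(self.decision(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._svc.predict(self._scaler.transform(X))


def train_rbf_svm(train: Dataset, cfg: KernelConfig = KernelConfig()
                  ) -> FittedSVM:
    """Fit the RBF-kernel SVM on standardized features."""
    classes, counts = np.unique(train.y, return_counts=True)
    if len(classes) != 2 or counts.min() < 2:
        raise ValueError("need at least 2 samples in each of 2 classes")
    if not np.isfinite(train.X).all():
        raise ValueError("non-finite features")
    scaler = StandardScaler().fit(train.X)
    Xs = scaler.transform(train.X)
    gamma = cfg.gamma if cfg.gamma is not None else "scale"
    svc = SVC(kernel="rbf", C=cfg.cost, gamma=gamma,
              random_state=cfg.seed)
    svc.fit(Xs, train.y)
    return FittedSVM(svc, scaler, positive_label=classes.max())


def _fold_splitter(ds: Dataset, folds: int, grouping: str, seed: int):
    y = ds.y
    if grouping == "roi":
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        return cv.split(ds.X, y)
    if grouping == "patient":
        cv = StratifiedGroupKFold(n_splits=folds, shuffle=True,
                                  random_state=seed)
        return cv.split(ds.X, y, groups=ds.groups)
    raise ValueError(f"unknown grouping {grouping!r}")


def cross_validate(ds: Dataset, cfg: KernelConfig = KernelConfig(),
                   folds: int = 10, grouping: str = "roi",
                   balance: SmoteProfile | None = None,
                   beta: float = 1.0) -> MetricsReport:
    """Stratified k-fold cross-validation with pooled metrics.

    Every sample is predicted exactly once; confusion counts and ROC scores
    are pooled over held-out predictions.  With ``grouping='patient'`` all
    ROIs of a patient share a fold.  SMOTE, when requested, is applied
    within training folds only unless the profile says ``whole-dataset``.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    classes, counts = np.unique(ds.y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    if grouping == "roi" and counts.min() < folds:
        raise ValueError("fold count exceeds smallest class size")
    balance = balance or SmoteProfile(mode="off")
    eval_ds = ds
    if balance.mode == "whole-dataset":
        from noduletex.smote import balance_dataset
        eval_ds = balance_dataset(ds, amount_pct=balance.amount_pct,
                                  k=balance.k, majority_target="match",
                                  seed=cfg.seed)
    pos_label = classes.max()
    scores = np.full(eval_ds.n, np.nan)
    preds = np.empty(eval_ds.n, dtype=eval_ds.y.dtype)
    per_fold = []
    for fold_i, (tr, te) in enumerate(
            _fold_splitter(eval_ds, folds, grouping, cfg.seed)):
        Xtr, ytr = eval_ds.X[tr], eval_ds.y[tr]
        if balance.mode == "within-fold":
            lab, cnt = np.unique(ytr, return_counts=True)
            minority = lab[np.argmin(cnt)]
            if cnt.min() > balance.k:
                synth = smote_oversample(Xtr[ytr == minority],
                                         balance.amount_pct, balance.k,
                                         seed=cfg.seed + 101 * fold_i)
                Xtr = np.vstack([Xtr, synth])
                ytr = np.concatenate(
                    [ytr, np.full(len(synth), minority, dtype=ytr.dtype)])
        fold_train = Dataset(X=Xtr, y=ytr,
                             groups=np.full(len(ytr), "", dtype=object),
                             feature_names=list(eval_ds.feature_names))
        model = train_rbf_svm(fold_train, cfg)
        scores[te] = model.decision(eval_ds.X[te])
        preds[te] = model.predict(eval_ds.X[te])
        per_fold.append({"fold": fold_i, "n_test": int(len(te))})
    evaluated = ~np.isnan(scores)
    y = eval_ds.y[evaluated]
    c = ConfusionCounts(
        a_tp=int(((preds[evaluated] == pos_label) & (y == pos_label)).sum()),
        b_fn=int(((preds[evaluated] != pos_label) & (y == pos_label)).sum()),
        c_tn=int(((preds[evaluated] != pos_label) & (y != pos_label)).sum()),
        d_fp=int(((preds[evaluated] == pos_label) & (y != pos_label)).sum()),
    )
    report = compute_metrics(c, beta=beta)
    report.auc = roc_auc(scores[evaluated], (y == pos_label).astype(int))[0]
    report.n_folds = folds
    report.per_fold = per_fold
    return report


def grid_search(ds: Dataset, gammas: Sequence[Optional[float]] = (None, 0.01, 0.1),
                costs: Sequence[float] = (0.1, 1.0, 10.0), folds: int = 5,
                grouping: str = "roi", seed: int = 0) -> Tuple[KernelConfig, float]:
    """Small CV grid search over (gamma, cost); returns the best config and
    its AUC.  Off by default everywhere — the standard pipeline runs with
    the fixed heuristic hyper-parameters."""
    best: Tuple[KernelConfig, float] | None = None
    for gamma in gammas:
        for cost in costs:
            cfg = KernelConfig(gamma=gamma, cost=cost, seed=seed)
            auc = cross_validate(ds, cfg, folds=folds, grouping=grouping).auc
            if best is None or auc > best[1]:
                best = (cfg, auc)
    assert best is not None
    return best


#: Table-style diameter strata in mm (closed intervals on rounded diameters)
DIAMETER_GROUPS: Dict[str, Tuple[int, int]] = {
    "A": (7, 10),
    "B": (11, 20),
    "C": (21, 30),
    "A+B": (7, 20),
}


def stratified_eval(ds: Dataset, diameter_mm: Sequence[float],
                    cfg: KernelConfig = KernelConfig(), folds: int = 10,
                    grouping: str = "roi",
                    balance: SmoteProfile | None = None) -> Dict[str, MetricsReport]:
    """Cross-validated metrics per nodule-size group.

    Groups are A: 7-10 mm, B: 11-20 mm, C: 21-30 mm and the pooled A+B,
    with membership decided on diameters rounded to whole millimetres.
    Groups whose class sizes cannot support the fold count are reported as
    absent (omitted from the result), not as zeros.
    """
    diameter_mm = np.asarray(diameter_mm, dtype=float)
    if len(diameter_mm) != ds.n:
        raise ValueError("diameter vector does not match dataset")
    rounded = np.round(diameter_mm)
    out: Dict[str, MetricsReport] = {}
    for name, (lo, hi) in DIAMETER_GROUPS.items():
        mask = (rounded >= lo) & (rounded <= hi)
        if not mask.any():
            continue
        sub = Dataset(X=ds.X[mask], y=ds.y[mask], groups=ds.groups[mask],
                      feature_names=list(ds.feature_names))
        classes, counts = np.unique(sub.y, return_counts=True)
        if len(classes) != 2 or counts.min() < folds:
            continue
        out[name] = cross_validate(sub, cfg, folds=folds, grouping=grouping,
                                   balance=balance)
    return out
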