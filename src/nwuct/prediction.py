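"""Malignant-edema prediction: classifiers, LOOCV, ROC and paired-AUC tests.

Three standard classifiers (SVM, logistic regression, random forest) are
configured through scikit-learn with library defaults — the contribution
here is the evaluation harness, not the learners.  Models are scored by
leave-one-out cross-validation: n folds, standardisation (for the
scale-sensitive SVM/LR) fitted on each training fold only, and all metrics
computed on the pooled held-out predictions.

Confusion-matrix metrics include the Matthews correlation coefficient,
which uses all four cells and is robust to the 39/77 class imbalance of a
typical MCE cohort.  Paired AUCs are compared with DeLong's nonparametric
test via midrank structural components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ModelConfig",
    "ConfusionMatrix",
    "EvalReport",
    "confusion_metrics",
    "reconstruct_confusion",
    "roc_auc",
    "youden_cutoff",
    "delong_test",
    "loocv_evaluate",
    "rf_grid_search",
    "time_normalized_nwu",
    "round_half_up",
]

RF_RANDOM_STATE_GRID = tuple(range(2, 17, 2))        # 2..16 step 2
RF_N_ESTIMATORS_GRID = tuple(range(100, 1001, 100))  # 100..1000 step 100


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties away from zero, matching printed-report precision."""
    factor = 10.0**decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class ModelConfig:
    classifier: Literal["svm", "lr", "rf"] = "rf"
    feature_set: str = "nwu_clinical_imaging"
    rf_random_state: int = 10
    rf_n_estimators: int = 100
    rf_random_state_grid: tuple[int, ...] = RF_RANDOM_STATE_GRID
    rf_n_estimators_grid: tuple[int, ...] = RF_N_ESTIMATORS_GRID
    standardize: Optional[bool] = None  # None = auto: SVM/LR yes, RF no
    seed: int = 0

    def __post_init__(self) -> None:
        if self.classifier not in ("svm", "lr", "rf"):
            raise ValueError(f"unsupported classifier {self.classifier!r}")
        if not self.rf_random_state_grid or not self.rf_n_estimators_grid:
            raise ValueError("hyperparameter grids must be non-empty")

    @property
    def standardize_effective(self) -> bool:
        if self.standardize is not None:
            return self.standardize
        return self.classifier in ("svm", "lr")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class EvalReport:
    scores: np.ndarray
    predictions: np.ndarray
    labels: np.ndarray
    confusion: ConfusionMatrix
    metrics: dict[str, float]
    roc: tuple[np.ndarray, np.ndarray, np.ndarray]  # fpr, tpr, thresholds
    auc: float
    config: Optional[ModelConfig] = None


def confusion_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """ACC/SEN/SPE/PPV/NPV/F1/MCC for a binary matrix (positive class = MCE).

    Any metric with a zero denominator is reported as 0.0 together with a
    ``degenerate_mcc``/``degenerate`` flag.
    """
    tp, fp, tn, fn = cm.tp, cm.fp, cm.tn, cm.fn
    n = cm.n
    if n == 0:
        raise ValueError("empty confusion matrix")

    def ratio(num, den):
        return num / den if den > 0 else 0.0

    acc = (tp + tn) / n
    sen = ratio(tp, tp + fn)
    spe = ratio(tn, tn + fp)
    ppv = ratio(tp, tp + fp)
    npv = ratio(tn, tn + fn)
    f1 = ratio(2 * tp, 2 * tp + fp + fn)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    degenerate_mcc = denom == 0
    mcc = 0.0 if degenerate_mcc else (tp * tn - fp * fn) / math.sqrt(denom)
    return {
        "acc": acc, "sen": sen, "spe": spe, "ppv": ppv, "npv": npv,
        "f1": f1, "mcc": mcc, "degenerate_mcc": float(degenerate_mcc),
    }


def reconstruct_confusion(
    sen: float, spe: float, n_pos: int, n_neg: int, decimals: int = 2
) -> ConfusionMatrix:
    """Recover the integer confusion matrix behind printed SEN/SPE values.

    Searches all integer (tp, tn) with the given group sizes whose
    sensitivity and specificity round (half-up) to the printed values;
    errors out unless exactly one matrix is consistent.
    """
    tps = [t for t in range(n_pos + 1) if round_half_up(t / n_pos, decimals) == sen]
    tns = [t for t in range(n_neg + 1) if round_half_up(t / n_neg, decimals) == spe]
    if len(tps) != 1 or len(tns) != 1:
        raise ValueError(
            f"printed SEN/SPE do not identify a unique matrix "
            f"({len(tps)} x {len(tns)} candidates)"
        )
    tp, tn = tps[0], tns[0]
    return ConfusionMatrix(tp=tp, fp=n_neg - tn, tn=tn, fn=n_pos - tp)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def _check_two_classes(labels: np.ndarray) -> None:
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present")


def roc_auc(
    scores: Sequence[float] | np.ndarray, labels: Sequence[int] | np.ndarray
) -> tuple[tuple[np.ndarray, np.ndarray, np.ndarray], float]:
    """ROC curve (thresholds descending) and AUC.

    The AUC equals the Mann-Whitney probability that a random positive
    outscores a random negative, ties counted one half.
    """
    from sklearn.metrics import roc_curve

    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    _check_two_classes(labels)
    fpr, tpr, thr = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return (fpr, tpr, thr), auc


def youden_cutoff(roc: tuple[np.ndarray, np.ndarray, np.ndarray]) -> float:
    """Threshold maximising Youden's J = TPR - FPR (lowest threshold on ties)."""
    fpr, tpr, thr = roc
    if thr.size == 0:
        raise ValueError("empty ROC curve")
    j = tpr - fpr
    best = np.flatnonzero(j == j.max())
    # roc_curve thresholds are descending; the last tied index is the lowest
    idx = int(best[-1])
    t = float(thr[idx])
    if np.isinf(t):  # sklearn's sentinel above the max score
        t = float(thr[min(idx + 1, thr.size - 1)])
    return t


# ---------------------------------------------------------------------------
# DeLong's test for paired AUCs
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_auc_variance(scores: np.ndarray, labels: np.ndarray):
    """AUCs and their covariance via midrank structural components.

    ``scores`` has one row per model; positives are labels == 1.
    """
    pos = scores[:, labels == 1]
    neg = scores[:, labels == 0]
    m, n = pos.shape[1], neg.shape[1]
    k = scores.shape[0]
    aucs = np.empty(k)
    v_pos = np.empty((k, m))
    v_neg = np.empty((k, n))
    for r in range(k):
        all_ranks = _midrank(np.concatenate([pos[r], neg[r]]))
        pos_ranks = _midrank(pos[r])
        neg_ranks = _midrank(neg[r])
        aucs[r] = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        v_pos[r] = (all_ranks[:m] - pos_ranks) / n
        v_neg[r] = 1.0 - (all_ranks[m:] - neg_ranks) / m
    s_pos = np.cov(v_pos) if k > 1 else np.atleast_2d(np.var(v_pos, ddof=1))
    s_neg = np.cov(v_neg) if k > 1 else np.atleast_2d(np.var(v_neg, ddof=1))
    cov = np.atleast_2d(s_pos) / m + np.atleast_2d(s_neg) / n
    return aucs, cov


def delong_test(
    scores_a: Sequence[float] | np.ndarray,
    scores_b: Sequence[float] | np.ndarray,
    labels: Sequence[int] | np.ndarray,
) -> tuple[float, float, float, float]:
    """Two-sided DeLong test for the difference of two correlated AUCs.

    Returns ``(auc_a, auc_b, z, p)``.  Identical score vectors (or any pair
    with zero AUC difference) give p = 1; a zero-variance difference with
    unequal AUCs is an error.
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if a.shape != b.shape or a.shape[0] != labels.shape[0]:
        raise ValueError("scores_a, scores_b and labels must have equal length")
    _check_two_classes(labels)
    aucs, cov = _delong_auc_variance(np.vstack([a, b]), labels)
    delta = aucs[0] - aucs[1]
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var <= 0:
        if abs(delta) < 1e-12:
            return float(aucs[0]), float(aucs[1]), 0.0, 1.0
        raise ValueError("zero variance of the AUC difference with unequal AUCs")
    z = delta / math.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return float(aucs[0]), float(aucs[1]), float(z), float(p)


# ---------------------------------------------------------------------------
# LOOCV
# ---------------------------------------------------------------------------

def _make_classifier(config: ModelConfig):
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.svm import SVC

    if config.classifier == "svm":
        return SVC(kernel="rbf", random_state=config.seed)
    if config.classifier == "lr":
        return LogisticRegression(max_iter=1000, random_state=config.seed)
    return RandomForestClassifier(
        n_estimators=config.rf_n_estimators,
        random_state=config.rf_random_state,
    )


def _decision_scores(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


def loocv_evaluate(
    features: np.ndarray,
    labels: Sequence[int] | np.ndarray,
    config: ModelConfig,
) -> EvalReport:
    """Leave-one-out evaluation of one classifier configuration.

    One fold per subject; standardisation statistics (when applicable) come
    from the training fold only, so no information leaks from the held-out
    subject.  Metrics, ROC and AUC are computed on the pooled held-out
    scores and predicted labels.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n < 3:
        raise ValueError("LOOCV needs at least 3 subjects")
    _check_two_classes(y)

    scores = np.empty(n)
    preds = np.empty(n, dtype=int)
    standardize = config.standardize_effective
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        Xtr, Xte = X[train], X[~train]
        if standardize:
            mu = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0)
            sd[sd == 0] = 1.0
            Xtr = (Xtr - mu) / sd
            Xte = (Xte - mu) / sd
        model = _make_classifier(config)
        model.fit(Xtr, y[train])
        scores[i] = _decision_scores(model, Xte)[0]
        preds[i] = int(model.predict(Xte)[0])

    cm = ConfusionMatrix(
        tp=int(((preds == 1) & (y == 1)).sum()),
        fp=int(((preds == 1) & (y == 0)).sum()),
        tn=int(((preds == 0) & (y == 0)).sum()),
        fn=int(((preds == 0) & (y == 1)).sum()),
    )
    metrics = confusion_metrics(cm)
    roc, auc = roc_auc(scores, y)
    return EvalReport(
        scores=scores, predictions=preds, labels=y,
        confusion=cm, metrics=metrics, roc=roc, auc=auc, config=config,
    )


def rf_grid_search(
    features: np.ndarray,
    labels: Sequence[int] | np.ndarray,
    config: Optional[ModelConfig] = None,
) -> tuple[tuple[int, int], list[dict]]:
    """Exhaustive (random_state, n_estimators) search scored by LOOCV AUC.

    The whole grid is scored (80 combinations for the default grids); ties
    are broken toward the smallest n_estimators, then smallest random_state.
    Returns the winning pair and the full score table.
    """
    config = config or ModelConfig(classifier="rf")
    table: list[dict] = []
    for rs in config.rf_random_state_grid:
        for ne in config.rf_n_estimators_grid:
            c = ModelConfig(
                classifier="rf",
                feature_set=config.feature_set,
                rf_random_state=rs,
                rf_n_estimators=ne,
                rf_random_state_grid=config.rf_random_state_grid,
                rf_n_estimators_grid=config.rf_n_estimators_grid,
                standardize=config.standardize,
                seed=config.seed,
            )
            report = loocv_evaluate(features, labels, c)
            table.append({"random_state": rs, "n_estimators": ne, "auc": report.auc})
    best = max(table, key=lambda r: (r["auc"], -r["n_estimators"], -r["random_state"]))
    return (best["random_state"], best["n_estimators"]), table


def time_normalized_nwu(nwu: float, t_hours: float) -> tuple[float, float]:
    """Time-normalised NWU variants: NWU/t and NWU/log(t+1) (natural log)."""
    if t_hours <= 0:
        raise ValueError("t_hours must be positive")
    return nwu / t_hours, nwu / math.log(t_hours + 1.0)
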