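"""Cross-validation and performance metrics for rule models.

Stratified k-fold CV with per-fold refitting of the whole pipeline
(discretization included, so cut-points never see test rows unless
``paper_mode`` deliberately fits them once on the full table).  Metrics:
accuracy, sensitivity, specificity from the pooled confusion matrix,
and AUC as the Mann-Whitney statistic with midrank tie handling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import rankdata
from sklearn.base import clone

from .cohort import CohortTable
from .discretize import EBDiscretizer

DEFAULT_SEED = 20150813
DEFAULT_LAMBDA_GRID = tuple(np.arange(0.5, 4.01, 0.5))

__all__ = [
    "CVReport",
    "stratified_folds",
    "confusion_metrics",
    "auc",
    "cross_validate",
    "lambda_sweep",
    "DEFAULT_SEED",
    "DEFAULT_LAMBDA_GRID",
]


@dataclass
class CVReport:
    """Results of one cross-validated evaluation."""

    k: int
    seed: int
    lambda_used: float
    per_fold: list[dict]
    pooled: dict

    def to_dict(self) -> dict:
        return asdict(self)


def stratified_folds(table: CohortTable, k: int, seed: int) -> np.ndarray:
    """Class-stratified fold assignment (array of fold ids, 0..k-1).

    Per-class and overall fold sizes each differ by at most one; the
    assignment is a deterministic function of the seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > table.n:
        raise ValueError(f"k = {k} exceeds the number of records {table.n}")
    rng = np.random.default_rng(seed)
    y = table.data[table.target_name].to_numpy()
    assignment = np.full(table.n, -1, dtype=int)
    fold_counts = [0] * k  # per-fold allocation so far, per class below
    fold_sizes = np.zeros(k, dtype=int)
    for lvl in table.target_levels:
        idx = np.nonzero(y == lvl)[0]
        rng.shuffle(idx)
        n_c = len(idx)
        base, extra = divmod(n_c, k)
        counts = np.full(k, base, dtype=int)
        # hand the remainder to the currently smallest folds, keeping the
        # overall fold sizes within one of each other
        order = np.lexsort((np.arange(k), fold_sizes))
        counts[order[:extra]] += 1
        pos = 0
        for f in range(k):
            assignment[idx[pos : pos + counts[f]]] = f
            pos += counts[f]
        fold_sizes += counts
    return assignment


def confusion_metrics(truth, predictions, positive_label) -> dict:
    """Accuracy, sensitivity, specificity of hard predictions."""
    truth = np.asarray(truth)
    predictions = np.asarray(predictions)
    if len(truth) != len(predictions):
        raise ValueError("truth and predictions must have equal length")
    if len(truth) == 0:
        raise ValueError("empty input")
    is_pos = truth == positive_label
    pred_pos = predictions == positive_label
    tp = int(np.sum(is_pos & pred_pos))
    fn = int(np.sum(is_pos & ~pred_pos))
    tn = int(np.sum(~is_pos & ~pred_pos))
    fp = int(np.sum(~is_pos & pred_pos))
    out = {
        "accuracy": (tp + tn) / len(truth),
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "confusion": {"tp": tp, "fn": fn, "tn": tn, "fp": fp},
    }
    return out


def auc(scores, binary_labels, positive_label=None) -> float:
    """Area under the ROC curve by the Mann-Whitney midrank statistic:
    P(score_pos > score_neg) + 0.5 * P(equal)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(binary_labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("AUC needs both classes present")
    if positive_label is None:
        positive_label = "Pos" if "Pos" in classes else sorted(classes)[-1]
    pos = labels == positive_label
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def cross_validate(
    table: CohortTable,
    estimator=None,
    k: int = 10,
    seed: int = DEFAULT_SEED,
    paper_mode: bool = False,
) -> CVReport:
    """Stratified k-fold CV of a rule-learning estimator on a cohort.

    ``estimator`` is a (possibly unfitted) :class:`BRLClassifier`; it is
    cloned per fold.  With ``paper_mode`` the discretization is fitted
    once on the full table before splitting (the classifier then sees
    only categorical columns); by default cut-points are learned inside
    each training fold.
    """
    from .learn import BRLClassifier

    if estimator is None:
        estimator = BRLClassifier()
    X_full = table.data[table.predictor_names].copy()
    y_full = table.data[table.target_name].to_numpy()
    positive = table.target_levels[0]

    if paper_mode:
        disc = EBDiscretizer(lam=getattr(estimator, "lam", 3.5)).fit(X_full, y_full)
        X_full = disc.transform(X_full)

    folds = stratified_folds(table, k, seed)
    pooled_truth, pooled_pred, pooled_score = [], [], []
    per_fold = []
    for f in range(k):
        test = folds == f
        est = clone(estimator)
        est.fit(X_full.loc[~test], y_full[~test])
        pred = est.predict(X_full.loc[test])
        score = est.positive_scores(X_full.loc[test])
        truth = y_full[test]
        fold_metrics = confusion_metrics(truth, pred, positive)
        fold_metrics["auc"] = (
            auc(score, truth, positive) if len(np.unique(truth)) == 2 else float("nan")
        )
        fold_metrics["n_test"] = int(test.sum())
        per_fold.append(fold_metrics)
        pooled_truth.append(truth)
        pooled_pred.append(pred)
        pooled_score.append(score)

    truth = np.concatenate(pooled_truth)
    pred = np.concatenate(pooled_pred)
    score = np.concatenate(pooled_score)
    pooled = confusion_metrics(truth, pred, positive)
    pooled["auc"] = auc(score, truth, positive)
    return CVReport(
        k=k,
        seed=seed,
        lambda_used=float(getattr(estimator, "lam", float("nan"))),
        per_fold=per_fold,
        pooled=pooled,
    )


def lambda_sweep(
    table: CohortTable,
    grid=None,
    k: int = 10,
    seed: int = DEFAULT_SEED,
    estimator=None,
    paper_mode: bool = False,
) -> tuple[float, dict[float, CVReport]]:
    """Evaluate a lambda grid and return the lowest lambda with the best
    pooled CV accuracy (AUC breaks accuracy ties)."""
    from .learn import BRLClassifier

    if grid is None:
        grid = DEFAULT_LAMBDA_GRID
    grid = [float(g) for g in grid]
    if not grid:
        raise ValueError("lambda grid must be non-empty")
    if estimator is None:
        estimator = BRLClassifier()
    reports: dict[float, CVReport] = {}
    for lam in grid:
        est = clone(estimator)
        est.set_params(lam=lam)
        reports[lam] = cross_validate(table, est, k=k, seed=seed, paper_mode=paper_mode)
    best = None
    for lam in sorted(reports):
        r = reports[lam]
        key = (r.pooled["accuracy"], r.pooled["auc"])
        if best is None or key[0] > best[1][0] + 1e-12 or (
            abs(key[0] - best[1][0]) <= 1e-12 and key[1] > best[1][1] + 1e-12
        ):
            best = (lam, key)
    return best[0], reports
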