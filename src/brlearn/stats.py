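"""Evidence statistics for classification rules.

Each rule is scored against the training cohort by its coverage: TP is
the number of covered records of the rule's predicted class, FP the
covered records of the other class.  Two statistics summarize the
evidence:

* the Laplace posterior ``(TP + 1) / (TP + FP + 2)`` — the posterior
  mean of the rule's class probability under a Beta(1, 1) prior;
* a one-sided Fisher exact p-value: the upper-tail hypergeometric
  probability of drawing at least TP predicted-class records when
  TP + FP records are sampled without replacement from the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import hypergeom

from .cohort import CohortTable
from .rules import Rule, RuleModel

__all__ = [
    "CoverageCounts",
    "rule_coverage",
    "rule_posterior",
    "rule_fisher_p",
    "annotate_model",
    "predict",
    "positive_score",
]


@dataclass(frozen=True)
class CoverageCounts:
    tp: int
    fp: int
    n_pred_class: int
    n_other: int

    def __post_init__(self) -> None:
        if not (0 <= self.tp <= self.n_pred_class and 0 <= self.fp <= self.n_other):
            raise ValueError(f"inconsistent coverage counts {self}")


def rule_coverage(rule: Rule, table: CohortTable) -> CoverageCounts:
    """Tally TP/FP coverage of one rule over the cohort."""
    for c in rule.conditions:
        spec = table.spec(c.variable)
        if spec.levels is not None and c.value not in spec.levels:
            raise ValueError(f"unknown level {c.value!r} for variable {c.variable!r}")
    covered = np.ones(table.n, dtype=bool)
    for c in rule.conditions:
        covered &= table.data[c.variable].astype(str).to_numpy() == c.value
    y = table.data[table.target_name].to_numpy()
    totals = table.class_counts()
    pred = rule.predicted_class
    other = [lvl for lvl in table.target_levels if lvl != pred][0]
    tp = int(np.sum(covered & (y == pred)))
    fp = int(np.sum(covered & (y == other)))
    return CoverageCounts(tp, fp, totals[pred], totals[other])


def rule_posterior(tp: int, fp: int) -> float:
    """Laplace-smoothed posterior of the rule's predicted class."""
    if tp < 0 or fp < 0:
        raise ValueError("counts must be non-negative")
    return (tp + 1.0) / (tp + fp + 2.0)


def rule_fisher_p(counts: CoverageCounts) -> float:
    """One-sided upper-tail Fisher exact p for a rule's coverage.

    P(X >= tp) with X ~ Hypergeom(N = n_pred_class + n_other,
    K = n_pred_class, draws = tp + fp).  An empty rule (tp = fp = 0)
    scores 1.
    """
    n_total = counts.n_pred_class + counts.n_other
    draws = counts.tp + counts.fp
    if draws == 0:
        return 1.0
    return float(hypergeom.sf(counts.tp - 1, n_total, counts.n_pred_class, draws))


def annotate_model(model: RuleModel, table: CohortTable) -> RuleModel:
    """Return a copy of the model with tp/fp/posterior/p on every rule.

    The default catch-all rule (if present) is scored on the residual
    records that no explicit rule covers.
    """
    y = table.data[table.target_name].to_numpy()
    totals = table.class_counts()
    matched = np.zeros(table.n, dtype=bool)
    columns: dict[str, np.ndarray] = {}
    explicit: list[tuple[Rule, np.ndarray]] = []
    for rule in model.rules:
        if rule.is_default:
            continue
        covered = np.ones(table.n, dtype=bool)
        for c in rule.conditions:
            if c.variable not in columns:
                columns[c.variable] = table.data[c.variable].astype(str).to_numpy()
            covered &= columns[c.variable] == c.value
        explicit.append((rule, covered))
        matched |= covered

    annotated = []
    for rule in model.rules:
        if rule.is_default:
            covered = ~matched
        else:
            covered = next(cov for r, cov in explicit if r is rule)
        pred = rule.predicted_class
        other = [lvl for lvl in table.target_levels if lvl != pred][0]
        tp = int(np.sum(covered & (y == pred)))
        fp = int(np.sum(covered & (y == other)))
        counts = CoverageCounts(tp, fp, totals[pred], totals[other])
        annotated.append(
            replace(
                rule,
                tp=tp,
                fp=fp,
                posterior=rule_posterior(tp, fp),
                p_value=rule_fisher_p(counts),
            )
        )
    return RuleModel(tuple(annotated), model.target_name, model.target_levels, model.search_kind)


def predict(model: RuleModel, record) -> tuple[str, float]:
    """Class and posterior from the unique rule matching the record."""
    rule = model.match(record)
    if rule.posterior is None:
        raise ValueError("model is not annotated; run annotate_model first")
    return rule.predicted_class, rule.posterior


def positive_score(model: RuleModel, record, positive: str | None = None) -> float:
    """Probability-style score for the positive class (for ROC/AUC)."""
    if positive is None:
        positive = model.target_levels[0]
    cls, post = predict(model, record)
    return post if cls == positive else 1.0 - post
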