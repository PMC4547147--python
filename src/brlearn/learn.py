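"""Bayesian rule learning: global parent-set search and decision-tree search.

Both searches score a candidate partition of the training records by the
K2-style log marginal likelihood of the binary target given the
partition, with all Dirichlet hyperparameters equal to 1:

    score(partition) = sum over groups g of
        log [ Gamma(C)/Gamma(C + N_g) * prod_c Gamma(1 + n_gc) ]

The score is decomposable over groups, so greedy moves are evaluated
locally.

* Global search grows a parent set of the target greedily: start from
  the highest-scoring single predictor, keep adding the predictor that
  most improves the score of the full cross-product partition, stop when
  no addition strictly improves it or ``max_parents`` is reached.  One
  rule is emitted per observed parent-value combination, plus a default
  catch-all rule so the model stays exhaustive on unseen records.

* Tree search (the local-structure variant) grows a decision tree: at
  each node the leaf's score term is replaced by the sum of its
  children's terms for the best unused split variable, accepted only on
  strict improvement.  Root-to-leaf paths become the rules, giving a
  more parsimonious model in which rules may use different variables.

Ties in greedy selection break toward the variable with fewer levels,
then the lexicographically smaller name.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .cohort import CohortError, CohortTable, VariableSpec
from .discretize import EBDiscretizer, interval_log_score, _as_frame
from .rules import Condition, Rule, RuleModel, TreeNode
from .stats import annotate_model

__all__ = ["bayes_score", "brl_global_search", "brl_tree_search", "tree_to_rules", "BRLClassifier"]

_TIE_TOL = 1e-9


def bayes_score(table: CohortTable, parent_partition) -> float:
    """Score of a disjoint, covering partition of the cohort's records.

    ``parent_partition`` is an iterable of row-index collections; the
    score is the sum of each group's class-count marginal likelihood.
    """
    y = table.data[table.target_name].to_numpy()
    seen = np.zeros(table.n, dtype=int)
    total = 0.0
    for group in parent_partition:
        idx = np.asarray(list(group), dtype=int)
        seen[idx] += 1
        total += interval_log_score([int(np.sum(y[idx] == lvl)) for lvl in table.target_levels])
    if not np.all(seen == 1):
        raise ValueError("partition must cover every record exactly once")
    return total


@dataclass
class _Encoded:
    """Integer-coded view of a categorical cohort for fast scoring."""

    codes: dict[str, np.ndarray]
    n_levels: dict[str, int]
    levels: dict[str, tuple[str, ...]]
    y: np.ndarray  # 0 = positive level, 1 = negative level
    table: CohortTable

    @classmethod
    def from_table(cls, table: CohortTable) -> "_Encoded":
        codes, n_levels, levels = {}, {}, {}
        for v in table.variables:
            if v.kind != "categorical":
                raise CohortError(
                    f"predictor {v.name!r} is continuous; discretize before rule learning"
                )
            lut = {lvl: i for i, lvl in enumerate(v.levels)}
            codes[v.name] = table.data[v.name].astype(str).map(lut).to_numpy(dtype=np.int64)
            n_levels[v.name] = len(v.levels)
            levels[v.name] = tuple(v.levels)
        y = (table.data[table.target_name].to_numpy() == table.target_levels[1]).astype(np.int64)
        return cls(codes, n_levels, levels, y, table)


def _counts_score(counts: np.ndarray) -> float:
    """Sum of interval scores over the rows of a (groups, 2) count matrix."""
    from scipy.special import gammaln

    counts = np.asarray(counts, dtype=float)
    n = counts.sum(axis=1)
    return float(np.sum(gammaln(2.0) - gammaln(2.0 + n) + gammaln(1.0 + counts).sum(axis=1)))


def _grouped_counts(group_ids: np.ndarray, n_groups: int, y: np.ndarray) -> np.ndarray:
    flat = np.bincount(group_ids * 2 + y, minlength=n_groups * 2)
    return flat.reshape(n_groups, 2)


def _partition_score(enc: _Encoded, parents: list[str], idx: np.ndarray | None = None) -> float:
    if idx is None:
        idx = np.arange(len(enc.y))
    if not parents:
        return interval_log_score(np.bincount(enc.y[idx], minlength=2))
    gid = np.zeros(len(idx), dtype=np.int64)
    n_groups = 1
    for p in parents:
        gid = gid * enc.n_levels[p] + enc.codes[p][idx]
        n_groups *= enc.n_levels[p]
    return _counts_score(_grouped_counts(gid, n_groups, enc.y[idx]))


def _majority(counts, target_levels: tuple[str, str], global_counts) -> str:
    """Majority class of a (pos, neg) count pair; ties fall back to the
    training table's majority, then the negative (second) level."""
    pos, neg = int(counts[0]), int(counts[1])
    if pos != neg:
        return target_levels[0] if pos > neg else target_levels[1]
    gpos, gneg = int(global_counts[0]), int(global_counts[1])
    if gpos != gneg:
        return target_levels[0] if gpos > gneg else target_levels[1]
    return target_levels[1]


# ---------------------------------------------------------------------------
# Global search


def brl_global_search(table: CohortTable, max_parents: int = 8) -> RuleModel:
    """Greedy parent-set growth under the Bayesian score."""
    if max_parents < 1:
        raise ValueError("max_parents must be >= 1")
    enc = _Encoded.from_table(table)
    global_counts = np.bincount(enc.y, minlength=2)
    names = sorted(enc.codes)
    if not names:
        rule = Rule((), _majority(global_counts, table.target_levels, global_counts), is_default=True)
        model = RuleModel((rule,), table.target_name, table.target_levels, "global")
        return annotate_model(model, table)

    chosen: list[str] = []
    current = _partition_score(enc, chosen)
    while len(chosen) < max_parents:
        best = None
        for name in names:
            if name in chosen:
                continue
            s = _partition_score(enc, chosen + [name])
            key = (-s, enc.n_levels[name], name)
            if best is None or _key_better(key, best[0]):
                best = (key, name, s)
        if best is None:
            break
        _, name, s = best
        # the first parent is always the highest-scoring single variable;
        # later additions must strictly improve the score
        if chosen and s <= current + _TIE_TOL:
            break
        chosen.append(name)
        current = s

    # one rule per observed combination, in level-product order
    gid = np.zeros(table.n, dtype=np.int64)
    n_groups = 1
    for p in chosen:
        gid = gid * enc.n_levels[p] + enc.codes[p]
        n_groups *= enc.n_levels[p]
    counts = _grouped_counts(gid, n_groups, enc.y)
    rules: list[Rule] = []
    for combo_idx, combo in enumerate(product(*(range(enc.n_levels[p]) for p in chosen))):
        if counts[combo_idx].sum() == 0:
            continue
        conditions = tuple(
            Condition(p, enc.levels[p][code]) for p, code in zip(chosen, combo)
        )
        rules.append(
            Rule(conditions, _majority(counts[combo_idx], table.target_levels, global_counts))
        )
    rules.append(
        Rule((), _majority((0, 0), table.target_levels, global_counts), is_default=True)
    )
    model = RuleModel(tuple(rules), table.target_name, table.target_levels, "global")
    return annotate_model(model, table)


def _key_better(a, b) -> bool:
    """Selection key comparison with a score tolerance: keys are
    (-score, n_levels, name)."""
    if abs(a[0] - b[0]) > _TIE_TOL:
        return a[0] < b[0]
    return a[1:] < b[1:]


# ---------------------------------------------------------------------------
# Tree search


def brl_tree_search(table: CohortTable, max_depth: int = 8) -> TreeNode:
    """Greedy local-structure (decision-tree) search."""
    if max_depth < 0:
        raise ValueError("max_depth must be >= 0")
    enc = _Encoded.from_table(table)
    global_counts = np.bincount(enc.y, minlength=2)
    idx = np.arange(table.n)
    return _grow(enc, idx, frozenset(), 0, max_depth, global_counts)


def _grow(
    enc: _Encoded,
    idx: np.ndarray,
    used: frozenset[str],
    depth: int,
    max_depth: int,
    global_counts: np.ndarray,
) -> TreeNode:
    counts = np.bincount(enc.y[idx], minlength=2)
    leaf = TreeNode(
        class_counts={
            enc.table.target_levels[0]: int(counts[0]),
            enc.table.target_levels[1]: int(counts[1]),
        },
        predicted_class=_majority(counts, enc.table.target_levels, global_counts),
    )
    if depth >= max_depth or len(idx) == 0 or np.count_nonzero(counts) <= 1:
        return leaf
    leaf_score = interval_log_score(counts)
    best = None
    for name in sorted(enc.codes):
        if name in used:
            continue
        split = _counts_score(
            _grouped_counts(enc.codes[name][idx], enc.n_levels[name], enc.y[idx])
        )
        key = (-split, enc.n_levels[name], name)
        if best is None or _key_better(key, best[0]):
            best = (key, name, split)
    if best is None or best[2] <= leaf_score + _TIE_TOL:
        return leaf
    _, name, _ = best
    children = {}
    codes = enc.codes[name][idx]
    for code, level in enumerate(enc.levels[name]):
        children[level] = _grow(
            enc, idx[codes == code], used | {name}, depth + 1, max_depth, global_counts
        )
    return TreeNode(split_variable=name, children=children)


def tree_to_rules(tree: TreeNode, table: CohortTable) -> RuleModel:
    """One rule per leaf, annotated and ordered for reporting.

    Rules predicting the negative (second) class are listed first, each
    class block sorted by descending posterior, then descending TP, then
    rule text — the layout used in clinical rule reports.
    """
    raw: list[Rule] = []

    def walk(node: TreeNode, conditions: tuple[Condition, ...]) -> None:
        if node.is_leaf:
            raw.append(Rule(conditions, node.predicted_class))
            return
        for level, child in node.children.items():
            walk(child, conditions + (Condition(node.split_variable, level),))

    walk(tree, ())
    model = RuleModel(tuple(raw), table.target_name, table.target_levels, "tree")
    model = annotate_model(model, table)
    pos, neg = table.target_levels

    def order_key(rule: Rule):
        return (
            0 if rule.predicted_class == neg else 1,
            -(rule.posterior or 0.0),
            -(rule.tp or 0),
            rule.render(table.target_name),
        )

    ordered = tuple(sorted(model.rules, key=order_key))
    return RuleModel(ordered, table.target_name, table.target_levels, "tree")


# ---------------------------------------------------------------------------
# Estimator


class BRLClassifier(ClassifierMixin, BaseEstimator):
    """Bayesian rule learning classifier over mixed biomarker tables.

    Continuous (numeric) columns are discretized internally with EBD
    using the ``lam`` prior; categorical columns are used as-is.  The
    fitted model is a mutually exclusive, exhaustive set of IF-THEN
    rules with per-rule posterior probabilities and Fisher exact
    p-values.

    Parameters
    ----------
    search : {"tree", "global"}, default "tree"
        Local-structure decision-tree search or global parent-set search.
    lam : float, default 3.5
        EBD lambda prior controlling the number of cut-points.
    max_parents : int, default 8
        Parent-set cap for the global search.
    max_depth : int, default 8
        Depth cap for the tree search.
    positive_label : str or None
        Which class is "positive" for scoring; defaults to ``"Pos"`` if
        present, else the lexicographically larger class label.
    target_name : str, default "MRDx"
        Name given to the target column in reports.

    Attributes
    ----------
    classes_ : ndarray of the two class labels (sorted)
    model_ : RuleModel, annotated on the training data
    tree_ : TreeNode, present when ``search == "tree"``
    discretizer_ : EBDiscretizer or None
    """

    def __init__(
        self,
        search: str = "tree",
        lam: float = 3.5,
        max_parents: int = 8,
        max_depth: int = 8,
        positive_label: str | None = None,
        target_name: str = "MRDx",
    ):
        self.search = search
        self.lam = lam
        self.max_parents = max_parents
        self.max_depth = max_depth
        self.positive_label = positive_label
        self.target_name = target_name

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y):
        if self.search not in ("tree", "global"):
            raise ValueError("search must be 'tree' or 'global'")
        X = _as_frame(X).reset_index(drop=True)
        y = np.asarray(y).astype(str)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError(f"expected a binary target, got classes {list(classes)}")
        self.classes_ = classes
        pos = self.positive_label
        if pos is None:
            pos = "Pos" if "Pos" in classes else sorted(classes)[-1]
        if pos not in classes:
            raise ValueError(f"positive_label {pos!r} not among classes {list(classes)}")
        neg = [c for c in classes if c != pos][0]
        target_levels = (pos, neg)

        if any(pd.api.types.is_numeric_dtype(X[c]) for c in X.columns):
            self.discretizer_ = EBDiscretizer(lam=self.lam).fit(X, y)
            Xd = self.discretizer_.transform(X)
        else:
            self.discretizer_ = None
            Xd = X.copy()

        variables = []
        for col in Xd.columns:
            if self.discretizer_ is not None and col in self.discretizer_.schemes_:
                levels = self.discretizer_.schemes_[col].labels
            else:
                levels = tuple(sorted(Xd[col].astype(str).unique()))
            variables.append(VariableSpec(col, "categorical", levels=levels))
            Xd[col] = Xd[col].astype(str)
        data = Xd.copy()
        if self.target_name in data.columns:
            raise ValueError(f"predictor column clashes with target name {self.target_name!r}")
        data[self.target_name] = y
        table = CohortTable(data, variables, self.target_name, target_levels)
        self.table_ = table

        if self.search == "tree":
            self.tree_ = brl_tree_search(table, max_depth=self.max_depth)
            self.model_ = tree_to_rules(self.tree_, table)
        else:
            self.tree_ = None
            self.model_ = brl_global_search(table, max_parents=self.max_parents)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def _records(self, X) -> list[dict]:
        X = _as_frame(X)
        if self.discretizer_ is not None:
            X = self.discretizer_.transform(X)
        return X.astype(str).to_dict("records")

    def predict(self, X):
        self._check_fitted()
        return np.asarray([self.model_.match(r).predicted_class for r in self._records(X)])

    def predict_proba(self, X):
        """Per-class probabilities from the matching rule's posterior."""
        self._check_fitted()
        out = np.empty((len(_as_frame(X)), 2))
        for i, rec in enumerate(self._records(X)):
            rule = self.model_.match(rec)
            post = rule.posterior if rule.posterior is not None else 0.5
            for j, cls in enumerate(self.classes_):
                out[i, j] = post if cls == rule.predicted_class else 1.0 - post
        return out

    def positive_scores(self, X) -> np.ndarray:
        """Score of the positive class per record (for ROC analysis)."""
        self._check_fitted()
        pos = self.model_.target_levels[0]
        j = int(np.nonzero(self.classes_ == pos)[0][0])
        return self.predict_proba(X)[:, j]

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise RuntimeError("BRLClassifier is not fitted")
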