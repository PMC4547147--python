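"""Rule learning: Bayesian score, greedy searches, tree-to-rules."""

import math
from itertools import product

import numpy as np
import pandas as pd
import pytest

from brlearn.cohort import CohortTable, VariableSpec
from brlearn.discretize import interval_log_score
from brlearn.learn import (
    BRLClassifier,
    _Encoded,
    _partition_score,
    bayes_score,
    brl_global_search,
    brl_tree_search,
    tree_to_rules,
)
from brlearn.rules import TreeNode


def make_table(columns: dict, y, target_levels=("Pos", "Neg")):
    data = pd.DataFrame({**columns, "MRDx": y})
    variables = [
        VariableSpec(name, "categorical", levels=tuple(sorted(set(vals))))
        for name, vals in columns.items()
    ]
    return CohortTable(data, variables, "MRDx", target_levels)


def tree_score(node: TreeNode) -> float:
    return sum(
        interval_log_score(list(leaf.class_counts.values())) for leaf in node.leaves()
    )


@pytest.fixture()
def signal_table():
    """One perfectly predictive binary variable among two noise columns."""
    rng = np.random.default_rng(5)
    n = 40
    y = np.where(np.arange(n) < 18, "Pos", "Neg")
    return make_table(
        {
            "signal": np.where(y == "Pos", "Yes", "No"),
            "noise1": rng.choice(["a", "b"], size=n),
            "noise2": rng.choice(["x", "y", "z"], size=n),
        },
        y,
    )


class TestBayesScore:
    def test_single_record_group_closed_form(self):
        t = make_table({"v": ["a"]}, ["Pos"])
        assert bayes_score(t, [[0]]) == pytest.approx(math.log(0.5))

    def test_decomposes_over_groups(self):
        t = make_table({"v": ["a", "b"]}, ["Pos", "Neg"])
        assert bayes_score(t, [[0], [1]]) == pytest.approx(2 * math.log(0.5))
        joint = bayes_score(t, [[0, 1]])
        assert joint == pytest.approx(interval_log_score((1, 1)))

    def test_partition_must_cover_exactly(self):
        t = make_table({"v": ["a", "b"]}, ["Pos", "Neg"])
        with pytest.raises(ValueError, match="cover"):
            bayes_score(t, [[0]])
        with pytest.raises(ValueError, match="cover"):
            bayes_score(t, [[0, 1], [1]])


class TestGlobalSearch:
    def test_dominant_variable_chosen_first(self, signal_table):
        model = brl_global_search(signal_table)
        assert "signal" in model.selected_variables

    def test_first_parent_is_single_variable_argmax(self, signal_table):
        """max_parents=1 reduces to an exhaustive single-variable scan."""
        model = brl_global_search(signal_table, max_parents=1)
        enc = _Encoded.from_table(signal_table)
        scores = {v: _partition_score(enc, [v]) for v in signal_table.predictor_names}
        assert model.selected_variables == {max(scores, key=scores.get)}

    def test_rules_cover_every_possible_record(self, signal_table):
        model = brl_global_search(signal_table)
        levels = {v.name: v.levels for v in signal_table.variables}
        names = list(levels)
        for combo in product(*(levels[n] for n in names)):
            record = dict(zip(names, combo))
            hits = model.matching_rules(record)
            assert len(hits) <= 1
            assert model.match(record) is not None

    def test_default_rule_handles_unseen_combination(self):
        t = make_table(
            {"a": ["x", "x", "y", "y"], "b": ["p", "p", "q", "q"]},
            ["Pos", "Pos", "Neg", "Neg"],
        )
        model = brl_global_search(t)
        # (x, q) never observed: the default rule must catch it
        rule = model.match({"a": "x", "b": "q"})
        if rule.is_default:
            assert rule.posterior == 0.5
            assert rule.p_value == 1.0

    def test_no_predictors_yields_single_default_rule(self):
        t = CohortTable(
            pd.DataFrame({"MRDx": ["Pos", "Neg", "Neg"]}), [], "MRDx"
        )
        model = brl_global_search(t)
        assert len(model.rules) == 1
        assert model.match({}) .predicted_class == "Neg"

    def test_greedy_steps_strictly_improve_score(self, signal_table):
        model = brl_global_search(signal_table)
        enc = _Encoded.from_table(signal_table)
        # recover the chosen parent order by re-running the scan greedily
        chosen = sorted(model.selected_variables)
        # score of each prefix of the (unordered) selected set must beat
        # the empty partition; full set beats any single removal
        full = _partition_score(enc, list(model.selected_variables))
        assert full > _partition_score(enc, []) - 1e-12
        if len(chosen) > 1:
            for v in chosen:
                reduced = [c for c in chosen if c != v]
                assert full > _partition_score(enc, reduced) + 1e-12


class TestTreeSearch:
    def test_pure_table_is_single_leaf(self):
        t = make_table({"v": ["a", "b", "a"]}, ["Neg", "Neg", "Neg"])
        tree = brl_tree_search(t)
        assert tree.is_leaf
        assert tree.predicted_class == "Neg"

    def test_strong_mde_effect_splits_root_on_mde(self):
        rng = np.random.default_rng(11)
        n = 200
        y = np.where(np.arange(n) < 80, "Pos", "Neg")
        mde = np.where(
            y == "Pos", rng.choice(["Yes", "No"], n, p=[0.85, 0.15]),
            rng.choice(["Yes", "No"], n, p=[0.03, 0.97]),
        )
        t = make_table({"MDE": mde, "noise": rng.choice(["a", "b"], n)}, y)
        tree = brl_tree_search(t)
        assert tree.split_variable == "MDE"
        assert tree.children["Yes"].predicted_class == "Pos"

    def test_each_split_improves_the_leaf_score(self, signal_table):
        tree = brl_tree_search(signal_table)

        def check(node):
            if node.is_leaf:
                return
            own = interval_log_score(list(node.total_counts().values()))
            children = sum(
                interval_log_score(list(c.total_counts().values()))
                for c in node.children.values()
            )
            assert children > own + 1e-12
            for c in node.children.values():
                check(c)

        check(tree)

    def test_leaf_counts_conserve_class_totals(self, signal_table):
        tree = brl_tree_search(signal_table)
        assert tree.total_counts() == signal_table.class_counts()

    def test_determinism(self, signal_table):
        t1 = brl_tree_search(signal_table)
        t2 = brl_tree_search(signal_table)
        assert tree_to_rules(t1, signal_table) == tree_to_rules(t2, signal_table)

    def test_max_depth_zero_gives_majority_leaf(self, signal_table):
        tree = brl_tree_search(signal_table, max_depth=0)
        assert tree.is_leaf
        assert tree.predicted_class == "Neg"

    @pytest.mark.parametrize("seed", range(8))
    def test_greedy_never_beats_exhaustive_depth2(self, seed):
        """Greedy depth-2 tree score <= best over all depth-<=2 trees."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 21))
        cols = {f"v{i}": rng.choice(["0", "1"], size=n) for i in range(3)}
        y = rng.choice(["Pos", "Neg"], size=n)
        if len(set(y)) < 2:
            y[0] = "Pos" if y[0] == "Neg" else "Neg"
        t = make_table(cols, y)
        greedy = brl_tree_search(t, max_depth=2)
        best = max(_enumerate_depth2_scores(t))
        assert tree_score(greedy) <= best + 1e-9


def _enumerate_depth2_scores(table):
    """Scores of every tree of depth <= 2 over the table's predictors."""
    y = table.data[table.target_name].to_numpy()
    levels = {v.name: v.levels for v in table.variables}

    def leaf_score(mask):
        return interval_log_score(
            [int(np.sum(y[mask] == lvl)) for lvl in table.target_levels]
        )

    def subtree_scores(mask, names, depth):
        yield leaf_score(mask)
        if depth == 0:
            return
        for name in names:
            col = table.data[name].to_numpy()
            remaining = [m for m in names if m != name]
            parts = []
            for lvl in levels[name]:
                parts.append(
                    list(subtree_scores(mask & (col == lvl), remaining, depth - 1))
                )
            # best combination is the per-child max (children independent)
            yield sum(max(p) for p in parts)

    all_mask = np.ones(len(y), dtype=bool)
    return list(subtree_scores(all_mask, list(levels), 2))


class TestTreeToRules:
    def test_single_leaf_gives_one_unconditional_rule(self):
        t = make_table({"v": ["a", "b", "a"]}, ["Neg", "Neg", "Neg"])
        tree = brl_tree_search(t)
        model = tree_to_rules(tree, t)
        assert len(model.rules) == 1
        assert model.rules[0].conditions == ()
        assert model.rules[0].tp == 3

    def test_paper_topology_yields_13_exclusive_exhaustive_rules(
        self, paper_tree, paper_table
    ):
        """The published tree converts to exactly 13 rules, 8 Neg / 5 Pos,
        and every possible record matches exactly one."""
        model = tree_to_rules(paper_tree, paper_table)
        assert len(model.rules) == 13
        by_class = [r.predicted_class for r in model.rules]
        assert by_class.count("Neg") == 8
        assert by_class.count("Pos") == 5
        levels = {v.name: v.levels for v in paper_table.variables}
        names = list(levels)
        for combo in product(*(levels[n] for n in names)):
            record = dict(zip(names, combo))
            assert len(model.matching_rules(record)) == 1

    def test_random_records_match_exactly_one_rule(self, signal_table):
        tree = brl_tree_search(signal_table)
        model = tree_to_rules(tree, signal_table)
        rng = np.random.default_rng(99)
        levels = {v.name: v.levels for v in signal_table.variables}
        for _ in range(500):
            record = {n: rng.choice(ls) for n, ls in levels.items()}
            assert len(model.matching_rules(record)) == 1


class TestBRLClassifierEstimator:
    def test_sklearn_clone_and_params(self):
        from sklearn.base import clone

        est = BRLClassifier(search="global", lam=2.0)
        c = clone(est)
        assert c.get_params()["lam"] == 2.0
        assert c.get_params()["search"] == "global"

    def test_fit_predict_on_mixed_frame(self):
        rng = np.random.default_rng(2)
        n = 120
        y = np.where(np.arange(n) < 50, "Pos", "Neg")
        X = pd.DataFrame(
            {
                "MDE": np.where(
                    y == "Pos",
                    rng.choice(["Yes", "No"], n, p=[0.8, 0.2]),
                    rng.choice(["Yes", "No"], n, p=[0.05, 0.95]),
                ),
                "vol": np.where(y == "Pos", 1.0, 0.0) * 30 + rng.normal(100, 15, n),
            }
        )
        est = BRLClassifier().fit(X, y)
        assert set(est.classes_) == {"Pos", "Neg"}
        pred = est.predict(X)
        assert (pred == y).mean() > 0.8
        proba = est.predict_proba(X)
        assert proba.shape == (n, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_works_inside_sklearn_pipeline(self):
        from sklearn.pipeline import Pipeline

        rng = np.random.default_rng(3)
        n = 60
        y = np.where(np.arange(n) < 25, "Pos", "Neg")
        X = pd.DataFrame({"a": np.where(y == "Pos", 2.0, -2.0) + rng.normal(0, 0.5, n)})
        pipe = Pipeline([("brl", BRLClassifier())]).fit(X, y)
        assert pipe.score(X, y) > 0.9

    def test_binary_target_required(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="binary"):
            BRLClassifier().fit(X, ["A", "B", "C"])
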