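"""Shared fixtures: the published 13-rule cardiomyopathy model, the
decision tree it derives from, and a cohort engineered to reproduce its
printed coverage counts (32 Pos / 51 Neg)."""

import pandas as pd
import pytest

from brlearn.cohort import CohortTable, VariableSpec
from brlearn.rules import Condition, Rule, TreeNode

# (conditions, predicted class, TP, FP, printed Prob, printed P)
PAPER_RULES = [
    ([("MDE", "No"), ("RVESVR", "Low"), ("RVEF%", "(33.7 to 57]")], "Neg", 5, 0, 0.857, 0.081),
    ([("MDE", "No"), ("RVESVR", "Normal"), ("LVEDVR", "Normal"), ("LVESVR", "Normal"), ("SVI ml/m^2", "≤ 67")], "Neg", 22, 3, 0.852, 0.001),
    ([("MDE", "No"), ("RVESVR", "Normal"), ("LVEDVR", "Low")], "Neg", 16, 2, 0.85, 0.005),
    ([("MDE", "No"), ("RVESVR", "Normal"), ("LVEDVR", "Normal"), ("LVESVR", "High")], "Neg", 3, 0, 0.8, 0.227),
    ([("MDE", "No"), ("RVESVR", "Low"), ("RVEF%", "> 57"), ("LVEDVR", "Normal")], "Neg", 2, 0, 0.75, 0.375),
    ([("MDE", "No"), ("RVESVR", "Low"), ("RVEF%", "> 57"), ("LVEDVR", "Low")], "Neg", 2, 2, 0.5, 0.843),
    ([("MDE", "No"), ("RVESVR", "Low"), ("RVEF%", "≤ 33.7")], "Neg", 0, 0, 0.5, 1.0),
    ([("MDE", "No"), ("RVESVR", "Low"), ("RVEF%", "> 57"), ("LVEDVR", "High")], "Neg", 0, 0, 0.5, 1.0),
    ([("MDE", "Yes")], "Pos", 17, 1, 0.9, 0.0),
    ([("MDE", "No"), ("RVESVR", "Normal"), ("LVEDVR", "Normal"), ("LVESVR", "Low")], "Pos", 3, 0, 0.8, 0.054),
    ([("MDE", "No"), ("RVESVR", "Normal"), ("LVEDVR", "High")], "Pos", 2, 0, 0.75, 0.146),
    ([("MDE", "No"), ("RVESVR", "High")], "Pos", 2, 0, 0.75, 0.146),
    ([("MDE", "No"), ("RVESVR", "Normal"), ("LVEDVR", "Normal"), ("LVESVR", "Normal"), ("SVI ml/m^2", "> 67")], "Pos", 1, 0, 0.667, 0.386),
]

RANGE3 = ("Low", "Normal", "High")
PAPER_VARIABLES = [
    VariableSpec("MDE", "categorical", levels=("No", "Yes")),
    VariableSpec("RVESVR", "categorical", levels=RANGE3),
    VariableSpec("RVEF%", "categorical", levels=("≤ 33.7", "(33.7 to 57]", "> 57")),
    VariableSpec("LVEDVR", "categorical", levels=RANGE3),
    VariableSpec("LVESVR", "categorical", levels=RANGE3),
    VariableSpec("SVI ml/m^2", "categorical", levels=("≤ 67", "> 67")),
]


@pytest.fixture(scope="session")
def paper_rules():
    return [
        Rule(
            conditions=tuple(Condition(v, val) for v, val in conds),
            predicted_class=cls,
        )
        for conds, cls, *_ in PAPER_RULES
    ]


@pytest.fixture(scope="session")
def paper_table():
    """Cohort engineered to reproduce the printed per-rule TP/FP exactly.

    Each rule region gets TP records of its predicted class and FP of
    the other; unconditioned variables take their first level, which
    cannot leak a record into another (mutually exclusive) region.
    """
    defaults = {v.name: v.levels[0] for v in PAPER_VARIABLES}
    rows = []
    for conds, cls, tp, fp, *_ in PAPER_RULES:
        other = "Neg" if cls == "Pos" else "Pos"
        region = dict(defaults)
        region.update(dict(conds))
        for _ in range(tp):
            rows.append({**region, "MRDx": cls})
        for _ in range(fp):
            rows.append({**region, "MRDx": other})
    data = pd.DataFrame(rows)
    return CohortTable(data, PAPER_VARIABLES, "MRDx", ("Pos", "Neg"))


def _leaf(cls, tp, fp):
    other = "Neg" if cls == "Pos" else "Pos"
    return TreeNode(class_counts={cls: tp, other: fp}, predicted_class=cls)


@pytest.fixture(scope="session")
def paper_tree():
    """The published decision-tree topology, leaves keyed by rule number."""
    rvef_low_branch = TreeNode(
        split_variable="RVEF%",
        children={
            "≤ 33.7": _leaf("Neg", 0, 0),                      # rule 7
            "(33.7 to 57]": _leaf("Neg", 5, 0),                # rule 1
            "> 57": TreeNode(
                split_variable="LVEDVR",
                children={
                    "Low": _leaf("Neg", 2, 2),                 # rule 6
                    "Normal": _leaf("Neg", 2, 0),              # rule 5
                    "High": _leaf("Neg", 0, 0),                # rule 8
                },
            ),
        },
    )
    lvesvr_branch = TreeNode(
        split_variable="LVESVR",
        children={
            "Low": _leaf("Pos", 3, 0),                         # rule 10
            "Normal": TreeNode(
                split_variable="SVI ml/m^2",
                children={
                    "≤ 67": _leaf("Neg", 22, 3),               # rule 2
                    "> 67": _leaf("Pos", 1, 0),                # rule 13
                },
            ),
            "High": _leaf("Neg", 3, 0),                        # rule 4
        },
    )
    rvesvr_normal_branch = TreeNode(
        split_variable="LVEDVR",
        children={
            "Low": _leaf("Neg", 16, 2),                        # rule 3
            "Normal": lvesvr_branch,
            "High": _leaf("Pos", 2, 0),                        # rule 11
        },
    )
    mde_no_branch = TreeNode(
        split_variable="RVESVR",
        children={
            "Low": rvef_low_branch,
            "Normal": rvesvr_normal_branch,
            "High": _leaf("Pos", 2, 0),                        # rule 12
        },
    )
    return TreeNode(
        split_variable="MDE",
        children={"Yes": _leaf("Pos", 17, 1), "No": mde_no_branch},  # rule 9 at Yes
    )
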