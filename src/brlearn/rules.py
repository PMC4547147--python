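"""Probabilistic IF-THEN rule models and the decision trees behind them.

A rule model is a mutually exclusive, exhaustive set of conjunction
rules over categorical predictors: every possible record matches exactly
one rule, and that rule alone supplies the predicted class and its
posterior probability.  Rules carry evidence statistics from training
data — true/false positive coverage (TP/FP), a Laplace posterior, and a
one-sided Fisher exact p-value.

Text serialization mirrors the clinical reporting dialect::

    IF (MDE = No) & (RVEF% = (33.7 to 57]) THEN (MRDx = Neg)
    Prob = 0.857, P = 0.081, TP = 5, FP = 0

Open-ended interval conditions render without "=", e.g. ``(RVEF% ≤ 33.7)``
or ``(SVI ml/m^2 > 67)``.  An unconditional rule renders ``IF (TRUE)``;
a catch-all default rule (matching records no other rule covers) renders
``IF (ELSE)``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from typing import Mapping

__all__ = [
    "Condition",
    "Rule",
    "RuleModel",
    "TreeNode",
    "RuleParseError",
    "write_rule_model_text",
    "read_rule_model",
    "write_rule_model_json",
]


class RuleParseError(ValueError):
    pass


@dataclass(frozen=True)
class Condition:
    """One conjunct: variable equals a categorical value (or interval label)."""

    variable: str
    value: str

    def render(self) -> str:
        v = self.value
        if v.startswith("≤") or v.startswith(">") or v.startswith("<="):
            return f"({self.variable} {v})"
        return f"({self.variable} = {v})"

    def matches(self, record: Mapping[str, str]) -> bool:
        return str(record[self.variable]) == self.value


@dataclass(frozen=True)
class Rule:
    """A conjunction rule with a predicted class and evidence statistics.

    ``is_default`` marks the catch-all rule emitted by the global search:
    it matches exactly the records matched by no other rule in the model.
    """

    conditions: tuple[Condition, ...]
    predicted_class: str
    tp: int | None = None
    fp: int | None = None
    posterior: float | None = None
    p_value: float | None = None
    is_default: bool = False

    def __post_init__(self) -> None:
        variables = [c.variable for c in self.conditions]
        if len(set(variables)) != len(variables):
            raise ValueError("rule conditions must reference distinct variables")
        if self.is_default and self.conditions:
            raise ValueError("a default rule carries no conditions")
        for name, lo, hi in (("tp", self.tp, None), ("fp", self.fp, None)):
            if lo is not None and lo < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.posterior is not None and not 0.0 < self.posterior < 1.0:
            raise ValueError("posterior must lie in (0, 1)")
        # computed p-values are strictly positive; 0.0 is tolerated because
        # display rounding (the text format prints 3 decimals) can produce it
        if self.p_value is not None and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value must lie in [0, 1]")

    def matches(self, record: Mapping[str, str]) -> bool:
        """Condition satisfaction; a default rule matches via the model only."""
        if self.is_default:
            return False
        return all(c.matches(record) for c in self.conditions)

    def render(self, target_name: str) -> str:
        if self.is_default:
            lhs = "(ELSE)"
        elif not self.conditions:
            lhs = "(TRUE)"
        else:
            lhs = " & ".join(c.render() for c in self.conditions)
        return f"IF {lhs} THEN ({target_name} = {self.predicted_class})"

    def stats_line(self) -> str:
        prob = "?" if self.posterior is None else f"{round(self.posterior, 3):g}"
        p = "?" if self.p_value is None else f"{round(self.p_value, 3):g}"
        tp = "?" if self.tp is None else self.tp
        fp = "?" if self.fp is None else self.fp
        return f"Prob = {prob}, P = {p}, TP = {tp}, FP = {fp}"


@dataclass(frozen=True)
class RuleModel:
    """An ordered, mutually exclusive, exhaustive rule set."""

    rules: tuple[Rule, ...]
    target_name: str = "MRDx"
    target_levels: tuple[str, str] = ("Pos", "Neg")
    search_kind: str = "tree"

    def __post_init__(self) -> None:
        if sum(r.is_default for r in self.rules) > 1:
            raise ValueError("at most one default rule")

    @property
    def selected_variables(self) -> set[str]:
        return {c.variable for r in self.rules for c in r.conditions}

    def matching_rules(self, record: Mapping[str, str]) -> list[Rule]:
        return [r for r in self.rules if r.matches(record)]

    def match(self, record: Mapping[str, str]) -> Rule:
        """The unique rule covering a record (the default as fallback)."""
        hits = self.matching_rules(record)
        if len(hits) == 1:
            return hits[0]
        if not hits:
            for r in self.rules:
                if r.is_default:
                    return r
            raise ValueError(f"no rule matches record {dict(record)!r}")
        raise ValueError(f"{len(hits)} rules match record {dict(record)!r}; model is not exclusive")

    def to_dict(self) -> dict:
        return {
            "target_name": self.target_name,
            "target_levels": list(self.target_levels),
            "search_kind": self.search_kind,
            "rules": [
                {
                    "conditions": [[c.variable, c.value] for c in r.conditions],
                    "predicted_class": r.predicted_class,
                    "tp": r.tp,
                    "fp": r.fp,
                    "posterior": r.posterior,
                    "p_value": r.p_value,
                    "is_default": r.is_default,
                }
                for r in self.rules
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RuleModel":
        rules = tuple(
            Rule(
                conditions=tuple(Condition(v, val) for v, val in r["conditions"]),
                predicted_class=r["predicted_class"],
                tp=r["tp"],
                fp=r["fp"],
                posterior=r["posterior"],
                p_value=r["p_value"],
                is_default=r.get("is_default", False),
            )
            for r in d["rules"]
        )
        return cls(rules, d["target_name"], tuple(d["target_levels"]), d["search_kind"])


@dataclass
class TreeNode:
    """A node of a local-structure decision tree.

    Internal nodes split on one categorical variable with a child per
    level; leaves carry per-class record counts and a predicted class.
    No variable repeats along a root-to-leaf path.
    """

    split_variable: str | None = None
    children: dict[str, "TreeNode"] | None = None
    class_counts: dict[str, int] | None = None
    predicted_class: str | None = None

    @property
    def is_leaf(self) -> bool:
        return self.split_variable is None

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for child in self.children.values():
            out.extend(child.leaves())
        return out

    def total_counts(self) -> dict[str, int]:
        totals: dict[str, int] = {}
        for leaf in self.leaves():
            for c, n in (leaf.class_counts or {}).items():
                totals[c] = totals.get(c, 0) + n
        return totals

    def to_text(self, indent: int = 0) -> str:
        pad = "  " * indent
        if self.is_leaf:
            counts = ", ".join(f"{c}: {n}" for c, n in (self.class_counts or {}).items())
            return f"{pad}-> {self.predicted_class}  [{counts}]"
        lines = [f"{pad}{self.split_variable}?"]
        for level, child in self.children.items():
            lines.append(f"{pad}= {level}:")
            lines.append(child.to_text(indent + 1))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"class_counts": self.class_counts, "predicted_class": self.predicted_class}
        return {
            "split_variable": self.split_variable,
            "children": {lvl: child.to_dict() for lvl, child in self.children.items()},
        }


# ---------------------------------------------------------------------------
# Serialization

_RULE_RE = re.compile(r"^\s*(?:\d+\.\s*)?IF\s+(?P<lhs>.*?)\s+THEN\s+\((?P<tgt>.+?)\s*=\s*(?P<cls>.+?)\)\s*$")
_STATS_RE = re.compile(
    r"^\s*(?:Posterior Probability \(Prob\)|Prob)\s*=\s*(?P<prob>[^,]+),\s*"
    r"P\s*=\s*(?P<p>[^,]+),\s*TP\s*=\s*(?P<tp>[^,]+),\s*FP\s*=\s*(?P<fp>.+?)\s*$"
)


def write_rule_model_text(model: RuleModel, path) -> None:
    """Write the model in the numbered IF-THEN report layout."""
    lines = []
    for i, rule in enumerate(model.rules, start=1):
        lines.append(f"{i}. {rule.render(model.target_name)}")
        lines.append(rule.stats_line())
        lines.append("")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines))


def write_rule_model_json(model: RuleModel, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(model.to_dict(), fh, indent=1)


def read_rule_model(path) -> RuleModel:
    """Read a rule model from JSON (lossless) or the text layout."""
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    stripped = text.lstrip()
    if stripped.startswith("{"):
        return RuleModel.from_dict(json.loads(text))
    return _parse_rule_text(text)


def _parse_condition(token: str) -> Condition:
    token = token.strip()
    if not (token.startswith("(") and token.endswith(")")):
        raise RuleParseError(f"malformed condition {token!r}")
    inner = token[1:-1]
    # equality first; interval operators bind the trailing number
    if " = " in inner:
        var, value = inner.split(" = ", 1)
        return Condition(var.strip(), value.strip())
    for op in (" ≤ ", " <= ", " > "):
        if op in inner:
            var, bound = inner.rsplit(op, 1)
            sym = "≤" if op.strip() in ("≤", "<=") else ">"
            return Condition(var.strip(), f"{sym} {bound.strip()}")
    raise RuleParseError(f"no operator in condition {token!r}")


def _parse_rule_text(text: str) -> RuleModel:
    rules: list[Rule] = []
    target_name = None
    pending: dict | None = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        m = _RULE_RE.match(line)
        if m:
            if pending is not None:
                rules.append(Rule(**pending))
            target_name = m.group("tgt").strip()
            lhs = m.group("lhs").strip()
            if lhs == "(ELSE)":
                conditions: tuple[Condition, ...] = ()
                is_default = True
            elif lhs == "(TRUE)":
                conditions, is_default = (), False
            else:
                conditions = tuple(_parse_condition(t) for t in lhs.split(" & "))
                is_default = False
            pending = {
                "conditions": conditions,
                "predicted_class": m.group("cls").strip(),
                "is_default": is_default,
            }
            continue
        s = _STATS_RE.match(line)
        if s:
            if pending is None:
                raise RuleParseError(f"line {lineno}: statistics before any rule")
            pending.update(
                tp=_parse_opt_int(s.group("tp")),
                fp=_parse_opt_int(s.group("fp")),
                posterior=_parse_opt_float(s.group("prob")),
                p_value=_parse_opt_float(s.group("p")),
            )
            rules.append(Rule(**pending))
            pending = None
            continue
        raise RuleParseError(f"line {lineno}: cannot parse {line.strip()!r}")
    if pending is not None:
        rules.append(Rule(**pending))
    if not rules or target_name is None:
        raise RuleParseError("no rules found")
    levels_seen = []
    for r in rules:
        if r.predicted_class not in levels_seen:
            levels_seen.append(r.predicted_class)
    if set(levels_seen) <= {"Pos", "Neg"}:
        target_levels: tuple[str, str] = ("Pos", "Neg")
    elif len(levels_seen) == 2:
        target_levels = (levels_seen[0], levels_seen[1])
    else:
        target_levels = (levels_seen[0], levels_seen[0] + "_other")
    return RuleModel(tuple(rules), target_name, target_levels, search_kind="tree")


def _parse_opt_int(tok: str) -> int | None:
    tok = tok.strip()
    return None if tok == "?" else int(tok)


def _parse_opt_float(tok: str) -> float | None:
    tok = tok.strip()
    return None if tok == "?" else float(tok)
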