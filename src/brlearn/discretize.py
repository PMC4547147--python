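"""Efficient Bayesian Discretization (EBD).

Supervised discretization of a continuous predictor against a binary
class column.  Candidate thresholds are class-boundary midpoints; the
chosen subset maximizes

    log prior(I) + sum over intervals of the interval log-score,

where ``prior(I intervals) = lambda^-(I-1)`` (a geometric penalty on the
number of cut-points) and each interval's log-score is the Bayesian
marginal likelihood of its class column under a uniform Dirichlet(1)
prior:

    log [ Gamma(C) / Gamma(C + N) * prod_c Gamma(1 + n_c) ]

with C classes and interval class counts n_c summing to N.  The optimum
over all 2^B subsets of the B candidates is found by an O(B^2) dynamic
program; ties break toward fewer intervals, then smaller thresholds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import CohortError

__all__ = [
    "CutPointScheme",
    "EBDConfig",
    "candidate_boundaries",
    "interval_log_score",
    "ebd_discretize",
    "apply_scheme",
    "EBDiscretizer",
    "format_number",
    "interval_labels",
    "label_bounds",
]


def format_number(x: float) -> str:
    """Compact numeric rendering used in interval labels: 57, 33.7, 0.5."""
    return f"{x:g}"


def interval_labels(thresholds: tuple[float, ...]) -> tuple[str, ...]:
    """Labels in the clinical rule dialect: "<= a", "(a to b]", "> b"."""
    if not thresholds:
        return ("any",)
    labels = [f"≤ {format_number(thresholds[0])}"]
    for a, b in zip(thresholds, thresholds[1:]):
        labels.append(f"({format_number(a)} to {format_number(b)}]")
    labels.append(f"> {format_number(thresholds[-1])}")
    return tuple(labels)


def label_bounds(label: str) -> tuple[float, float]:
    """Inverse of :func:`interval_labels`: label -> half-open (lo, hi]."""
    label = label.strip()
    if label == "any":
        return (-math.inf, math.inf)
    if label.startswith("≤") or label.startswith("<="):
        return (-math.inf, float(label.lstrip("≤<=").strip()))
    if label.startswith(">"):
        return (float(label[1:].strip()), math.inf)
    if label.startswith("(") and label.endswith("]") and " to " in label:
        a, b = label[1:-1].split(" to ")
        return (float(a), float(b))
    raise ValueError(f"not an interval label: {label!r}")


@dataclass(frozen=True)
class CutPointScheme:
    """Ordered thresholds mapping a continuous variable to interval labels."""

    variable: str
    thresholds: tuple[float, ...]
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be strictly increasing")
        if not self.labels:
            object.__setattr__(self, "labels", interval_labels(self.thresholds))
        if len(self.labels) != len(self.thresholds) + 1:
            raise ValueError("need len(thresholds) + 1 labels")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "thresholds": list(self.thresholds),
            "labels": list(self.labels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CutPointScheme":
        return cls(d["variable"], tuple(d["thresholds"]), tuple(d["labels"]))


@dataclass(frozen=True)
class EBDConfig:
    """EBD settings: the lambda cut-point prior and an interval cap."""

    lam: float = 3.5
    max_intervals: int | None = None

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError("lambda must be positive")
        if self.max_intervals is not None and self.max_intervals < 1:
            raise ValueError("max_intervals must be >= 1")


def candidate_boundaries(values, labels) -> list[float]:
    """Class-boundary midpoints between consecutive distinct values.

    A midpoint between adjacent distinct sorted values qualifies iff the
    class count vectors of the two value groups differ; runs of identical
    class composition contribute no candidate.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if len(values) != len(labels) or len(values) == 0:
        raise ValueError("values and labels must be non-empty and equal length")
    order = np.argsort(values, kind="stable")
    v, y = values[order], labels[order]
    uniq, group = np.unique(v, return_inverse=True)
    classes, y_codes = np.unique(y, return_inverse=True)
    counts = np.zeros((len(uniq), len(classes)), dtype=np.int64)
    np.add.at(counts, (group, y_codes), 1)
    changed = np.any(counts[:-1] != counts[1:], axis=1)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    return [float(m) for m in mids[changed]]


def interval_log_score(class_counts) -> float:
    """Log marginal likelihood of one interval's class counts, Dirichlet(1).

    log [ Gamma(C)/Gamma(C+N) * prod_c Gamma(1+n_c) ].  An empty interval
    scores 0 (log 1).
    """
    counts = np.asarray(class_counts, dtype=float)
    c = counts.size
    n = counts.sum()
    return float(gammaln(c) - gammaln(c + n) + gammaln(1.0 + counts).sum())


def ebd_discretize(values, labels, cfg: EBDConfig = EBDConfig(), variable: str = "x") -> CutPointScheme:
    """Optimal cut-point selection by dynamic programming.

    Maximizes ``-(I-1) log(lambda) + sum_i interval_log_score(interval i)``
    over all subsets of the candidate boundaries; ties break toward fewer
    intervals, then lexicographically smaller threshold tuples.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if len(values) == 0:
        raise ValueError("need at least one observation")
    cands = candidate_boundaries(values, labels)
    if not cands:
        return CutPointScheme(variable, ())

    classes, y_codes = np.unique(labels, return_inverse=True)
    n_classes = len(classes)
    edges = np.array(cands)
    # segment s = values in (edges[s-1], edges[s]] ... with open extremes
    seg = np.searchsorted(edges, values, side="left")
    n_seg = len(edges) + 1
    seg_counts = np.zeros((n_seg, n_classes), dtype=np.int64)
    np.add.at(seg_counts, (seg, y_codes), 1)
    # prefix[i] = counts of segments 0..i-1
    prefix = np.vstack([np.zeros((1, n_classes), dtype=np.int64), np.cumsum(seg_counts, axis=0)])

    n_total = len(values)
    gl = gammaln(np.arange(n_total + n_classes + 2, dtype=float))
    log_lam = math.log(cfg.lam)
    gl_c = float(gammaln(n_classes))

    B = len(edges)
    # DP over "states" 0..B+1: state j means all data left of edge j-1 has
    # been partitioned (state B+1 covers everything).  f[j] = best score,
    # k[j] = its interval count, back[j] = previous state on the best path.
    # Span score S[i, j] = interval covering segments i..j-1, from prefix
    # class counts; computed row-wise to stay O(B) memory per step.
    f = np.full(B + 2, -np.inf)
    k = np.zeros(B + 2, dtype=np.int64)
    back = np.full(B + 2, -1, dtype=np.int64)
    f[0], k[0] = 0.0, 0
    max_iv = cfg.max_intervals if cfg.max_intervals is not None else B + 1
    penalty = np.zeros(B + 1)
    penalty[1:] = log_lam  # starting a new interval at edge i>0 costs log(lambda)
    tol = 1e-9

    for j in range(1, B + 2):
        cnt = prefix[j] - prefix[:j]  # (j, C) counts of span i..j-1
        span = gl_c - gl[n_classes + cnt.sum(axis=1)] + gl[1 + cnt].sum(axis=1)
        cand = f[:j] + span - penalty[:j]
        cand[k[:j] + 1 > max_iv] = -np.inf
        m = float(cand.max())
        ties = np.nonzero(cand >= m - tol)[0]
        if len(ties) == 1:
            i = int(ties[0])
        else:
            i = min(
                (int(t) for t in ties),
                key=lambda t: (k[t] + 1, _path_cuts(back, edges, t) + ((float(edges[t - 1]),) if t > 0 else ())),
            )
        f[j], k[j], back[j] = cand[i], k[i] + 1, i
    cuts = _path_cuts(back, edges, B + 1)
    return CutPointScheme(variable, cuts)


def _path_cuts(back: np.ndarray, edges: np.ndarray, j: int) -> tuple[float, ...]:
    """Reconstruct the threshold tuple of the best path ending at state j."""
    cuts: list[float] = []
    while j > 0:
        i = int(back[j])
        if i > 0:
            cuts.append(float(edges[i - 1]))
        j = i
    return tuple(reversed(cuts))


def scheme_score(values, labels, scheme: CutPointScheme, cfg: EBDConfig) -> float:
    """Total EBD objective of an arbitrary scheme (prior + interval scores)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    idx = np.searchsorted(np.asarray(scheme.thresholds), values, side="left")
    total = -(len(scheme.thresholds)) * math.log(cfg.lam)
    for i in range(len(scheme.thresholds) + 1):
        seg = labels[idx == i]
        total += interval_log_score([np.sum(seg == c) for c in classes])
    return total


def apply_scheme(values, scheme: CutPointScheme) -> pd.Series:
    """Map continuous values to interval labels (left-open, right-closed)."""
    values = np.asarray(values, dtype=float)
    if not np.isfinite(values).all():
        bad = int(np.nonzero(~np.isfinite(values))[0][0])
        raise CohortError(f"non-finite value at position {bad} for {scheme.variable!r}")
    idx = np.searchsorted(np.asarray(scheme.thresholds), values, side="left")
    return pd.Series(np.asarray(scheme.labels, dtype=object)[idx], dtype=object)


class EBDiscretizer(TransformerMixin, BaseEstimator):
    """Supervised discretizer applying EBD column-wise.

    Fit on a DataFrame with continuous (numeric) and categorical columns
    and a binary class vector; ``transform`` replaces each numeric column
    by its learned interval labels and passes categorical columns through.

    Parameters
    ----------
    lam : float, default 3.5
        EBD lambda prior penalizing cut-points.
    max_intervals : int or None
        Optional cap on intervals per variable.

    Attributes
    ----------
    schemes_ : dict mapping column name -> CutPointScheme
    feature_names_in_ : ndarray of column names seen at fit
    """

    def __init__(self, lam: float = 3.5, max_intervals: int | None = None):
        self.lam = lam
        self.max_intervals = max_intervals

    def fit(self, X, y):
        X = _as_frame(X)
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        cfg = EBDConfig(self.lam, self.max_intervals)
        self.schemes_ = {}
        for col in X.columns:
            if pd.api.types.is_numeric_dtype(X[col]):
                self.schemes_[col] = ebd_discretize(
                    X[col].to_numpy(dtype=float), y, cfg, variable=col
                )
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        if not hasattr(self, "schemes_"):
            raise RuntimeError("EBDiscretizer is not fitted")
        X = _as_frame(X)
        out = pd.DataFrame(index=X.index)
        for col in X.columns:
            if col in self.schemes_:
                out[col] = apply_scheme(X[col].to_numpy(dtype=float), self.schemes_[col]).to_numpy()
            else:
                out[col] = X[col]
        return out

    def save_schemes(self, path) -> None:
        with open(path, "w") as fh:
            json.dump([s.to_dict() for s in self.schemes_.values()], fh, indent=1)


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])
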