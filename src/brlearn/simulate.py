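"""Synthetic pediatric cMRI biomarker cohorts.

Generates case/control tables with the structure of a pediatric
cardiomyopathy/myocarditis cohort: 32 positives and 51 negatives by
default, ~30 predictors mixing continuous cMRI biomarkers (ventricular
volumes, ejection fractions, stroke volume index, ...), gender, binary
MDE status, and five derived Low/Normal/High "Range" variables computed
against age- and gender-specific reference means by the 2-SD rule.

The class signal has two parts: MDE is sampled class-conditionally
(default rates 17/32 for positives vs 1/51 for negatives, the only
class-conditional MDE information available for the emulated cohort),
and selected continuous biomarkers are shifted for positives by a fixed
number of reference SDs (dilated volumes, depressed ejection
fractions).  A "region mechanism" built from an existing rule model can
replace the marginal feature signal to make specific rule regions
recoverable (:func:`implant_rule_model`).

The reference table is synthetic: plausible pediatric values fixed by a
seed, standing in for published normal-range tables which are not
distributed with this package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .cohort import (
    CohortError,
    CohortTable,
    RANGE_LEVELS,
    ReferenceRangeTable,
    VariableSpec,
    derive_range_variable,
)
from .discretize import label_bounds
from .rules import Condition, RuleModel

__all__ = [
    "SyntheticConfig",
    "RegionSpec",
    "default_reference_table",
    "generate_cohort",
    "implant_rule_model",
    "AGE_BANDS",
    "RANGE_SOURCES",
]

AGE_BANDS = ((0.0, 2.0), (2.0, 6.0), (6.0, 12.0), (12.0, 18.0), (18.0, 22.0))

# derived Range variable -> underlying continuous volume
RANGE_SOURCES = {
    "LVEDVR": "LVEDV",
    "LVESVR": "LVESV",
    "RVEDVR": "RVEDV",
    "RVESVR": "RVESV",
    "SVR": "SV",
}

# per-band reference means (male); female means are scaled by 0.9
_REFERENCE_MEANS = {
    "LVEDV": (25.0, 50.0, 80.0, 120.0, 145.0),
    "LVESV": (10.0, 20.0, 32.0, 48.0, 58.0),
    "RVEDV": (28.0, 55.0, 85.0, 125.0, 150.0),
    "RVESV": (12.0, 24.0, 38.0, 55.0, 66.0),
    "SV": (15.0, 30.0, 48.0, 72.0, 87.0),
}

# age-independent baselines for the remaining continuous biomarkers
_BASELINES = {
    "LVEF%": (62.0, 6.0),
    "RVEF%": (55.0, 6.0),
    "SVI ml/m^2": (42.0, 10.0),
    "LVEDVI ml/m^2": (75.0, 12.0),
    "LVESVI ml/m^2": (30.0, 8.0),
    "RVEDVI ml/m^2": (78.0, 13.0),
    "RVESVI ml/m^2": (35.0, 9.0),
    "AS Wall cm": (0.8, 0.15),
    "PS Wall cm": (0.8, 0.15),
    "LV EDD cm": (4.2, 0.7),
    "LV ESD cm": (2.8, 0.5),
    "FS%": (34.0, 5.0),
    "RV Major Axis cm": (7.0, 1.0),
    "RV Minor Axis cm": (3.2, 0.5),
    "RV Major Axis Index cm/m^2": (5.5, 0.8),
    "RV Minor Axis Index cm/m^2": (2.6, 0.4),
    "HR bpm": (90.0, 18.0),
    "CO l/min": (4.5, 1.2),
    "CI l/min/m^2": (3.6, 0.7),
}

# positive-class mean shifts, in units of the variable's SD: dilated
# ventricular volumes, depressed ejection fractions, mildly raised SVI
_DEFAULT_EFFECTS = {
    "LVEDV": 0.8,
    "LVESV": 0.9,
    "RVESV": 0.7,
    "LVEF%": -0.9,
    "RVEF%": -0.8,
    "SVI ml/m^2": 0.3,
}


@dataclass(frozen=True)
class RegionSpec:
    """A rule region with class-conditional allocation weights."""

    conditions: tuple[Condition, ...]
    weight_pos: float
    weight_neg: float


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters of the fixture cohort."""

    n_pos: int = 32
    n_neg: int = 51
    seed: int = 0
    mde_rate_pos: float = 17.0 / 32.0
    mde_rate_neg: float = 1.0 / 51.0
    effect_map: dict = field(default_factory=lambda: dict(_DEFAULT_EFFECTS))
    reference_seed: int = 0
    region_mechanism: tuple[RegionSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise CohortError("class sizes must be non-negative")
        for r in (self.mde_rate_pos, self.mde_rate_neg):
            if not 0.0 <= r <= 1.0:
                raise CohortError(f"MDE rate {r} outside [0, 1]")

    def scaled_to(self, n_total: int) -> "SyntheticConfig":
        """Same composition ratio at a different cohort size."""
        n_pos = int(round(n_total * self.n_pos / (self.n_pos + self.n_neg)))
        return replace(self, n_pos=n_pos, n_neg=n_total - n_pos)

    def null(self) -> "SyntheticConfig":
        """Signal-free variant: equal MDE rates, no feature shifts."""
        pooled = (
            (self.mde_rate_pos * self.n_pos + self.mde_rate_neg * self.n_neg)
            / (self.n_pos + self.n_neg)
        )
        return replace(
            self, mde_rate_pos=pooled, mde_rate_neg=pooled, effect_map={}, region_mechanism=()
        )

    def to_json(self) -> str:
        d = {
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "seed": self.seed,
            "mde_rate_pos": self.mde_rate_pos,
            "mde_rate_neg": self.mde_rate_neg,
            "effect_map": self.effect_map,
            "reference_seed": self.reference_seed,
            "region_mechanism": [
                {
                    "conditions": [[c.variable, c.value] for c in r.conditions],
                    "weight_pos": r.weight_pos,
                    "weight_neg": r.weight_neg,
                }
                for r in self.region_mechanism
            ],
        }
        return json.dumps(d, indent=1)


def default_reference_table(seed: int = 0) -> ReferenceRangeTable:
    """Synthetic age/gender reference means and SDs for the five volumes.

    Means grow monotonically across age bands; SDs are ~16% of the mean
    with a small seeded jitter.  Fixture data only — not published
    normal ranges.
    """
    rng = np.random.default_rng(seed)
    entries = {}
    for var, band_means in _REFERENCE_MEANS.items():
        for gender, factor in (("M", 1.0), ("F", 0.9)):
            for band, base in enumerate(band_means):
                mean = base * factor * (1.0 + 0.03 * rng.uniform(-1, 1))
                sd = 0.16 * mean * (1.0 + 0.10 * rng.uniform(-1, 1))
                entries[(var, gender, band)] = (float(mean), float(sd))
    return ReferenceRangeTable(AGE_BANDS, entries)


def _base_params(var: str, gender: str, age: float, ref: ReferenceRangeTable) -> tuple[float, float]:
    if var in _REFERENCE_MEANS:
        return ref.lookup(var, gender, age)
    return _BASELINES[var]


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Exact integer allocation of ``total`` proportional to ``weights``."""
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0 or total == 0:
        return np.zeros(len(w), dtype=int)
    quota = total * w / w.sum()
    alloc = np.floor(quota).astype(int)
    rem = total - alloc.sum()
    order = np.argsort(-(quota - alloc), kind="stable")
    alloc[order[:rem]] += 1
    return alloc


def generate_cohort(cfg: SyntheticConfig) -> CohortTable:
    """Draw one synthetic cohort; deterministic given the config."""
    rng = np.random.default_rng(cfg.seed)
    ref = default_reference_table(cfg.reference_seed)
    n = cfg.n_pos + cfg.n_neg
    if n == 0:
        raise CohortError("empty cohort requested")
    y = np.array(["Pos"] * cfg.n_pos + ["Neg"] * cfg.n_neg, dtype=object)
    y = y[rng.permutation(n)]
    is_pos = y == "Pos"

    ages = rng.uniform(0.0, 22.0, size=n)
    genders = np.where(rng.random(n) < 0.5, "M", "F").astype(object)
    mde_rate = np.where(is_pos, cfg.mde_rate_pos, cfg.mde_rate_neg)
    mde = np.where(rng.random(n) < mde_rate, "Yes", "No").astype(object)

    continuous_vars = list(_REFERENCE_MEANS) + list(_BASELINES)
    values: dict[str, np.ndarray] = {}
    for var in continuous_vars:
        col = np.empty(n)
        shift = float(cfg.effect_map.get(var, 0.0))
        z = rng.standard_normal(n)
        for i in range(n):
            mean, sd = _base_params(var, genders[i], ages[i], ref)
            col[i] = mean + (shift * sd if is_pos[i] else 0.0) + sd * z[i]
        values[var] = col

    if cfg.region_mechanism:
        _apply_regions(cfg, rng, ref, y, ages, genders, mde, values)

    data = pd.DataFrame({"Age": ages, "Gender": genders, "MDE": mde})
    for var in continuous_vars:
        data[var] = values[var]
    for rng_var, source in RANGE_SOURCES.items():
        data[rng_var] = derive_range_variable(
            values[source], ages, genders, ref, source
        ).to_numpy()
    data["MRDx"] = y

    variables = [
        VariableSpec("Age", "continuous", units="years"),
        VariableSpec("Gender", "categorical", levels=("F", "M")),
        VariableSpec("MDE", "categorical", levels=("No", "Yes")),
    ]
    variables += [VariableSpec(v, "continuous") for v in continuous_vars]
    variables += [
        VariableSpec(v, "categorical", levels=RANGE_LEVELS) for v in RANGE_SOURCES
    ]
    return CohortTable(data, variables, "MRDx", ("Pos", "Neg"))


def _apply_regions(cfg, rng, ref, y, ages, genders, mde, values) -> None:
    """Force records into rule regions per class-conditional weights."""
    regions = cfg.region_mechanism
    w_pos = np.array([r.weight_pos for r in regions])
    w_neg = np.array([r.weight_neg for r in regions])
    for cls, weights in (("Pos", w_pos), ("Neg", w_neg)):
        idx = np.nonzero(y == cls)[0]
        alloc = _largest_remainder(weights, len(idx))
        if alloc.sum() == 0:
            continue
        if alloc.sum() < len(idx):
            # weights cover less than the class (zero-coverage regions left
            # neutral): the unallocated remainder keeps its base draw
            idx = idx[: alloc.sum()]
        pos = 0
        for region, count in zip(regions, alloc):
            for i in idx[pos : pos + count]:
                _force_record(region.conditions, int(i), rng, ref, ages, genders, mde, values)
            pos += count


def _force_record(conditions, i, rng, ref, ages, genders, mde, values) -> None:
    for c in conditions:
        if c.variable == "MDE":
            mde[i] = c.value
        elif c.variable == "Gender":
            genders[i] = c.value
        elif c.variable in RANGE_SOURCES:
            source = RANGE_SOURCES[c.variable]
            mean, sd = ref.lookup(source, genders[i], ages[i])
            if c.value == "Low":
                lo, hi = -np.inf, mean - 2.0 * sd
            elif c.value == "High":
                lo, hi = mean + 2.0 * sd, np.inf
            elif c.value == "Normal":
                lo, hi = mean - 2.0 * sd, mean + 2.0 * sd
            else:
                raise CohortError(f"unknown range level {c.value!r}")
            values[source][i] = _trunc_draw(rng, mean, sd, lo, hi)
        elif c.variable in values:
            mean, sd = _base_params(c.variable, genders[i], ages[i], ref)
            lo, hi = label_bounds(c.value)
            values[c.variable][i] = _trunc_draw(rng, mean, sd, lo, hi)
        else:
            raise CohortError(f"cannot force unknown variable {c.variable!r}")


def _trunc_draw(rng, mean: float, sd: float, lo: float, hi: float) -> float:
    a = (lo - mean) / sd if np.isfinite(lo) else -np.inf
    b = (hi - mean) / sd if np.isfinite(hi) else np.inf
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def implant_rule_model(cfg: SyntheticConfig, model: RuleModel) -> SyntheticConfig:
    """Turn a rule model into a generative region mechanism.

    Each non-default rule becomes a region whose class-conditional
    weights are its (TP, FP) coverage counts (or posterior odds when the
    model is unannotated), so that generated coverage counts converge to
    the scaled printed values as the cohort grows.  Zero-coverage rules
    (posterior 0.5, no evidence) are left neutral.
    """
    regions = []
    for rule in model.rules:
        if rule.is_default:
            continue
        if rule.tp is not None and rule.fp is not None:
            w_of_pred, w_of_other = float(rule.tp), float(rule.fp)
        elif rule.posterior is not None:
            w_of_pred, w_of_other = rule.posterior, 1.0 - rule.posterior
        else:
            raise CohortError("rules need tp/fp or posterior to be implanted")
        if w_of_pred == 0.0 and w_of_other == 0.0:
            continue
        if rule.predicted_class == model.target_levels[0]:
            wp, wn = w_of_pred, w_of_other
        else:
            wp, wn = w_of_other, w_of_pred
        regions.append(RegionSpec(rule.conditions, wp, wn))
    if not regions:
        return cfg
    return replace(cfg, region_mechanism=tuple(regions))
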