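"""Cohort tables of clinical biomarkers.

A cohort is a patient-by-variable table with a binary diagnostic target
(e.g. MRDx = Pos/Neg).  Predictors are a mix of continuous biomarkers
(ventricular volumes, ejection fractions, stroke volume index, ...) and
categorical ones (MDE status, gender, derived low/normal/high "Range"
variables).  Missing values are never imputed: a blank cell is a hard
input error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

RANGE_LEVELS = ("Low", "Normal", "High")


class CohortError(ValueError):
    """Raised for malformed or inconsistent cohort input."""


@dataclass(frozen=True)
class VariableSpec:
    """Schema entry for one predictor column.

    Parameters
    ----------
    name : str
        Column name, unique within a table.
    kind : {"continuous", "categorical"}
    units : str, optional
        Free-text units such as ``"ml/m^2"`` or ``"%"``.
    levels : tuple of str, optional
        Ordered category labels; required for categorical variables and
        forbidden for continuous ones.
    """

    name: str
    kind: str
    units: str = ""
    levels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise CohortError(f"unknown variable kind {self.kind!r} for {self.name!r}")
        if self.kind == "categorical":
            if not self.levels:
                raise CohortError(f"categorical variable {self.name!r} needs levels")
            if len(set(self.levels)) != len(self.levels):
                raise CohortError(f"duplicate levels for {self.name!r}")
        elif self.levels is not None:
            raise CohortError(f"continuous variable {self.name!r} must not have levels")


@dataclass
class CohortTable:
    """A validated patient x variable matrix with a binary target column.

    ``data`` holds one column per variable plus the target column;
    ``target_levels`` orders the two class labels (positive first).
    """

    data: pd.DataFrame
    variables: list[VariableSpec]
    target_name: str
    target_levels: tuple[str, str] = ("Pos", "Neg")

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise CohortError("duplicate variable names")
        if self.target_name not in self.data.columns:
            raise CohortError(f"target column {self.target_name!r} missing")
        if len(self.target_levels) != 2:
            raise CohortError("target must have exactly two levels")
        if len(self.data) < 1:
            raise CohortError("cohort must contain at least one record")
        for v in self.variables:
            if v.name not in self.data.columns:
                raise CohortError(f"variable column {v.name!r} missing from data")
        _check_no_missing(self.data)
        observed_t = set(self.data[self.target_name].unique())
        if not observed_t <= set(self.target_levels):
            raise CohortError(
                f"target values {sorted(observed_t - set(self.target_levels))} "
                f"outside declared levels {self.target_levels}"
            )
        for v in self.variables:
            if v.kind == "categorical":
                bad = set(self.data[v.name].unique()) - set(v.levels)
                if bad:
                    raise CohortError(
                        f"values {sorted(map(str, bad))} of {v.name!r} outside "
                        f"declared levels"
                    )

    # -- convenience -------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def predictor_names(self) -> list[str]:
        return [v.name for v in self.variables]

    def spec(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def levels(self, name: str) -> tuple[str, ...]:
        s = self.spec(name)
        if s.levels is None:
            raise CohortError(f"{name!r} is continuous; no levels")
        return s.levels

    def class_counts(self) -> dict[str, int]:
        vc = self.data[self.target_name].value_counts()
        return {lvl: int(vc.get(lvl, 0)) for lvl in self.target_levels}

    def subset(self, index: Sequence[int] | np.ndarray) -> "CohortTable":
        """Row subset by positional index; empty classes are permitted."""
        sub = self.data.iloc[np.asarray(index)].reset_index(drop=True)
        out = CohortTable.__new__(CohortTable)
        out.data = sub
        out.variables = self.variables
        out.target_name = self.target_name
        out.target_levels = self.target_levels
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortTable):
            return NotImplemented
        return (
            self.variables == other.variables
            and self.target_name == other.target_name
            and self.target_levels == other.target_levels
            and self.data.reset_index(drop=True).equals(other.data.reset_index(drop=True))
        )


@dataclass
class ReferenceRangeTable:
    """Age- and gender-specific reference means/SDs for volume biomarkers.

    Entries are keyed by ``(variable, gender, age_band_index)``; the age
    bands partition the supported range [0, 22] without overlap.
    """

    age_bands: tuple[tuple[float, float], ...]
    entries: dict[tuple[str, str, int], tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo = 0.0
        for a, b in self.age_bands:
            if a != lo or b <= a:
                raise CohortError("age bands must partition [0, 22] without overlap")
            lo = b
        if lo != 22:
            raise CohortError("age bands must end at 22")
        for key, (mean, sd) in self.entries.items():
            if not sd > 0:
                raise CohortError(f"sd must be positive for {key}")

    def band_index(self, age: float) -> int:
        for i, (a, b) in enumerate(self.age_bands):
            # last band is closed on the right
            if a <= age < b or (i == len(self.age_bands) - 1 and age == b):
                return i
        raise CohortError(f"age {age} outside supported range [0, 22]")

    def lookup(self, variable: str, gender: str, age: float) -> tuple[float, float]:
        band = self.band_index(age)
        try:
            return self.entries[(variable, gender, band)]
        except KeyError:
            raise CohortError(
                f"no reference entry for ({variable!r}, {gender!r}, "
                f"age band {self.age_bands[band]})"
            ) from None


def _check_no_missing(df: pd.DataFrame) -> None:
    for col in df.columns:
        s = df[col]
        mask = s.isna()
        if s.dtype == object:
            mask = mask | (s.astype(str).str.strip() == "")
        if mask.any():
            row = int(np.nonzero(mask.to_numpy())[0][0])
            raise CohortError(f"missing value at row {row + 1}, column {col!r}")


# ---------------------------------------------------------------------------
# CSV I/O


def read_cohort_csv(
    path,
    target_name: str,
    schema: Sequence[VariableSpec] | None = None,
    target_levels: tuple[str, str] | None = None,
) -> CohortTable:
    """Read a cohort from a headered CSV file.

    Variable kinds are inferred (a column is continuous iff every cell
    parses as a number) unless an explicit ``schema`` is given.  Any empty
    cell is an error naming the offending row and column — no imputation.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    if target_name not in raw.columns:
        raise CohortError(f"target column {target_name!r} not found in {path}")
    _check_no_missing(raw)

    observed = sorted(raw[target_name].unique())
    if len(observed) > 2:
        raise CohortError(
            f"target {target_name!r} has {len(observed)} labels {observed}; expected 2"
        )
    if target_levels is None:
        if set(observed) <= {"Pos", "Neg"}:
            target_levels = ("Pos", "Neg")
        else:
            target_levels = tuple(observed) if len(observed) == 2 else (observed[0], observed[0] + "_other")  # type: ignore[assignment]

    data = pd.DataFrame(index=raw.index)
    variables: list[VariableSpec] = []
    schema_map = {v.name: v for v in schema} if schema is not None else None
    for col in raw.columns:
        if col == target_name:
            data[col] = raw[col]
            continue
        if schema_map is not None:
            if col not in schema_map:
                raise CohortError(f"column {col!r} not in provided schema")
            spec = schema_map[col]
            if spec.kind == "continuous":
                data[col] = _parse_numeric(raw[col], col)
            else:
                data[col] = raw[col]
            variables.append(spec)
        else:
            parsed = pd.to_numeric(raw[col], errors="coerce")
            if parsed.notna().all():
                data[col] = _parse_numeric(raw[col], col)
                variables.append(VariableSpec(col, "continuous"))
            else:
                data[col] = raw[col]
                variables.append(
                    VariableSpec(col, "categorical", levels=tuple(sorted(raw[col].unique())))
                )
    return CohortTable(data, variables, target_name, target_levels)


def _parse_numeric(s: pd.Series, col: str) -> pd.Series:
    # Python's float() parses with correct rounding, so write/read/write
    # serialization is byte-stable (pd.to_numeric's fast path is not)
    out = np.empty(len(s), dtype=float)
    for i, tok in enumerate(s):
        try:
            out[i] = float(tok)
        except ValueError:
            raise CohortError(
                f"unparseable numeric value {tok!r} at row {i + 1}, column {col!r}"
            ) from None
    return pd.Series(out, index=s.index)


def write_cohort_csv(table: CohortTable, path) -> None:
    """Write the cohort as RFC-4180 CSV with a header row."""
    table.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Derived "Range" variables


def derive_range_variable(
    values: Iterable[float],
    ages: Iterable[float],
    genders: Iterable[str],
    ref: ReferenceRangeTable,
    variable: str,
) -> pd.Series:
    """Categorize a volume series as Low/Normal/High against reference data.

    A value more than two standard deviations below (above) the age- and
    gender-specific reference mean is labelled ``"Low"`` (``"High"``); all
    others, including values exactly at the +/-2 SD boundary, are
    ``"Normal"``.
    """
    values = np.asarray(list(values), dtype=float)
    ages = list(ages)
    genders = list(genders)
    if not (len(values) == len(ages) == len(genders)):
        raise CohortError("values, ages, genders must have equal length")
    out = []
    for v, age, g in zip(values, ages, genders):
        mean, sd = ref.lookup(variable, g, age)
        if v < mean - 2.0 * sd:
            out.append("Low")
        elif v > mean + 2.0 * sd:
            out.append("High")
        else:
            out.append("Normal")
    return pd.Series(out, dtype=object)
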