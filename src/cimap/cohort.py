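"""Cohort data model: variable dictionary, validated records, I/O and summaries.

A cohort is a rectangular table of categorical observations, one row per
emergency-department presentation. Every column is declared in a
:class:`VariableDictionary`; every non-missing cell must be one of the
declared levels of its variable. Missingness is represented internally as
``None`` and externally by each variable's ``missing_code`` (empty string by
default). Analyses downstream use pairwise-complete records.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import DomainError, SchemaError, ValidationError

VALID_KINDS = ("binary", "categorical", "count", "integer_bounded")
VALID_ROLES = ("ACE", "demographic", "clinical", "outcome", "derived")


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of a single study variable.

    Parameters
    ----------
    name : str
        Column name, unique within a dictionary.
    kind : str
        One of ``binary``, ``categorical``, ``count``, ``integer_bounded``.
        Binary variables must declare exactly two levels.
    levels : tuple of str
        Ordered level labels. All stored values are labels, including
        integer-valued variables such as age.
    role : str
        One of ``ACE``, ``demographic``, ``clinical``, ``outcome``, ``derived``.
    missing_code : str
        Label treated as missing on input/output (default: empty string).
    """

    name: str
    kind: str
    levels: tuple
    role: str = "clinical"
    missing_code: str = ""

    def __post_init__(self):
        object.__setattr__(self, "levels", tuple(str(v) for v in self.levels))
        if not self.name:
            raise SchemaError("variable name must be non-empty")
        if self.kind not in VALID_KINDS:
            raise SchemaError(f"{self.name}: unknown kind {self.kind!r}")
        if self.role not in VALID_ROLES:
            raise SchemaError(f"{self.name}: unknown role {self.role!r}")
        if len(self.levels) == 0:
            raise SchemaError(f"{self.name}: levels must be non-empty")
        if len(set(self.levels)) != len(self.levels):
            raise SchemaError(f"{self.name}: duplicate levels")
        if self.kind == "binary" and len(self.levels) != 2:
            raise SchemaError(
                f"{self.name}: binary variable must have exactly 2 levels, "
                f"got {len(self.levels)}"
            )
        if self.missing_code in self.levels:
            raise SchemaError(f"{self.name}: missing code collides with a level")

    @property
    def n_levels(self) -> int:
        return len(self.levels)


class VariableDictionary:
    """Ordered collection of :class:`VariableSpec`, addressable by name."""

    def __init__(self, specs: Iterable[VariableSpec]):
        specs = list(specs)
        names = [s.name for s in specs]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate variable names in dictionary")
        self._specs = {s.name: s for s in specs}

    def __getitem__(self, name: str) -> VariableSpec:
        try:
            return self._specs[name]
        except KeyError:
            raise SchemaError(f"variable {name!r} not declared") from None

    def __contains__(self, name: str) -> bool:
        return name in self._specs

    def __iter__(self) -> Iterator[VariableSpec]:
        return iter(self._specs.values())

    def __len__(self) -> int:
        return len(self._specs)

    def __eq__(self, other) -> bool:
        return isinstance(other, VariableDictionary) and self._specs == other._specs

    @property
    def names(self) -> list:
        return list(self._specs)

    def subset(self, names: Sequence[str]) -> "VariableDictionary":
        return VariableDictionary([self[n] for n in names])

    # ---- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "variables": [
                {
                    "name": s.name,
                    "kind": s.kind,
                    "levels": list(s.levels),
                    "role": s.role,
                    "missing_code": s.missing_code,
                }
                for s in self
            ]
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "VariableDictionary":
        try:
            entries = payload["variables"]
        except (KeyError, TypeError):
            raise SchemaError("dictionary payload must contain a 'variables' list")
        return cls(
            VariableSpec(
                name=e["name"],
                kind=e["kind"],
                levels=tuple(e["levels"]),
                role=e.get("role", "clinical"),
                missing_code=e.get("missing_code", ""),
            )
            for e in entries
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "VariableDictionary":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path) -> "VariableDictionary":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class Cohort:
    """Validated cohort table.

    ``data`` holds one column per declared variable, values as level labels
    (dtype object) with ``None`` marking missingness.
    """

    data: pd.DataFrame
    dictionary: VariableDictionary

    def __post_init__(self):
        cols = list(self.data.columns)
        declared = self.dictionary.names
        if set(cols) != set(declared):
            extra = sorted(set(cols) - set(declared))
            missing = sorted(set(declared) - set(cols))
            raise SchemaError(
                f"columns and dictionary disagree (undeclared: {extra}, absent: {missing})"
            )
        # normalise column order to dictionary order
        self.data = self.data[declared].reset_index(drop=True)
        for spec in self.dictionary:
            col = self.data[spec.name]
            ok = col.isin(spec.levels) | col.isna()
            if not ok.all():
                bad = self.data.index[~ok]
                row = int(bad[0])
                raise ValidationError(
                    f"value {col.iloc[row]!r} at row {row}, column {spec.name!r} "
                    f"is not a declared level {list(spec.levels)}"
                )

    @property
    def n(self) -> int:
        return len(self.data)

    def codes(self, names: Sequence[str] | None = None) -> np.ndarray:
        """Integer level codes (missing = -1), columns in requested order."""
        names = list(names) if names is not None else self.dictionary.names
        out = np.empty((self.n, len(names)), dtype=np.int64)
        for j, name in enumerate(names):
            spec = self.dictionary[name]
            cat = pd.Categorical(self.data[name], categories=spec.levels)
            out[:, j] = cat.codes
        return out

    def counts(self, name: str) -> dict:
        """Per-level non-missing counts for one variable."""
        spec = self.dictionary[name]
        vc = self.data[name].value_counts(dropna=True)
        return {lev: int(vc.get(lev, 0)) for lev in spec.levels}


def read_cohort(path, dictionary: VariableDictionary) -> Cohort:
    """Read a cohort CSV (RFC 4180, header row mandatory) and validate it.

    Missing codes are converted to missing; every column must be declared.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in df.columns:
        if col not in dictionary:
            raise SchemaError(f"undeclared column {col!r} in {path}")
    for col in df.columns:
        spec = dictionary[col]
        df[col] = df[col].replace({spec.missing_code: None})
    return Cohort(df, dictionary.subset(list(df.columns)))


def write_cohort(cohort: Cohort, path) -> None:
    """Write the cohort as CSV, restoring each variable's missing code."""
    df = cohort.data.copy()
    for spec in cohort.dictionary:
        df[spec.name] = df[spec.name].where(df[spec.name].notna(), spec.missing_code)
    df.to_csv(path, index=False, lineterminator="\n")


def recode_attendance(counts) -> np.ndarray:
    """Collapse per-record attendance frequencies to a 0/1 indicator.

    Zero stays zero; any count >= 1 becomes 1. Negative counts are a domain
    error.
    """
    arr = np.asarray(counts)
    if arr.size and arr.min() < 0:
        raise DomainError("attendance counts must be non-negative")
    return (arr >= 1).astype(np.int64)


def _percent(count: int, n: int) -> float:
    """Percent of total sample, half-up to 1 dp; 0 when n == 0."""
    if n == 0:
        return 0.0
    return float(np.floor(1000.0 * count / n + 0.5) / 10.0)


@dataclass
class SummaryTable:
    """Descriptive counts (and % of total sample) per variable level.

    When a stratum variable is given, additional columns report counts and
    percentages (still of total n, the printed-table convention) within
    records whose stratum value is the second declared level.
    """

    table: pd.DataFrame
    n: int
    stratum: str | None = None
    undefined_percent: bool = False

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, lineterminator="\n")

    def to_text(self) -> str:
        return self.table.to_string(index=False)

    def cell(self, variable: str, level: str, column: str = "count"):
        sub = self.table[
            (self.table["variable"] == variable) & (self.table["level"] == level)
        ]
        if sub.empty:
            raise KeyError((variable, level))
        return sub.iloc[0][column]


def summarise(cohort: Cohort, stratum: str | None = None) -> SummaryTable:
    """Per-level counts and % of total sample, optionally within a stratum.

    Percentages use the full sample size as denominator even inside the
    stratum, matching the descriptive-table convention of the study design.
    """
    n = cohort.n
    mask = None
    if stratum is not None:
        spec = cohort.dictionary[stratum]
        if spec.kind != "binary":
            raise SchemaError(f"stratum {stratum!r} must be binary, got {spec.kind}")
        mask = cohort.data[stratum] == spec.levels[1]
    rows = []
    for spec in cohort.dictionary:
        col = cohort.data[spec.name]
        vc = col.value_counts(dropna=True)
        for lev in spec.levels:
            c = int(vc.get(lev, 0))
            row = {
                "variable": spec.name,
                "level": lev,
                "count": c,
                "percent": _percent(c, n),
            }
            if mask is not None:
                cs = int(((col == lev) & mask).sum())
                row["count_stratum"] = cs
                row["percent_stratum"] = _percent(cs, n)
            rows.append(row)
    table = pd.DataFrame(rows)
    return SummaryTable(table=table, n=n, stratum=stratum, undefined_percent=(n == 0))
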