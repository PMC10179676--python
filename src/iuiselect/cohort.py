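"""Domain types for IUI cycle cohorts and their CSV interchange format.

A cohort is a flat table with one row per insemination cycle.  Couples are
clusters: a couple contributes up to four cycles, stops after a clinical
pregnancy, and belongs to exactly one recruitment period.  Covariates are
described by :class:`ParameterSpec` records which also carry the policy
needed by threshold discovery (which extreme may be flagged, and whose
extreme defines the cutoff).
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

__all__ = [
    "COMPARTMENTS",
    "DIRECTION_POLICIES",
    "SOURCE_GROUPS",
    "PERIODS",
    "CohortError",
    "ParameterSpec",
    "CycleRecord",
    "Cohort",
    "read_parameters",
    "write_parameters",
    "read_cohort",
    "write_cohort",
    "split_periods",
]

COMPARTMENTS = ("ejaculate", "swim_up", "male_demographic", "female")
DIRECTION_POLICIES = ("upper", "lower", "both", "none")
SOURCE_GROUPS = ("pregnancy", "no_pregnancy")
PERIODS = ("discovery", "validation")

#: accepted spellings for the period column on input
_PERIOD_ALIASES = {
    "1": "discovery",
    "2": "validation",
    "discovery": "discovery",
    "validation": "validation",
}

MAX_CYCLES = 4


class CohortError(ValueError):
    """Structural or parse error in cohort/parameter data."""


@dataclass(frozen=True)
class ParameterSpec:
    """A measured variable plus its threshold-direction/source policy."""

    name: str
    compartment: str
    units: str
    direction_policy: str = "both"
    source_group: str = "pregnancy"
    include_in_model: bool = True

    def __post_init__(self) -> None:
        if not self.name:
            raise CohortError("parameter name must be non-empty")
        if self.compartment not in COMPARTMENTS:
            raise CohortError(
                f"{self.name}: unknown compartment {self.compartment!r}"
            )
        if not self.units:
            raise CohortError(f"{self.name}: units must be non-empty")
        if self.direction_policy not in DIRECTION_POLICIES:
            raise CohortError(
                f"{self.name}: unknown direction_policy {self.direction_policy!r}"
            )
        if self.source_group not in SOURCE_GROUPS:
            raise CohortError(
                f"{self.name}: unknown source_group {self.source_group!r}"
            )
        if self.direction_policy == "none" and self.include_in_model:
            raise CohortError(
                f"{self.name}: direction_policy 'none' implies include_in_model=False"
            )


@dataclass
class CycleRecord:
    """One insemination cycle of one couple."""

    couple_id: str
    cycle_index: int
    period: str
    values: dict[str, float | None]
    pregnancy: bool
    multiple_pregnancy: bool | None = None

    def __post_init__(self) -> None:
        if not 1 <= int(self.cycle_index) <= MAX_CYCLES:
            raise CohortError(
                f"couple {self.couple_id}: cycle_index {self.cycle_index} "
                f"outside [1, {MAX_CYCLES}]"
            )
        if self.period not in PERIODS:
            raise CohortError(
                f"couple {self.couple_id}: unknown period {self.period!r}"
            )
        if self.multiple_pregnancy and not self.pregnancy:
            raise CohortError(
                f"couple {self.couple_id} cycle {self.cycle_index}: "
                "multiple_pregnancy requires pregnancy"
            )


@dataclass
class Cohort:
    """An ordered collection of cycles plus the parameter schema."""

    cycles: list[CycleRecord] = field(default_factory=list)
    parameters: list[ParameterSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants --------------------------------------------------------

    def validate(self) -> None:
        names = [p.name for p in self.parameters]
        if len(set(names)) != len(names):
            raise CohortError("duplicate parameter names in schema")
        known = set(names)
        per_couple: dict[str, list[CycleRecord]] = defaultdict(list)
        for i, cyc in enumerate(self.cycles):
            extra = set(cyc.values) - known
            if extra:
                raise CohortError(
                    f"row {i} (couple {cyc.couple_id}): values for parameters "
                    f"not in schema: {sorted(extra)}"
                )
            per_couple[cyc.couple_id].append(cyc)
        for cid, cycs in per_couple.items():
            idx = [c.cycle_index for c in cycs]
            if len(set(idx)) != len(idx):
                raise CohortError(f"couple {cid}: duplicate cycle_index")
            if len({c.period for c in cycs}) > 1:
                raise CohortError(f"couple {cid}: appears in both periods")
            preg_idx = [c.cycle_index for c in cycs if c.pregnancy]
            if preg_idx and max(idx) > min(preg_idx):
                raise CohortError(
                    f"couple {cid}: cycle recorded after pregnancy at "
                    f"cycle {min(preg_idx)}"
                )

    # -- accessors ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.cycles)

    @property
    def parameter_names(self) -> list[str]:
        return [p.name for p in self.parameters]

    def couples(self) -> dict[str, list[CycleRecord]]:
        """Cycles grouped by couple, preserving order of first appearance."""
        grouped: dict[str, list[CycleRecord]] = {}
        for cyc in self.cycles:
            grouped.setdefault(cyc.couple_id, []).append(cyc)
        return grouped

    def values_for(
        self,
        parameter: str,
        pregnancy: bool | None = None,
    ) -> list[float]:
        """Non-missing values of one parameter, optionally restricted by outcome."""
        out = []
        for cyc in self.cycles:
            if pregnancy is not None and cyc.pregnancy != pregnancy:
                continue
            v = cyc.values.get(parameter)
            if v is not None and not (isinstance(v, float) and math.isnan(v)):
                out.append(float(v))
        return out

    def to_frame(self) -> pd.DataFrame:
        """Tabular view, one row per cycle, schema columns in schema order."""
        rows = []
        for cyc in self.cycles:
            row: dict[str, object] = {
                "couple_id": cyc.couple_id,
                "cycle_index": cyc.cycle_index,
                "period": cyc.period,
                "pregnancy": int(cyc.pregnancy),
                "multiple_pregnancy": (
                    "" if cyc.multiple_pregnancy is None
                    else int(cyc.multiple_pregnancy)
                ),
            }
            for name in self.parameter_names:
                v = cyc.values.get(name)
                row[name] = float("nan") if v is None else v
            rows.append(row)
        cols = ["couple_id", "cycle_index", "period", "pregnancy",
                "multiple_pregnancy", *self.parameter_names]
        return pd.DataFrame(rows, columns=cols)


# -- parameter schema CSV ---------------------------------------------------

_PARAM_COLS = ["name", "compartment", "units", "direction_policy",
               "source_group", "include_in_model"]


def read_parameters(path: str | Path) -> list[ParameterSpec]:
    path = Path(path)
    if not path.exists():
        raise CohortError(f"parameter file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(_PARAM_COLS) - set(df.columns)
    if missing:
        raise CohortError(f"{path}: missing columns {sorted(missing)}")
    specs = []
    for i, row in df.iterrows():
        flag = row["include_in_model"].strip().lower()
        if flag not in {"true", "false", "1", "0"}:
            raise CohortError(
                f"{path} row {i}: bad include_in_model {row['include_in_model']!r}"
            )
        specs.append(ParameterSpec(
            name=row["name"],
            compartment=row["compartment"],
            units=row["units"],
            direction_policy=row["direction_policy"],
            source_group=row["source_group"],
            include_in_model=flag in {"true", "1"},
        ))
    return specs


def write_parameters(specs: Sequence[ParameterSpec], path: str | Path) -> None:
    df = pd.DataFrame(
        [{
            "name": s.name,
            "compartment": s.compartment,
            "units": s.units,
            "direction_policy": s.direction_policy,
            "source_group": s.source_group,
            "include_in_model": str(s.include_in_model).lower(),
        } for s in specs],
        columns=_PARAM_COLS,
    )
    df.to_csv(path, index=False)


# -- cohort CSV -------------------------------------------------------------

_META_COLS = ["couple_id", "cycle_index", "period", "pregnancy",
              "multiple_pregnancy"]


def _parse_bool(cell: str, row: int, col: str) -> bool:
    s = cell.strip().lower()
    if s in {"1", "true"}:
        return True
    if s in {"0", "false"}:
        return False
    raise CohortError(f"row {row}, column {col}: cannot parse boolean {cell!r}")


def read_cohort(
    path: str | Path,
    schema: Sequence[ParameterSpec] | str | Path,
) -> Cohort:
    """Read and validate a per-cycle cohort CSV against a parameter schema.

    Raises :class:`CohortError` with row/column diagnostics for malformed
    cells, duplicate (couple, cycle) pairs, or sequence violations.
    """
    path = Path(path)
    if not path.exists():
        raise CohortError(f"cohort file not found: {path}")
    if not isinstance(schema, (list, tuple)):
        schema = read_parameters(schema)
    specs = list(schema)
    names = [s.name for s in specs]

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(_META_COLS) - set(df.columns)
    if missing:
        raise CohortError(f"{path}: missing columns {sorted(missing)}")
    unknown = set(df.columns) - set(_META_COLS) - set(names)
    if unknown:
        raise CohortError(
            f"{path}: columns not in parameter schema: {sorted(unknown)}"
        )

    cycles: list[CycleRecord] = []
    seen: set[tuple[str, int]] = set()
    for i, row in df.iterrows():
        try:
            cycle_index = int(row["cycle_index"])
        except ValueError:
            raise CohortError(
                f"row {i}, column cycle_index: cannot parse integer "
                f"{row['cycle_index']!r}"
            ) from None
        period_raw = row["period"].strip()
        if period_raw not in _PERIOD_ALIASES:
            raise CohortError(f"row {i}, column period: unknown {period_raw!r}")
        pregnancy = _parse_bool(row["pregnancy"], i, "pregnancy")
        mp_cell = row["multiple_pregnancy"].strip()
        multiple = None if mp_cell == "" else _parse_bool(
            mp_cell, i, "multiple_pregnancy")
        values: dict[str, float | None] = {}
        for name in names:
            cell = row.get(name, "")
            if cell is None or str(cell).strip() == "":
                values[name] = None
                continue
            try:
                values[name] = float(cell)
            except ValueError:
                raise CohortError(
                    f"row {i}, column {name}: cannot parse number {cell!r}"
                ) from None
        key = (row["couple_id"], cycle_index)
        if key in seen:
            raise CohortError(
                f"row {i}: duplicate (couple_id, cycle_index) = {key}"
            )
        seen.add(key)
        try:
            cycles.append(CycleRecord(
                couple_id=row["couple_id"],
                cycle_index=cycle_index,
                period=_PERIOD_ALIASES[period_raw],
                values=values,
                pregnancy=pregnancy,
                multiple_pregnancy=multiple,
            ))
        except CohortError as exc:
            raise CohortError(f"row {i}: {exc}") from None
    return Cohort(cycles=cycles, parameters=specs)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort CSV; ``read_cohort`` of the result round-trips."""
    df = cohort.to_frame()
    df.to_csv(path, index=False)


def split_periods(cohort: Cohort) -> tuple[Cohort, Cohort]:
    """Partition into (discovery, validation) sub-cohorts.

    Cluster structure is preserved; couples appearing in both periods are a
    structural error (already enforced by the Cohort invariant).
    """
    disc = [c for c in cohort.cycles if c.period == "discovery"]
    val = [c for c in cohort.cycles if c.period == "validation"]
    return (
        Cohort(cycles=disc, parameters=list(cohort.parameters)),
        Cohort(cycles=val, parameters=list(cohort.parameters)),
    )
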