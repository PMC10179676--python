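"""Extreme-value threshold discovery, consistency validation and binarization.

The procedure has three stages.  In the discovery period, for each parameter
and each permitted direction, a candidate cutoff is emitted whenever the
pregnancy group's extreme lies strictly inside the no-pregnancy group's range
on that side; the cutoff itself is taken from the parameter's configured
source group (pregnancy extremes for male parameters, no-pregnancy extremes
for most female parameters).  Candidates are then checked for consistency
against the validation period's source-group extremes, and surviving rules
are used to turn each cycle into a row of {0,1} "altered" flags.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, ParameterSpec

__all__ = [
    "ThresholdError",
    "ThresholdRule",
    "BinaryDesign",
    "discover",
    "validate",
    "binarize",
    "rules_to_json",
    "rules_from_json",
    "rules_to_csv",
]

logger = logging.getLogger(__name__)

DIRECTIONS = ("upper", "lower")
STATUSES = ("candidate", "validated", "dropped")
CUTOFF_POLICIES = ("discovery", "validation", "tighter")


class ThresholdError(ValueError):
    """Invalid threshold-stage input."""


@dataclass(frozen=True)
class ThresholdRule:
    """A directional cutoff: 'altered' means strictly beyond the cutoff.

    ``source_group`` records whose extreme defined the cutoff; it is needed
    again at validation time, so it is carried on the rule rather than
    looked up in the parameter schema.
    """

    parameter: str
    direction: str
    cutoff: float
    source_period: str = "discovery"
    status: str = "candidate"
    source_group: str = "pregnancy"

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ThresholdError(f"unknown direction {self.direction!r}")
        if self.status not in STATUSES:
            raise ThresholdError(f"unknown status {self.status!r}")
        if not math.isfinite(self.cutoff):
            raise ThresholdError(f"{self.parameter}: cutoff must be finite")

    def is_altered(self, value: float | None) -> bool | None:
        """1/0 flag for a value; ``None`` propagates missingness.

        Strictly beyond the cutoff is altered; a value equal to the cutoff
        is normal.
        """
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return None
        if self.direction == "upper":
            return value > self.cutoff
        return value < self.cutoff

    @property
    def column(self) -> str:
        return f"{self.parameter}_{self.direction}"


@dataclass
class BinaryDesign:
    """Per-cycle {0,1} altered flags ready for model fitting.

    ``flags`` is a float frame (NaN marks missing), one column per rule,
    aligned with ``outcome`` and ``cluster_id``.
    """

    flags: pd.DataFrame
    outcome: np.ndarray
    cluster_id: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.flags)
        if len(self.outcome) != n or len(self.cluster_id) != n:
            raise ThresholdError("flags/outcome/cluster_id length mismatch")
        vals = self.flags.to_numpy(dtype=float)
        ok = np.isnan(vals) | (vals == 0.0) | (vals == 1.0)
        if not ok.all():
            raise ThresholdError("flags must be 0, 1 or missing")

    @property
    def columns(self) -> list[str]:
        return list(self.flags.columns)

    def __len__(self) -> int:
        return len(self.flags)


def _check_unique(rules: Iterable[ThresholdRule]) -> None:
    seen = set()
    for r in rules:
        key = (r.parameter, r.direction)
        if key in seen:
            raise ThresholdError(f"duplicate rule for {key}")
        seen.add(key)


def _group_extremes(
    cohort: Cohort, parameter: str
) -> tuple[list[float], list[float]]:
    preg = cohort.values_for(parameter, pregnancy=True)
    nopreg = cohort.values_for(parameter, pregnancy=False)
    return preg, nopreg


def discover(
    discovery: Cohort,
    specs: Sequence[ParameterSpec] | None = None,
) -> list[ThresholdRule]:
    """Flag candidate extreme-value cutoffs in the discovery period.

    For each parameter and permitted direction, an upper candidate is emitted
    when ``max(pregnancy) < max(no_pregnancy)`` strictly (and symmetrically
    for lower); the cutoff is the source group's extreme on that side.
    Missing values are ignored per parameter.
    """
    if specs is None:
        specs = discovery.parameters
    n_preg = sum(c.pregnancy for c in discovery.cycles)
    n_nopreg = len(discovery.cycles) - n_preg
    if n_preg == 0 or n_nopreg == 0:
        raise ThresholdError(
            "discovery period needs at least one pregnancy and one "
            "non-pregnancy cycle; no rules derivable"
        )
    rules: list[ThresholdRule] = []
    for spec in specs:
        if spec.direction_policy == "none":
            continue
        preg, nopreg = _group_extremes(discovery, spec.name)
        if not preg or not nopreg:
            logger.warning(
                "parameter %s has no observed values in one or both outcome "
                "groups; skipped", spec.name)
            continue
        source = preg if spec.source_group == "pregnancy" else nopreg
        directions = (
            DIRECTIONS if spec.direction_policy == "both"
            else (spec.direction_policy,)
        )
        for direction in directions:
            if direction == "upper":
                contained = max(preg) < max(nopreg)
                cutoff = max(source)
            else:
                contained = min(preg) > min(nopreg)
                cutoff = min(source)
            if contained:
                rules.append(ThresholdRule(
                    parameter=spec.name,
                    direction=direction,
                    cutoff=cutoff,
                    source_period="discovery",
                    status="candidate",
                    source_group=spec.source_group,
                ))
    _check_unique(rules)
    return rules


def validate(
    candidates: Sequence[ThresholdRule],
    validation: Cohort,
    cutoff_policy: str = "discovery",
) -> list[ThresholdRule]:
    """Test candidate cutoffs for consistency in the validation period.

    An upper candidate survives iff the validation-period source-group
    maximum is <= the cutoff (boundary inclusive); a lower candidate iff the
    minimum is >= the cutoff.  Survivors keep the discovery cutoff by
    default; ``cutoff_policy`` may instead adopt the validation-period
    source-group extreme ("validation") or the tighter of the two
    ("tighter").
    """
    if cutoff_policy not in CUTOFF_POLICIES:
        raise ThresholdError(f"unknown cutoff_policy {cutoff_policy!r}")
    _check_unique(candidates)
    if candidates and not any(c.pregnancy for c in validation.cycles):
        raise ThresholdError("validation period contains no pregnancy")
    out: list[ThresholdRule] = []
    for rule in candidates:
        preg, nopreg = _group_extremes(validation, rule.parameter)
        source = preg if rule.source_group == "pregnancy" else nopreg
        if not source:
            logger.warning(
                "parameter %s absent from validation data; rule dropped",
                rule.parameter)
            out.append(replace(rule, status="dropped"))
            continue
        if rule.direction == "upper":
            v_extreme = max(source)
            ok = v_extreme <= rule.cutoff
            tighter = min(rule.cutoff, v_extreme)
        else:
            v_extreme = min(source)
            ok = v_extreme >= rule.cutoff
            tighter = max(rule.cutoff, v_extreme)
        if not ok:
            out.append(replace(rule, status="dropped"))
            continue
        if cutoff_policy == "discovery":
            cutoff, src = rule.cutoff, "discovery"
        elif cutoff_policy == "validation":
            cutoff, src = v_extreme, "validation"
        else:
            cutoff = tighter
            src = "discovery" if cutoff == rule.cutoff else "validation"
        out.append(replace(rule, status="validated", cutoff=cutoff,
                           source_period=src))
    return out


def binarize(
    cohort: Cohort,
    rules: Sequence[ThresholdRule],
    require_validated: bool = True,
) -> BinaryDesign:
    """Turn cycles into {0,1} altered flags under the given rules."""
    if require_validated:
        bad = [r for r in rules if r.status != "validated"]
        if bad:
            raise ThresholdError(
                "binarize requires validated rules; got "
                + ", ".join(f"{r.parameter}[{r.status}]" for r in bad)
            )
    _check_unique(rules)
    cols = {r.column: [] for r in rules}
    for cyc in cohort.cycles:
        for r in rules:
            flag = r.is_altered(cyc.values.get(r.parameter))
            cols[r.column].append(
                float("nan") if flag is None else float(flag))
    flags = pd.DataFrame(cols, columns=[r.column for r in rules],
                         dtype=float)
    if not rules:
        flags = pd.DataFrame(index=range(len(cohort.cycles)))
    outcome = np.array([int(c.pregnancy) for c in cohort.cycles])
    cluster = np.array([c.couple_id for c in cohort.cycles], dtype=object)
    return BinaryDesign(flags=flags, outcome=outcome, cluster_id=cluster)


# -- serialization ----------------------------------------------------------

def rules_to_json(rules: Sequence[ThresholdRule], path: str | Path) -> None:
    payload = [
        {
            "parameter": r.parameter,
            "direction": r.direction,
            "cutoff": r.cutoff,
            "source_period": r.source_period,
            "status": r.status,
            "source_group": r.source_group,
        }
        for r in rules
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def rules_from_json(path: str | Path) -> list[ThresholdRule]:
    payload = json.loads(Path(path).read_text())
    return [ThresholdRule(**item) for item in payload]


def rules_to_csv(rules: Sequence[ThresholdRule], path: str | Path) -> None:
    pd.DataFrame(
        [{
            "parameter": r.parameter,
            "direction": r.direction,
            "cutoff": r.cutoff,
            "source_period": r.source_period,
            "status": r.status,
            "source_group": r.source_group,
        } for r in rules],
        columns=["parameter", "direction", "cutoff", "source_period",
                 "status", "source_group"],
    ).to_csv(path, index=False)
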