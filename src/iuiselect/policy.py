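"""Eligibility decision rule and retrospective cohort evaluation.

A cycle is recommended for insemination unless ANY significant validated
rule flags one of its values as altered (rules with missing values abstain).
``evaluate_policy`` partitions all cycles by (recommended x pregnancy) and
reports the counterfactual pregnancy rate among retained cycles;
``describe`` computes the per-period and global descriptive statistics.

Printing conventions: the descriptive rates are displayed truncated (the
source tables truncate, e.g. 25/104 -> 24.03), while policy percentages use
conventional half-up rounding.  Unrounded values are always emitted
alongside.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .cohort import Cohort, CohortError, CycleRecord
from .thresholds import ThresholdRule

__all__ = [
    "PolicyResult",
    "DescriptiveReport",
    "recommend",
    "evaluate_policy",
    "predicted_rate_from_breakdown",
    "relative_increase_pct",
    "describe",
    "truncate",
    "round_half_up",
]


def truncate(x: float, ndigits: int = 2) -> float:
    """Truncate toward zero at ``ndigits`` decimals."""
    scale = 10 ** ndigits
    return math.trunc(x * scale) / scale


def round_half_up(x: float, ndigits: int = 0) -> float:
    scale = 10 ** ndigits
    return math.floor(x * scale + 0.5) / scale


def recommend(
    cycle: CycleRecord, rules: Sequence[ThresholdRule]
) -> bool:
    """True (proceed with IUI) unless any rule flags the cycle as altered."""
    for rule in rules:
        if rule.is_altered(cycle.values.get(rule.parameter)):
            return False
    return True


@dataclass
class PolicyResult:
    """Four-way retained/declined breakdown and counterfactual rates.

    All ``pct_*`` fields are percentages of ALL cycles; ``predicted_rate``
    is pregnancies among retained cycles over retained cycles (NaN when
    nothing is retained).
    """

    n_cycles: int
    n_retained_pregnant: int
    n_retained_nonpregnant: int
    n_declined_pregnant: int
    n_declined_nonpregnant: int
    per_cycle: list[bool]

    @property
    def pct_preg_retained(self) -> float:
        return 100.0 * self.n_retained_pregnant / self.n_cycles

    @property
    def pct_nonpreg_retained(self) -> float:
        return 100.0 * self.n_retained_nonpregnant / self.n_cycles

    @property
    def pct_preg_declined(self) -> float:
        return 100.0 * self.n_declined_pregnant / self.n_cycles

    @property
    def pct_nonpreg_declined(self) -> float:
        return 100.0 * self.n_declined_nonpregnant / self.n_cycles

    @property
    def observed_rate(self) -> float:
        return 100.0 * (self.n_retained_pregnant + self.n_declined_pregnant) \
            / self.n_cycles

    @property
    def predicted_rate(self) -> float:
        retained = self.n_retained_pregnant + self.n_retained_nonpregnant
        if retained == 0:
            warnings.warn("no retained cycles; predicted rate undefined",
                          stacklevel=2)
            return float("nan")
        return 100.0 * self.n_retained_pregnant / retained

    @property
    def relative_increase(self) -> float:
        return relative_increase_pct(self.predicted_rate, self.observed_rate)

    def to_dict(self) -> dict:
        return {
            "n_cycles": self.n_cycles,
            "n_retained_pregnant": self.n_retained_pregnant,
            "n_retained_nonpregnant": self.n_retained_nonpregnant,
            "n_declined_pregnant": self.n_declined_pregnant,
            "n_declined_nonpregnant": self.n_declined_nonpregnant,
            "pct_preg_retained": self.pct_preg_retained,
            "pct_nonpreg_retained": self.pct_nonpreg_retained,
            "pct_preg_declined": self.pct_preg_declined,
            "pct_nonpreg_declined": self.pct_nonpreg_declined,
            "observed_rate": self.observed_rate,
            "predicted_rate": self.predicted_rate,
            "relative_increase": self.relative_increase,
            "rounded": {
                "pct_preg_retained": round_half_up(self.pct_preg_retained, 1),
                "pct_nonpreg_retained": round_half_up(self.pct_nonpreg_retained, 1),
                "predicted_rate": round_half_up(self.predicted_rate, 1),
                "relative_increase": round_half_up(self.relative_increase, 0),
            },
        }


def predicted_rate_from_breakdown(
    pct_preg_retained: float, pct_nonpreg_retained: float
) -> float:
    """Counterfactual rate from a (pregnant, non-pregnant) retained
    breakdown expressed as percentages of all cycles."""
    total = pct_preg_retained + pct_nonpreg_retained
    if total == 0:
        raise ZeroDivisionError("no retained cycles")
    return 100.0 * pct_preg_retained / total


def relative_increase_pct(predicted: float, observed: float) -> float:
    if observed <= 0:
        return float("nan")
    return (predicted / observed - 1.0) * 100.0


def evaluate_policy(
    cohort: Cohort, rules: Sequence[ThresholdRule]
) -> PolicyResult:
    """Retrospectively apply the decline rule to every cycle."""
    if not cohort.cycles:
        raise CohortError("cannot evaluate policy on an empty cohort")
    per_cycle = [recommend(c, rules) for c in cohort.cycles]
    rp = rn = dp = dn = 0
    for cyc, keep in zip(cohort.cycles, per_cycle):
        if keep and cyc.pregnancy:
            rp += 1
        elif keep:
            rn += 1
        elif cyc.pregnancy:
            dp += 1
        else:
            dn += 1
    return PolicyResult(
        n_cycles=len(cohort.cycles),
        n_retained_pregnant=rp,
        n_retained_nonpregnant=rn,
        n_declined_pregnant=dp,
        n_declined_nonpregnant=dn,
        per_cycle=per_cycle,
    )


@dataclass
class DescriptiveReport:
    """Pregnancy/cycle/couple counts and rates, per period and global."""

    sections: dict[str, dict] = field(default_factory=dict)

    def __getitem__(self, key: str) -> dict:
        return self.sections[key]

    def to_dict(self) -> dict:
        return self.sections

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.sections, indent=2) + "\n")


def _describe_cycles(cycles: Sequence[CycleRecord]) -> dict:
    n_cycles = len(cycles)
    couples: dict[str, bool] = {}
    pregnancies = 0
    multiples = 0
    by_index = {i: 0 for i in range(1, 5)}
    for c in cycles:
        couples[c.couple_id] = couples.get(c.couple_id, False) or c.pregnancy
        if c.pregnancy:
            pregnancies += 1
            by_index[c.cycle_index] = by_index.get(c.cycle_index, 0) + 1
            if c.multiple_pregnancy:
                multiples += 1
    n_couples = len(couples)
    pregnant_couples = sum(couples.values())
    rate_cycle = 100.0 * pregnancies / n_cycles if n_cycles else 0.0
    rate_couple = 100.0 * pregnant_couples / n_couples if n_couples else 0.0
    rate_multiple = 100.0 * multiples / pregnancies if pregnancies else 0.0
    return {
        "pregnancies": pregnancies,
        "cycles": n_cycles,
        "couples": n_couples,
        "pregnant_couples": pregnant_couples,
        "multiple_pregnancies": multiples,
        "pregnancies_by_cycle_index": by_index,
        "rate_per_cycle": rate_cycle,
        "cumulative_rate_per_couple": rate_couple,
        "multiple_pregnancy_rate": rate_multiple,
        "printed": {
            "rate_per_cycle": truncate(rate_cycle, 2),
            "cumulative_rate_per_couple": truncate(rate_couple, 2),
            "rate_per_cycle_1dp": truncate(rate_cycle, 1),
            "cumulative_rate_per_couple_1dp": truncate(rate_couple, 1),
            "multiple_pregnancy_rate": truncate(rate_multiple, 2),
        },
    }


def describe(cohort: Cohort) -> DescriptiveReport:
    """Descriptive statistics per recruitment period and globally."""
    sections: dict[str, dict] = {}
    for period in ("discovery", "validation"):
        cycles = [c for c in cohort.cycles if c.period == period]
        if cycles:
            sections[period] = _describe_cycles(cycles)
    sections["global"] = _describe_cycles(cohort.cycles)
    return DescriptiveReport(sections=sections)
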