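"""Synthetic IUI cohorts with the statistical structure the analysis assumes.

Couple-level covariates are drawn once per couple from truncated normals
(constant across that couple's cycles, as most are measured once per
patient); per-cycle pregnancy is Bernoulli from a logistic model with a
couple-level normal random intercept, which induces approximately
exchangeable within-couple correlation.  Optional hard threshold rules force
the pregnancy probability to zero beyond a cutoff, and anchor records are
placed so downstream discovery recovers each hard cutoff exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cohort import Cohort, CohortError, CycleRecord, ParameterSpec
from .thresholds import ThresholdRule

__all__ = [
    "TruncatedNormal",
    "CovariateModel",
    "OutcomeModel",
    "SyntheticConfig",
    "default_parameters",
    "default_covariate_model",
    "generate_cohort",
    "fixture_from_extremes",
    "cohort_from_counts",
    "empirical_icc",
]


@dataclass(frozen=True)
class TruncatedNormal:
    mean: float
    sd: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise CohortError("sd must be >= 0")
        if self.low > self.high:
            raise CohortError(f"invalid truncation: low {self.low} > high {self.high}")

    def sample(self, rng: np.random.Generator) -> float:
        """Rejection sampling; falls back to clipping for extreme bounds."""
        if self.sd == 0:
            return float(min(max(self.mean, self.low), self.high))
        for _ in range(1000):
            x = rng.normal(self.mean, self.sd)
            if self.low <= x <= self.high:
                return float(x)
        return float(min(max(rng.normal(self.mean, self.sd), self.low),
                         self.high))


@dataclass
class CovariateModel:
    """Per-parameter truncated-normal marginals (mean, sd, low, high)."""

    distributions: dict[str, TruncatedNormal] = field(default_factory=dict)

    def __getitem__(self, name: str) -> TruncatedNormal:
        return self.distributions[name]

    @classmethod
    def from_dict(cls, spec: Mapping[str, Mapping[str, float]]) -> "CovariateModel":
        return cls({
            name: TruncatedNormal(d["mean"], d["sd"], d["low"], d["high"])
            for name, d in spec.items()
        })


@dataclass
class OutcomeModel:
    """Logistic outcome model with couple random intercept and hard rules."""

    intercept: float
    coefficients: dict[str, float] = field(default_factory=dict)
    random_intercept_sd: float = 0.0
    hard_rules: list[ThresholdRule] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.random_intercept_sd < 0:
            raise CohortError("random_intercept_sd must be >= 0")


@dataclass
class SyntheticConfig:
    couples_discovery: int
    couples_validation: int
    covariates: CovariateModel
    outcome: OutcomeModel
    seed: int
    max_cycles: int = 4

    def __post_init__(self) -> None:
        if self.couples_discovery < 0 or self.couples_validation < 0:
            raise CohortError("couple counts must be >= 0")
        if self.max_cycles < 1:
            raise CohortError("max_cycles must be >= 1")


# Reference marginals (mean, sd, min, max) for the defaults; values follow
# the descriptive tables of the source cohort.
_DEFAULT_MARGINALS: dict[str, tuple[float, float, float, float, str, str, str, str]] = {
    # name: (mean, sd, low, high, compartment, units, direction, source)
    "male_age": (34.99, 4.46, 26.0, 44.0, "male_demographic", "years", "upper", "pregnancy"),
    "ejaculate_volume": (3.69, 1.62, 0.5, 8.0, "ejaculate", "mL", "none", "pregnancy"),
    "ejaculate_concentration": (93.67, 64.87, 4.0, 439.0, "ejaculate", "10^6 sperm/mL", "lower", "pregnancy"),
    "ejaculate_total_count": (315.27, 233.75, 12.5, 1223.0, "ejaculate", "10^6 sperm", "lower", "pregnancy"),
    "ejaculate_progressive_motility": (46.01, 18.31, 5.0, 86.0, "ejaculate", "%", "lower", "pregnancy"),
    "ejaculate_immotile": (32.07, 19.60, 1.0, 86.0, "ejaculate", "%", "upper", "pregnancy"),
    "ejaculate_total_motile": (164.52, 159.72, 2.5, 819.0, "ejaculate", "10^6 sperm", "lower", "pregnancy"),
    "ejaculate_morphology": (6.19, 4.14, 1.0, 18.0, "ejaculate", "%", "lower", "pregnancy"),
    "ejaculate_alkaline_comet": (47.04, 12.88, 22.0, 82.0, "ejaculate", "%", "upper", "pregnancy"),
    "ejaculate_neutral_comet": (56.21, 17.05, 23.0, 91.0, "ejaculate", "%", "upper", "pregnancy"),
    "swimup_concentration": (85.70, 69.99, 1.19, 395.95, "swim_up", "10^6 sperm/mL", "none", "pregnancy"),
    "swimup_total_count": (34.85, 28.11, 0.48, 158.38, "swim_up", "10^6 sperm", "none", "pregnancy"),
    "swimup_progressive_motility": (72.87, 19.33, 10.0, 98.0, "swim_up", "%", "lower", "pregnancy"),
    "swimup_immotile": (13.75, 15.79, 0.0, 81.0, "swim_up", "%", "upper", "pregnancy"),
    "swimup_total_motile": (25.27, 21.72, 0.26, 125.12, "swim_up", "10^6 sperm", "none", "pregnancy"),
    "swimup_alkaline_comet": (42.27, 11.92, 20.0, 75.0, "swim_up", "%", "upper", "pregnancy"),
    "swimup_neutral_comet": (52.47, 16.33, 17.0, 91.0, "swim_up", "%", "upper", "pregnancy"),
    "female_age": (32.54, 4.39, 21.0, 40.0, "female", "years", "upper", "no_pregnancy"),
    "female_bmi": (24.84, 6.14, 17.24, 45.0, "female", "kg/m^2", "upper", "no_pregnancy"),
    "infertility_duration": (25.64, 19.74, 5.0, 120.0, "female", "months", "upper", "no_pregnancy"),
    "fsh": (6.73, 1.74, 1.58, 11.4, "female", "mUI/mL", "upper", "pregnancy"),
    "lh": (6.40, 3.91, 0.54, 27.28, "female", "mUI/mL", "upper", "no_pregnancy"),
    "estradiol": (52.30, 47.65, 6.0, 450.0, "female", "pg/mL", "lower", "no_pregnancy"),
    "prolactin": (14.91, 8.90, 3.18, 77.82, "female", "ng/mL", "none", "pregnancy"),
    "antral_follicle_count": (14.01, 6.85, 3.0, 30.0, "female", "count", "lower", "no_pregnancy"),
}


def default_parameters() -> list[ParameterSpec]:
    """Parameter schema matching the default covariate model."""
    return [
        ParameterSpec(
            name=name, compartment=comp, units=units,
            direction_policy=direction, source_group=source,
            include_in_model=direction != "none",
        )
        for name, (_, _, _, _, comp, units, direction, source)
        in _DEFAULT_MARGINALS.items()
    ]


def default_covariate_model() -> CovariateModel:
    return CovariateModel({
        name: TruncatedNormal(m, s, lo, hi)
        for name, (m, s, lo, hi, *_rest) in _DEFAULT_MARGINALS.items()
    })


def _hard_rule_blocks(rules: Sequence[ThresholdRule],
                      values: Mapping[str, float | None]) -> bool:
    for rule in rules:
        if rule.is_altered(values.get(rule.parameter)):
            return True
    return False


def _beyond(rule: ThresholdRule, dist: TruncatedNormal | None) -> float:
    """A value strictly beyond a rule's cutoff, kept inside any bounds."""
    span = abs(rule.cutoff) * 0.05 + 1.0
    if rule.direction == "upper":
        v = rule.cutoff + span
        if dist is not None and dist.high > rule.cutoff:
            v = min(v, (rule.cutoff + dist.high) / 2.0)
        return v
    v = rule.cutoff - span
    if dist is not None and dist.low < rule.cutoff:
        v = max(v, (rule.cutoff + dist.low) / 2.0)
    return v


def generate_cohort(
    config: SyntheticConfig,
    parameters: Sequence[ParameterSpec] | None = None,
) -> Cohort:
    """Simulate a two-period cohort; fully reproducible from ``config.seed``.

    When ``hard_rules`` are present, the first ``2 * n_rules`` couples of
    each period are anchors: one pregnant couple sits exactly at each
    cutoff, and one never-pregnant couple sits strictly beyond it, so that
    the pregnancy-group extreme in each period equals the cutoff and
    threshold discovery recovers it exactly.
    """
    if parameters is None:
        parameters = [
            spec for spec in default_parameters()
            if spec.name in config.covariates.distributions
        ]
        known = {p.name for p in parameters}
        for name in config.covariates.distributions:
            if name not in known:
                parameters = list(parameters) + [ParameterSpec(
                    name=name, compartment="female", units="a.u.",
                    direction_policy="both", include_in_model=True)]
    rng = np.random.default_rng(config.seed)
    rules = list(config.outcome.hard_rules)
    cycles: list[CycleRecord] = []

    for period, n_couples, prefix in (
        ("discovery", config.couples_discovery, "D"),
        ("validation", config.couples_validation, "V"),
    ):
        n_anchor = 2 * len(rules)
        if rules and 0 < n_couples < n_anchor:
            raise CohortError(
                f"{period}: {n_couples} couples cannot host "
                f"{n_anchor} hard-rule anchors")
        for k in range(n_couples):
            cid = f"{prefix}{k + 1:04d}"
            values = {
                name: config.covariates[name].sample(rng)
                for name in config.covariates.distributions
            }
            b = (rng.normal(0.0, config.outcome.random_intercept_sd)
                 if config.outcome.random_intercept_sd > 0 else 0.0)
            anchor_role = None
            if rules and k < n_anchor:
                rule = rules[k // 2]
                if k % 2 == 0:  # pregnant anchor exactly at the cutoff
                    values[rule.parameter] = float(rule.cutoff)
                    anchor_role = "pregnant"
                else:  # never-pregnant anchor strictly beyond
                    dist = config.covariates.distributions.get(rule.parameter)
                    values[rule.parameter] = _beyond(rule, dist)
                    anchor_role = "blocked"
                # keep other anchored parameters inside their cutoffs
                for other in rules:
                    if other.parameter == rule.parameter and other is not rule:
                        continue
                    if other is rule:
                        continue
                    if other.is_altered(values.get(other.parameter)):
                        values[other.parameter] = float(other.cutoff)
            if anchor_role == "pregnant":
                cycles.append(CycleRecord(cid, 1, period, dict(values),
                                          pregnancy=True))
                continue
            for c in range(1, config.max_cycles + 1):
                if anchor_role == "blocked":
                    preg = False
                else:
                    eta = config.outcome.intercept + b + sum(
                        coef * values[name]
                        for name, coef in config.outcome.coefficients.items()
                    )
                    prob = 1.0 / (1.0 + math.exp(-eta)) if eta > -700 else 0.0
                    if _hard_rule_blocks(rules, values):
                        prob = 0.0
                    preg = bool(rng.random() < prob)
                cycles.append(CycleRecord(cid, c, period, dict(values),
                                          pregnancy=preg))
                if preg:
                    break
    return Cohort(cycles=cycles, parameters=list(parameters))


def fixture_from_extremes(
    extremes: Mapping[str, Mapping[str, Mapping[str, Sequence[float]]]],
    n_per_group: int = 6,
    seed: int = 0,
    parameters: Sequence[ParameterSpec] | None = None,
) -> Cohort:
    """Cohort whose per-period, per-group observed min/max EQUAL a table.

    ``extremes[period][parameter][group] = (min, max)`` with period in
    {discovery, validation} and group in {pregnancy, no_pregnancy}.  The two
    extremes are placed as actual records (record 0 carries every minimum,
    record 1 every maximum); the remaining ``n_per_group - 2`` records are
    drawn uniformly strictly inside the range.  Each record is its own
    single-cycle couple, so cluster invariants hold trivially.
    """
    if n_per_group < 2:
        raise CohortError("n_per_group must be >= 2 to realise both extremes")
    rng = np.random.default_rng(seed)
    all_params: list[str] = []
    for table in extremes.values():
        for name in table:
            if name not in all_params:
                all_params.append(name)
    if parameters is None:
        parameters = [
            ParameterSpec(name=n, compartment="female", units="a.u.",
                          direction_policy="both", include_in_model=True)
            for n in all_params
        ]
    cycles: list[CycleRecord] = []
    serial = 0
    for period in ("discovery", "validation"):
        table = extremes.get(period, {})
        if not table:
            continue
        for group in ("no_pregnancy", "pregnancy"):
            for i in range(n_per_group):
                serial += 1
                values: dict[str, float | None] = {}
                for name in all_params:
                    rng_pair = table.get(name, {}).get(group)
                    if rng_pair is None:
                        values[name] = None
                        continue
                    lo, hi = float(rng_pair[0]), float(rng_pair[1])
                    if lo > hi:
                        raise CohortError(
                            f"{period}/{name}/{group}: min {lo} > max {hi}")
                    if i == 0:
                        values[name] = lo
                    elif i == 1:
                        values[name] = hi
                    else:
                        values[name] = float(rng.uniform(lo, hi))
                cycles.append(CycleRecord(
                    couple_id=f"F{serial:04d}", cycle_index=1, period=period,
                    values=values, pregnancy=(group == "pregnancy")))
    return Cohort(cycles=cycles, parameters=list(parameters))


def cohort_from_counts(
    period: str,
    n_couples: int,
    n_cycles: int,
    pregnancies_by_cycle_index: Mapping[int, int],
    n_multiple: int = 0,
    couple_prefix: str = "C",
) -> Cohort:
    """Covariate-free cohort realising exact printed counts.

    Builds ``n_couples`` couples totalling ``n_cycles`` cycles where
    ``pregnancies_by_cycle_index[k]`` couples achieve pregnancy at cycle k
    (and stop there); the remaining couples never conceive and their cycle
    counts are spread in 1..4 to hit the cycle total.  The first
    ``n_multiple`` pregnancies are marked multiple.  Useful to reproduce
    descriptive statistics from published counts alone.
    """
    by_idx = {int(k): int(v) for k, v in pregnancies_by_cycle_index.items()}
    preg_couples = sum(by_idx.values())
    preg_cycles = sum(k * v for k, v in by_idx.items())
    rest_couples = n_couples - preg_couples
    rest_cycles = n_cycles - preg_cycles
    if rest_couples < 0 or rest_cycles < 0:
        raise CohortError("pregnancy counts exceed couple/cycle totals")
    if rest_couples == 0 and rest_cycles > 0:
        raise CohortError("cycles left over but no couples to host them")
    if rest_couples > 0 and not (
            rest_couples <= rest_cycles <= 4 * rest_couples):
        raise CohortError(
            f"cannot place {rest_cycles} cycles on {rest_couples} couples "
            "(1..4 cycles each)")
    cycles: list[CycleRecord] = []
    serial = 0
    placed_multiple = 0
    for idx in sorted(by_idx):
        for _ in range(by_idx[idx]):
            serial += 1
            cid = f"{couple_prefix}{serial:04d}"
            for c in range(1, idx + 1):
                preg = c == idx
                multi = None
                if preg and placed_multiple < n_multiple:
                    multi = True
                    placed_multiple += 1
                elif preg:
                    multi = False
                cycles.append(CycleRecord(cid, c, period, {}, preg, multi))
    if rest_couples:
        base, extra = divmod(rest_cycles, rest_couples)
        for j in range(rest_couples):
            serial += 1
            cid = f"{couple_prefix}{serial:04d}"
            k = base + (1 if j < extra else 0)
            for c in range(1, k + 1):
                cycles.append(CycleRecord(cid, c, period, {}, False, None))
    return Cohort(cycles=cycles, parameters=[])


def empirical_icc(cohort: Cohort) -> float:
    """Moment estimator of the within-couple outcome correlation.

    Average of (y_j - ybar)(y_k - ybar) over all within-couple pairs,
    divided by the overall outcome variance.  Raises if no couple has two or
    more cycles.
    """
    y = np.array([float(c.pregnancy) for c in cohort.cycles])
    if len(y) == 0:
        raise CohortError("empty cohort")
    ybar = y.mean()
    var = float(((y - ybar) ** 2).mean())
    cross = 0.0
    n_pairs = 0
    for cycs in cohort.couples().values():
        r = np.array([float(c.pregnancy) for c in cycs]) - ybar
        m = len(r)
        if m < 2:
            continue
        cross += float((r.sum() ** 2 - (r ** 2).sum()) / 2.0)
        n_pairs += m * (m - 1) // 2
    if n_pairs == 0:
        raise CohortError("no couple with >= 2 cycles; ICC undefined")
    if var == 0.0:
        raise CohortError("outcome constant; ICC undefined")
    return cross / (n_pairs * var)
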