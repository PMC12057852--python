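"""Exhaustive mining of 1- and 2-condition association rules.

A rule A -> B states that participants meeting every condition in the
antecedent A (the "applicable group") tend to show the consequent item B.
With counts from the 2x2 applicable x outcome table —

    a = |A and B|,  b = |A and not B|,  c = |not A and B|,  d = rest,
    N = a + b + c + d

— the three rule metrics are

    support    = a / N
    confidence = a / (a + b)
    lift       = confidence / prior(B),   prior(B) = (a + c) / N.

Lift above 1 means the antecedent raises the chance of the consequent;
its ceiling is 1 / prior(B), attained exactly at confidence 1.  The
cohorts here are small (tens of participants, ~30 items), so rules are
enumerated exhaustively — no Apriori pruning is needed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

from .discretize import Item, ItemMatrix
from .errors import DegenerateDataError, UndefinedMetricError

DEFAULT_MIN_CONFIDENCE = 0.80
DEFAULT_MIN_LIFT = 1.1


@dataclass(frozen=True)
class AssociationRule:
    """An antecedent item set, a consequent item, and their joint counts."""

    antecedent: frozenset[Item]
    consequent: Item
    n_total: int
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if self.a + self.b + self.c + self.d != self.n_total:
            raise ValueError("counts do not partition N")
        if self.a + self.b < 1:
            raise ValueError("empty applicable group")
        variables = [it.variable for it in self.antecedent]
        if len(set(variables)) != len(variables):
            raise ValueError("antecedent uses one variable twice")
        if self.consequent.variable in variables:
            raise ValueError("antecedent reuses the consequent's variable")

    @property
    def order(self) -> int:
        return len(self.antecedent)

    @property
    def support(self) -> float:
        return self.a / self.n_total

    @property
    def confidence(self) -> float:
        return self.a / (self.a + self.b)

    @property
    def prior(self) -> float:
        return (self.a + self.c) / self.n_total

    @property
    def lift(self) -> float:
        return float(self.lift_frac)

    @property
    def support_frac(self) -> Fraction:
        return Fraction(self.a, self.n_total)

    @property
    def confidence_frac(self) -> Fraction:
        return Fraction(self.a, self.a + self.b)

    @property
    def lift_frac(self) -> Fraction:
        if self.a + self.c == 0:
            raise UndefinedMetricError("lift undefined: consequent never occurs")
        return Fraction(self.a * self.n_total, (self.a + self.b) * (self.a + self.c))

    @property
    def lift_ceiling(self) -> float:
        """Maximum lift attainable against this consequent: N / (a + c)."""
        return self.n_total / (self.a + self.c)

    def antecedent_labels(self) -> tuple[str, ...]:
        return tuple(sorted(it.label for it in self.antecedent))


@dataclass(frozen=True)
class MiningConfig:
    """Extraction gates for rule mining.

    Defaults follow the conventional clinical-rule thresholds: keep a
    rule when confidence >= 0.80 and lift >= 1.1; no support floor.
    """

    consequent: Item
    max_order: int = 2
    min_confidence: float = DEFAULT_MIN_CONFIDENCE
    min_lift: float = DEFAULT_MIN_LIFT
    min_support: float = 0.0
    excluded_variables: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.max_order not in (1, 2):
            raise ValueError("max_order must be 1 or 2")
        if not (0.0 <= self.min_confidence <= 1.01):
            raise ValueError("min_confidence out of range")
        if not (0.0 <= self.min_support <= 1.0):
            raise ValueError("min_support out of range")
        if self.min_lift <= 0:
            raise ValueError("min_lift must be positive")


def rule_metrics_from_counts(
    a: int, b: int, c: int, d: int
) -> tuple[float, float, float]:
    """Support, confidence and lift from 2x2 counts (a, b, c, d).

    ``a`` counts participants with both antecedent and consequent, ``b``
    antecedent only, ``c`` consequent only, ``d`` neither.
    """
    for name, v in zip("abcd", (a, b, c, d)):
        if v < 0:
            raise ValueError(f"negative count {name}={v}")
    n = a + b + c + d
    if a + b == 0:
        raise UndefinedMetricError("confidence undefined: empty applicable group")
    if a + c == 0:
        raise UndefinedMetricError("lift undefined: consequent never occurs")
    support = a / n
    confidence = a / (a + b)
    lift = confidence * n / (a + c)
    return support, confidence, lift


def count_rule(
    matrix: ItemMatrix, antecedent: Iterable[Item], consequent: Item
) -> tuple[int, int, int, int]:
    """Count the 2x2 applicable x outcome table for one candidate rule.

    A participant is applicable iff every antecedent item is true for
    them (conjunction).
    """
    antecedent = list(antecedent)
    variables = [it.variable for it in antecedent]
    if len(set(variables)) != len(variables):
        raise ValueError("antecedent contains two states of one variable")
    if consequent.variable in variables:
        raise ValueError("antecedent reuses the consequent's variable")
    applicable = np.ones(matrix.n, dtype=bool)
    for it in antecedent:
        applicable &= matrix.column(it)
    outcome = matrix.column(consequent)
    a = int(np.sum(applicable & outcome))
    b = int(np.sum(applicable & ~outcome))
    c = int(np.sum(~applicable & outcome))
    d = int(np.sum(~applicable & ~outcome))
    return a, b, c, d


def _candidate_items(matrix: ItemMatrix, config: MiningConfig) -> list[Item]:
    excluded = set(config.excluded_variables) | {config.consequent.variable}
    return [it for it in matrix.items if it.variable not in excluded]


def _passes(rule: AssociationRule, config: MiningConfig) -> bool:
    return (
        rule.confidence_frac >= Fraction(config.min_confidence).limit_denominator(10**6)
        and rule.lift_frac >= Fraction(config.min_lift).limit_denominator(10**6)
        and rule.support_frac >= Fraction(config.min_support).limit_denominator(10**6)
    )


def mine_rules(matrix: ItemMatrix, config: MiningConfig) -> list[AssociationRule]:
    """Enumerate every rule of order <= max_order that passes the gates.

    Output order is deterministic: lift descending, then confidence,
    then support, then lexicographic antecedent labels.  Raises when
    the consequent is degenerate (present in all or no participants).
    """
    if matrix.n == 0:
        raise DegenerateDataError("empty item matrix")
    outcome = matrix.column(config.consequent)
    n_true = int(outcome.sum())
    if n_true == 0 or n_true == matrix.n:
        raise DegenerateDataError(
            f"degenerate consequent {config.consequent.key()}: prior "
            f"{n_true}/{matrix.n}"
        )
    candidates = _candidate_items(matrix, config)
    rules: list[AssociationRule] = []
    pools: list[Iterable[tuple[Item, ...]]] = [
        ((it,) for it in candidates)
    ]
    if config.max_order >= 2:
        pools.append(
            pair
            for pair in itertools.combinations(candidates, 2)
            if pair[0].variable != pair[1].variable
        )
    for pool in pools:
        for antecedent in pool:
            a, b, c, d = count_rule(matrix, antecedent, config.consequent)
            if a + b == 0:  # antecedent never realized; no rule to state
                continue
            rule = AssociationRule(
                antecedent=frozenset(antecedent),
                consequent=config.consequent,
                n_total=matrix.n,
                a=a,
                b=b,
                c=c,
                d=d,
            )
            if _passes(rule, config):
                rules.append(rule)
    rules.sort(
        key=lambda r: (
            -r.lift_frac,
            -r.confidence_frac,
            -r.support_frac,
            r.antecedent_labels(),
        )
    )
    return rules


@dataclass(frozen=True)
class RuleComparison:
    """Single-vs-combined comparison for one combined rule."""

    combined: AssociationRule
    constituents: tuple[AssociationRule, ...]
    strengthened: bool
    lift_ceiling: float


def compare_single_vs_combined(
    singles: Sequence[AssociationRule], combined: Sequence[AssociationRule]
) -> list[RuleComparison]:
    """For each combined rule, find its gate-passing single constituents
    and flag whether confidence AND lift strictly improved on all of them.

    A combined rule with no extracted single constituent is reported
    with ``strengthened=False`` (there is nothing it strengthens).
    """
    all_rules = list(singles) + list(combined)
    consequents = {r.consequent for r in all_rules}
    if len(consequents) > 1:
        raise ValueError("rules mix different consequents")
    totals = {r.n_total for r in all_rules}
    if len(totals) > 1:
        raise ValueError("rules mix different cohort sizes")
    by_item = {next(iter(r.antecedent)): r for r in singles if r.order == 1}
    reports = []
    for rule in combined:
        constituents = tuple(
            by_item[it] for it in sorted(rule.antecedent, key=lambda i: i.key())
            if it in by_item
        )
        strengthened = bool(constituents) and all(
            rule.confidence_frac > s.confidence_frac and rule.lift_frac > s.lift_frac
            for s in constituents
        )
        reports.append(
            RuleComparison(
                combined=rule,
                constituents=constituents,
                strengthened=strengthened,
                lift_ceiling=rule.lift_ceiling,
            )
        )
    return reports
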