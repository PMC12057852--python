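"""Contingency-table tests for extracted rules.

Each rule's applicable / non-applicable x outcome 2x2 table is tested
for association at a 5% level.  The test is chosen by Cochran's rule:
Fisher's exact test whenever any expected cell count (row total x
column total / N) falls below 5, otherwise the chi-square test without
continuity correction.  Fisher's two-sided p-value sums the
hypergeometric probabilities of all tables with probability no larger
than the observed one (scipy's convention).

No multiplicity adjustment is applied by default; Benjamini-Hochberg
adjusted p-values can be reported alongside the raw ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateDataError
from .mining import AssociationRule

FISHER = "fisher"
CHISQ = "chisq"
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class RuleTestResult:
    rule: AssociationRule | None
    table: tuple[int, int, int, int]
    test_used: str
    p_value: float
    alpha: float
    significant: bool
    expected_counts: tuple[float, float, float, float]
    p_adjusted: float | None = None


def expected_counts(a: int, b: int, c: int, d: int) -> tuple[float, float, float, float]:
    """Expected cell counts under independence (row x column margins / N)."""
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    return (r1 * c1 / n, r1 * c2 / n, r2 * c1 / n, r2 * c2 / n)


def choose_test(a: int, b: int, c: int, d: int) -> str:
    """Cochran's rule: Fisher if any expected count < 5, else chi-square."""
    for name, v in zip("abcd", (a, b, c, d)):
        if v < 0:
            raise ValueError(f"negative count {name}={v}")
    if a + b == 0 or c + d == 0:
        raise DegenerateDataError("empty row margin: table admits no test")
    if min(expected_counts(a, b, c, d)) < 5:
        return FISHER
    return CHISQ


def test_table(
    a: int,
    b: int,
    c: int,
    d: int,
    alpha: float = DEFAULT_ALPHA,
    rule: AssociationRule | None = None,
    yates: bool = False,
) -> RuleTestResult:
    """Two-sided association test on a 2x2 table with automatic test choice."""
    test = choose_test(a, b, c, d)
    table = np.array([[a, b], [c, d]])
    if test == FISHER:
        p = float(stats.fisher_exact(table, alternative="two-sided").pvalue)
    else:
        p = float(
            stats.chi2_contingency(table, correction=yates).pvalue
        )
    return RuleTestResult(
        rule=rule,
        table=(a, b, c, d),
        test_used=test,
        p_value=p,
        alpha=alpha,
        significant=p < alpha,
        expected_counts=expected_counts(a, b, c, d),
    )


def test_rule(
    rule: AssociationRule, alpha: float = DEFAULT_ALPHA, yates: bool = False
) -> RuleTestResult:
    return test_table(rule.a, rule.b, rule.c, rule.d, alpha=alpha, rule=rule, yates=yates)


def test_all(
    rules: Sequence[AssociationRule],
    alpha: float = DEFAULT_ALPHA,
    adjustment: str = "none",
    yates: bool = False,
) -> list[RuleTestResult]:
    """Test every rule in input order, optionally with BH adjustment.

    When ``adjustment='benjamini_hochberg'`` the adjusted p-values are
    reported alongside the raw ones; the significance flag stays based
    on the raw p-value (adjustment is a reporting option, not a gate).
    """
    if not rules:
        raise ValueError("no rules to test")
    if adjustment not in ("none", "benjamini_hochberg"):
        raise ValueError(f"unknown adjustment {adjustment!r}")
    results = [test_rule(r, alpha=alpha, yates=yates) for r in rules]
    if adjustment == "benjamini_hochberg":
        adjusted = stats.false_discovery_control(
            [r.p_value for r in results], method="bh"
        )
        results = [
            RuleTestResult(
                rule=r.rule,
                table=r.table,
                test_used=r.test_used,
                p_value=r.p_value,
                alpha=r.alpha,
                significant=r.significant,
                expected_counts=r.expected_counts,
                p_adjusted=float(p_adj),
            )
            for r, p_adj in zip(results, adjusted)
        ]
    return results
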