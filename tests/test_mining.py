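from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from krqol import count_rule, mine_rules, rule_metrics_from_counts
from krqol.discretize import Item
from krqol.errors import DegenerateDataError, UndefinedMetricError
from krqol.mining import (
    AssociationRule,
    MiningConfig,
    compare_single_vs_combined,
)
from krqol.reconstruct import matrix_from_counts, matrix_from_single_rule_counts
from krqol.reference_counts import SINGLE_RULE_COUNTS, SLUG_ITEMS

from conftest import random_item_matrix


# ---------------------------------------------------------------- metrics


@pytest.mark.parametrize(
    "counts, expected",
    [
        # published worked examples (consequent: low 2-year PCS, N=44)
        ((10, 0, 22, 12), (10 / 44, 1.0, 44 / 32)),
        ((24, 3, 8, 9), (24 / 44, 24 / 27, (24 / 27) / (32 / 44))),
        ((22, 4, 10, 8), (0.5, 22 / 26, (22 / 26) / (32 / 44))),
    ],
)
def test_metrics_from_published_counts(counts, expected):
    support, confidence, lift = rule_metrics_from_counts(*counts)
    assert support == pytest.approx(expected[0])
    assert confidence == pytest.approx(expected[1])
    assert lift == pytest.approx(expected[2])


@given(st.integers(1, 50), st.integers(1, 50))
@settings(deadline=None, derandomize=True)
def test_perfect_rule_closed_form(k, m):
    """(k, 0, 0, m): support k/(k+m), confidence 1, lift (k+m)/k."""
    support, confidence, lift = rule_metrics_from_counts(k, 0, 0, m)
    assert support == pytest.approx(k / (k + m))
    assert confidence == 1.0
    assert lift == pytest.approx((k + m) / k)


def test_metrics_undefined_cases():
    with pytest.raises(UndefinedMetricError, match="confidence"):
        rule_metrics_from_counts(0, 0, 5, 5)
    with pytest.raises(UndefinedMetricError, match="lift"):
        rule_metrics_from_counts(0, 5, 0, 5)
    with pytest.raises(ValueError, match="negative"):
        rule_metrics_from_counts(-1, 5, 2, 5)


# ---------------------------------------------------------------- counting


def test_count_rule_matches_brute_force():
    """count_rule equals a per-participant loop on random matrices."""
    rng = np.random.default_rng(7)
    for _ in range(20):
        m = random_item_matrix(rng, 30, 6)
        consequent = m.items[0]
        for order in (1, 2):
            candidates = [it for it in m.items if it.variable != consequent.variable]
            for antecedent in itertools.combinations(candidates, order):
                if order == 2 and antecedent[0].variable == antecedent[1].variable:
                    continue
                a = b = c = d = 0
                for i in range(m.n):
                    applicable = all(m.column(it)[i] for it in antecedent)
                    outcome = m.column(consequent)[i]
                    if applicable and outcome:
                        a += 1
                    elif applicable:
                        b += 1
                    elif outcome:
                        c += 1
                    else:
                        d += 1
                assert count_rule(m, antecedent, consequent) == (a, b, c, d)


def test_count_rule_combined_published_margins():
    """On a matrix realizing the old-age + high-WOMAC-pain margins the
    conjunction count is (13, 0, 19, 12)."""
    matrix = matrix_from_counts(
        [("age", "high"), ("womac_pain", "high")], ("pcs_2y", "low"), 13, 0, 19, 12
    )
    antecedent = [matrix.find("age", "high"), matrix.find("womac_pain", "high")]
    consequent = matrix.find("pcs_2y", "low")
    assert count_rule(matrix, antecedent, consequent) == (13, 0, 19, 12)


def test_count_rule_perfect_association():
    rng = np.random.default_rng(3)
    m = random_item_matrix(rng, 25, 2)
    consequent = m.items[0]
    # force a twin variable whose high state equals the consequent column
    m.membership[:, 2] = m.column(consequent)
    m.membership[:, 3] = ~m.column(consequent)
    a, b, c, d = count_rule(m, [m.items[2]], consequent)
    n_true = int(m.column(consequent).sum())
    assert (a, b, c, d) == (n_true, 0, 0, m.n - n_true)


def test_count_rule_rejects_degenerate_antecedent():
    rng = np.random.default_rng(5)
    m = random_item_matrix(rng, 10, 3)
    with pytest.raises(ValueError, match="two states"):
        count_rule(m, [m.items[2], m.items[3]], m.items[0])
    with pytest.raises(ValueError, match="consequent"):
        count_rule(m, [m.items[1]], m.items[0])


# ---------------------------------------------------------------- mining


def brute_force_mine(matrix, config):
    """Independent enumerator: all order-1/2 antecedents, plain floats."""
    out = []
    candidates = [
        it
        for it in matrix.items
        if it.variable != config.consequent.variable
        and it.variable not in config.excluded_variables
    ]
    antecedents = [(it,) for it in candidates]
    if config.max_order >= 2:
        antecedents += [
            p
            for p in itertools.combinations(candidates, 2)
            if p[0].variable != p[1].variable
        ]
    n = matrix.n
    outcome = matrix.column(config.consequent)
    for antecedent in antecedents:
        mask = np.logical_and.reduce([matrix.column(it) for it in antecedent])
        a = int((mask & outcome).sum())
        ab = int(mask.sum())
        if ab == 0:
            continue
        confidence = Fraction(a, ab)
        support = Fraction(a, n)
        lift = confidence / Fraction(int(outcome.sum()), n)
        if (
            confidence >= Fraction(config.min_confidence).limit_denominator(10**6)
            and lift >= Fraction(config.min_lift).limit_denominator(10**6)
            and support >= Fraction(config.min_support).limit_denominator(10**6)
        ):
            out.append((frozenset(antecedent), (a, ab)))
    return set(out)


def test_mine_rules_matches_oracle_on_random_matrices():
    rng = np.random.default_rng(11)
    for _ in range(30):
        n = int(rng.integers(10, 51))
        m = random_item_matrix(rng, n, 8)
        consequent = m.items[1]  # a "low" item
        prior = m.column(consequent).mean()
        if prior in (0.0, 1.0):
            continue
        config = MiningConfig(consequent=consequent)
        mined = mine_rules(m, config)
        got = {(r.antecedent, (r.a, r.a + r.b)) for r in mined}
        assert got == brute_force_mine(m, config)


def test_mine_rules_published_single_margins_rank_comorbidity_first():
    """On a matrix realizing all eight published single-rule tables the
    comorbidity rule tops the single rules at confidence 1, lift 1.375."""
    matrix = matrix_from_single_rule_counts(SINGLE_RULE_COUNTS, SLUG_ITEMS)
    config = MiningConfig(consequent=matrix.find("pcs_2y", "low"), max_order=1)
    rules = mine_rules(matrix, config)
    labels = [next(iter(r.antecedent)).key() for r in rules]
    assert labels[0] == ("cci", "high")
    assert rules[0].confidence == 1.0
    assert rules[0].lift == pytest.approx(1.375)
    # all eight published singles pass the confidence/lift gates
    assert len(rules) == 8


def test_mine_rules_unattainable_threshold(demo_cohort, specs):
    from krqol import build_item_matrix

    matrix = build_item_matrix(demo_cohort, specs)
    config = MiningConfig(consequent=matrix.find("pcs_2y", "low"), min_confidence=1.01)
    assert mine_rules(matrix, config) == []


def test_mine_rules_degenerate_consequent():
    rng = np.random.default_rng(2)
    m = random_item_matrix(rng, 12, 3)
    m.membership[:, 0] = True
    m.membership[:, 1] = False
    with pytest.raises(DegenerateDataError, match="degenerate consequent"):
        mine_rules(m, MiningConfig(consequent=m.items[0]))


def test_mined_rules_invariants(demo_cohort, specs):
    """Metric identities and anti-monotonicity on every mined rule."""
    from krqol import build_item_matrix

    matrix = build_item_matrix(demo_cohort, specs)
    config = MiningConfig(
        consequent=matrix.find("pcs_2y", "low"), min_confidence=0.5, min_lift=0.8
    )
    rules = mine_rules(matrix, config)
    assert rules, "expected some rules at permissive thresholds"
    singles = {next(iter(r.antecedent)): r for r in rules if r.order == 1}
    prior = Fraction(int(matrix.column(config.consequent).sum()), matrix.n)
    for r in rules:
        assert r.a + r.b + r.c + r.d == matrix.n
        assert 0 <= r.support_frac <= r.confidence_frac <= 1
        assert r.lift_frac * prior == r.confidence_frac
        assert r.lift_frac <= Fraction(matrix.n, r.a + r.c)
        if r.order == 2:
            for it in r.antecedent:
                if it in singles:
                    assert r.a <= singles[it].a
                    assert r.support_frac <= singles[it].support_frac


def test_mining_is_deterministic(demo_cohort, specs):
    from krqol import build_item_matrix

    matrix = build_item_matrix(demo_cohort, specs)
    config = MiningConfig(consequent=matrix.find("pcs_2y", "low"))
    first = mine_rules(matrix, config)
    second = mine_rules(matrix, config)
    assert [(r.antecedent, r.a, r.b, r.c, r.d) for r in first] == [
        (r.antecedent, r.a, r.b, r.c, r.d) for r in second
    ]


# ------------------------------------------------- single vs combined


def _rule(items, a, b, c, d):
    return AssociationRule(
        antecedent=frozenset(items),
        consequent=Item("pcs_2y", "low"),
        n_total=a + b + c + d,
        a=a,
        b=b,
        c=c,
        d=d,
    )


OLD = Item("age", "high", "Old age")
PAIN = Item("womac_pain", "high", "High preoperative WOMAC-pain score")


def test_combined_rule_strengthens_old_age():
    """Old age alone: confidence 22/26, lift 1.16; with high WOMAC-pain:
    confidence 1.0, lift 1.375 -> flagged as strengthened."""
    single = _rule([OLD], 22, 4, 10, 8)
    combined = _rule([OLD, PAIN], 13, 0, 19, 12)
    (report,) = compare_single_vs_combined([single], [combined])
    assert report.strengthened
    assert report.constituents == (single,)
    assert report.lift_ceiling == pytest.approx(44 / 32)


def test_combined_rule_equal_metrics_not_flagged():
    single = _rule([OLD], 22, 0, 10, 12)
    combined = _rule([OLD, PAIN], 22, 0, 10, 12)
    (report,) = compare_single_vs_combined([single], [combined])
    assert not report.strengthened


def test_compare_rejects_mixed_consequents():
    single = _rule([OLD], 22, 4, 10, 8)
    other = AssociationRule(
        antecedent=frozenset([OLD, PAIN]),
        consequent=Item("mcs_2y", "low"),
        n_total=44,
        a=13,
        b=0,
        c=19,
        d=12,
    )
    with pytest.raises(ValueError, match="consequent"):
        compare_single_vs_combined([single], [other])
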