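from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from krqol import (
    PlantedRule,
    SimulationConfig,
    build_item_matrix,
    count_rule,
    default_variable_specs,
    mine_rules,
    recover_planted_rules,
    simulate_cohort,
)
from krqol.errors import ConfigError
from krqol.mining import MiningConfig
from krqol.simulate import planted_marginal_probability


def test_same_seed_reproduces_cohort():
    a = simulate_cohort(SimulationConfig(seed=42))
    b = simulate_cohort(SimulationConfig(seed=42))
    pd.testing.assert_frame_equal(a.data, b.data)
    c = simulate_cohort(SimulationConfig(seed=43))
    assert not a.data.equals(c.data)


def test_default_cohort_schema(demo_cohort):
    """44 rows, all columns present and in range (validated on build)."""
    assert len(demo_cohort) == 44
    assert demo_cohort.column("cesd").between(0, 60).all()
    assert demo_cohort.column("sex").isin(["female", "male"]).all()


def test_minimal_cohort():
    cohort = simulate_cohort(SimulationConfig(n_participants=2, seed=0))
    assert len(cohort) == 2


def test_planted_perfect_rule_survives_discretization():
    """P(low 2y PCS | comorbidity) = 1 planted on fixed-cutoff variables
    yields confidence exactly 1.0 in the binarized data."""
    config = SimulationConfig(
        seed=5,
        planted_rules=(
            PlantedRule((("cci", "high"),), "pcs_2y", "low", 1.0, 0.65),
        ),
    )
    cohort = simulate_cohort(config)
    matrix = build_item_matrix(cohort, default_variable_specs())
    a, b, c, d = count_rule(
        matrix, [matrix.find("cci", "high")], matrix.find("pcs_2y", "low")
    )
    if a + b > 0:  # comorbidity realized in this cohort
        assert b == 0  # every comorbid participant is low


def test_contradictory_planted_rules_rejected():
    with pytest.raises(ConfigError, match="contradictory"):
        SimulationConfig(
            planted_rules=(
                PlantedRule((("cci", "high"),), "pcs_2y", "low", 1.0, 0.6),
                PlantedRule((("age", "high"),), "pcs_2y", "high", 0.9, 0.6),
            )
        )


def test_planted_rule_on_unknown_variable_rejected():
    with pytest.raises(ConfigError, match="unknown variable"):
        SimulationConfig(
            planted_rules=(
                PlantedRule((("nope", "high"),), "pcs_2y", "low", 1.0, 0.6),
            )
        )


def test_antecedent_cannot_be_planted_outcome():
    with pytest.raises(ConfigError, match="itself a planted outcome"):
        SimulationConfig(
            planted_rules=(
                PlantedRule((("cci", "high"),), "pcs_2y", "low", 1.0, 0.6),
                PlantedRule((("pcs_2y", "low"),), "mcs_2y", "low", 0.9, 0.5),
            )
        )


def test_marginal_calibration_large_sample():
    """Binarized prevalences track the configured marginals: comorbidity
    10/44, old age 26/44, low 2-year PCS at its planted marginal."""
    config = SimulationConfig(seed=9)
    big = SimulationConfig(n_participants=4000, seed=9)
    cohort = simulate_cohort(big)
    matrix = build_item_matrix(cohort, default_variable_specs())
    n = matrix.n

    def prevalence(variable, state):
        return matrix.column(matrix.find(variable, state)).mean()

    for variable, state, target in [
        ("cci", "high", 10 / 44),
        ("age", "high", 26 / 44),
        ("cesd", "high", 4 / 44),
        ("sex", "female", 18 / 44),
    ]:
        se = np.sqrt(target * (1 - target) / n)
        assert abs(prevalence(variable, state) - target) < 4 * se, variable

    target = planted_marginal_probability(config, config.planted_rules[0])
    se = np.sqrt(target * (1 - target) / n)
    assert abs(prevalence("pcs_2y", "low") - target) < 4 * se


def test_recover_planted_rule_at_large_n():
    """Planted conditional 0.95 vs baseline 0.60 is re-estimated within
    +-0.03 (confidence) and +-0.05 (lift) at n=2000."""
    config = SimulationConfig(
        seed=3,
        planted_rules=(
            PlantedRule((("cci", "high"),), "pcs_2y", "low", 0.95, 0.60),
        ),
    )
    (report,) = recover_planted_rules(config, n_large=2000, seed=3)
    assert abs(report.estimated_confidence - 0.95) < 0.03
    assert abs(report.estimated_lift - report.planted_lift) < 0.05
    assert report.se_confidence < 0.02


def test_recover_null_rule_lift_near_one():
    config = SimulationConfig(
        seed=4,
        planted_rules=(
            PlantedRule((("cci", "high"),), "pcs_2y", "low", 0.6, 0.6),
        ),
    )
    (report,) = recover_planted_rules(config, n_large=2000, seed=4)
    assert report.planted_lift == pytest.approx(1.0)
    assert abs(report.estimated_lift - 1.0) < 3 * report.se_lift + 1e-9


def test_recover_two_disjoint_rules():
    config = SimulationConfig(
        seed=6,
        planted_rules=(
            PlantedRule((("cci", "high"),), "pcs_2y", "low", 0.9, 0.6),
            PlantedRule((("age", "high"),), "mcs_2y", "low", 0.8, 0.4),
        ),
    )
    first, second = recover_planted_rules(config, n_large=3000, seed=6)
    assert abs(first.estimated_confidence - 0.9) < 0.03
    assert abs(second.estimated_confidence - 0.8) < 0.03


def test_null_cohort_rule_count_stable():
    """With no planted rules, the number of spurious gate-passing rules
    at N=44 is deterministic per seed and identical across reruns."""
    config = SimulationConfig(seed=123, planted_rules=())
    counts = []
    for _ in range(2):
        cohort = simulate_cohort(config)
        matrix = build_item_matrix(cohort, default_variable_specs())
        rules = mine_rules(
            matrix, MiningConfig(consequent=matrix.find("pcs_2y", "low"))
        )
        counts.append(len(rules))
    assert counts[0] == counts[1]
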