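"""End-to-end orchestration: cohort -> items -> rules -> tests -> reports.

One mining run covers the four default consequents (low PCS and low MCS
at 1 and 2 years after surgery); an empty rule table for a consequent is
a valid, reported outcome.  All outputs are deterministic: rerunning on
identical inputs produces byte-identical TSVs, and the run manifest
records config digests so that any change of input or threshold is
visible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Sequence

from . import __version__
from .cohort import (
    CohortTable,
    VariableSpec,
    variable_config_digest,
    write_rules_table,
)
from .discretize import Item, ItemMatrix, build_item_matrix
from .errors import KrqolError, UndefinedMetricError
from .mining import (
    AssociationRule,
    MiningConfig,
    RuleComparison,
    compare_single_vs_combined,
    mine_rules,
    rule_metrics_from_counts,
)
from .rounding import fmt_pvalue, round_half_up
from .rule_tests import RuleTestResult, test_all, test_table

#: the four outcome items mined by default: PCS and MCS, 1 and 2 years
#: after surgery, low state
DEFAULT_CONSEQUENTS: tuple[tuple[str, str], ...] = (
    ("pcs_1y", "low"),
    ("pcs_2y", "low"),
    ("mcs_1y", "low"),
    ("mcs_2y", "low"),
)


@dataclass
class ConsequentResult:
    consequent: Item
    rules: list[AssociationRule]
    tests: list[RuleTestResult]
    comparisons: list[RuleComparison]
    error: str | None = None

    @property
    def singles(self) -> list[AssociationRule]:
        return [r for r in self.rules if r.order == 1]

    @property
    def combined(self) -> list[AssociationRule]:
        return [r for r in self.rules if r.order == 2]


@dataclass
class MiningRun:
    matrix: ItemMatrix
    results: list[ConsequentResult]
    min_confidence: float
    min_lift: float
    min_support: float
    max_order: int
    alpha: float
    adjustment: str = "none"
    extra: dict = field(default_factory=dict)


def run_mining(
    cohort: CohortTable,
    specs: Sequence[VariableSpec],
    consequents: Sequence[tuple[str, str]] = DEFAULT_CONSEQUENTS,
    max_order: int = 2,
    min_confidence: float = 0.80,
    min_lift: float = 1.1,
    min_support: float = 0.0,
    alpha: float = 0.05,
    adjustment: str = "none",
    excluded_variables: Sequence[str] = (),
) -> MiningRun:
    """Mine, test and compare rules for every requested consequent.

    A consequent whose prior is degenerate in this cohort (all or no
    participants) is reported with an error string instead of rules.
    """
    matrix = build_item_matrix(cohort, specs)
    results: list[ConsequentResult] = []
    for variable, state in consequents:
        consequent = matrix.find(variable, state)
        config = MiningConfig(
            consequent=consequent,
            max_order=max_order,
            min_confidence=min_confidence,
            min_lift=min_lift,
            min_support=min_support,
            excluded_variables=frozenset(excluded_variables),
        )
        try:
            rules = mine_rules(matrix, config)
        except KrqolError as exc:
            results.append(ConsequentResult(consequent, [], [], [], error=str(exc)))
            continue
        tests = (
            test_all(rules, alpha=alpha, adjustment=adjustment) if rules else []
        )
        singles = [r for r in rules if r.order == 1]
        combined = [r for r in rules if r.order == 2]
        comparisons = compare_single_vs_combined(singles, combined)
        results.append(ConsequentResult(consequent, rules, tests, comparisons))
    return MiningRun(
        matrix=matrix,
        results=results,
        min_confidence=min_confidence,
        min_lift=min_lift,
        min_support=min_support,
        max_order=max_order,
        alpha=alpha,
        adjustment=adjustment,
    )


def run_summary(run: MiningRun) -> dict:
    """JSON-serializable run summary: thresholds, priors, rule counts."""
    per_consequent = []
    for res in run.results:
        entry: dict = {
            "consequent": {
                "variable": res.consequent.variable,
                "state": res.consequent.state,
                "label": res.consequent.label,
            },
        }
        if res.error is not None:
            entry["error"] = res.error
        else:
            n = run.matrix.n
            n_true = int(run.matrix.column(res.consequent).sum())
            entry.update(
                {
                    "n": n,
                    "prior": n_true / n,
                    "lift_ceiling": n / n_true if n_true else None,
                    "n_single_rules": len(res.singles),
                    "n_combined_rules": len(res.combined),
                    "n_significant": sum(t.significant for t in res.tests),
                    "n_strengthened": sum(c.strengthened for c in res.comparisons),
                }
            )
        per_consequent.append(entry)
    return {
        "version": __version__,
        "n_participants": run.matrix.n,
        "thresholds": {
            "min_confidence": run.min_confidence,
            "min_lift": run.min_lift,
            "min_support": run.min_support,
            "max_order": run.max_order,
            "alpha": run.alpha,
            "adjustment": run.adjustment,
        },
        "consequents": per_consequent,
    }


def write_run_outputs(
    run: MiningRun,
    out_dir: str | Path,
    specs: Sequence[VariableSpec],
    input_digest: str | None = None,
    seed: int | None = None,
) -> dict:
    """Write per-consequent rule TSVs, summary.json and manifest.json.

    Returns the manifest dict.  File names are stable slugs of the
    consequent item, e.g. ``rules_pcs_2y_low.tsv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inventory: list[str] = []
    for res in run.results:
        slug = f"{res.consequent.variable}_{res.consequent.state}"
        path = out / f"rules_{slug}.tsv"
        write_rules_table(res.rules, res.tests or None, path)
        inventory.append(path.name)
    summary = run_summary(run)
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2) + "\n", encoding="utf-8")
    inventory.append(summary_path.name)
    manifest = {
        "version": __version__,
        "seed": seed,
        "input_digest": input_digest,
        "variable_config_digest": variable_config_digest(specs),
        "thresholds": summary["thresholds"],
        "outputs": sorted(inventory),
    }
    manifest["manifest_digest"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n", encoding="utf-8"
    )
    return manifest


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def verify_counts(rows: Sequence[tuple[str, int, int, int, int]], alpha: float = 0.05):
    """Audit path: recompute metrics and tests from labelled 2x2 counts.

    Each row is ``(label, a, b, c, d)``.  Malformed rows (undefined
    metrics, degenerate margins) are reported as per-row errors without
    aborting the batch.  Returns a list of per-row dicts.
    """
    report = []
    for label, a, b, c, d in rows:
        entry: dict = {"label": label, "a": a, "b": b, "c": c, "d": d}
        try:
            support, confidence, lift = rule_metrics_from_counts(a, b, c, d)
            n = a + b + c + d
            entry.update(
                {
                    "support_pct": round_half_up(Fraction(a, n) * 100),
                    "confidence_pct": round_half_up(Fraction(a, a + b) * 100),
                    "lift": round_half_up(Fraction(a * n, (a + b) * (a + c))),
                }
            )
            test = test_table(a, b, c, d, alpha=alpha)
            entry.update(
                {
                    "test": test.test_used,
                    "p_value": test.p_value,
                    "p_display": fmt_pvalue(test.p_value),
                    "significant": test.significant,
                }
            )
        except (KrqolError, UndefinedMetricError, ValueError) as exc:
            entry["error"] = str(exc)
        report.append(entry)
    return report
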