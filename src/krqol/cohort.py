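"""Participant-level cohort tables and per-variable dichotomization config.

The analysis operates on one row per knee-replacement patient with
preoperative clinical measures (demographics, comorbidity, depressive
symptoms, WOMAC knee symptoms, sit-to-stand time) and SF-12 physical /
mental component summaries (PCS / MCS) at baseline and 1 and 2 years
after surgery.  All scores arrive already scaled; this module only
validates ranges and reads/writes the tables.

Rows with missing values or out-of-range scores are rejected rather than
imputed — the analysed cohort is defined as complete cases.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import pandas as pd
import yaml

from .errors import ConfigError, SchemaError, ValidationError
from .rounding import fmt_percent, fmt_pvalue, round_half_up

if TYPE_CHECKING:  # pragma: no cover
    from .mining import AssociationRule
    from .rule_tests import RuleTestResult

#: methods a VariableSpec may declare
METHODS = ("fixed_cutoff", "median_split", "categorical_passthrough")

#: declared value ranges; None bound means unbounded on that side
RANGES: dict[str, tuple[float | None, float | None]] = {
    "age": (0.0, None),
    "sit_to_stand_s": (0.0, None),
    "bmi": (0.0, None),
    "cci": (0.0, None),
    "cesd": (0.0, 60.0),
    "womac_pain": (0.0, 20.0),
    "womac_stiffness": (0.0, 8.0),
    "womac_physfunc": (0.0, 68.0),
    "pcs_pre": (0.0, 100.0),
    "pcs_1y": (0.0, 100.0),
    "pcs_2y": (0.0, 100.0),
    "mcs_pre": (0.0, 100.0),
    "mcs_1y": (0.0, 100.0),
    "mcs_2y": (0.0, 100.0),
}

#: allowed levels for categorical columns
CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "sex": ("female", "male"),
    "joint_type": ("unilateral", "bilateral"),
}

#: integer-valued columns
INTEGER_COLUMNS = ("cci", "cesd")

ID_COLUMN = "participant_id"


@dataclass(frozen=True)
class VariableSpec:
    """How one variable is turned into a two-state (or categorical) item pair.

    Parameters
    ----------
    variable
        Column name in the cohort table.
    method
        ``fixed_cutoff`` (split at a literature cut-off), ``median_split``
        (equal-frequency split at the sample median) or
        ``categorical_passthrough`` (one item per observed level).
    cutoff
        Threshold for ``fixed_cutoff``; the high state is ``value >= cutoff``
        by default.
    high_if
        Comparison yielding the high state: ``ge`` (default) or ``gt``.
    labels
        ``(high_label, low_label)`` human-readable state names used in
        reports, e.g. ``("Old age", "Young age")``.
    """

    variable: str
    method: str
    cutoff: float | None = None
    high_if: str = "ge"
    labels: tuple[str, str] = ("high", "low")

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ConfigError(
                f"{self.variable}: unknown method {self.method!r}; "
                f"expected one of {METHODS}"
            )
        if self.method == "fixed_cutoff" and self.cutoff is None:
            raise ConfigError(f"{self.variable}: fixed_cutoff requires a cutoff")
        if self.method != "fixed_cutoff" and self.cutoff is not None:
            raise ConfigError(
                f"{self.variable}: cutoff given but method is {self.method}"
            )
        if self.high_if not in ("ge", "gt"):
            raise ConfigError(f"{self.variable}: high_if must be 'ge' or 'gt'")
        if self.labels[0] == self.labels[1]:
            raise ConfigError(f"{self.variable}: state labels must be distinct")


@dataclass
class CohortTable:
    """Validated participant-level table; row order is meaningful."""

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        validate_cohort_frame(self.data)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def participant_ids(self) -> list[str]:
        return list(self.data[ID_COLUMN])

    def column(self, name: str) -> pd.Series:
        return self.data[name]


def _required_columns(specs: Sequence[VariableSpec]) -> list[str]:
    return [ID_COLUMN] + [s.variable for s in specs]


def validate_cohort_frame(df: pd.DataFrame) -> None:
    """Raise on duplicate ids, missing cells or out-of-range values."""
    if ID_COLUMN not in df.columns:
        raise SchemaError(f"missing column: {ID_COLUMN}")
    if df[ID_COLUMN].duplicated().any():
        dup = df.loc[df[ID_COLUMN].duplicated(), ID_COLUMN].iloc[0]
        raise ValidationError(f"duplicate participant_id: {dup!r}")
    for col in df.columns:
        if col == ID_COLUMN:
            continue
        series = df[col]
        if series.isna().any():
            row = int(series.index[series.isna()][0])
            raise ValidationError(f"missing value in column {col!r}, row {row}")
        if col in CATEGORICAL_LEVELS:
            levels = CATEGORICAL_LEVELS[col]
            bad = ~series.isin(levels)
            if bad.any():
                row = int(series.index[bad][0])
                raise ValidationError(
                    f"column {col!r}, row {row}: value {series[row]!r} "
                    f"not in {levels}"
                )
            continue
        values = pd.to_numeric(series, errors="coerce")
        if values.isna().any():
            row = int(values.index[values.isna()][0])
            raise ValidationError(f"column {col!r}, row {row}: not numeric")
        if col in INTEGER_COLUMNS and not (values == values.round()).all():
            bad = values != values.round()
            row = int(values.index[bad][0])
            raise ValidationError(f"column {col!r}, row {row}: must be integer")
        lo, hi = RANGES.get(col, (None, None))
        if lo is not None and (values < lo).any():
            row = int(values.index[values < lo][0])
            raise ValidationError(
                f"column {col!r}, row {row}: value {values[row]} below {lo}"
            )
        if hi is not None and (values > hi).any():
            row = int(values.index[values > hi][0])
            raise ValidationError(
                f"column {col!r}, row {row}: value {values[row]} above {hi}"
            )


def read_cohort(path: str | Path, specs: Sequence[VariableSpec]) -> CohortTable:
    """Read a cohort CSV and validate it against the variable schema.

    Raises :class:`SchemaError` if a configured variable has no column,
    :class:`ValidationError` for missing or out-of-range cells.
    """
    df = pd.read_csv(path, dtype={ID_COLUMN: str})
    for col in _required_columns(specs):
        if col not in df.columns:
            raise SchemaError(f"missing column: {col}")
    df = df.reset_index(drop=True)
    table = CohortTable(df)
    return table


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    cohort.data.to_csv(path, index=False)


def _spec_from_entry(variable: str, entry: dict) -> VariableSpec:
    if not isinstance(entry, dict):
        raise ConfigError(f"{variable}: expected a mapping of options")
    unknown = set(entry) - {"method", "cutoff", "high_if", "labels"}
    if unknown:
        raise ConfigError(f"{variable}: unknown option(s) {sorted(unknown)}")
    labels = entry.get("labels", ("high", "low"))
    if len(labels) != 2:
        raise ConfigError(f"{variable}: labels must be a pair")
    return VariableSpec(
        variable=variable,
        method=entry.get("method", "fixed_cutoff"),
        cutoff=entry.get("cutoff"),
        high_if=entry.get("high_if", "ge"),
        labels=(str(labels[0]), str(labels[1])),
    )


def read_variable_config(path: str | Path) -> list[VariableSpec]:
    """Load the per-variable dichotomization config (YAML mapping)."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return parse_variable_config(raw)


def parse_variable_config(raw: object) -> list[VariableSpec]:
    if not raw:
        raise ConfigError("no variables configured")
    if not isinstance(raw, dict):
        raise ConfigError("variable config must be a mapping variable -> options")
    return [_spec_from_entry(str(var), entry) for var, entry in raw.items()]


def default_variable_specs() -> list[VariableSpec]:
    """The shipped default recipe for all 16 analysis variables.

    Fixed cut-offs follow the standard clinical conventions (age >= 60
    old; BMI >= 30 obese; CES-D >= 16 depressive symptoms; one or more
    comorbidities; SF-12 norm-based score split at 50); sit-to-stand
    and the WOMAC subscales use the equal-frequency (median) split.
    """
    text = (
        importlib.resources.files("krqol")
        .joinpath("config/default_variables.yaml")
        .read_text(encoding="utf-8")
    )
    return parse_variable_config(yaml.safe_load(text))


def write_rules_table(
    rules: Sequence["AssociationRule"],
    tests: Sequence["RuleTestResult"] | None,
    path: str | Path,
) -> None:
    """Write a mined-rule table as TSV, one row per rule.

    Percentages and lift are rounded half-up to 2 decimals; raw counts
    and test results (when provided) are carried alongside so every
    printed metric can be recomputed from the row itself.
    """
    if tests is not None and len(tests) != len(rules):
        raise ValueError("rules and tests must be parallel lists")
    header = [
        "antecedent",
        "consequent",
        "support_pct",
        "confidence_pct",
        "lift",
        "a",
        "b",
        "c",
        "d",
        "test",
        "p_value",
        "significant",
    ]
    lines = ["\t".join(header)]
    for i, rule in enumerate(rules):
        n = rule.n_total
        support = Fraction(rule.a, n)
        confidence = Fraction(rule.a, rule.a + rule.b)
        lift = Fraction(rule.a * n, (rule.a + rule.b) * (rule.a + rule.c))
        if tests is not None:
            t = tests[i]
            test_cols = [t.test_used, fmt_pvalue(t.p_value), str(t.significant).lower()]
        else:
            test_cols = ["", "", ""]
        lines.append(
            "\t".join(
                [
                    " + ".join(sorted(it.label for it in rule.antecedent)),
                    rule.consequent.label,
                    fmt_percent(support),
                    fmt_percent(confidence),
                    f"{round_half_up(lift):.2f}",
                    str(rule.a),
                    str(rule.b),
                    str(rule.c),
                    str(rule.d),
                ]
                + test_cols
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def variable_config_digest(specs: Iterable[VariableSpec]) -> str:
    """Stable digest of the dichotomization recipe, for run manifests."""
    import hashlib
    import json

    payload = [
        {
            "variable": s.variable,
            "method": s.method,
            "cutoff": s.cutoff,
            "high_if": s.high_if,
            "labels": list(s.labels),
        }
        for s in specs
    ]
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()
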