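#!/usr/bin/env python
"""Generate the default synthetic knee-replacement cohort (N=44).

Writes the cohort CSV and an audit dump of its binarized item matrix
under results/.  The cohort emulates the study schema with marginal
prevalences calibrated to the published participant characteristics and
one planted dependency (comorbidity -> low 2-year PCS at confidence 1).
"""

from pathlib import Path

from krqol import SimulationConfig, build_item_matrix, default_variable_specs, simulate_cohort
from krqol.cohort import write_cohort
from krqol.discretize import matrix_audit_frame

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    config = SimulationConfig(seed=20250920)
    cohort = simulate_cohort(config)
    write_cohort(cohort, OUT / "cohort.csv")
    matrix = build_item_matrix(cohort, default_variable_specs())
    matrix_audit_frame(matrix).to_csv(OUT / "item_matrix.tsv", sep="\t")

    n = matrix.n
    print(f"simulated {n} participants -> {OUT / 'cohort.csv'}")
    for variable, state in [("cci", "high"), ("age", "high"), ("pcs_2y", "low")]:
        k = int(matrix.column(matrix.find(variable, state)).sum())
        print(f"  {variable}={state}: {k}/{n}")
    print(f"item matrix ({len(matrix.items)} items) -> {OUT / 'item_matrix.tsv'}")


if __name__ == "__main__":
    main()
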