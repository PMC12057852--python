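#!/usr/bin/env python
"""Run the full mining pipeline on the simulated cohort.

Reads results/cohort.csv (written by 01_simulate_cohort.py; regenerated
here if absent), mines 1- and 2-condition rules for the four default
consequents (low PCS / MCS at 1 and 2 years) at the confidence >= 0.80
and lift >= 1.1 gates, tests every rule's 2x2 table, and writes the
rule tables, summary and manifest under results/mining/.
"""

import json
from pathlib import Path

from krqol import default_variable_specs, read_cohort
from krqol.cohort import write_cohort
from krqol.pipeline import file_digest, run_mining, write_run_outputs
from krqol.simulate import SimulationConfig, simulate_cohort

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "results" / "cohort.csv"
OUT = ROOT / "results" / "mining"


def main() -> None:
    specs = default_variable_specs()
    if not COHORT.exists():
        COHORT.parent.mkdir(exist_ok=True)
        write_cohort(simulate_cohort(SimulationConfig(seed=20250920)), COHORT)
    cohort = read_cohort(COHORT, specs)
    run = run_mining(cohort, specs)
    write_run_outputs(run, OUT, specs, input_digest=file_digest(COHORT), seed=20250920)

    print(f"mined {len(cohort)} participants -> {OUT}")
    for res in run.results:
        if res.error:
            print(f"  {res.consequent.label}: {res.error}")
            continue
        n_sig = sum(t.significant for t in res.tests)
        n_str = sum(c.strengthened for c in res.comparisons)
        print(
            f"  {res.consequent.label}: {len(res.singles)} single / "
            f"{len(res.combined)} combined rule(s), {n_sig} significant, "
            f"{n_str} combined rule(s) strengthen their constituents"
        )
    summary = json.loads((OUT / "summary.json").read_text())
    print(f"thresholds: {summary['thresholds']}")


if __name__ == "__main__":
    main()
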