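#!/usr/bin/env python
"""Generate the synthetic study inputs: a 28-line 5-FU cell panel, a
200-patient treated discovery cohort, and a two-group multi-omics cohort.

Writes all matrices under results/data/ plus the planted-truth manifest the
later scripts check themselves against.
"""

import json
from pathlib import Path

import pandas as pd

from reosig import io as rio
from reosig.simulate import (PatientArm, SimulationConfig, gen_cell_line_cohort,
                             gen_patient_cohort)

SEED = 0
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    sim = SimulationConfig(seed=SEED, patient=PatientArm(n_patients=200))

    cell_expr, gi50, cell_truth = gen_cell_line_cohort(sim)
    pat_expr, pat_surv, pat_truth = gen_patient_cohort(sim)

    rio.write_matrix_tsv(cell_expr, OUT / "cell_expression.tsv")
    rio.write_drug_response_tsv(gi50, OUT / "cell_gi50.tsv")
    rio.write_matrix_tsv(pat_expr, OUT / "patient_expression.tsv")
    rio.write_survival_tsv(pat_surv, OUT / "patient_survival.tsv")
    (OUT / "planted_truths.json").write_text(json.dumps(
        {"cell": cell_truth, "patient": pat_truth}, indent=2, sort_keys=True))

    n_high = sum(v == "high" for v in pat_truth["true_risk"].values())
    print(f"cell panel: {cell_expr.shape[0]} genes x {cell_expr.shape[1]} lines "
          f"({len(cell_truth['resistant'])} resistant / "
          f"{len(cell_truth['sensitive'])} sensitive)")
    print(f"patient cohort: {pat_expr.shape[1]} patients, "
          f"{int(pat_surv.event.sum())} events, "
          f"{n_high} truly high-risk")
    print(f"wrote inputs to {OUT}")


if __name__ == "__main__":
    main()
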