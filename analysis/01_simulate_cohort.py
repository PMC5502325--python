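#!/usr/bin/env python
"""Generate the study-shaped synthetic cohort used by the later stages.

Writes results/cohort.tsv (163 subjects x 105 mixed-type predictors plus a
binary outcome column at ~7% prevalence, with missing entries and a few
>50%-missing columns) and results/truth.json recording the planted parents,
their noisy-copy distractors, and the Bayes-optimal AUC of the true
predictor.
"""

import json
from pathlib import Path

import numpy as np

from ptsdml.cohort import CohortTable, write_cohort
from ptsdml.simulate import SyntheticSpec, generate_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 25


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    spec = SyntheticSpec(seed=SEED)
    table, target, truth = generate_cohort(spec)

    with_outcome = CohortTable(
        values=np.column_stack([table.values, target.labels.astype(float)]),
        variable_names=table.variable_names + ["outcome"],
        variable_kinds=table.variable_kinds + ["binary"],
        missing_mask=np.column_stack(
            [table.missing_mask, np.zeros(table.n_subjects, dtype=bool)]
        ),
        subject_ids=table.subject_ids,
    )
    write_cohort(with_outcome, RESULTS / "cohort.tsv")
    with open(RESULTS / "truth.json", "w") as fh:
        json.dump(
            {
                "seed": SEED,
                "parents": truth.parents,
                "parent_effects": list(truth.parent_effects),
                "distractor_map": truth.distractor_map,
                "bayes_auc": truth.bayes_auc,
            },
            fh,
            indent=2,
        )

    print(f"cohort: {table.n_subjects} subjects, {table.n_variables} predictors")
    print(f"positives: {target.n_positive} "
          f"({target.labels.mean():.1%} prevalence)")
    print(f"planted parents: {', '.join(truth.parents)}")
    print(f"Bayes-optimal AUC of the true predictor: {truth.bayes_auc:.3f}")
    high = (table.missing_mask.mean(axis=0) > 0.5).sum()
    print(f"columns with >50% missingness: {high}")
    print(f"wrote {RESULTS/'cohort.tsv'} and {RESULTS/'truth.json'}")


if __name__ == "__main__":
    main()
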