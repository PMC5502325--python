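#!/usr/bin/env python
"""Missingness filter, kNN imputation and 0-1 normalization of the cohort.

Reads results/cohort.tsv (from 01_simulate_cohort.py), drops variables
missing in more than half the subjects, imputes the rest with k=10 nearest
neighbours, rescales every variable to [0, 1], and writes
results/cohort_clean.tsv.  This full-table pass is for the feature-stability
stages; the cross-validation stage refits imputation donors and
normalization bounds inside each training fold instead.
"""

from pathlib import Path

from ptsdml.cohort import extract_target, read_cohort, write_cohort
from ptsdml.preprocess import preprocess_pipeline

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort_path = RESULTS / "cohort.tsv"
    if not cohort_path.exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    table = read_cohort(cohort_path)
    predictors, target = extract_target(table, "outcome", cutoff=0.5)
    clean, report = preprocess_pipeline(predictors)
    write_cohort(clean, RESULTS / "cohort_clean.tsv")

    print(f"variables before filter: {predictors.n_variables}")
    for name, frac in report.dropped_variables:
        print(f"  dropped {name}: {frac:.0%} missing")
    print(f"variables after filter: {clean.n_variables}")
    print(f"imputed cells: {report.imputed_cell_count}")
    print(f"wrote {RESULTS/'cohort_clean.tsv'}")


if __name__ == "__main__":
    main()
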