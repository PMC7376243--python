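#!/usr/bin/env python
"""Baseline-characteristics table for the simulated cohort.

Reads results/cohort/ (written by 01_simulate_cohort.py), splits
patients by delivered-term vs delivered-preterm, and compares age and
BMI with the normality-gated two-group procedure (Shapiro-Wilk gate,
then pooled t-test with means or Mann-Whitney with medians), plus a
chi-square for smoking.  Writes results/tables/baseline_comparisons.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from vocptb.cohort import compare_groups, read_cohort, summarize_cohort

ROOT = Path(__file__).resolve().parent.parent
COHORT = ROOT / "results" / "cohort"
OUT = ROOT / "results" / "tables"


def main() -> None:
    if not (COHORT / "patients.csv").exists():
        sys.exit("run 01_simulate_cohort.py first")
    patients = read_cohort(COHORT / "patients.csv", COHORT / "swabs.csv")
    evaluable = [p for p in patients if p.preterm is not None]
    groups = np.array(["preterm" if p.preterm else "term" for p in evaluable])
    rows = []
    for name, getter, categorical in (
        ("age_years", lambda p: p.age_years, False),
        ("bmi", lambda p: p.bmi, False),
        ("smoking", lambda p: p.smoking, True),
    ):
        values = np.array([getter(p) for p in evaluable])
        res = compare_groups(values, groups, categorical=categorical)
        rows.append(
            {"characteristic": name, "test": res.test, "p_value": round(res.p_value, 4)}
        )
        print(f"{name:12s} {res.test:14s} p = {res.p_value:.4f}")
    OUT.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT / "baseline_comparisons.csv", index=False)
    summary = summarize_cohort(patients)
    pd.DataFrame(
        [
            {"rate": name, **fields}
            for name, fields in summary.to_dict().items()
        ]
    ).to_csv(OUT / "cohort_rates.csv", index=False)
    print(f"wrote {OUT / 'baseline_comparisons.csv'} and {OUT / 'cohort_rates.csv'}")


if __name__ == "__main__":
    main()
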