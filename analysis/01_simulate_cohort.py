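#!/usr/bin/env python
"""Simulate the study cohort and write its tables.

Generates a 216-patient high-risk antenatal clinic cohort (BV
prevalence 12%, spontaneous preterm rate 20%, 59% preterm among
BV-positive women, 2-3 swabs per patient in weeks 10-29) and writes
patients.csv / swabs.csv under results/cohort/.  Spectra are not
written here — they are large and regenerate deterministically from the
same seed in 03_run_voc_analyses.py.
"""

from pathlib import Path

from vocptb.cohort import summarize_cohort, write_cohort
from vocptb.synthetic import CohortSimParams, generate_cohort

SEED = 7
OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main() -> None:
    params = CohortSimParams(n_patients=216, seed=SEED)
    patients, _ = generate_cohort(params, with_spectra=False)
    OUT.mkdir(parents=True, exist_ok=True)
    write_cohort(patients, OUT / "patients.csv", OUT / "swabs.csv")
    summary = summarize_cohort(patients)
    print(f"simulated {len(patients)} patients (seed {SEED}) -> {OUT}")
    for name, f in summary.to_dict().items():
        print(f"  {name}: {f['count']}/{f['denominator']} = {f['pct']}%")


if __name__ == "__main__":
    main()
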