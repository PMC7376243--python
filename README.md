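# voc-ptb

Volatile-organic-compound (VOC) analysis of vaginal swabs for
predicting bacterial vaginosis (BV) and spontaneous preterm birth.

Preterm birth (delivery before 37+0 weeks) is the leading cause of
death in children under five, and its multifactorial nature makes
prediction hard. One candidate signal is the VOC profile of a vaginal
swab measured by GC-IMS (gas chromatography–ion mobility
spectrometry), which reflects both the vaginal microbiome and the host
response to it. `voc-ptb` implements the full analysis pipeline for
such data: spectrum I/O in a documented text dialect, dimensionality
reduction (uniform crop + background threshold), class-balanced
tenfold cross-validation with in-fold Mann–Whitney rank-sum feature
selection, random-forest and Gaussian-process classification, and the
diagnostic-test panel (ROC/AUC with DeLong 95% CI, Youden-optimal
sensitivity/specificity with Clopper–Pearson CIs, PPV, NPV,
between-group p). A synthetic-data module generates GC-IMS-like
spectra and obstetric cohorts so every stage is testable without any
instrument data.

## The method in brief

Each sample is a dense matrix X over retention time × drift time. A
crop window W and threshold τ, chosen once and applied to all samples,
give features x_f = X[f]·1{X[f] ≥ τ} for cells f ∈ W. With balanced
classes, stratified tenfold CV runs: within each fold, rank every
feature by the two-sided Mann–Whitney p-value on the training 90%,
keep the 100 smallest, fit the classifier, and score the held-out 10%.
Pooled out-of-fold probabilities p̂ᵢ give

* AUC = P(p̂⁺ > p̂⁻) + ½·P(p̂⁺ = p̂⁻)  (concordance form, DeLong CI),
* sensitivity/specificity/PPV/NPV at the threshold maximising
  Youden's J = se + sp − 1,
* a Mann–Whitney p comparing p̂ across outcome groups.

Feature selection happens *inside* each fold; the package includes a
deliberately broken whole-dataset-selection variant and a test that
demonstrates the AUC inflation it causes on null data.

## Worked example

Simulate a 216-patient high-risk clinic cohort and run the three
analyses (BV from the first swab; preterm from the first swab; preterm
from the swab closest to delivery), each with both classifiers:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_cohort_table.py
python analysis/03_run_voc_analyses.py   # ~2 minutes
```

`01_simulate_cohort.py` prints the cohort's headline rates (seed 7):

```
simulated 216 patients (seed 7) -> results/cohort
  bv_positive: 25/216 = 11.6%
  preterm: 35/205 = 17.1%
  before_32_weeks: 13/205 = 6.3%
  preterm_given_bv_positive: 13/23 = 56.5%
  preterm_given_bv_negative: 22/182 = 12.1%
```

— a draw from the configured population (BV 12%, preterm 20%, 59%
preterm among BV-positive women). `03_run_voc_analyses.py` prints the
six diagnostic blocks; with this seed the BV analysis reaches AUC
0.98–1.00 (the simulated VOC effect marks BV-positive patients
directly) while the preterm analyses sit at AUC 0.57–0.70, because
preterm status sees the VOC signal only through the BV–preterm
enrichment. The report lands in `results/voc_report.json` /
`results/voc_report.csv` with one block per analysis × classifier:
AUC with CI, sensitivity and specificity with exact CIs, PPV, NPV,
the between-group p, confusion counts, and swab-timing median (IQR)
summaries.

The same steps are available as a CLI (`voc-ptb simulate | convert |
preprocess | cv | evaluate | cohort-summary | run`), e.g.:

```bash
voc-ptb simulate --n-patients 50 --seed 3 --out /tmp/demo --write-spectra
voc-ptb cohort-summary --patients /tmp/demo/patients.csv --swabs /tmp/demo/swabs.csv
voc-ptb run --patients /tmp/demo/patients.csv --swabs /tmp/demo/swabs.csv \
            --spectra /tmp/demo/spectra --seed 3 --out /tmp/demo/report
```

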