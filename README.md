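# edchest

ECG- and HRV-based 30-day cardiac risk stratification for patients presenting
to the emergency department with chest pain.

Emergency physicians triaging chest pain need a rapid, objective estimate of
the risk of a 30-day major adverse cardiac event (MACE: death, acute
myocardial infarction, or revascularization). `edchest` implements a complete
pipeline for building and using additive integer risk scores that combine
demographics, triage vitals, 12-lead ECG flags, and short-term heart rate
variability (HRV) extracted from a 6-minute single-lead monitoring ECG:

- **signal** — band-pass filtering (5–28 Hz zero-phase Butterworth),
  amplitude-adaptive squared-derivative QRS detection, RR-interval labelling
  (normal / ectopic) by a local-median ratio rule, and the >30 %-abnormal
  eligibility rule;
- **hrv** — the 16 standard short-term parameters: AVRR, SDRR, average HR,
  SD HR, RMSSD, NN50, pNN50, triangular index, TINN, and Welch band powers
  (total, VLF 0.0033–0.04 Hz, LF 0.04–0.15 Hz, HF 0.15–0.40 Hz, normalized
  LF/HF, LF/HF ratio) of the cubic-spline resampled tachogram;
- **scoring** — the SEDRSM (Singapore ED risk stratification model, range
  0–37) and the seven-item TIMI UA/NSTEMI score (range 0–7);
- **derivation** — re-derivation of a score from a cohort: univariate
  screening (Welch t / Mann–Whitney / chi-square / Fisher), likelihood-ratio
  backward stepwise logistic regression (own IRLS engine), Hosmer–Lemeshow
  calibration, and coefficient-to-points normalization;
- **evaluation** — AUROC with DeLong intervals and paired comparison,
  sensitivity/specificity/PPV/NPV with Wald CIs, ROC curves, score-bin
  summaries;
- **simulate** — synthetic ECG waveforms, RR series with controllable LF/HF
  content, and cohorts whose outcome follows a known logistic model.

## The score construction

Candidate predictors surviving univariate screening (p < 0.05) are
categorized into risk indicators and entered into a likelihood-ratio
backward stepwise logistic regression (removal threshold p ≥ 0.10, variable
blocks removed jointly). The final unstandardized coefficients β_i are
normalized by the smallest coefficient and rounded to the nearest integer,

    points_i = round(β_i / min_j β_j),

and a patient's score is the arithmetic sum of the points of the categories
they satisfy. For the published ten-variable model (male 0.773, age ≥60
0.323, HR ≤55 1.510, HR 56–114 0.716, ST elevation 2.138, ST depression
2.382, Q wave 1.076, QT prolongation 0.372, AVRR <0.77 s 0.415, TINN <0.11 s
0.712, TINN >0.17 s 0.277, HF <0.07 0.531) the divisor is 0.277 and the
points are 3, 1, 5, 3, 8, 9, 4, 1, 1, 3, 1, 2 — a score ranging from 0
to 37.

## Worked example

```python
import edchest as ec

cohort = ec.simulate_cohort(ec.CohortSimSpec(n=763, seed=7))
scored = ec.add_scores(cohort)                      # sedrsm_score, timi_score

auc  = ec.auroc(scored.sedrsm_score, scored.mace30)
auct = ec.auroc(scored.timi_score, scored.mace30)
p    = ec.delong_compare(scored.sedrsm_score, scored.timi_score, scored.mace30)
dv   = ec.discrim(scored.sedrsm_score, scored.mace30, cutoff=9)
```

which prints, for this seed:

```
events: 255
SEDRSM AUROC 0.743 (95% CI 0.705, 0.780)
TIMI   AUROC 0.588 (95% CI 0.547, 0.630)
DeLong p = 7.24e-11
cutoff 9: sens 0.890 (0.852, 0.929), spec 0.364, ppv 0.413, npv 0.869
```

The synthetic cohort has 763 patients with ~33 % MACE prevalence; the SEDRSM
clearly outranks the TIMI comparator (paired DeLong p ≪ 0.001), and at the
cutoff of 9 points the score trades specificity for high sensitivity. The
absolute AUROC depends on the covariate joint distribution, which for
synthetic data is only structurally faithful (see `docs/methods.md`).

Re-deriving a score from a cohort uses the model/results interface:

```python
res = ec.RiskScoreModel.from_dataframe(cohort).fit(p_remove=0.10)
print(res.summary())          # screening, stepwise trace, betas, ORs, points
res.score_table.max_score     # maximum attainable total
res.hosmer_lemeshow().p_value # decile calibration
```

The same workflows are available from the shell:

```sh
edchest simulate cohort --n 763 --prevalence 0.333 --seed 7 --out cohort.csv
edchest score sedrsm --cohort cohort.csv --out scored.csv
edchest evaluate --cohort scored.csv --cutoff 9 --compare timi_score
edchest derive --cohort cohort.csv --p-remove 0.10 --out model.json
edchest simulate ecg --duration 360 --fs 250 --seed 7 --out rec.csv
edchest hrv --input rec.csv --start 0 --duration 360
```

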