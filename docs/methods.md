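# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of `edchest`, in the spirit of a statistical package's methods
appendix. Everything quantitative stated here is computed by the test suite
or by `scripts/acceptance.py`; nothing is asserted from memory.

## 1. Signal chain

**Filtering.** The QRS band-pass is a 4th-order Butterworth (5–28 Hz)
applied forward–backward (`scipy.signal.sosfiltfilt`), giving zero phase so
R-peak timing is unbiased. The band removes baseline wander and P/T-wave
energy while preserving the QRS complex; the effective attenuation is
double the one-pass order. Edge transients are confined to roughly one
second at each boundary, which is why segment selection and filtering
commute only in the interior.

**QRS detection.** The detection function is the squared first derivative
of the filtered signal smoothed by a 0.12 s moving average (about the width
of a QRS complex). The threshold is adaptive: within consecutive 10 s
blocks it is 0.4 × the block's 95th percentile of the detection function.
Because every quantity scales with the square of the input amplitude, the
detected indices are exactly invariant to any positive rescaling of the
waveform (asserted as a property test). Peaks closer than a 0.25 s
refractory period are merged (the larger wins), and each surviving peak is
refined to the local maximum of the filtered waveform within ±0.1 s. All
parameters are keyword-configurable; the defaults were chosen once from
standard practice for adult sinus rhythm (refractory 0.25 s corresponds to
240 beats/min, far above any sinus rate).

**Interval labelling.** Real pipelines remove artefacts and ectopic beats
by hand; the package substitutes a deterministic rule: an interval is
labelled ectopic when it falls outside [0.75, 1.25] × the median of its 5
nearest intervals. The window is symmetric in index distance and uses the
provisional all-normal labels in a single pass, which makes the rule
order-independent and reproducible. A recording is eligible for HRV
analysis when the abnormal fraction is ≤ 0.30 — the boundary itself
(exactly 30 %) remains eligible, since the exclusion rule is "greater
than 30 %".

## 2. HRV parameters

Only intervals labelled normal enter any metric (NN intervals).

- Time domain: AVRR = mean NN; SDRR = population SD (dividing by n; at the
  series lengths involved the n vs n−1 distinction is far below any
  verification tolerance, and the convention is configurable in the sense
  that callers can compute either from the series); average HR and SD HR
  are the mean/SD of the per-interval instantaneous rate 60/NN (not
  60/mean NN — the two differ by Jensen's inequality and the per-interval
  convention is the one adopted); RMSSD, NN50 (successive differences
  strictly exceeding 50 ms in magnitude), pNN50 = 100·NN50 / (number of NN
  intervals).
- Geometry: the NN histogram uses bin width 1/128 s, the conventional
  short-term resolution. The triangular index is N/height(modal bin); TINN
  is the base M − N of the best least-squares triangle with its apex fixed
  at the modal bin, found by exhaustive search over bin edges N below and M
  above the mode. A single-occupied-bin histogram (constant series) is
  degenerate and returns triangular index 1, TINN 0.
- Spectra: the tachogram (NN value anchored at its later beat's time) is
  cubic-spline resampled at 4 Hz and analysed by Welch's method (hann
  window, 120 s segments, 50 % overlap, constant detrend). Band powers are
  trapezoid integrals of the one-sided PSD over VLF 0.0033–0.04, LF
  0.04–0.15, HF 0.15–0.40 Hz; total power spans 0.0033–0.40 Hz. Powers are
  reported in s² because the tachogram is in seconds. Normalized LF/HF are
  percentages of LF+HF and sum to 100 by construction; when LF+HF is
  numerically zero (below 1e-20 s², i.e. a constant tachogram) the
  normalized powers and LF/HF ratio are undefined and are flagged rather
  than returned as infinities.

The power unit of the HF score cutoff (default 0.07) follows whatever unit
convention the HRV pipeline used; the cutoff is an ordinary configurable
number in the score rules.

## 3. Integer score construction

`build_score_table` implements the classic normalization: divisor = the
smallest coefficient, points = round(β/divisor) half away from zero (no
published ratio lands exactly on .5; the convention is stated for exact
reproducibility). Coefficients must be positive — a negative coefficient
means the category coding points the wrong way and is rejected rather than
silently floored. The score range maximum is the sum over variables of each
variable's largest points, 37 for the default SEDRSM instance.

Boundary semantics of the default criteria are taken literally from their
labels: age ≥60; heart rate in whole beats/min (non-integer rates floored)
with ≤55 / 56–114 / ≥115 (reference); AVRR <0.77 s; TINN <0.11 s, closed
band 0.11–0.17 s (reference), >0.17 s; HF <0.07. The TIMI comparator is the
standard seven-item UA/NSTEMI score, one point each for age ≥65, ≥3
coronary risk factors, known ≥50 % stenosis, aspirin within 7 days, ≥2
anginal episodes in 24 h, ST deviation, elevated markers.

## 4. Derivation pipeline

**Screening.** Continuous candidates: Welch's t when both outcome groups
pass a Lilliefors-corrected Kolmogorov–Smirnov normality check at 0.05
(parameters are estimated from the sample, so the Lilliefors null
distribution is the correct one), otherwise Mann–Whitney. Binary
candidates: chi-square, falling back to Fisher's exact test when any
expected cell count is below 5. Selection means p < 0.05. The type-I error
of the composite continuous path is calibrated at the nominal 5 % (checked
over 1000 null replicates).

**Logistic engine.** `fit_logistic` is a Newton/IRLS implementation
(always-included intercept, convergence |ΔLL| < 1e-8, at most 100
iterations). It matches `statsmodels.Logit` to 1e-6 on coefficients and
log-likelihood in the tests — the external fit serves as a cross-check,
never the engine. A coefficient exceeding 50 in magnitude during iteration
signals (quasi-)separation and raises, because a silently diverged fit
would poison every downstream LR test.

**Stepwise elimination.** Multi-category variables enter and leave as
blocks. At each step every remaining block is tested by the likelihood
ratio against the current model (reduced fits warm-started from the current
coefficients); the block with the largest p ≥ 0.10 is removed and the model
is refit. The procedure is deterministic given column order. The 0.10
removal threshold is configurable; it is the value consistent with a
published model that retains a predictor at p = 0.090 while testing
three-level variables as blocks. With k pure-noise candidates the final
model is empty with probability ≈ 1 − (1 − 0.9^k) being the last survivor's
escape rate — about 0.90 for one candidate and 0.71 for three; the tests
assert the analytically correct bounds.

**Calibration.** Hosmer–Lemeshow over deciles of predicted risk:
statistic Σ (O−E)²/(E(1−E/n_g)), df = groups − 2. Ties that empty a decile
cause adjacent groups to merge, and the merge is recorded in the result.
Under a well-specified model the 5 % rejection rate is confirmed over 500
replicates.

**Facade.** `RiskScoreModel.fit()` composes the four steps and returns a
results object carrying the univariate table, the stepwise trace, the final
IRLS fit, predicted risks, the Hosmer–Lemeshow diagnostic, and the derived
integer score table, with a plain-text `summary()`. Continuous candidates
that were screened in but have no prespecified categorization are split at
the cohort median — a neutral default for variables the original cutoff
procedure (visual inspection of event rates) cannot reproduce
algorithmically.

## 5. Evaluation

AUROC is the tie-corrected Mann–Whitney concordance; its variance and the
paired two-score comparison use DeLong's structural components. Equality of
the two score vectors short-circuits to p = 1 (the variance of the
difference is zero). Discriminatory values call a patient positive at
score ≥ cutoff and carry Wald intervals p ± 1.96√(p(1−p)/n) on their own
denominators, clipped to [0, 1]; this is the arithmetic that reproduces the
published intervals exactly, which is why Wald (rather than Wilson or
Clopper–Pearson) is the default. PPV/NPV with an empty denominator are
flagged undefined, not NaN-by-surprise. Score-bin summaries pool the sparse
extremes (0–6 and 17–37 by default) and report both the per-bin event rate
and each outcome group's distribution across bins.

## 6. Synthetic data

**RR series.** Beat-to-beat intervals follow a mean plus two sinusoidal
modulations at the LF and HF band centres (0.1 and 0.25 Hz) plus Gaussian
jitter; the spec enforces `mean_rr > amp_lf + amp_hf + 3·jitter_sd` so
intervals stay positive. Defaults (mean 0.8 s, amplitudes 0.03 s, jitter
5 ms, 360 s) emulate a calm sinus-rhythm 6-minute segment.

**ECG.** Each beat contributes a Gaussian R-wave (default support 0.12 s,
1 mV) at its true time, plus optional 0.3 Hz baseline wander and white
noise; the true beat times ride along on the record. This waveform has no
P/T waves, no QRS morphology variation, and no non-stationary noise — so
detector tests on it demonstrate timing accuracy and amplitude invariance,
not robustness to real-world artefact.

**Cohorts.** Covariates are drawn from marginals matched to the emulated
study population (65 % male; age N(60.5, 13.3²) truncated to [22, 100];
triage HR N(77, 22²) truncated above 30; 12-lead flag frequencies 0.085 /
0.087 / 0.068 / 0.342 for STE/STD/Q/QT; TINN and HF log-normal with the
published means and SDs). AVRR is coupled to the triage heart rate
(60/HR + N(0, 0.03 s)) by default so records are physiologically coherent.
Nine additional candidates (DBP, T inversion, IVCD, SDRR, average HR,
RMSSD, NN50, pNN50, VLF) are drawn independently of the outcome to exercise
screening and elimination. The outcome is Bernoulli(logistic(α + Σβ·x))
over the categorized indicators with the published coefficient set; the
intercept α is found by bisection over 100,000 fixed covariate draws so the
population prevalence is within 0.002 of the target (default 1/3). TIMI
items are partly derived from the shared covariates (age ≥65, ST
deviation), partly independent, and the markers item leans on the latent
risk so the comparator score is informative without being competitive.

Because only the marginals are published, the synthetic covariate joint
distribution is a modelling choice; the synthetic AUROC of the score
(≈0.74 at study size) is therefore a property check — the score is strongly
predictive when the data follow its generating model — not a reproduction
of the cohort-specific 0.780.

One structural consequence of the literal coefficient set deserves note:
HR ≤55 carries risk, but so does AVRR <0.77 s — which corresponds to HR
above ~78. With HR and AVRR coupled, the two opposing effects partially
cancel in the *marginal* HR and AVRR distributions, so the univariate
screen can occasionally reject them even in large synthetic cohorts. This
is a real feature of the model geometry, not a bug in the screen.

## 7. Problem sizes and numerical choices

The test battery uses the sizes at which each property is statistically
meaningful while remaining desk-scale: 100 random series for HRV oracle
equivalence, 6-minute ECGs at 250 Hz for detector round trips, 1000
replicates of n = 763 for screening type-I error, 20 replicates of
n = 20,000 cohorts for parameter recovery and end-to-end derivation, 500
replicates for Hosmer–Lemeshow calibration. IRLS warm starts make the
stepwise LR tests cheap; the full suite completes in well under a minute.

Exact end-to-end recovery of the published integer points is structurally
fragile regardless of cohort size: the true AVRR ratio 0.415/0.277 = 1.498
sits two thousandths below the rounding boundary, so unbiased estimation
noise flips that point in about half of all replicates, and several other
ratios (5.448, 2.582, 2.571, 8.597) sit within ~0.1 of a boundary. The
corresponding test states this and reports the measured rates.

## 8. Known limitations

- The QRS detector targets clean single-lead sinus rhythm; it does not
  classify arrhythmias, handle pacing artefacts, or fuse leads.
- The ectopic-labelling rule is a stand-in for human editing; its ratio
  bounds (0.75/1.25) are conventional, not learned.
- WFDB support covers single-segment format-16 records only; CSV
  (`time_s,mv`) is the primary interchange format.
- Score category cutoffs are inputs, not learned: the original cutpoint
  selection by visual inspection has no algorithmic counterpart.
- Printed power values in the emulated study have no stated units; powers
  here are s², and the HF cutoff is exposed as a configurable number.
- Synthetic cohorts use (mostly) independent covariate marginals; real
  covariate correlation structure would change screening power and the
  achievable AUROC.
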