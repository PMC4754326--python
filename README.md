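# oplsage

Age-corrected multivariate classification of Alzheimer's disease from
regional MRI measures, with orthogonal projections to latent structures
(OPLS) discriminant analysis.

## The problem

Structural MRI yields dozens of regional measures — cortical thickness
means and subcortical volumes — that jointly discriminate Alzheimer's
disease (AD) patients from cognitively normal controls (CTL) and help
predict which patients with mild cognitive impairment (MCI) will progress
to AD. Age is a confounder: normal aging thins the cortex and enlarges the
ventricles in a pattern that partially mimics the disease, so old controls
and young patients are the ones a classifier tends to get wrong.

`oplsage` implements, end to end, a classification workflow that
quantifies this problem and two ways of fixing it:

* **uncorrected** — the discriminant model sees the raw measures;
* **covariate** — the subject's age enters the model as an additional
  variable;
* **detrended** — a linear model of each measure on age, fit by ordinary
  least squares **in the control group only**, is used to remove the
  age drift from every subject: `x' = x − β̂₁ · (age − age_ref)`.

It is aimed at biostatisticians and imaging researchers who want a
tested, reproducible reference for OPLS-based discrimination with
confound correction — including a synthetic-cohort generator, since the
large clinical cohorts this kind of analysis is run on (ADNI,
AddNeuroMed) are access-restricted.

## The model

Features are mean-centered and scaled to unit variance (parameters fit on
training data only). A two-class OPLS model with the response coded
CTL = 0 / AD = 1 separates descriptor variation into **one predictive
component** and `k` components orthogonal to the response:

```
w ∝ Xᵀy                       predictive weight (unit norm)
repeat k times:
    p   = Xᵀt / tᵀt,  t = Xw
    w_o ∝ p − (wᵀp) w          orthogonal weight (unit norm)
    X  ← X − t_o p_oᵀ          deflate, t_o = X w_o
t = Xw,  c = yᵀt / tᵀt        score → class regression
ŷ = ȳ + c · t
```

With `k` orthogonal components the training predictions coincide with a
(1+k)-component NIPALS PLS model — verified against an independent PLS
oracle in the tests. `k` is chosen by sevenfold cross-validated
Q² = 1 − PRESS/SS (smallest `k` within 0.01 of the best). Models are
**hierarchical**: one base model on the 21 volumes, one on the 34
thickness means, and a top model on the base models' cross-validated
scores (plus scaled age for the covariate strategy). A fixed cut-off of
0.5 on the cross-validated score assigns class membership; the fitted
AD/CTL models then score MCI subjects as unseen data, and predictions are
evaluated against progression status at 12/18/24/36-month follow-up.

Finally, correctly vs incorrectly classified subjects are compared per
variable (age, education, MMSE with pooled-variance t tests; sex, ApoE-e4,
cohort with Pearson χ² without continuity correction) — the analysis that
shows the uncorrected model misclassifying old controls and young
patients, and both corrections removing that age difference.

## Worked example

```bash
oplsage run --seed 1 --correction detrend --out-dir out/
```

simulates the default cohort (340 CTL / 360 stable MCI / 85 progressive
MCI / 297 AD, ages ≈ 75 ± 6–7 y, 55 measures with realistic collinearity
and age drift), fits the detrended model and prints:

```
== detrend model ==
  Q2=0.566  R2=0.568  n_ortho={'volume': 2, 'thickness': 1, 'top': 0}
  AD/CTL: acc=85.6 sens=82.5 spec=88.2 (tp=245 fn=52 tn=300 fp=40)
  MCI (month 12): acc=65.6 sens=60.0 spec=66.9
    month 12: acc=64.9 sens=59.7 spec=66.3
    month 18: acc=67.7 sens=61.7 spec=70.1
    month 24: acc=70.7 sens=62.3 spec=76.3
    month 36: acc=72.9 sens=62.4 spec=82.5
```

Q² is the cross-validated fraction of response variation the model
predicts (goodness of prediction), R² the fraction it explains on the
training data. The AD/CTL line gives the 0.5-cutoff classification rates
with their confusion counts (positive class = AD). The MCI block reports
prediction of progression as unseen data: overall at month 12, then per
follow-up month within the sub-cohort followed beyond one year — accuracy
grows with follow-up because subjects who convert later already carry the
atrophy pattern at baseline. Running all three strategies
(`oplsage run --seed 1`) shows the ordering the method is built to
demonstrate: Q² 0.520 → 0.554 → 0.566 and accuracy 83.7 → 84.9 → 85.6 for
uncorrected → covariate → detrended, with the misclassified-subject age
difference (p < 0.001 uncorrected) eliminated by both corrections.
`out/` receives the metrics JSON, per-subject score CSVs, the
comparison tables and this report.

The same experiment is available as a library:

```python
from oplsage import SimulationConfig, generate_cohort, fit_hierarchical

cohort = generate_cohort(SimulationConfig(seed=1))
model, cv = fit_hierarchical(cohort, correction="detrend", seed=1)
print(cv.q2, cv.r2)
```

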