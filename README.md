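# mcifuse

Multi-modal recurrent pipeline for predicting conversion from mild cognitive
impairment (MCI) to Alzheimer's disease (AD) from irregular longitudinal
biomarkers — with a synthetic cohort simulator, so every stage runs and is
tested without access to restricted clinical data.

## The problem

MCI is the prodromal stage between normal cognition and AD; some MCI
patients convert to AD within a given window after baseline and some do not.
Predicting, at baseline + Δt months (Δt ∈ {6, 12, 18, 24}), whether an MCI
patient will have converted is central to trial enrichment and timely
treatment. The available evidence is multi-modal and awkward: longitudinal
cognitive composites (memory, executive function) and CSF analytes
(Aβ₁₋₄₂, t-tau, p-tau) with *different numbers of visits per patient*,
plus cross-sectional MRI phenotypes (hippocampal volume, entorhinal
thickness) and demographics (age, sex, education, *APOE* ε4). Many patients
lack one or more modalities entirely.

## The method

Each modality *m* gets its own gated recurrent unit (GRU) encoder that folds
a variable-length visit sequence {x₁, …, x_T} into a fixed-size hidden state
h_T, starting from h₀ = 0:

    z_t = σ(W_z x_t + U_z h_{t−1} + b_z)        update gate
    r_t = σ(W_r x_t + U_r h_{t−1} + b_r)        reset gate
    c_t = tanh(W_c x_t + U_c (r_t ⊙ h_{t−1}) + b_c)
    h_t = (1 − z_t) ⊙ h_{t−1} + z_t ⊙ c_t

(cross-sectional modalities are length-one sequences). Training happens in
two stages:

1. **Per-modality GRU classifiers.** Each encoder plus a softmax read-out
   ŷ = softmax(W_y h_T) is trained by full-batch gradient descent on the
   cross-entropy of the final-step prediction, with exact gradients from
   backpropagation through time. Training warm-starts on auxiliary classes
   — cognitively normal subjects (labelled non-converter) and AD patients
   (labelled converter) — before continuing on horizon-labelled MCI
   subjects. Every subject who has a modality contributes to that
   modality's encoder, so non-overlapping samples are never discarded.
2. **Concatenation fusion.** Encoders are frozen; the per-modality hidden
   states are concatenated in registry order (18 dimensions under the stock
   registry: 3 + 5 + 6 + 4) with zero-fill for absent modalities, and an
   l1-regularized logistic classifier is fit on labelled MCI subjects only.

Evaluation follows the horizon protocol: an MCI subject is a converter at
Δt if conversion occurred by that month, a non-converter if unconverted
with follow-up ≥ Δt, and excluded otherwise; repeated stratified k-fold
cross-validation (default 5 folds × 10 repeats) is run on eligible MCI
subjects, with CN/AD auxiliaries in every training split and no test fold.
Reported metrics are accuracy, sensitivity, specificity, rank-statistic AUC
and balanced accuracy, with paired t-tests between schemes.

The simulator generates cohorts from a latent linear disease-severity
trajectory per subject with linear-Gaussian per-modality emissions,
grid-defined conversion events, per-subject sequence-length draws, and
block modality missingness (CSF scarcest) — the statistical structure the
method assumes, at configurable size.

## Worked example

```python
from mcifuse import SimConfig, simulate_cohort, TrainConfig, Scheme, run_scheme

cohort = simulate_cohort(SimConfig(n_cn=40, n_mci_c=60, n_mci_nc=70, n_ad=30, seed=1))
res = run_scheme(cohort, Scheme.proposed(cohort), 24.0, TrainConfig(seed=0), cv=(5, 2, 0))
print(res.aggregate().round(3))
```

prints

```
              mean     sd
accuracy     0.858  0.060
sensitivity  0.611  0.172
specificity  0.952  0.053
auc          0.915  0.060
```

— the mean and standard deviation over the 10 (repeat, fold) records of the
24-month-horizon metrics for the fused longitudinal model on a 200-subject
synthetic cohort: 86% of held-out MCI subjects classified correctly, an AUC
of 0.92, and (as usual at this prevalence) higher specificity than
sensitivity.

The same pipeline is scriptable from the shell:

```
mcifuse simulate --seed 1 --out cohort/
mcifuse run --cohort cohort/ --schemes proposed,baseline,single:cognitive \
            --dt 6,12,18,24 --folds 5 --repeats 10 --out results/
mcifuse report --results results/
```

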