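# Methods

## Model

The classifier is a two-stage late-fusion architecture over four modality
streams (cognitive composites, demographics, CSF analytes, MRI phenotypes).

**Stage 1 — per-modality recurrent encoders.** Each modality has a GRU with
input weights W ∈ R^{H×F}, recurrent weights U ∈ R^{H×H} and biases b ∈ R^H
per gate (update, reset, candidate), plus a linear read-out W_y ∈ R^{2×H}.
The hidden state starts at zero, which (a) makes a length-one sequence a
single cell step, so cross-sectional modalities need no special casing, and
(b) keeps every hidden entry strictly inside (−1, 1) because the candidate
is tanh-bounded and the state update is a convex combination. A vanilla
recurrent cell h_t = tanh(W_h h_{t−1} + W_x x_t), with no biases, is kept
alongside as the reference formulation; the GRU is what the pipeline
trains. The GRU follows the standard convention (update gate z weights the
candidate, 1 − z the previous state, biases included).

The per-modality classifier is trained on the cross-entropy of the
final-step prediction only — intermediate step outputs are not penalized —
as the negative mean log-likelihood, with predicted probabilities clipped
at 1e-12 before the log. Gradients are exact backpropagation through time,
hand-written in numpy as reverse accumulation over the unrolled sequence
and vectorized over groups of equal-length sequences; the test suite checks
them entrywise against central finite differences (relative error ≤ 1e-5 on
random small instances). Sequences here are short (≈ 1–8 visits), so no
truncation or gradient clipping is needed.

**Auxiliary pre-training.** The CN-vs-AD boundary is an easier, more
populated proxy for the non-converter-vs-converter boundary, so each
encoder first trains on CN (labelled non-converter) and AD (labelled
converter) subjects possessing that modality, then continues on the
auxiliaries plus horizon-labelled MCI subjects. MCI labels used in stage 1
are horizon-specific (the same Δt rule as evaluation), so each Δt trains
its own encoders.

**Stage 2 — concatenation fusion.** Encoders are frozen; stage-2 fitting
never modifies a single encoder parameter (asserted bitwise in tests). Each
subject's per-modality final states are concatenated in registry order;
under the stock registry the fused vector has 3 + 5 + 6 + 4 = 18 entries.
A subject lacking a modality gets a zero block — the neutral point of the
standardized representation space; a training-mean fill is available as an
alternative policy. The fused classifier is l1-regularized logistic
regression (mean logistic loss + λ‖w‖₁, intercept unpenalized), fit to
labelled MCI subjects only.

## Optimization choices

* Stage 1: full-batch gradient descent, constant learning rate (default
  0.2, 30 pre-training + 60 main epochs). No momentum or adaptive steps —
  the simplest deterministic optimizer; hidden sizes are 3–6 and sample
  sizes a few hundred, so convergence is not the bottleneck. A fixed-order
  mini-batch mode exists but the default is full batch.
* Initialization: uniform(−1, 1)/√(fan-in) weights, zero biases, seeded;
  per-modality seeds are derived from the config seed and the modality name
  (CRC32) so encoders are independent but reproducible.
* Standardization: per-feature z-scoring with statistics from the training
  subjects of each fold (constant features pass through with unit scale).
  Demographics are standardized like everything else.
* Stage 2 is solved by FISTA (accelerated proximal gradient with exact
  soft-thresholding), step size from the spectral norm of the design
  matrix; deterministic, and validated against an independent convex solver
  to 1e-4. λ defaults to 0.01; `select_l1_strength` implements an inner
  3-fold grid search over {1e-3 … 10} and is engaged by setting
  `l1_strength=None`. The stock benchmark uses the fixed default to keep
  the repeated-CV runtime at desk scale.

## Evaluation protocol

At horizon Δt an MCI subject is *converter* if conversion_month ≤ Δt,
*non-converter* if unconverted with follow-up ≥ Δt (converting after the
window counts as non-conversion at that horizon), *ineligible* otherwise —
so eligible counts shrink with Δt. Folds are stratified over eligible MCI
subjects only (scikit-learn StratifiedKFold, per-repeat child seeds from a
numpy SeedSequence); CN/AD auxiliaries join every training split and never
a test fold (asserted every fold). The fold seed stream is independent of
the training seed stream so CV structure and initialization can be varied
separately. Decision threshold is fixed at 0.5; AUC is the Mann–Whitney
rank statistic with ties averaged. Reported mean ± sd are over all
repeat × fold records, and AUC is averaged per fold (not pooled).
The paired t-test between schemes pairs records by (repeat, fold); the
zero-variance branch is defined as t = 0, p = 1 for identical vectors and
t = ±∞, p = 0 for a constant nonzero shift.

The accuracy identity ACC = prev·SEN + (1 − prev)·SPE is asserted on every
fold as an internal consistency check.

## Synthetic cohorts

Subject i in group g has latent severity s_i(t) = a_i + b_i·t with
a_i ~ N(μ_a[g], 0.6) (CN −2.0, MCI −0.4, AD +2.0) and b_i ~ N(μ_b[g],
0.025) per month (CN 0.0, MCI 0.035, AD 0.04). An MCI subject converts at
the first visit-grid month (spacing 6) within follow-up (drawn from
{24, …, 48}) where severity crosses 1.0; requested converter /
non-converter counts are enforced by rejection sampling. Severity-driven
modalities emit loading·s(t) + intercept + N(0, σ_m) at each visit;
demographics are severity-independent (age, sex, education) except an
APOE-ε4-like binary whose carrier frequency follows the observed gradient
(CN 0.275, MCI-NC 0.418, MCI-C 0.658, AD ≈ 0.666). Longitudinal sequence
lengths are round(N(mean, sd)) truncated to ≥ 1 — cognitive 3.7 ± 1.32
visits, CSF 1.4 ± 0.5, demographics and MRI single-visit — and follow-up is
extended to cover the last simulated visit so length draws are never
truncated. Modalities are independently present (demographics always, CSF
scarcest at 0.6). Everything is driven by one seeded generator;
`converter_fraction` exposes the raw conversion probability of a fixed
trajectory pool, which is monotone non-increasing in the threshold.

Two named configurations:

* `benchmark_config` (~600 subjects, scaled-down group proportions):
  loadings and noise are set so each severity-driven modality is a
  *partial* view (cognitive noise 1.0, CSF/MRI 0.4). With the cohort
  defaults the cognitive stream alone nearly determines the label — a
  single-factor model with four visits pins the trajectory — which would
  make multi-modal fusion pointless; moderating per-view signal-to-noise is
  what makes the fusion-vs-single comparison meaningful. On this benchmark
  (5-fold × 3 repeats, Δt = 24) the fused longitudinal scheme dominates the
  baseline-truncated scheme and every single-modality scheme in mean
  accuracy and AUC.
* `separable_config` (noise-free ceiling): all modalities present, exact
  emissions, full visit grid to a common 36-month follow-up, and a
  `severity_margin` of 0.25 — MCI trajectories whose grid severities come
  within the margin of the threshold are rejected, so classes are separable
  *with a gap*. Without the margin, subjects arbitrarily close to the
  threshold make literal 100% accuracy unattainable by any finite-sample
  learner; with it, the pipeline reaches accuracy 1.0, which is the point
  of a ceiling check.

**What the simulator does not emulate:** real assay units and covariance
between analytes, visit-time irregularity (the grid is exact), informative
missingness (presence is independent of severity), diagnosis noise, and
multi-factor pathology (severity is one-dimensional). Passing tests
therefore demonstrate that the architecture, training procedure and
protocol behave as designed under the assumed data-generating structure —
not that the reported numbers transfer to any clinical cohort.

## Degenerate inputs and numerical edges

Empty sequences, single-class training sets, unknown modalities, shape
mismatches and non-finite parameters are hard errors. Softmax uses max
subtraction; the logistic uses scipy's expit; probabilities are clipped at
1e-12 before logs; standardization floors sd at 1e-8. CSV round trips are
bit-exact (`%.17g` on write, round-trip float parsing on read).

## Known limitations

* Stage 2 cannot improve stage-1 representations (no joint
  backpropagation through the fusion head into the encoders) — a property
  of the design, preserved deliberately.
* Full-batch descent with a constant rate is slow near saturation; the
  epoch budgets are sized for the hidden dimensions used here, not for
  larger encoders.
* Per-Δt encoder training multiplies cost by the number of horizons.
* The zero-fill missing-modality policy biases fused scores toward the
  class prior for sparsely observed subjects; the mean-fill alternative is
  implemented but not the default.
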