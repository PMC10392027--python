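# Methods

This note documents the statistical model behind `tepcox`, the choices made
where the design was genuinely open, and what the synthetic cohorts do and
do not establish about behavior on real data.

## The model

The pipeline estimates a per-patient risk score from gene expression under
the proportional-hazards assumption: the hazard of patient *i* is
λ(t | x_i) = λ₀(t) · exp(η_i), where η_i is a log relative hazard produced
in the full model by a small feed-forward network over a selected gene
signature, and in the classical fits by a linear predictor x_iᵀβ.

All likelihood computations use the Cox partial likelihood with the
**Breslow** convention for tied event times (tied events share one risk-set
denominator):

ℓ(η) = Σ_{i: event} [ η_i − log Σ_{j: t_j ≥ t_i} exp(η_j) ].

One tie convention is used everywhere — the Newton fits, the penalized
solver and the network loss — so that the zero-hidden-layer network is
*exactly* the classical Cox model and the equivalence can be tested
tightly. The Efron correction is available on `fit_cox(ties="efron")` for
cross-checks against libraries that default to it; with no ties the two
coincide.

### Stage 1: preprocessing (`tepcox.preprocess`)

Raw nonnegative expression is normalized as log2(CPM + 1), filtered to
genes detected in ≥ 20% of samples (`min_frac_expressed=0.2`; near-zero
genes destabilize per-gene Cox fits), batch-adjusted per gene by a
location–scale map (subtract batch mean, rescale batch SD to the pooled SD,
re-add the pooled mean), and z-scored per gene. Every statistic in this
chain is learned on the training cohort alone and frozen into
`PreprocessParams`; validation cohorts pass through `apply_frozen`, which
never updates the parameters (the `content_hash` of the params is the
auditable invariant). Genes missing from a validation cohort are imputed at
the training center (z = 0) up to a 20% tolerance, beyond which the
transform refuses. Batches unseen at fit time are left unadjusted — there
is no honest frozen offset for them — and this is logged.

### Stage 2: gene selection (`tepcox.screening`)

1. **Univariate screen.** One single-gene Cox fit per gene (vectorized
   scalar Newton–Raphson, identical math to `fit_cox`); genes with Wald
   p < α pass (default α = 0.05, configurable). Constant genes are skipped.
2. **L1-penalized Cox.** On the survivors, minimize
   −(1/n) ℓ(Xβ) + λ‖β‖₁ by cyclic coordinate descent on the diagonal
   quadratic expansion of the partial likelihood (IRLS outer loop with
   step-halving so the true objective decreases monotonically; glmnet-style
   active-set sweeps inside). KKT conditions are verified at 1e-6 at every
   returned solution. λ_max (the smallest all-zero penalty) is computed
   from the score at the origin; the default path is 50 log-spaced points
   down to 0.01·λ_max.
3. **Choosing λ.** Two modes:
   - `target_size=k`: take the path point whose active set is closest to
     k genes (ties toward the smaller penalty). The default is k = 100,
     mirroring a fixed-size signature design.
   - `target_size=None`: 5-fold cross-validation, folds stratified by event
     status, maximizing the summed van Houwelingen contributions
     ℓ_all(β₋k) − ℓ_train(β₋k). **The univariate screen is refit inside
     every training fold.** Screening once on the full cohort selects genes
     for their (possibly spurious) full-data association, which leaks
     outcome information into the held-out folds; with the nested design a
     pure-noise cohort of 2000 genes yields a near-empty signature, as it
     should.

### Stage 3: the neural risk model (`tepcox.network`)

A fully connected network with ReLU activations, inverted dropout
(default rate 0.1) and a single linear output with **no bias** — the
partial likelihood is shift-invariant, so an output bias is unidentifiable.
Default hidden widths are (64, 32): modest capacity for ~100 inputs and a
few hundred samples. The loss is the negative Breslow partial
log-likelihood of the batch, with risk sets formed within the batch (the
standard device for mini-batch proportional-hazards training); runs with
fewer than 256 training samples use the full batch, where the loss is
exact. The gradient with respect to the outputs has the closed form
d_i − exp(η_i)·Σ_{t_k ≤ t_i} d_k/S_k and is backpropagated analytically;
the whole model is plain numpy.

Optimization: Adam (lr 1e-3, decoupled L2 weight decay 1e-4), early
stopping on a 20% event-stratified validation split by held-out partial
likelihood with patience 10. Every random element — initialization, the
split, batch shuffling, dropout masks — flows from one seed, so training is
bit-reproducible. With `val_frac=0` the learning rate is annealed
exponentially over the run and, in the full-batch dropout-free case, the
final weights are polished by backtracking-line-search gradient descent;
this is what lets the linear configuration reproduce the Newton Cox optimum
to ~1e-12 in log-likelihood.

### Stage 4: evaluation (`tepcox.evaluation`)

- **Harrell's C** (the conventional default reading of "concordance
  index"): usable pairs are (i, j) with t_i < t_j and event_i = 1, plus
  tied-time pairs with exactly one event; score ties credit 1/2.
  Confidence intervals are nonparametric bootstrap percentile bounds
  (default 1000 replicates, seeded).
- **Time-dependent AUC** at horizon t: cumulative-case / dynamic-control
  with inverse-probability-of-censoring weights — cases (t_i ≤ t, event)
  weighted 1/Ĝ(t_i⁻), controls (t_j > t) weighted 1/Ĝ(t), Ĝ the
  Kaplan–Meier estimate of the censoring distribution. Without censoring
  before the horizon the estimator reduces exactly to the rank-statistic
  binary AUC, which is tested.
- **Risk groups.** Dichotomization at the training-median risk score; the
  cutoff is carried to validation cohorts, never re-derived there.
  Groups are compared by Kaplan–Meier curves and the two-group log-rank
  test (hypergeometric variance).

### Stage 5: independence analysis and nomogram (`tepcox.nomogram`)

The risk score is refit jointly with the established predictors — platelet
count, age, log10 CA125 (its distribution is log-normal), residual disease
(0/1) and FIGO stage (ordinal 1–4, entering linearly to match a
single-hazard-ratio-per-variable presentation). Collinear designs
(condition number > 1e8) are refused with the offending pair named.

The nomogram follows the standard regression-nomogram convention:
points_k(x) = 100·|β_k|·(x − x_k*)/B with x_k* the range end minimizing
β_k·x and B = max_k |β_k|·range_k, so the strongest covariate spans exactly
0–100 points and points always increase with hazard. Total points map
affinely back to the linear predictor, and survival at each horizon comes
from the fit's Breslow baseline, S(t|x) = exp(−Ĥ₀(t)·e^{lp(x)}). Because
the point maps are exact affine transforms (no figure-style rounding), the
nomogram reproduces the direct Cox prediction to numerical precision; the
0.01 test tolerance absorbs only the range clamping.

## The synthetic cohort generator

`tepcox.synthetic` draws cohorts from the same model family the pipeline
assumes, with known ground truth:

- latent per-gene expression z ~ N(0, 1) (optional equicorrelated block
  among signal genes); per-batch additive offsets ~ N(0, batch_sd²) on the
  log scale; values exponentiated to a positive abundance scale, so the
  preprocessing chain (log, batch adjustment, z-score) approximately
  recovers z up to a monotone transform;
- hazard on the standardized scale: η = Σ β_k z_k + clinical terms, with
  alternating-sign signal coefficients;
- event times by Weibull inverse-transform sampling,
  T = scale·(−log U / e^η)^{1/shape}; censoring is the minimum of an
  exponential time and an administrative cutoff;
- clinical covariates drawn independently of expression by default: age
  ~ N(52, 8) truncated to [25, 85], FIGO stage 1–4 with probabilities
  (0.05, 0.10, 0.60, 0.25), residual disease Bernoulli(0.45), CA125
  log-normal, platelet count ~ N(300, 80) truncated positive. A
  `platelet_confounding` flag couples platelet count to the hazard to
  emulate paraneoplastic thrombocytosis; a `nonlinear` flag adds a
  gene–gene interaction to the hazard for stress-testing the network
  against linear fits.

Defaults describe one training-cohort-sized draw: 303 samples × 2000
genes, 20 signal genes at |β| = 0.5 per SD, Weibull shape 1.3 / scale 40
months (median survival in the low-30s of months, matching the scale of an
advanced ovarian-cancer cohort), censoring rate 1/80 per month with a
72-month administrative cutoff (roughly a third of follow-up censored),
3 batches with batch_sd 0.5. The real cohorts' censoring pattern is not
published; these are plausibility choices, fixed once.

**What passing tests show — and don't.** The generator satisfies the
proportional-hazards assumption exactly, has Gaussian (after log)
expression, independent samples, and batch effects of exactly the
location–scale form the adjustment removes. Real platelet RNA-seq data
satisfy none of these exactly: counts are overdispersed and zero-inflated,
batch effects are not purely location–scale, effects need not be
proportional over time, and clinical covariates correlate with expression.
Passing tests therefore establish correctness of the *computations* and
sane statistical behavior under the assumed model, not expected
performance on clinical data.

## Numerical choices

- Risk-set log-sum-exp is computed with a single global shift (suffix sums
  of shifted exponentials), keeping the partial likelihood stable for
  |η| up to hundreds.
- Newton–Raphson for `fit_cox`: step-halving to guarantee ascent,
  convergence when the score norm < 1e-9 or the Newton step < 1e-11
  (the step size bounds the remaining error under quadratic convergence);
  standard errors from the inverse observed information; Wald 95% CIs.
  A standardized effect |β|·sd(x) > 5 triggers a monotone-likelihood
  (separation) warning and marks the fit non-converged.
- Coordinate descent resolves exact subgradient ties at λ_max to zero via
  a 1e-12 relative slack; solutions must pass a KKT check at 1e-6 or the
  solver raises rather than returning silently wrong coefficients.
- Test and acceptance runs scale simulation sizes to the problem: unit
  oracles use n ≤ 20, calibration studies use n in the hundreds and up to
  20 seeds, the large-sample concordance check uses n = 5000, and CV grids
  in tests use 8–30 path points instead of the production default of 50.
  Problem sizes are stated in each test.

## Known limitations

- No time-varying covariates, stratified baselines, frailty terms or
  competing risks; no proportionality diagnostics.
- The mini-batch loss uses within-batch risk sets, a biased (but standard)
  estimate of the full-cohort partial likelihood; full-batch mode is exact.
- The bootstrap CI for the C-index is percentile-based; no BCa correction.
- Nomogram covariates enter linearly (no splines); categorical covariates
  beyond binary/ordinal codings are not expanded automatically.
- The normalization and batch-adjustment steps are reasonable defaults for
  the generator's data model, not a reimplementation of any particular
  study's (unpublished) preprocessing.
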