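# tepcox

Survival prediction from tumor-educated platelet (TEP) transcriptomes: a
tested, reusable implementation of a deep proportional-hazards analysis
pipeline for gene-expression survival signatures.

Circulating platelets take up tumor-derived RNA and shift their own
transcription in cancer patients, which makes platelet RNA-seq an
attractive liquid-biopsy readout. This package implements the full
modeling chain needed to turn a platelet (or any bulk) expression matrix
plus censored follow-up into a validated prognostic score:

1. **Preprocessing** — log2-CPM normalization, per-gene location–scale
   batch adjustment, expression filtering and z-scoring, with every
   parameter frozen on the training cohort for leakage-free application to
   prospective validation cohorts.
2. **Gene selection** — per-gene univariate Cox screening, then
   L1-penalized (LASSO) Cox regression by coordinate descent, with either
   cross-validated or fixed-size signature selection (default 100 genes).
3. **Risk model** — a fully connected network (ReLU, dropout 0.1) ending
   in a Cox proportional-hazards likelihood head. The training loss is the
   negative Breslow partial log-likelihood
   ℓ(η) = Σ_{i:event} [η_i − log Σ_{t_j ≥ t_i} e^{η_j}], with η the
   network output; with zero hidden layers the model *is* classical Cox
   regression, and the package tests that equivalence to numerical
   precision.
4. **Evaluation** — Harrell's C-index with bootstrap CIs, IPCW
   time-dependent ROC/AUC at clinical horizons (e.g. 3-year PFS), and
   risk-group stratification with Kaplan–Meier curves and log-rank tests.
5. **Downstream** — multivariable Cox adjustment of the score against
   platelet count, age, CA125, residual disease and FIGO stage, and an
   exact points-based nomogram mapping covariates to survival
   probabilities.

Because real platelet RNA-seq cohorts of this kind are not publicly
deposited, the package ships a first-class synthetic cohort generator
(`tepcox.synthetic`) that draws censored survival-transcriptome cohorts
from a Weibull proportional-hazards model with known signal genes, batch
effects and clinical confounders — every stage is tested against this
ground truth. See `docs/methods.md` for the model and its assumptions.

## Worked example

```python
from tepcox import (SimulationConfig, generate_cohort, fit_preprocess,
                    build_signature, train_deepcox, TrainConfig,
                    apply_frozen, evaluate_cohort)

train = SimulationConfig(n_samples=400, n_genes=1000, n_signal=20,
                         cohort="train", seed=21)
valid = SimulationConfig(n_samples=150, n_genes=1000, n_signal=20,
                         cohort="vc1", seed=22)
expr, clinical, _ = generate_cohort(train)
v_expr, v_clinical, _ = generate_cohort(valid)

z, params = fit_preprocess(expr)                  # frozen on training data
sig = build_signature(z, clinical, target_size=30, seed=2)
cl = clinical.aligned_to(z.sample_ids)
model = train_deepcox(z.subset_genes(sig.gene_ids), cl.time, cl.event,
                      TrainConfig(hidden=(32, 16), max_epochs=150), seed=3)

rep = evaluate_cohort(model, z, clinical, horizons=[36.0], seed=4,
                      n_boot=500, cohort="train")
v_rep = evaluate_cohort(model, apply_frozen(v_expr, params), v_clinical,
                        horizons=[36.0], seed=4, n_boot=500,
                        cutoff=rep.risk_cutoff, cohort="vc1")
```

Running this (it is `examples/04_train_and_validate.py`) prints:

```
trained on 31 genes; early stopping kept epoch 52
train: C-index 0.855 (95% CI 0.828-0.877), 3-year AUC 0.949, log-rank p between risk groups 3.37e-61
vc1: C-index 0.693 (95% CI 0.623-0.758), 3-year AUC 0.799, log-rank p between risk groups 5.98e-06
```

The training C-index (0.86) is optimistic, as it always is; the validation
cohort — transformed with frozen parameters, scored by the frozen model,
split at the training risk cutoff — is the honest estimate: C-index 0.69
means a randomly chosen comparable patient pair is correctly risk-ordered
~70% of the time (0.5 is chance), the 3-year AUC 0.80 is the
censoring-adjusted discrimination of 3-year survival status, and the
log-rank p-value says the two risk groups' survival curves are clearly
separated. The other scripts in `examples/` walk through each capability:
cohort simulation, the classical survival primitives, signature selection,
and the nomogram.

A thin CLI mirrors the stages (`tepcox simulate|preprocess|select|train|
predict|evaluate|nomogram|run`); `tepcox run --config cfg.yaml --out dir`
executes the whole pipeline from a YAML configuration and writes every
intermediate artifact as diff-able text plus a manifest of seeds and
content hashes.

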