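# zzformer

Transformer-based survival modelling for high-dimensional bulk gene
expression, built for prognostic-signature studies in oncology (the package
was developed around a tumor-associated-macrophage marker panel for
hepatocellular carcinoma, but accepts any gene list).

## The model

A patient's expression vector **x** ∈ ℝ^G over a gene signature is
layer-normalized and linearly projected into `num_tokens = ⌊G / 64⌋` tokens
of width 64. A learnable CLS token is prepended and the sequence passes
through two pre-norm transformer encoder blocks (8-head scaled dot-product
attention, softmax(QKᵀ/√d_k)V, plus a position-wise feed-forward sub-layer,
each with residual connections and dropout 0.1). The CLS output is
normalized and mapped linearly to a scalar **Prognosis Index** (PI); higher
PI means worse predicted prognosis.

Training minimizes the Cox negative log partial likelihood over the cohort

L = − Σ_{i: δᵢ=1} [ rᵢ − log Σ_{j: tⱼ ≥ tᵢ} exp(rⱼ) ]

with Adam + L2 weight decay, full-cohort batches (the loss couples samples
through risk sets), and early stopping on the validation concordance index.
Evaluation uses the concordance index (C-index)

C = Σ_{i,j} 1[ηᵢ < ηⱼ] · 1[Tᵢ > Tⱼ] · δⱼ / Σ_{i,j} 1[Tᵢ > Tⱼ] · δⱼ,

under repeated five-fold cross-validation: per round one fold tests, the
next fold validates, three folds train; 20 rounds give 100 runs, reported
as mean ± sd of the test C-index. Gene-level interpretation uses a
kernel-weighted sampling Shapley estimator of each gene's contribution to
the PI. A synthetic cohort simulator (Weibull proportional-hazards times,
calibrated independent censoring, planted linear or interaction signals)
makes every component testable without external data.

The neural network and its training run on a small reverse-mode autodiff
core over numpy (`zzformer.autodiff`), verified against finite differences;
no deep-learning framework is required.

## Worked example

```python
import numpy as np
from zzformer import (SimulationConfig, simulate_cohort, oracle_cindex,
                      make_fold_plan, run_cv, ZZFormerSpec)

cohort, truth = simulate_cohort(SimulationConfig(
    n_samples=400, n_genes=512, signal_genes=20, beta_magnitude=1.0,
    censor_target=0.649, seed=1))
print(f"censoring {truth.realized_censoring:.3f}  "
      f"oracle C {oracle_cindex(cohort, truth):.3f}")

plan = make_fold_plan(cohort.n_samples, n_folds=5, n_rounds=1, base_seed=0)
result = run_cv(cohort, ZZFormerSpec(), plan)
print(result.aggregate().to_string(index=False))
```

```
censoring 0.647  oracle C 0.947
   model     mean      sd  n_runs
ZZFormer 0.698905 0.03082       5
```

The cohort mirrors the reference study's geometry (400 samples, ~65%
censoring, a ~500-gene panel with a sparse prognostic subset). `oracle C`
is the concordance of the true generative risk — the ceiling any fitted
model can approach; the fitted transformer reaches ≈0.70 on held-out folds,
well above chance (0.5) and below the oracle, as expected when 240 training
samples face 512 features. One-round means fluctuate by roughly ±0.03
across fold seeds.

The same pipeline is scriptable:

```bash
zzformer simulate --n 400 --p 512 --signal 20 --seed 1 --out sim/
zzformer cv --expression sim/expression.tsv --clinical sim/clinical.tsv \
            --model zzformer --rounds 2 --out cv/
zzformer train --expression sim/expression.tsv --clinical sim/clinical.tsv \
               --out run/
zzformer explain --checkpoint run/checkpoint.npz --expression sim/expression.tsv \
                 --clinical sim/clinical.tsv --summarize-background --out shap/
```

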