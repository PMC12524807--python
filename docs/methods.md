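# Methods

## Model

The model maps a gene-expression vector x ∈ ℝ^G (G = number of signature
genes retained in a cohort) to a scalar Prognosis Index (PI). The pipeline
is:

1. **Feature embedding.** x is layer-normalized across genes, then a single
   dense map ℝ^G → ℝ^{T·D} produces T = ⌊G / D⌋ tokens of width D
   (`token_dim`, default 64). One dense map — rather than per-chunk
   projections — lets every token draw on every gene, and consumes all G
   features even when G is not a multiple of D; the floor formula fixes
   only the token count.
2. **CLS token.** A learnable D-vector is prepended (initialized
   0.02·N(0,1)). No positional encodings are used: tokens carry no order
   semantics, and the CLS token is distinguished by its learned content.
3. **Encoder.** `num_blocks` (default 2) pre-norm transformer blocks:
   multi-head self-attention (default 8 heads, per-head dimension
   d_k = D/8, attention = softmax(QKᵀ/√d_k)V with learned Q/K/V/output
   projections) and a position-wise feed-forward sub-layer (hidden width
   4·D, GELU), each wrapped in a residual connection with dropout (default
   0.1). Pre-norm placement was chosen for training stability; post-norm is
   available via `ModelConfig(pre_norm=False)`. The feed-forward width and
   activation are conventional transformer defaults — the architecture
   source fixes only the token/head/block counts.
4. **Head.** The CLS position is layer-normalized and mapped linearly to
   the PI. Higher PI = higher predicted hazard = worse prognosis. Only the
   CLS token feeds the head; mean-pooling over tokens is deliberately not
   offered.

All tensors are float64 and gradients come from a small reverse-mode
autodiff core (`zzformer.autodiff`) written for exactly the operations the
model needs; every primitive's gradient is tested against central finite
differences, and the analytic Cox-loss gradient doubles as an independent
check of the full backward pass.

## Loss and training

The Cox negative log partial likelihood is computed with risk sets
inclusive of tied times (Breslow's convention; the simulator emits
continuous times, so ties only arise from external data and are handled,
not corrected à la Efron). The implementation subtracts the max risk
before exponentiating (exact, by shift invariance of the partial
likelihood) and exposes both the sum form (`cox_nll`) and a per-event mean
used inside the optimizer for learning-rate stability.

Optimization is full-cohort Adam (lr default 0.002) with L2 weight decay
added to the gradient. Decay applies only to weight matrices — not to
LayerNorm gains/biases or the CLS vector — following standard practice;
decaying norm gains measurably hurt held-out concordance. Because the risk
sets couple all samples, full-batch training is the default and correct
choice; with ~100–200 optimizer steps per fit, decoupled (AdamW-style)
decay would be far too weak at these step counts, which is why the
L2-in-Adam form is used.

Early stopping monitors the validation C-index (falling back to validation
loss when the validation fold cannot rank) with patience 20 over at most
200 epochs, restoring the best-validation weights. Two guards matter in
practice:

- epochs are eligible for selection only once the training loss has
  dropped ≥ 2% below its first-epoch value (`warmup_loss_drop`). Without
  this, a chance validation spike at a barely-trained epoch can freeze the
  model near its initialization — observed repeatedly on weak-signal
  cohorts, where it cost ~0.1 C-index;
- a non-finite loss aborts with the epoch number rather than propagating
  NaNs.

The linear-Cox baseline is the degenerate single-linear-layer case
(PI = βᵀx) trained with the identical loss and loop (lr default 0.01); its
coefficients agree with an established Cox implementation on fixtures, and
it doubles as the closed-form oracle for the Shapley estimator.

## Evaluation protocol

`concordance_index` implements the ordered-pair definition: pairs (i, j)
with T_i > T_j and subject j's death observed are comparable; a pair is
concordant when η_i < η_j. The default `strict` tie policy gives tied
predictions no credit (the literal indicator); `half` gives 0.5 (Harrell).
Pairs with tied survival times are not comparable. A brute-force O(n²)
double loop serves as the testing oracle, and the half-credit policy is
cross-checked against scikit-survival.

The cross-validation harness partitions samples into five near-equal folds
per round (round r reuses `base_seed + r`), assigns fold f as test, fold
(f+1) mod 5 as validation (the protocol source says only that "another"
fold validates; the cyclic choice makes the assignment deterministic), and
the rest as training; 20 rounds × 5 folds = 100 runs. Standardization
(per-gene z-score, constant genes mapped to 0) is fit on training rows
only, per run. Models flagged `needs_validation=False` train on all four
non-test folds. Runs that fail (e.g. an eventless training fold) are
recorded with a reason and excluded from aggregates rather than silently
dropped. Grid search uses one dedicated round on a seed disjoint from the
evaluation rounds and scores each configuration by the fold-mean of
(train C + validation C) — the literal reading of the selection rule; a
validation-only score is available (`score="val"`), and on synthetic
fixtures the literal rule tends to favor under-regularized configurations
because training C saturates.

The harness adapters default to the determined architecture (token 64 / 8
heads / 2 blocks / dropout 0.1 / lr 0.002) with weight decay 0.3, the
strongest value in the study's L2 grid — appropriate for the p ≫ n regime
these panels live in.

## Synthetic cohorts

The simulator draws expression i.i.d. N(0,1) per gene (matching the
post-standardization scale the model consumes; a log-normal marginal is
available), plants `signal_genes` coefficients of magnitude
`beta_magnitude` with alternating sign, and generates event times by
inverse transform under a Weibull baseline (shape 1.5, scale 1000 days —
shape > 1 reflects the rising hazard typical of cancer cohorts; the scale
only sets units). The `interaction` risk form adds
`beta_magnitude · x₁·x₂`, a term outside any linear model's span.
Censoring is exponential, independent of covariates, with its rate found
by geometric bisection against one fixed uniform draw per subject, so the
realized censored fraction is monotone in the rate and lands within ~1e-4
of the target (default 0.649, the censoring proportion of the 370-sample
reference cohort). Duplicate observed times are perturbed by 1e-9 to keep
risk sets unambiguous.

What the simulator does **not** emulate: gene–gene correlation, count-like
or batch-affected marginals, informative censoring, or covariate-dependent
baseline hazards. Passing recovery tests therefore demonstrates that the
estimation machinery works under the proportional-hazards assumptions it
targets — not that real-cohort performance will match.

Reference conditions used by the recovery tests and the acceptance script,
chosen to mirror the reference study's geometry and fixed once:

- **linear fixture**: n = 400, p = 512, 20 signal genes, |β| = 1,
  censoring target 0.649 (the simulator defaults). The generative-risk
  oracle C-index is ≈ 0.95; the fitted transformer reaches ≈ 0.70 on
  held-out folds (one-round means vary by about ±0.03 across fold seeds —
  240 training samples against 512 features is deliberately austere), and
  a 20-seed label-permutation control sits at 0.5.
- **interaction fixture**: n = 600, p = 64, 2 signal genes, β magnitude
  1.5 (risk = x₁ − x₂ + 1.5·x₁·x₂). Sized so the interaction is genuinely
  learnable: at the linear fixture's geometry both models score ≈ 0.55 and
  the comparison is uninformative. The transformer-minus-linear paired
  difference over five rounds varies with the cohort realization (roughly
  −0.01 to +0.06 across simulation seeds): with only two signal genes the
  realized strength of the planted product term is itself a random
  quantity, so the nonlinearity advantage should be read as a distribution
  over cohorts, not a constant.

## Attribution

Gene attributions are sampling Shapley values: coalitions are drawn from
the Shapley kernel size distribution in antithetic (mask/complement)
pairs, a coalition's value is the model's mean PI with member genes set to
the explained sample and the rest filled from background rows, and a
least-squares solve with one eliminated coefficient enforces local
accuracy (baseline + Σφ = PI) exactly. The same sampled masks serve every
explained sample, so the design matrix is factored once. For a linear
model the estimates converge to β_j·(x_j − mean_bg(x_j)), the module's
strongest oracle; exact enumeration is provided for G ≤ 12. Global
importance ranks genes by mean |φ| over explained samples (signed means
are also exported). The background defaults to a seed-controlled training
subsample; collapsing it to its mean row (`--summarize-background`) trades
fidelity for a large speedup on the transformer and is what the top-k
recovery checks use. With G ≈ 500, 8192 coalitions and ~10 explained
samples give stable top-10 rankings; attribution is performed on a single
specified checkpoint (not an aggregate over folds).

## Numerical and design notes

- Constant genes standardize to 0 (scale forced to 1) instead of being
  dropped, keeping the feature space aligned with the signature.
- Gene symbols match by exact string after trimming and uppercasing; no
  alias resolution. Duplicate expression columns keep the first occurrence
  with a warning.
- Missing expression values are rejected at load; no imputation rule is
  offered.
- Input normalization (z-scoring before the model's own LayerNorm) is on
  by default and fit on training folds only; the embedding LayerNorm alone
  does not remove per-gene location/scale differences.
- `num_blocks=0` is a supported testing hook: the PI becomes a linear map
  of the CLS embedding, constant across samples — a wiring check.
- Checkpoints bundle weights, architecture config, the fitted
  standardizer and the gene list in one `.npz`, so `predict`/`explain`
  are self-contained.
- Seeds: every stochastic step (simulation, fold planning, initialization,
  dropout, coalition sampling) is driven by an explicit integer seed;
  CLI manifests record the resolved configuration and input checksums.

## Known limitations

- No baseline-hazard estimation: the model outputs relative risk only,
  so absolute survival curves are out of scope.
- Efron tie correction is not implemented (inclusive risk sets only).
- The transformer needs G ≥ token_dim (at least one token); panels smaller
  than 64 genes require lowering `token_dim`.
- At reference-fixture scale the transformer does not beat a well-tuned
  ridge-penalized linear Cox model on purely linear signal — consistent
  with its design goal of capturing interactions rather than dominating
  the linear regime.
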