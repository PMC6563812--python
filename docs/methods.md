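# Methods

This note records the model, the optimization scheme, and every numerical
choice the implementation makes, so results can be reproduced and audited
without reading the source.

## Model

A sparse N-way count tensor `X` (N ≥ 3) is modeled as entrywise Poisson
with rate given by a rank-R Kruskal (CP) model:

```
m[i1,...,iN] = sum_r  lambda_r * A(0)[i1,r] * ... * A(N-1)[iN,r]
```

with `lambda >= 0` and all factor matrices nonnegative. The data-fit term
is the Poisson negative log-likelihood with constants dropped
(equivalently, generalized KL divergence up to additive constants):

```
f(M) = sum_cells m  -  sum_{x>0} x * log(max(m, eps))
```

with `eps = 1e-10` flooring the logarithm (`EPS_FLOOR` in
`countcp.tensor`). The first sum is computed in closed form from factor
column sums, never by materializing the dense tensor; the second touches
only the stored nonzeros. Note `f` can be negative — it omits the
`log(x!)` constants — so convergence margins in tests are expressed
relative to `|f|`, not `f`.

### Normalization convention

One mode (the *designated* mode, index 0 by default) absorbs the
component weights: after fitting, every other mode's columns are
l1-normalized, and the weight vector `lambda` carries the scale pulled
out of the designated mode. Columns that are identically zero normalize
to zero with their weight zeroed and a `RuntimeWarning`.

## Objective

The full objective adds to `f`:

- **Angular diversity** `beta1 * sum_modes sum_{p<r} max(0, cos(a_p, a_r) - theta_n)^2`
  — a squared hinge on pairwise column cosines. The square makes the
  penalty continuously differentiable at the hinge, so its gradient is
  exact everywhere (verified against central finite differences).
- **Ridge** `(beta2 / 2) * sum ||A||_F^2`.
- **Logistic supervision** `beta3 * sum_labeled log(1 + exp(-y * (a_i . theta_w + theta_b)))`
  over labeled first-mode entities `i` with labels `y in {-1, +1}`
  (supplied externally as {0, 1}; −1 marks unlabeled), where `a_i` is the
  entity's factor row and `theta = [theta_w; theta_b]` are logistic
  coefficients refit between epochs (see below).
- **Simplex constraint** — not a penalty term: columns of the modes
  listed in `simplex_modes` are projected onto the l1-ball of radius
  `simplex_radius` (nonnegative, sum ≤ radius) after gradient steps.
- **Hard threshold** — optional projection keeping the `hard_threshold_k`
  largest entries per column; ties broken by lowest row index first.

Defaults: `beta1 = 0.02`, `beta2 = 0`, `beta3 = 0.06`, `theta_n = 0.9`,
no simplex modes, no hard threshold.

Because the Poisson term scales with the total observed count while the
penalties are O(1), penalty weights are effectively relative to the
count scale of the data; applications with large totals need
correspondingly larger `beta1`/`beta3` for the penalties to matter.

## Block partition and stratum schedule

For `d` workers, each mode `n` of length `I_n` is cut at boundaries
`floor(i * I_n / d)`, giving `d^N` axis-aligned blocks. Blocks are
grouped into `d^(N-1)` *strata* of `d` blocks each by the diagonal rule:
stratum `(s_1, ..., s_{N-1})` assigns worker `i` the block whose mode-0
range index is `i` and whose mode-k range index is `(i + s_k) mod d`. Two
blocks in the same stratum therefore share no range in any mode, so they
read and write disjoint factor rows. For a 3-way tensor with `d = 2`:
8 blocks, 4 strata. `scripts/acceptance.py` re-verifies the coverage and
disjointness properties by enumeration.

## Optimization

Each epoch visits every stratum (in index order by default;
`shuffle_strata` randomizes it); within a stratum, every block is
processed from the same model snapshot, and the resulting factor-row
slices are written back afterwards. Because reads are from the snapshot
and writes are disjoint, the result is **bit-identical** whether blocks
run serially or on a process pool — the test suite asserts exact array
equality between the two executors. If a user-supplied executor raises,
the engine falls back to serial execution for that stratum.

Per block, `inner_iters` SGD iterations cycle over the modes. The
mode-`n` gradient of the Poisson term splits into

- an exact linear part — the product over other modes of their block
  column sums, identical for every row of the block — and
- a ratio part `x/m` scattered over the block's nonzeros, estimated from
  a uniform minibatch of `batch_size` stored entries and scaled by
  `nnz_block / batch_size` (full-batch, hence exact, when the block has
  at most `batch_size` nonzeros). The estimator is unbiased, and at full
  batch the total gradient matches dense finite differences to 1e-5
  relative.

Steps use **Adam** (beta1 = 0.9, beta2 = 0.999, eps = 1e-8, bias
correction on) followed by clipping at zero to maintain nonnegativity,
then the simplex / hard-threshold projections where configured.

Two choices deal with the scale asymmetry created by absorbing `lambda`
into the designated mode (its entries are orders of magnitude larger
than the l1-normalized modes at realistic count scales):

- **Mass-matched initialization**: factors start uniform(0, 1),
  non-designated columns are l1-normalized, and the designated mode is
  rescaled once so the model's total mass equals the observed total
  count. Without this, a fixed step size cannot close the initial scale
  gap in any reasonable epoch budget.
- **Per-mode step scaling** (`step_scaling="mode_mean"`, the default):
  the step size used for mode `n` during an epoch is
  `learning_rate * mean(|A(n)|)` computed at epoch start, so
  `learning_rate` reads as a *relative* per-iteration step. Set
  `step_scaling="none"` for absolute steps.

At each epoch end, non-designated (and non-simplex) modes are
l1-renormalized with the scale absorbed into the designated mode, simplex
modes are re-projected on whole columns (block-local projections alone
would only bound each chunk), the objective is recorded, and — when
labels are present — `theta` is refit by ridge-regularized
iteratively-reweighted least squares (damped Newton) on the current
first-mode rows, with ridge 1e-4 on the weights (intercept unpenalized).
Fitting stops after `max_epochs` epochs or when the relative objective
change drops below `tol`.

Randomness is controlled end-to-end: every block draw uses a generator
seeded by `[seed, epoch, stratum_index, block_id]`, so results are
reproducible and independent of worker scheduling.

Defaults: `learning_rate = 1e-4` (relative, under mode-mean scaling),
`batch_size = 200`, `inner_iters = 10`, `max_epochs = 100`,
`n_workers = 1`, `tol = 1e-4`, `seed = 0`. On planted problems of the
sizes below, `learning_rate = 0.01` with 100–150 epochs converges well;
the conservative default suits large real tensors.

## Supervision and evaluation

- `fit_theta`: ridge logistic regression by damped Newton; matches
  scikit-learn's `LogisticRegression(C = 1/ridge)` to 1e-4.
- `auc`: rank-statistic AUC (Mann–Whitney form) with the standard ½
  credit for score ties; validated against explicit pairwise counting.
- `average_overlap`: mean pairwise column cosine over selected modes
  (modes 1 and 2 by default); in [0, 1] for nonnegative
  factors.
- `factor_match_score`: mean over components of the product across modes
  of column cosines, maximized over component matchings
  (Hungarian assignment); invariant to permutation and per-column
  rescaling, 1.0 at exact recovery.
- `fold_in_rows`: folds new first-mode entities into a fitted model by
  multiplicative KL updates of their factor rows with all other modes
  frozen (50 iterations by default); entities with no observed entries
  get zero rows.
- `holdout_auc`: stratified 80/20 split of labeled entities, refit on the
  training tensor, fold-in of test entities, AUC of their logistic
  scores.

## Synthetic generator

`SyntheticSpec` plants a ground-truth model: nonnegative factor columns
(optionally with an exact per-column sparsity fraction), pairwise column
cosines capped at `overlap` (columns are redrawn as blends of a disjoint
and a dense part, up to 80 attempts, stepping the blend by ×0.8), and
weights scaled so the model's expected total count equals `scale`.
`sample_tensor` draws from the model *exactly* and sparsely: it samples a
Poisson count per rank-one component and places each event by independent
per-mode categorical draws — the superposition is exactly entrywise
Poisson with the model's rates, and the dense tensor is never formed.
`generate_labels` draws entity labels Bernoulli(sigmoid(theta . [a; 1])).
Defaults: shape 30×30×30, rank 3, sparsity 0.3, scale 5e4, overlap 0.5.
A seasonal 12×52×11 fixture (`flu_fixture`) exercises shapes with
unequal, non-divisible mode lengths.

Scope: the generator covers 3-way problems from desk scale (~10^3 cells)
to ~10^5 total counts; sampling guards against requests above 10^8
expected events. Planted recovery at the default spec reaches factor
match scores ≈ 0.99 (mean ≥ 0.9 over seeds is asserted in the acceptance
suite).

## Numerical constants (summary)

| Constant | Value | Where |
| --- | --- | --- |
| log floor `EPS_FLOOR` | 1e-10 | `tensor.poisson_loss`, gradients |
| Adam (b1, b2, eps) | 0.9, 0.999, 1e-8 | `optimize.adam_step` |
| theta refit ridge | 1e-4 | `engine.THETA_RIDGE` |
| hard-threshold ties | lowest row index wins | `regularizers.hard_threshold` |
| block RNG seed | `[seed, epoch, stratum, block]` | `engine` |
| fold-in iterations | 50 | `evaluate.fold_in_rows` |
| overlap redraw | ×0.8 blend step, ≤ 80 tries | `synthetic.generate_model` |
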