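# Methods

`fitbench` is an assessment framework for supervised protein fitness
regression: it asks not only *how accurate* a regressor is, but *under which
notion of generalization* that accuracy was measured, and whether the
regressor's predictive uncertainties can be trusted. Because real deep
mutational scanning (DMS) campaigns and language-model embeddings are large
external artifacts, the framework ships a synthetic landscape generator that
reproduces the statistical structure those analyses rely on, so every
pipeline property is testable end to end on a laptop.

## The data model

A variant is a set of point substitutions of a wildtype sequence
(ProteinGym-style strings, `"A23G:T45K"`). An assay dataset attaches a
real-valued fitness label to each variant and, for iterative campaigns, the
acquisition round in which it was measured.

## Synthetic fitness landscapes

The ground-truth fitness of a variant is

    f(v) = link( Σ_s a(pos_s, aa_s)  +  Σ_{s<t} ε((pos_s, aa_s), (pos_t, aa_t)) )

* **Additive effects** `a(pos, aa)` are drawn per (site, residue) as
  `site(pos) + N(μ_eff, σ_eff²)`, where `site(pos) ~ N(0, σ_site²)` is shared
  by all residues at a site. The site component emulates position-level
  conservation — the property of real DMS data that makes effects at a site
  learnable from other mutations at the same site. Defaults: `μ_eff = −0.5`
  (most mutations deleterious), `σ_eff = 0.5`, `σ_site = 0` (i.i.d. effects
  unless site structure is requested).
* **Epistasis** is a set of residue-specific pairwise terms
  `ε ~ N(0, σ_epi²)` placed uniformly at random over site pairs. A term fires
  only when both exact (site, residue) pairs are present, so ruggedness is
  controlled jointly by `σ_epi` and the *number* of terms: with few terms a
  multi-mutant essentially never activates one and the landscape is
  effectively additive. Dense-epistasis settings (tens of thousands of terms)
  give an expected O(1) active terms per multi-mutant.
* **Link**: identity, or a sigmoid `1/(1+exp(−k(x−t)))` whose threshold and
  steepness produce the bimodal functional/non-functional label picture of
  single-mutant scans and the collapse of the functional fraction with
  mutation degree (verified for degrees 1–4 by Monte-Carlo).
* **Assay noise** is homoscedastic Gaussian (sd `assay_noise_sd`). Real
  assays are often heteroscedastic; that extension is out of scope and noted
  as a limitation. No published quantitative noise level was available for
  the systems that motivated the defaults, so the noise scale is a free
  parameter.

Variant samplers draw degree-d variants uniformly without replacement
(index unranking for enumerable spaces, rejection sampling for astronomically
large ones); all generators are bit-reproducible given (parameters, seed).

### Campaign simulation

`simulate_campaign` emulates iterative engineering: round 0 assays random
single mutants; in later rounds each batch slot either (with probability
`greedy_fraction`) adds one random substitution to a parent drawn from the
current top 10% of observed labels (swapping a residue at an already-mutated
site once the parent is at `max_degree`), or assays a random variant at the
current frontier degree. Nothing is re-measured.

The standard **biased-campaign study** uses L = 40, zero-mean additive
effects (so greedy selection can genuinely ratchet fitness upward — the
defining feature of the scenario), 30 000 epistatic terms of scale 1.0
(rugged enough that forward prediction is hard), noise sd 0.1, and a
10-round × 20-variant campaign with `greedy_fraction = 0.9` and
`max_degree = 12`. The **unbiased control** uses the same campaign shape with
`greedy_fraction = 0` on a purely additive zero-mean landscape, where round
and label are unconfounded by construction.

### Surrogate embeddings

`surrogate_embedding` maps variants through a fixed seeded random projection
of their one-hot encoding (optionally through `tanh`). It is *not* a trained
model and is labelled accordingly: it preserves exactly the properties the
pipeline needs from a mean-pooled language-model representation — a
deterministic sequence→vector map of controllable dimension and
(non)linearity — and none of the biology.

## Encodings and label handling

One-hot encoding flattens L × 22 indicators (20 amino acids + gap +
unknown, in a frozen alphabetical order) so that Hamming distance between
rows is twice the number of differing sites. `mean_pool` averages a
per-position embedding matrix over positions. Labels are standardized as
ȳ = (y − μ_y)/std(y) using the **training fold only** (population sd);
standardization on pooled data would leak test information and would break
the zero-mean GP prior assumption. Constant training labels raise an error.

## Regressors

All regressors return a per-point predictive mean and variance.

* **kNN**: mean of the k nearest labels (Euclidean distance, distance ties
  broken by lowest training index); variance = empirical variance of those k
  labels, floored at 1e-12. The neighbour-label variance is a pragmatic
  definition; it is typically very small, and the calibration metrics will
  duly report such a model as overconfident — that behaviour is part of what
  the framework is meant to expose, so no variance inflation is applied.
  Unoptimized default k = ⌈N/3⌉.
* **Random forest**: scikit-learn forest with the across-tree variance
  σ̂² = mean(ŷ_tree²) − mean(ŷ_tree)².
* **Exact GP** with linear, squared-exponential, or Matérn-5/2 kernels,
  zero-mean prior on standardized labels and Gaussian observation noise.
  Hyperparameters θ = {σ², l, σ_ε²} maximize the log marginal likelihood
  plus the log prior density (MAP) with σ², l ~ InvGamma(3, 3) and σ_ε²
  uniform on [0.01, 1.0] (enforced as an L-BFGS-B box in log space; the
  uniform contributes no gradient). Optimization uses analytic gradients,
  a 500-iteration cap, and multi-start (the user initialization plus
  restarts drawn from the priors; every start's initial value is itself a
  candidate, so the final objective never falls below the initialization).
  Cholesky failures escalate through a jitter ladder 1e-8 → 1e-4 before
  raising. The linear kernel uses a single shared σ² in the MAP fit; a
  per-dimension (ARD) form is available at the kernel level but is not
  optimized, since fitting d parameters with n ≪ d is ill-posed.

  The reported predictive variance is that of the *predictive* distribution,
  i.e. it includes σ_ε², because the calibration metrics compare residuals of
  noisy observations against σ̂. Predictions are de-standardized back to the
  original label scale.

* **Hyperparameter tuning** for kNN (k ∈ [1, ⌊0.95N/3⌋], budget 75) and the
  forest (n_estimators ∈ [2, N], budget 15) minimizes mean absolute error
  under an internal 3-fold CV, exhaustively when the integer range fits the
  budget and otherwise by Expected Improvement over the grid with a
  random-forest surrogate. With fewer than 6 training points tuning falls
  back to the defaults with a warning.

## Split protocols

* **Random CV** (k = 10 default): test sets partition the index set;
  appropriate for imputation of values missing at random.
* **Positional CV** (p = 15 default): ⌈L/p⌉ contiguous 1-based position
  blocks (the last possibly shorter); a variant with *any* mutated position
  in the block is tested, all others train, and the wildtype always trains.
  No training variant of a fold has a mutation in the held-out block.
* **Mutational CV**: train on degrees < k, test on degree k; optionally
  (include-equal mode) 5 folds that also train on 80% of the degree-k
  variants and test each of them exactly once.
* **Fractional CV**: per (fraction q, repetition), a fixed held-out
  evaluation set of ⌈0.2 n⌉ points and a training set of ⌈q · (n − n_test)⌉
  points from the remainder. The evaluation set is held at fixed size so test
  difficulty is constant along the learning curve; a complement mode (test on
  the whole non-training remainder) is available.
* **Chronological**: train on acquisition rounds < cut, test on the rest.

All plans are reproducible from (inputs, seed), disjoint within every fold,
and exportable as (fold, role, index) tables.

## Metrics

Accuracy: adjusted R² = 1 − Σ(yᵢ−ŷᵢ)²/Σ(yᵢ−μ_train)² with the **training**
mean as baseline (0 for the mean predictor, may be negative), MSE, and
Spearman ρ with average ranks for ties (constant vectors raise rather than
returning a silent NaN).

Uncertainty quality:

* **Reduced χ²** = (1/(N−1)) Σ((yᵢ−ŷᵢ)/σ̂ᵢ)²; ≈1 when calibrated, >1
  overconfident, <1 underconfident.
* **Calibration curve**: empirical coverage of probability-integral-transform
  residuals Φ((yᵢ−ŷᵢ)/σ̂ᵢ) at levels j/q (q = 10), the standard regression
  calibration construction; **ECE** is the mean absolute deviation of
  coverage from level.
* **Sharpness**: coefficient of variation of the predictive variances
  (sample sd over mean) — dimensionless and scale-invariant.
* **Confidence curve**: mean squared error over the retained sets
  {σ̂ᵢ ≤ h_j} with h_j the j/q-quantiles of σ̂ (squared-error loss; a literal
  mode divides by total N instead of the retained count for
  formula-compatibility). Non-decreasing curves indicate that the
  uncertainty ranks errors correctly.

## Baselines

Training-mean predictor (R² = 0 by construction); the **additive baseline**,
which predicts a multi-mutant as the sum of the observed labels of its
constituent single mutants (duplicates averaged into the lookup table,
variants with unobserved constituents reported as missing and excluded with a
logged count; for triples an alternative mode averages observed
double+single decompositions); and a **ranking oracle** that orders
candidates by any external score with stable ties, used as a selection
baseline.

On an additive noiseless landscape the additive baseline is exact on all
multi-mutants whose constituents were observed (ρ = 1, MSE = 0); its ranking
quality degrades as epistasis grows. On sigmoid-linked (bimodal) data it
remains a good *ranker* while its raw sums are far off in MSE — the
metric-disagreement phenomenon the extrapolation case report flags.

## Optimization as assessment

`bo_loop` runs Expected Improvement (maximization, no exploration jitter,
ξ = 0) over a fully labelled candidate pool: n_init = 5 random reveals, then
refit the surrogate (with its full hyperparameter protocol) every iteration,
score all unobserved candidates, reveal the EI argmax (ties → lowest index).
The budget counts total reveals; a `refit_every` throttle exists for
desk-scale experimentation but defaults to every iteration. Comparators:
uniformly random selection and score-ranked selection. Traces record the
reveal order, the running best, and the iteration at which the pool optimum
appeared; summaries aggregate best-so-far over quarters of the iteration
axis (boundaries ⌈budget·j/4⌉) with mean and standard error across seeds.

## Case reports

* **Selection bias**: Random-CV Spearman vs chronological Spearman on a
  campaign dataset, plus the round–label confound correlation. Under the
  biased-campaign study conditions the Random-CV estimate is dominated by
  the acquisition confound and collapses under the chronological split.
* **Extrapolation**: a (train regime × test degree) grid of MSE and Spearman
  with the additive baseline overlaid. Cells whose test-label spread falls
  below 10% of the degree-1 spread are flagged as variance-collapsed — error
  metrics there reflect a shrinking label scale, not model quality — and the
  report flags degrees where the MSE ordering and the ρ ordering of the two
  training regimes disagree.
* **Uncertainty growth**: mean predictive variance per mutation degree per
  regressor, fit on single-mutant data. Only mechanical properties are
  asserted: the linear kernel's prior variance grows with the input norm
  (one-hot multi-mutants... larger norm offsets from the training cloud), and
  stationary kernels revert to σ² + σ_ε² far from data. kNN/RF profiles are
  reported without assertion.

## Problem sizes and numerical choices

Benchmarks in the test-suite and the acceptance script use L = 11–40
landscapes, hundreds of variants per dataset, 10 campaign seeds, and a BO
budget of 100 on a 200-candidate pool — sizes chosen so the whole assessment
battery runs on a single CPU in minutes while leaving every phenomenon
measurable. Variance floors (1e-12), the σ_ε² box [0.01, 1.0], the Cholesky
jitter ladder, and stable tie-breaking (lowest index) are the only numerical
guards; degenerate inputs (constant labels, empty folds) raise or are
recorded as missing cells rather than propagating NaNs.

## What passing tests do and do not show

The generator reproduces the *structural* pathologies of variant-effect
data: bimodal labels, degree-dependent label collapse, position-level
learnability, lineage-driven acquisition bias, and controllable ruggedness.
It has no biophysical realism (no stability/ΔΔG model, no MSA statistics, no
trained embeddings), a single homoscedastic noise model, and residue-exact
epistasis only. Passing the battery therefore certifies the pipeline's
statistical machinery and its failure-mode detectors — not that any
particular regressor will perform comparably on a specific real protein
system.
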