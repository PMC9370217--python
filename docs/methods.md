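# Methods

`mixqspr` implements a complete QSPR (quantitative structure–property
relationship) workflow for **binary mixtures**, built around the use case of
predicting the surface tension of deep eutectic solvents (DESs). A binary DES
is a hydrogen-bond acceptor (HBA, usually a quaternary ammonium salt) and a
hydrogen-bond donor (HBD) mixed at a fixed molar ratio; its surface tension
σ (mN/m) depends on the two components, their ratio, and the temperature.

## Mixture descriptors

Per-component 0D–2D descriptors D₁, D₂ (precomputed externally, e.g.
Dragon-style; the package consumes a CSV table, it does not compute them) are
combined with the molar fractions x₁, x₂ into weighted-mixture (WM)
descriptors:

    D_pmix = x₁·D₁ + x₂·D₂
    D_nmix = |x₁·D₁ − x₂·D₂|

Method-1 uses only the `*_pmix` columns; Method-2 adds the `*_nmix` columns.
Temperature (K) and two halide indicator flags (Cl⁻ / Br⁻ present in the HBA
salt; only the cation carries descriptors) always join the candidate pool.
Near-constant columns (variance < 0.001) and the later member of any column
pair with |r| > 0.95 are pruned; the filter is fitted on the training rows
only and the surviving column list is applied to every other set, so no
information leaks from test data into the pruning decision. Both cutoffs are
strict inequalities, and the *earlier* column of a correlated pair survives —
the pair rule is order-dependent, so the convention is fixed and documented
rather than left to chance.

## Mixture-aware data splitting

Random train/test division leaks mixture identity (the same DES at two
temperatures lands on both sides). Two schemes avoid this:

* **Mixtures-out (MO)** — unique mixtures (component pair + reduced molar
  ratio) are sorted by occurrence count, descending, ties broken by ascending
  key string; the mixtures at 1-based positions `seed, seed+interval, …` go
  entirely to the test set.
* **Compounds-out (CO)** — the same seed/interval selection runs
  independently on the occurrence-sorted HBA list and HBD list; every record
  containing a selected chemical (in its role) goes to the test set, so the
  selected chemicals never appear in training.

Molar ratios are canonicalized by continued-fraction reduction (denominators
capped at 100, tolerance 1e−6; values that are not near any such fraction
fall back to x₁ rounded to 4 decimals). Enumeration over seed, interval ≤ 6
retains splits with |train| > |test| and |test| ≥ 0.15·|train|, collapsing
duplicate partitions onto the smallest (seed, interval). Everything is
deterministic: the same dataset and parameters give the same partition on
every run and platform.

## Forward selection with the %MAE_LOO gate

Models are ordinary least squares on a greedily grown feature set. At each
step every remaining candidate is scored by one of: training R², negative
mean absolute error, negative mean Poisson deviance (responses must be
positive; predictions are clipped at 1e−6 as a numerical safety net), or mean
R² over 5- or 10-fold cross-validation (fold assignment fixed by a stated
seed). The best candidate (score ties → lowest column index) is accepted only
if it cuts the leave-one-out mean absolute error of the incumbent model by at
least 5%; the first rejection stops selection. The gate compares against the
*immediately previous* model, not the best-so-far. MAE_LOO uses the exact OLS
identity e_i/(1−h_i), which equals a literal N-refit loop to machine
precision (asserted in the tests against that literal loop).

ρ = N/p (training points per adjustable variable) is reported as an
overfitting guard. Rank-deficient designs raise an error naming the dependent
columns.

## Validation battery

* **Q²_LOO / MAE_LOO** — leave-one-out, via the hat-matrix identity;
  Q² = 1 − PRESS/TSS.
* **Q²_LCO / MAE_LCO** — leave-chemical-out: for each unique chemical (HBA or
  HBD), all records containing it are removed, the *coefficients* are refit
  on the remainder with the feature subset frozen, and the held-out records
  predicted; predictions pool over all chemicals (a record is held out once
  per chemical it contains) and Q²_LCO uses the pooled observed mean.
  Freezing the subset makes the statistic a property of the model under
  evaluation; re-running selection per removal would measure the procedure
  instead and is intentionally not the default. A chemical whose removal
  leaves too few rows to refit is skipped and reported.
* **R²_Pred** = 1 − Σ(y_obs−y_pred)²/Σ(y_obs−ȳ_train)² on each external set;
  MAE, %AARD (100/N·Σ|Δ|/y_obs) and signed per-record %RD accompany it.
* **Scaled rm² metrics** — both vectors min–max scaled to [0,1]; r² is the
  squared Pearson correlation, r₀² and r₀′² come from through-origin
  regressions in the two directions; rm² = r²(1−√(r²−r₀²)), with the square
  root argument clamped at 0 against floating-point underflow; Δrm² is the
  absolute difference of the two variants.
* **Y-randomization** — the response is permuted n times (default 1000),
  the model refit each time; cR_P² = R·√(R² − mean R_r²), clamped at 0.
  Bit-reproducible given the RNG seed.
* **Leverage applicability domain** — h from the training (XᵀX)⁻¹ with
  intercept; warning value h* = 3(p+1)/N_tr; external rows are evaluated
  with the training (XᵀX)⁻¹. Standardized residuals divide by the sample
  standard deviation (ddof=1) of the plain training residuals —
  LOO-deleted residuals are not used. Flags: structural outlier h > h*,
  response outlier |standardized residual| > 3.

## Consensus prediction

Strategies CM0–CM3 over ≥ 2 fitted models: plain average (CM0), average over
qualified models (CM1), inverse-error weighted average (CM2) and per-record
best model (CM3). The concrete qualification and weighting rules are this
package's own choices: a model is qualified for a record when the record lies
inside that model's leverage domain (h ≤ h*), and a model's local error is
its mean absolute training error over the k = 10 nearest training records
(Euclidean distance in that model's z-scored feature space). Records with no
qualified model fall back to CM0 and are flagged. CM0–CM2 predictions always
lie within the envelope of the member predictions; CM3 returns exactly one
member's value.

## Campaign and ranking

The full workflow carves off an external validation set first (CO, seed 3,
interval 4), enumerates all admissible MO and CO splits of the remaining
modeling set, and builds one model per (split × descriptor method × scoring)
cell. Cells are ranked by the mean of Q²_LOO, Q²_LCO and R²_Pred(test), ties
by MAE_test ascending, and the top 15 distinct (partition, feature-set) pairs
are retained. The final choice among retained models averages four
statistics: Q²_LOO, Q²_LCO and R²_Pred against both the test and the external
set. Individual cell failures are recorded and do not abort the campaign.

## The shipped model

`mixqspr.frozen` bundles the published six-variable DES surface-tension
model (five WM descriptors + temperature; coefficients stored to exactly
their printed precision, standard errors as metadata only). ∂σ/∂T = −0.104
mN/m/K everywhere — surface tension decreases with temperature, as observed
experimentally. The descriptor *values* for new DESs must come from the same
external descriptor software used to build the model; the package documents
the six definitions but does not re-derive them.

## Synthetic data generator

The generator emulates the statistical structure of a DES property data
bank, not its chemistry: components with descriptor vectors drawn i.i.d.
N(0,1), mixtures as distinct (HBA, HBD, ratio) triples, each measured over a
temperature grid, and σ generated from a known linear model in WM space plus
Gaussian noise. Defaults: 25 HBA + 35 HBD components, 60 mixtures, ratios
1:1…1:4 and 2:1, temperatures 278.15–358.15 K in 20 K steps (300 records), 30
descriptors of which 5 are informative with coefficients of magnitude 2–6
(random sign), temperature coefficient −0.1 mN/m/K, intercept 70 mN/m, noise
SD 1 mN/m. 10% of descriptors are constant and 10% exact affine copies of
informative ones, so the variance and correlation filters are exercised on
every dataset.

The component library is deliberately wide relative to the number of
mixtures (mean component reuse ≈ 2, proportionally similar to a real data
bank where 113 mixtures draw on a broad component library). This matters for
identifiability: with a small library, every component-level column —
including the halide flags — inherits finite-library chance correlations of
~0.2–0.4 with the informative descriptors and becomes a genuine partial
proxy; forward selection then admits proxies on merit and exact support
recovery is ill-posed regardless of noise. With the wide library, chance
correlations shrink toward 1/√(n_mixtures) and recovery is clean. Passing
recovery tests on this generator therefore show that the selection machinery
is correct under near-orthogonal candidates; they do not show that forward
selection would isolate a unique "true" subset on strongly collinear real
descriptor sets, where several subsets can be statistically equivalent.

Under the default conditions, forward selection recovers the exact planted
feature set in ≈ 98% of 50 replicates (recomputed by `scripts/acceptance.py`)
and per-coefficient 2-standard-error coverage sits near its nominal ~95% —
which is why the test asserts coverage ≥ 90% rather than universal
containment: demanding every coefficient of every replicate inside 2 SE would
fail for a correctly calibrated estimator by construction.

## Problem sizes and determinism

All simulation-based tests and the acceptance script use the generator's
default scale (300 records) or smaller; the oracle-equivalence checks run on
50 random systems of 12–30 rows. Every stochastic step flows from an explicit
seed (`numpy.random.default_rng`), so reports, campaigns and generated
datasets are bit-reproducible.

## Known limitations

* Descriptor computation is out of scope; users must supply component
  descriptor tables from external software, matched by name to the shipped
  model's inputs if they want to use it.
* Ternary mixtures are not supported; SMILES are stored verbatim without
  structure standardization.
* The LCO statistic with per-removal re-selection (rather than frozen
  features) is not implemented.
* The consensus qualification/weighting rules are pragmatic stand-ins for
  the published consensus tool's internals; the strategy layer is pluggable.
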