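# Methods

## Setting

The package analyzes experiments in which cells are exposed to one of *m*
discrete stimulus levels x₁…x_m (doses, ligand concentrations) and each cell
reports a continuous response **y** ∈ ℝᵈ — a single readout or a vector of
successive time points.  The empirical channel is the collection
{(xᵢ, y_l^i) : l = 1…nᵢ}.  Three quantities are computed:

* **Mutual information** MI(X, Y) in bits under a stated input distribution
  P(X), the expected log₂ ratio of posterior to prior input probability;
* **Channel capacity** C* = max_{P(X)} MI(X, Y), with the capacity-achieving
  input distribution P*(X);
* **Pairwise probabilities of correct discrimination (PCD)**, the fraction of
  cells assignable to the correct one of two equiprobable stimuli by the
  Bayes rule, between 0.5 (indistinguishable) and 1 (disjoint responses).

The central design choice is to estimate the *conditional input distribution*
P(xᵢ | Y = y) — an m-class classification problem — rather than the possibly
high-dimensional conditional output densities P(y | X = xᵢ).  All three
quantities are then sample averages of functionals of the estimated
posterior; no density estimation or numerical integration over ℝᵈ is
involved, which is what makes the method practical for multivariate
time-series responses.

## Posterior model

The posterior is modeled by multinomial logistic regression with the last
level (in the deterministic level ordering: numeric ascending when all labels
parse as numbers, else lexicographic) as the baseline class:

    log P(xᵢ|Y=y) / P(x_m|Y=y) = αᵢ + βᵢᵀ y ,   i = 1…m−1.

Fitting is delegated to scikit-learn's lbfgs solver (gradient tolerance 1e-8,
at most 10⁴ iterations; failure to converge raises rather than returning a
silently bad fit).  Outputs are standardized per column internally for
conditioning; coefficients are mapped back so the linear form above holds in
the user's coordinates.  The softmax parameterization used by the optimizer
is converted to the baseline form.

**Prior handling.**  The optimizer sees the data as-is, so the raw fit is
calibrated at the empirical frequencies nᵢ/N.  Any other prior P(X) is imposed
by the closed-form intercept shift

    αᵢ ← αᵢ + log(P_old(x_m)/P_old(xᵢ)) − log(P_new(x_m)/P_new(xᵢ)),

with slopes untouched: changing the class prior in a generative view rescales
each class likelihood by a constant, which moves only the intercepts of the
log-ratios.  The same identity is what lets the capacity iteration below run
on a *single* regression fit.  A class-weighted from-scratch refit
(`fit_posterior_weighted`) is provided purely as a cross-check of this
shortcut; the two agree to well under 0.01 in posterior probability at
moderate effective counts (≳50 cells per level), and the agreement degrades
as a prior entry approaches zero because the weighted refit — not the
shortcut — then loses its effective sample for that class.

**Regularization.**  By default an L2 penalty of strength λ = 1e-4 is placed
on the slopes in the *total* log-likelihood objective (intercepts are never
penalized).  Because the penalty does not grow with N, its per-cell effect
decays as 1/N and the MI/capacity estimators remain consistent; a fixed
per-cell penalty was measured to leave a ≈0.04-bit bias on the benchmark
channel that does not shrink with sample size.  The small positive default
keeps slopes finite when classes are linearly separable — the common case for
well-discriminating channels — while `regularization=0` requests the pure
maximum-likelihood fit (and raises on separable data).  Posteriors are
clipped to [1e-12, 1−1e-12] before any logarithm.

## MI estimator

With the fitted posterior P̂ recalibrated to the requested prior,

    MI(X,Y) ≈ Σᵢ P(xᵢ) (1/nᵢ) Σ_l log₂[ P̂(xᵢ | y_l^i) / P(xᵢ) ].

The outer expectation over P(y | xᵢ) is replaced by the average over level
i's own cells.  The estimate is in-sample (no train/test split): the
bootstrap utility (stratified subsampling without replacement, default 80% of
each level, a fixed seed) quantifies variability instead.  Note that
subsampling a fraction f without replacement understates the sampling spread
of a fresh experiment of the subsample size by roughly √(1−f) (≈0.45 at
f = 0.8) for smooth statistics; the replicate spread is a variability
indicator, not a calibrated standard error.  Small negative estimates (within
~0.02 bits of zero) are expected for uninformative channels.

## Capacity by alternate maximization

Capacity is the double maximization of the auxiliary objective
J(P, Q) = Σᵢ P(xᵢ) E[log₂ Q(xᵢ|Y)/P(xᵢ) | X=xᵢ] over the input distribution P
and a surrogate posterior Q, each of which has a closed-form partial
maximizer:

1. Initialize P⁽⁰⁾ at the empirical frequencies; fit the logistic posterior
   once to obtain Q⁽⁰⁾.
2. At step k: compute Dᵢ = (1/nᵢ) Σ_l log₂ Q⁽ᵏ⁻¹⁾(xᵢ | y_l^i) (Monte-Carlo
   average of the expected log-posterior);
   set P⁽ᵏ⁾(xᵢ) ∝ exp(Dᵢ) (softmax over levels); recalibrate Q to P⁽ᵏ⁾ by
   the intercept shift; record
   C⁽ᵏ⁾ = Σᵢ P⁽ᵏ⁾(xᵢ)(Dᵢ(Q⁽ᵏ⁾) − log₂ P⁽ᵏ⁾(xᵢ)).
3. Stop when the lagged difference |C⁽ᵏ⁻¹⁾ − C⁽ᵏ⁻²⁾| falls below the
   tolerance (default 1e-6 bits) or after `max_iterations` (default 5000,
   then flagged `converged=False` rather than raising).

Each step maximizes J in one coordinate, so the trace C⁽ᵏ⁾ is non-decreasing
(asserted in tests to 1e-6 bits).  Internal accumulation is in nats so that
the softmax update exp(Dᵢ) matches the logarithm base of the Lagrange
solution; conversion to bits happens only at reporting.  A diagnostic mode
(`check_refit=True`) refits the regression from scratch each iteration under
the current prior (floored at 5% per level, where the refit oracle is
well-posed) and asserts agreement with the intercept shift.

## PCD estimator

For a pair (xᵢ, xⱼ) at the enforced equal prior (1/2, 1/2), the pointwise PCD
of a response is max{P̂(xᵢ|y), P̂(xⱼ|y)} and the overall PCD averages it over
both levels' responses with equal weight.  Because a classifier evaluated on
its training cells overstates discriminability, the estimate is the mean over
repeated stratified train/test splits (defaults: train fraction 0.8, 50
repeats): fit on the training cells, recalibrate to (1/2, 1/2) via the
intercept shift (exact and deterministic, as opposed to subsampling the
larger class), average over the *held-out* responses.  The train fraction is
a package default; 0.8 is consistent with the subsample fraction used for the
capacity uncertainty bands.  Per-pair seeds are derived from the matrix seed
and the pair's labels, so the full matrix is reproducible and pairs are
independent.  Ties (posterior exactly ½) contribute 0.5 via the max — no
randomized tie-breaking.

## Synthetic channels and oracles

The generator provides four families with exactly known conditionals:

* `lognormal_sigmoid` — Y|x ~ exp(N(μ(x), σ²)), μ(x) = V·x/(1+x); defaults
  V = 10, σ² = 1.  The benchmark `scenario1_spec()` uses eleven doses in
  [0, 100]: {0} ∪ 10 log-spaced values from 0.01 to 100, the standard spacing
  of a dose–response titration (the level set is overridable).
* `gaussian_shift` — equal-variance normals with given means; closed-form
  Bayes discriminability Φ(|Δμ|/2σ).
* `disjoint_uniform` / `identical` — the degenerate extremes (capacity
  log₂ m; zero information).

Ground truth: the 1-D output is discretized into 4096 bins whose interior
edges span the union of the per-level [1e-8, 1−1e-8] quantile ranges
(log-spaced for positive-support families), with tail mass absorbed into the
outer bins so each conditional row sums to one exactly.  MI is summed
directly on this transition matrix; capacity comes from the classical
discrete Blahut–Arimoto iteration run to 1e-9 bits.  Doubling the resolution
moves oracle values by less than 1e-4 bits (asserted).  These oracles share
no code path with the classifier-based estimators.

**Analysis representation for the log-normal benchmark.**  The linear-logit
posterior is exactly correct in *log*-output space for this family (log Y|x
is Gaussian with constant variance) and misspecified in raw space, where it
substantially underestimates information.  MI and capacity are invariant
under any invertible transform of the output, so the benchmark analyses feed
the classifier log responses (`simulate_channel(..., log_output=True)`).
This mirrors standard practice — fluorescence-derived intensities are
routinely log-transformed before model-based analysis — and is a reminder
that the estimator provides a *lower* bound tightened by a well-chosen
response representation.

What the synthetic families do not emulate: temporal autocorrelation
structure of real trajectories, cell-to-cell heterogeneity beyond the output
noise model, heavy-tailed or multimodal responses, and measurement dropout.
Passing tests therefore certify the estimators against channels where the
posterior family is well-specified (or harmlessly over-specified); on real
data the logistic posterior is an approximation and the MI estimate is, in
expectation, a lower bound on the true information.

## Problem sizes and numerical defaults

Validation uses n = 500–2000 cells per level for point comparisons (estimator
vs oracle agreement within 0.05 bits at n = 1000 per level on the benchmark
channel), n = 4000 per level for the Gaussian PCD oracle (±0.02), and 10
simulation seeds per sample size for the convergence-with-n checks; these
sizes put the Monte-Carlo error of each check well below its tolerance.
Capacity tolerance 1e-6 bits with the lagged stopping rule; optimizer
tolerance 1e-8; posterior clip 1e-12 (bounding each Dᵢ below by
log₂ 1e-12 ≈ −39.9 bits); oracle grid 4096 bins, discrete Blahut–Arimoto to
1e-9 bits.

## Known limitations

* The logistic posterior is linear in the supplied response coordinates; if
  the true class log-ratios are non-linear in those coordinates the MI and
  capacity estimates are biased downward (MI-lower-bound behavior).
  Transform or augment the response columns when a sufficient representation
  is known.
* In-sample MI/capacity can be optimistic at very small n (tens of cells per
  level) where the classifier can overfit; the PCD path controls this with
  train/test splits, and the bootstrap utility exposes the variability of the
  MI/capacity estimates.
* The capacity iteration may drive some levels' optimal mass to ~0; values
  below ~1e-6 should be read as "excluded from the optimal input alphabet",
  not as precise probabilities.
* PCD estimates share training data across repeats, so bootstrap replicates
  are not independent; the reported spread is a variability indicator, not a
  confidence interval.
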