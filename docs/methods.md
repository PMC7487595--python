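# Methods

## The observation model

A silent disease onset time X > 0 is never observed directly. Each subject i
attends n_i scheduled visits and gives a binary self-report at each one. Reports
are error-prone with known operating characteristics: sensitivity
φ₁ = Pr(report + | visit at or after X) and specificity
φ₀ = Pr(report − | visit before X), assumed constant over time and independent
across visits given X. A visit exactly at X counts as post-event, consistent with
the half-open intervals below. The package treats (φ₁, φ₀) as known constants;
estimating them is out of scope.

Pooling the distinct visit times over all subjects gives a grid
0 = τ₀ < τ₁ < … < τ_J < ∞ which partitions the time axis into J+1 intervals
I_j = (τ_{j−1}, τ_j], plus I_{J+1} = (τ_J, ∞) for subjects who never have the
event (X = ∞ by convention). The baseline distribution of X is described
nonparametrically by the interval masses θ_j = Pr(τ_{j−1} < X ≤ τ_j), with
Σθ_j = 1, and covariates act through a proportional-hazards model, so the
conditional probability of falling in interval j for a subject with linear
predictor η = z′β is S_{j−1}^{exp(η)} − S_j^{exp(η)}, where S_j = Σ_{k>j} θ_k
is the baseline survival at τ_j.

For each subject the matrix entry D_ij is the probability of the observed report
sequence given X ∈ I_j: every visit strictly before I_j contributes φ₀ (negative
report) or 1−φ₀ (positive), every visit at or after the interval's right end
contributes φ₁ (positive) or 1−φ₁ (negative). The subject likelihood is

    L_i = Σ_j D_ij (S_{j−1}^{h_i} − S_j^{h_i}),   h_i = exp(z_i′β),

a sum of nonnegative terms, which is how it is evaluated (the algebraically
identical "differenced" form Σ_j C_ij S_{j−1}^{h_i} with C_ij = D_ij − D_{i,j−1}
is kept as an independent cross-check in the tests). With a perfect test the D
row is the indicator of the interval bracketed by the last negative and first
positive report, and the likelihood reduces to the textbook grouped
interval-censored PH likelihood. A subject whose data have zero probability under
the model (e.g. a negative after a positive with φ₁ = 1) drives the log-likelihood
to −∞ and is reported by row index.

## Profiling θ

The sampler and the ML fitter treat θ as a nuisance vector and maximize over it
at fixed β. The profiler is an equality-constrained Newton iteration directly on
the probability simplex: the KKT system bordered by the sum-to-one constraint is
solved with analytic gradient and Hessian (cheap closed forms via prefix sums of
the differenced coefficients), Levenberg–Marquardt damping handles indefinite
Hessians far from the optimum, a backtracking line search enforces monotone
ascent, and coordinates are floored at ε = 1e−10. Coordinates pinned at the floor
are frozen by an active-set rule and released when the KKT multiplier (the mean
free-coordinate gradient) indicates that raising them would improve the
objective. Convergence is declared when a step improves the log-likelihood by
less than 1e−8 (or no tried direction improves it at all); the iteration cap is
200 with an internal evaluation budget, and a failed profile is restarted once
from the uniform vector. Each call inside the MCMC warm-starts from the current
state's θ, which typically leaves only 2–4 Newton steps per proposal and keeps a
full chain tractable.

The profile surface is not concave in general. For instances from the package's
generative regime (scheduled visits, effect sizes up to |β| ≈ 1.2, the accuracy
settings studied here) single-start profiling is empirically globally optimal —
the test suite verifies it against random simplex search on every instance it
draws. For adversarial unstructured instances (subjects with arbitrary visit
subsets and |z′β| ≳ 4) the surface can have multiple KKT points on different
boundary faces, and a local method may return the inferior one. This is an
inherent limitation of profiling and applies equally to any local optimizer used
for this model.

## Low-dimensional maximum likelihood

`fit_ml` maximizes the joint likelihood over (β, θ) for P ≤ 20 covariates,
parameterizing θ by a multinomial logit so the optimization (scipy L-BFGS-B) is
unconstrained, warm-started from the profiled θ at β = 0. Standard errors come
from the inverse of a numerically differentiated Hessian at the maximum; Wald z
statistics and two-sided p-values are reported per coefficient. A singular
Hessian yields NaN standard errors with a warning rather than an error.
`univariate_screen` applies this one covariate at a time, the usual screening
companion to the multivariable sampler.

## The spike-and-slab sampler

Priors: β_p | γ_p ~ γ_p N(0, b²) + (1−γ_p) δ₀; γ_p | ω ~ Bernoulli(ω);
ω ~ Beta(w₁, w₂); θ ~ Dirichlet(1). Defaults b = 1.0, w₁ = 5, w₂ = 100 give a
prior inclusion mass of w₁/(w₁+w₂) ≈ 4.8%, i.e. roughly five expected covariates
out of P = 100 — matched to the sparsity the method targets. The refine
probability p_main = 0.30 controls how often an included coefficient gets a
random-walk update per iteration; run length defaults to 100,000 iterations with
20,000 burn-in.

One iteration performs, in order:

1. **Flip move.** A covariate p is chosen uniformly; its indicator is flipped.
   An entering coefficient is drawn from the slab N(0, b²); a leaving one is set
   to exactly zero (the spike is exact, never a small number). θ is re-profiled
   at the proposal and the move is accepted with probability min(e^Δ, 1),
   Δ = l(θ*, β*) − l(θ, β) + (2γ*_p − 1) logit(ω). The slab prior of an entering
   coefficient cancels exactly against its proposal density; the test suite
   verifies this cancellation against a brute-force log target ratio rather than
   assuming it.
2. **Refine moves.** For each currently included covariate (ascending index,
   snapshot taken after the flip), independently with probability p_main, a
   symmetric random-walk proposal β*_p ~ N(β_p, b²) with its own θ re-profiling
   and acceptance Δ = Δl + (β_p² − β*_p²)/(2b²). Each refine is accepted or
   rejected individually because each Δ references a single coefficient.
3. **ω update.** Conjugate Gibbs draw from Beta(w₁ + K_γ, w₂ + P − K_γ).

θ is profiled (maximized), not sampled, exactly as the algorithm prescribes; the
chain therefore targets an approximate profiled posterior over (γ, β, ω), not the
full joint posterior. No correction is attempted, and inclusion probabilities
should be read as ranking statistics rather than calibrated posterior masses.
Covariates are ranked by the post-burn-in frequency of γ_p = 1; ties break by
ascending covariate index (stable and documented — relevant only in degenerate
cases such as all-zero counts).

A proposal whose θ-profile fails (optimizer failure, or data probability zero
under the proposal) is treated as a rejection and logged; zero-probability
proposals are counted separately from genuine optimizer failures. The accepted
state's profiled log-likelihood and linear predictor are cached, so a
single-coordinate proposal costs O(N) plus the profile.

Rejected spec-level alternative: re-profiling θ once per iteration instead of
once per refine proposal would be cheaper but would make each printed Δ refer to
a θ not profiled at its own β*, so per-proposal re-profiling was kept. The flip
covariate is drawn independently of any covariate refined in the same iteration.

## Synthetic data

The generator reproduces the reference simulation design: n = 100 subjects,
P = 100 SNP covariates, five true effects β = 1.0 (hazard ratio e ≈ 2.7) at
uniformly drawn positions, exponential event times with baseline hazard
λ₀ = −log(1−CIR)/T calibrated so the reference group (z = 0) reaches cumulative
incidence CIR ∈ {0.1, 0.3} over T = 8 years, four scheduled visits, Bernoulli
self-reports governed by (φ₁, φ₀) with the boundary convention that a visit at X
is post-event, and two designs: NMISS (all reports kept) and NTFP (reports after
the first positive discarded).

Two deliberate fidelity gaps, both documented here because the original design
matrices are access-controlled cohort data:

* SNP columns are generated under Hardy–Weinberg proportions ((1−q)², 2q(1−q),
  q²), dosage-coded 0/1/2 and standardized, with the published MAF composition
  (74% of columns with q ~ U(0.05, 0.35), 26% with q ~ U(0.35, 0.5)) — but
  independent across columns, so linkage-disequilibrium structure of real GWAS
  panels is absent. Monomorphic draws are resampled. A user-supplied covariate
  CSV can be substituted through the CLI to close this gap.
* The continuous ("metabolomics-like") variant uses Gaussian columns with an
  optional exchangeable correlation ρ, making no claim of fidelity to any real
  correlation structure.

Visit times default to 2/4/6/8 years (equal spacing over the study duration; the
reference design states four pre-scheduled visits without placement). Passing
tests on these synthetic designs demonstrates the estimator's behavior under the
stated generating mechanism, not robustness to LD, informative visit schedules,
missed visits or competing risks — all out of scope.

## The replication study

For each simulated dataset the driver computes the probability that a truly
associated covariate ranks among the top k = 5 by posterior inclusion
probability, under three strategies: the error-aware sampler on full panels
(BVS_e NMISS), the error-aware sampler on NTFP-truncated panels (BVS_e NTFP),
and the naive sampler assuming perfect reports (BVS_perfect), which always
NTFP-truncates first because a negative after a positive has zero probability
under a perfect test. The per-replicate fraction of true covariates in the top k
is averaged over replicates with its Monte-Carlo SE; the complementary count of
null covariates in the top k satisfies the exact partition identity
(metric · |true| + false positives = k). Random Survival Forests, used as an
external comparator in the original study, is not implemented; externally
produced rankings can be scored with the same metric functions.

Seeding: replicate r derives its data stream from SeedSequence(root, spawn_key
= (r, 0)) and strategy s its chain stream from spawn_key = (r, 1+s), so results
are identical regardless of worker count or completion order, and any replicate
is reproducible in isolation. Per-replicate results can be checkpointed as JSON
and interrupted studies resumed. More than 1% failed replicates aborts a study.

### Problem sizes used here

The reference results average 1,000 replicates of 100,000-iteration chains. The
package's test suite runs the study at 40 replicates with 12,000-iteration
chains (2,400 burn-in), and `scripts/acceptance.py` at 50 replicates with
15,000/3,000 — sizes chosen so the whole suite completes on a single CPU in
minutes. At these scales the Monte-Carlo SE of a metric is ≈ 0.32/√R ≈ 0.04–0.05,
and shortened chains depress the metric slightly (≈ 0.03–0.04 at the CIR = 0.1
perfect-report setting, by direct comparison of 10k vs 30k chains on identical
datasets); test tolerances widen the reference ±0.05 band by two Monte-Carlo SEs
accordingly. The full reference scale is available behind the CLI's
`--full-scale` flag.

## Numerical conventions

* Interval convention: (τ_{j−1}, τ_j] half-open; event at a visit time is
  detectable at that visit.
* θ floored at ε = 1e−10; survival tails clipped to [ε, 1]; powers computed as
  exp(h log S) in the log domain.
* A subject likelihood below 1e−100 is treated as zero (−∞ log-likelihood):
  below that, reciprocal-square terms in the Hessian overflow, and such a state
  is numerically indistinguishable from an impossible observation.
* Linear predictors are clipped at 700 before exponentiation purely to avoid
  overflow warnings; any proposal in that regime has zero acceptance probability
  anyway.
* Standardization: columns centered and scaled by the N−1 sample SD; constant
  columns are rejected.
* Missing covariate cells in input CSVs are imputed to 0 (the major-allele
  homozygote under dosage coding) before standardization, with a logged count.
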