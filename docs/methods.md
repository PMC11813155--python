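# Methods

## The prediction problem

The unit of analysis is an inbred line: its phenotype is a line mean
(the trait averaged over f individuals), and its predictors are m gene
expression values, with m in the thousands and the number of lines n ≈ 200.
Averaging raises the broad-sense heritability of the analyzed response to

    H²m = σG² / (σG² + σE²/f),

around 0.8 for f in the tens — so the ceiling on prediction accuracy is
high, and the binding constraint is estimating m >> n effects. Every model
here is a different answer to that constraint. All models consume X with
centered columns and centered y; predictions add the training mean back.
Centering and standardization always use training statistics only, and the
sample variance uses denominator n − 1 throughout, which makes
trace(WWᵀ/m) = n − 1 an exact identity for the standardized matrix W.

## Models and estimation

**PCR / PLSR.** Scores T (n × k) replace X; k ∈ {0, …, max_k} is chosen by
5-fold CV inside the training set (folds: shuffle once under the replicate
seed, deal into contiguous blocks; max_k defaults to min(n−1, 100)). PLSR
uses the wide-kernel route: all score extraction operates on the n × n
matrix XXᵀ, the right shape for m >> n; gene-space weights are recovered as
Xᵀ-products with sample-space vectors, so no m × m object is ever formed.
The per-component eigen-step is iterative with a max_iter cap (default 100,
raisable to 500); exceeding it sets `converged=False`, which the evaluation
records as a failure rather than raising. k = 0 (intercept-only) is an
admissible CV winner and is likewise flagged. CV selects the error
minimizer; k values whose CV error is within 1e-8·Var(y) of the minimum
count as ties and the smallest k wins — real CV differences are orders of
magnitude larger, so the tolerance only ever resolves exact-interpolation
ties.

**Ridge / lasso.** glmnet-style objective (1/2n)||y − Xβ||² + λP(β), with
columns standardized inside the solver and coefficients back-transformed
(this changes the meaning of λ and is therefore part of the contract). The
path runs from λ_max = max_j |x_jᵀy|/n (ridge: ×10³, mirroring the
reference package's treatment of the pure-ℓ2 path) down
`lambda.min.ratio` = 0.01 when n < m and 1e−4 otherwise — the reference
package's documented defaults. λ is the 5-fold CV error minimizer; the
one-standard-error rule is available (`rule="1se"`). Ridge solves each λ
exactly by SVD; lasso uses coordinate descent (scikit-learn's `lasso_path`)
with a loose duality gap inside CV folds (1e−4, folds only rank λ) and a
tight one (1e−6) for the final fit. A lasso fit with no active coefficients
is an intercept-only model: flagged, never raised.

**BayesC / GO-BayesC.** Spike-and-slab prior β_j ~ π N(0, σβ²) + (1−π)δ₀.
One compiled Gibbs kernel serves both models: each coordinate's (indicator,
effect) pair is sampled jointly from its exact conditional — the inclusion
log-odds combine the prior odds, the Occam factor ½log(v/σβ²) and the fit
term μ²/2v, with v and μ the conditional slab posterior variance and mean —
then π from its Beta conditional and the variances from scaled-inverse-χ²
conditionals. GO-BayesC carries two independent (π, σβ²) pairs for genes
inside/outside the selected term; a term covering the whole universe
reduces exactly to BayesC. The residual vector is refreshed from scratch
every 5,000 sweeps against floating-point drift. BayesC operates on
centered, not re-standardized, expression by default (the model is written
directly in expression units); the kernel models always standardize.

**TBLUP / GO-TBLUP.** Kernel mixed model y = t + e, t ~ N(0, σt²T) with
T = WWᵀ/m. Sampling happens in the eigenbasis of the training-block kernel,
where the conditional of t factorizes coordinate-wise; coordinates with
zero eigenvalue are pinned to zero, which handles the exact rank deficiency
of centered kernels (the all-ones vector is always null) without
regularization. Jitter of 1e−8·trace(T)/n is added only if a kernel is
indefinite beyond round-off — with eigenbasis sampling a Cholesky probe
would fail on *every* centered kernel and inject jitter systematically,
which is why the probe-and-jitter route was rejected. Held-out lines are
predicted per retained draw by the kernel conditional mean
T_cross T_train⁺ t. GO-TBLUP scales both kernels by the total gene count,
T_GO = W_GO W_GOᵀ/m, so
T_GO + T_notGO = T exactly and fixing the two variance components equal
reproduces the single-kernel model — both identities are tested. It reports
the posterior mean gene-set variance share σ²_tGO/(σ²_tGO + σ²_tnotGO).

**Prior calibration.** Scales follow the expected-R² convention with
R² = 0.8 by default: the residual scaled-inverse-χ²(df = 5) prior has its
mode at (1 − R²)Var(y); each component's variance prior puts its implied
prior variance explained at weight·R²·Var(y), dividing by π·Σ_j Var(x_j)
for effect-level components and by mean(diag T) for kernels. π has a
Beta(5, 5) hyperprior (prior count 10, mean ½). Two-component models split
R² equally by default (the partition is configurable; nothing in the
problem pins it). Samplers accept `fixed` values for any hyperparameter —
that exists solely so the oracle tests can compare against exact
enumeration and closed-form BLUP; production runs leave all free.

**Chain schedules and diagnostics.** Defaults are 130,000/30,000/thin 50
(effect-level, 2,000 retained draws) and 85,000/10,000/50 (kernel models,
1,500 retained). Convergence checking is automated rather than visual:
effective sample size (Geyer initial-positive-sequence estimator) must
reach 100 and the Geweke z comparing the first 10% to the last 50% of each
variance chain must stay within ±3; violations warn and set
`diagnostics_ok=False`, never silently pass and never raise.

**VARBVS-style CAVI.** Fully factorized approximation per prior log-odds
state; 20 states span prior inclusion 1/m to ½. Within a state the slab
and residual variances are re-estimated by EM (slab variance parametrized
as a multiple of σe²); states are combined by importance weights
proportional to exp(ELBO). The ELBO is evaluated at the variational
variances actually used by the sweep, *before* the hyperparameter move, so
the trace is an exact coordinate-ascent objective: it must be non-decreasing,
and a decrease beyond 1e−6 relative tolerance raises (that is an update
bug, not a modelling failure).

**MR.ASH-style VEB.** Prior π₀δ₀ + Σ_k π_k N(0, σe²·s_k²) over a fixed
variance grid; mixture weights estimated by coordinate ascent, β̄
initialized from the lasso solution at its CV-selected λ. Slab variances
are scaled by σe² — an unscaled parametrization admits a degenerate
direction (shrink σe², absorb noise into small slabs) that destroys
spike-weight recovery under the null. The default grid is 0 plus a
19-point geometric ladder from 4× the squared univariate standard error
(effects below twice their SE are indistinguishable from zero; slabs below
that leave the weight objective flat and π₀ unidentifiable) to twice the
largest squared univariate effect. Convergence: relative ELBO change
< 1e−8 or 1,000 sweeps. Both variational fits are deterministic —
identical inputs give bit-identical outputs.

## Evaluation protocol

25 replicates of uniform 90/10 line splits, test size round(0.1·n)
(20 of 198), replicate k seeded base_seed + k. Every method in a comparison
consumes the identical split plan (asserted via a plan hash carried in the
results); sampler streams are derived per (method, replicate) so chains are
never shared. Accuracy is the Pearson r between observed and predicted
test phenotypes; constant predictions, non-convergence and runtime errors
are taxonomized failures that contribute to the failure count but never to
the mean. The summary is mean ± SE over successful replicates (SE = sample
SD / √#successes), and a method whose failure rate exceeds 40% in at least
one stratum (e.g. one sex) is flagged excluded from comparison.

## GO scan and gene analysis

Gene sets come from GMT files (or the generator), restricted to the
expression gene universe with sets under 5 present genes dropped. The scan
fits one gene-set-informed model per term under the shared split plan; the
baseline (standard BayesC or TBLUP) is fit once per replicate, and for the
kernel variant each term's complement kernel is obtained as T − T_GO from
the replicate's cached full TRM, keeping the scan linear in the number of
terms. Terms are ranked by mean r (ties by term ID) and the top
max(1, ⌊0.01·N⌋) kept — 2,628 retained terms give 26, 2,580 give 25. Gene
counts across top terms are reported above a threshold (default 4); an
elbow heuristic (smallest c with < 5% of nonzero-count genes at ≥ c) is
offered but never applied silently.

## Synthetic data

The generator emulates the *shape* of an inbred-panel transcriptomic study,
not its biology. Expression is a latent-factor model X = LFᵀ/√k + ε with
k = 10 factors, the factor component normalized to unit variance per gene
(~50% shared variance at the default noise level — unnormalized loadings
would force k/(k+1) ≈ 91% co-expression, a degenerate regime in which
every gene proxies every other and sparse architectures are
unrecoverable). Effects are Gaussian on the standardized expression scale
(so target heritability is architecture-independent) under three
architectures: dense (all genes), sparse (n_causal genes, default 10), and
go_enriched (causal genes drawn from one designated term). Line-mean noise
is Gaussian with variance set from the realized Var(g) so that
Var(g)/(Var(g) + σ²_e,line) equals the target H²m (default 0.8, f = 25);
the realized value is recorded. Gene sets are random-membership terms of
size 5–50, plus the designated causal term when relevant. Two sexes can be
simulated as independent panels with effect correlation ρ.

What the generator does *not* model: raw counts and their mean–variance
relation, batch structure, covariate adjustments (infection status,
inversions), biologically structured co-expression modules, or any GO
semantics beyond set membership. Passing tests therefore demonstrate
correctness of the estimators and the protocol under a controlled
generative model — not that any method will achieve a particular accuracy
on real panel data.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run the method comparison at
n = 200, m = 2,000 with 25 shared splits, the gene-set recovery at
n = 150, m = 1,000 with a 100-term scan over 3 splits and 10 independent
runs, and the sampler-vs-enumeration checks at n = 40, m = 5 (where all
2⁵ models are enumerable). MCMC schedules in these checks are scaled down
(e.g. 2,000/400/4) — posterior means of well-mixing chains, not full
posterior summaries, are what those comparisons need; the enumeration
check runs at the full default schedule.

## Known limitations

* The wide-kernel PLSR handles univariate responses only.
* GO-BayesC shares one residual variance across groups; the R² partition
  across the two groups is a modelling choice (default ½/½), not something
  the data identify a priori.
* Variational PIPs inherit the usual mean-field optimism under correlated
  predictors; the enumeration comparison is run on near-orthogonal designs
  for that reason.
* The scan evaluates terms marginally; overlapping terms are not modeled
  jointly, so gene counts across top terms inherit term overlap.
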