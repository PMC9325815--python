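# Methods

## Scope

`selresp` estimates response to genomic selection in multi-environment
testcross trials by simulating from a fitted GBLUP mixed model.  The
statistical pipeline has three parts: (i) mixed-model machinery
(design construction, Henderson's equations, REML), (ii) the
variance-partitioning workflows that produce a current-year model with
separated GBV and GBV×year components, and (iii) the Monte-Carlo
selection-probability engine driven by the joint covariance of true and
estimated breeding values.

## Mixed models

### Model class

`MixedModel` fits
`y = Xβ + Σ_k Z_k u_k + e`, `u_k ~ N(0, G_k σ²_k)`, with four
covariance structures per random term:

* **iid** — `G = I` over the observed levels of one or more crossed
  factors;
* **iid by group** (`by=`) — one variance per group level, used for the
  year-nested nuisance terms of the two-year single-stage model;
* **kinship** — `G = K`, the VanRaden genomic relationship matrix over
  the entries observed in the data (entries absent from K are a hard
  error; kinship is never imputed);
* **kinship by group** (`kinship_by=`) — block-diagonal `⊕_j K_j` with a
  single common variance, the GBV×year structure (`K_j` is the kinship
  sub-block of the entries observed in year j).

Residuals are homogeneous, diagonal with group-specific variances
(location, or year-location), or fixed at known precisions
`R = diag(1/w_i)` with no free parameter (Smith weighting in stage 2).

Fixed effects use treatment coding with an always-present intercept;
aliased columns are dropped greedily in column order and recorded on
the results object, so reports state exactly which contrasts were
estimable.

### Kinship reparameterization

Every kinship-structured term is rewritten through an eigen-factor `L`
with `LLᵀ = K` (eigenvalues below `1e-10·λ_max` treated as zero):
`u = La`, `a ~ N(0, Iσ²)`.  This serves three purposes: singular K
(always, since centred dosages give rank ≤ N−1) never needs inverting;
every `G` block in the MME becomes `σ²I`, so the coefficient matrix is
`W'R⁻¹W + diag(0_p, 1/σ²_k)` with `W = [X, Z₁L₁, …]`; and the REML
identities below take their simplest form.  BLUPs and the
prediction-error matrix are mapped back by `ĝ = Lâ`,
`C = L C_a Lᵀ` with `C_a` the corresponding block of the inverse
coefficient matrix.  Per-entry-subset factors are cached on the
`KinshipMatrix`, so the four identical year blocks of a balanced
GBV×year term cost one eigendecomposition.

### REML

The residual log-likelihood is evaluated through
`−2ℓ_R = log|R| + log|G| + log|C_coef| + y'Py + (n−p) log 2π`, with
`y'Py` from the MME solution and per-residual-group cross-products
`W_g'W_g` precomputed once per model, so each likelihood evaluation is
one Cholesky (plus one triangular inversion for gradients) of the
coefficient matrix.  Scores use the standard identities
`tr(P Z_k Z_kᵀ) = (r_k σ²_k − tr(C_kk)) / σ⁴_k` and
`y'P Z_k Z_kᵀ P y = û_kᵀû_k / σ⁴_k`.

Estimation runs two EM warm-start iterations (monotone, robust to bad
starts) followed by average-information (AI) updates with step halving;
a failed AI step falls back to EM.  Components collapsing toward zero
are pinned to the boundary (active set) and released if the score turns
positive there; pinned and near-zero components are flagged `boundary`
and their SEs marked unreliable.  Convergence requires the change in
−2ℓ_R below 1e-6 and the gradient with respect to log-variances below
1e-4 (or a fully flat step).  Non-convergence after `maxiter` raises
`ConvergenceError` carrying the iteration trace.  Standard errors and
the covariance of the estimates come from the inverse AI matrix at the
optimum; the delta-method SE of ρ and the asymptotic correlation
between the GBV and GBV×year estimates are read off this matrix.

Starting values split `var(y)` equally across components, scaled by the
mean squared row norm of each term's design block; the lower bound on
any variance is `1e-10·var(y)`.

Cross-checks in the test suite: closed-form balanced one-way shrinkage
and PEV; ANOVA estimators on balanced data; statsmodels `MixedLM` on a
one-factor model; lme4 (via Rscript) on crossed random effects; a
direct dense GLS solve (no MME) for the stage-1 EBLUEs and their
covariance.

## Workflows

**Stage 1 (per year).**  Entry effects are *fixed* — adjusted means are
EBLUEs, avoiding double shrinkage when the means are carried into a
second genomic stage.  Nuisance terms (tester, location, entry×tester,
entry×location, trial, replicate, block, all disambiguated by nesting
labels) are random; residual variances are location-specific.  The
entry-mean covariance is the congruence of the fixed-effect covariance
with the (intercept + effect) contrast; Smith weights default to the
diagonal of its inverse, with the reciprocal-diagonal variant available
(`weights="inv_of_diag"`) since both are used in practice.  Terms whose
factor has a single observed level (e.g. one tester) are dropped from
that year's model.

**Stage 2.**  Entry-year means with a random (default) or fixed year
effect, GBV (`Kσ²_g`), GBV×year (`⊕K_jσ²_gy`, common variance) and the
residual fixed at the Smith precisions.  ρ and its delta-method SE are
computed from this fit.  Stage-1 covariances are computed per year
independently (the per-year models share no data).

**Current year.**  The apparent fit replaces the fixed entry effect by
a random GBV; its variance `σ̂²_g̃` absorbs both components.  The
ρ-adjustment is exact by construction
(`ρσ̂²_g̃ + (1−ρ)σ̂²_g̃ = σ̂²_g̃`).  The rerun adds a second
kinship-structured term with the *same* entry incidence matrix and
performs a single MME solve with every variance held fixed — no REML
update of any kind.  With shared incidence and proportional
covariances, `BLUP(u_g) = ρ·BLUP(u_g̃)` holds algebraically; the test
suite verifies it to 1e-8, and the C matrix of the GBV block is what
the simulation consumes.

**GCA2 assessment.**  Entries common to GCA1 and GCA2 of a cycle
(dropouts contribute nothing to the GCA2 genetic variance), fitted
single-stage over the two years with year-specific variances for the
nested nuisance terms and year-location residuals.

## Selection simulation

`Ω = [[D, M], [M, M]]` with `D = Kσ²_g`, `M = D − C` symmetrized.
Factorization attempts Cholesky; on failure it eigendecomposes, errors
if any eigenvalue is below `−1e-8·λ_max` (an inconsistent C), clips the
small negative remainder and keeps the positive part, recording the
method and the clipped count.  Draws `w = Γz` stream in chunks (default
2000), so S = 100k replicates never materialize an S×2N array.

For each replicate the statistic recorded for a given m is the k-th
smallest ĝ-rank among the m truly best entries by g (k = m for the
default "all m captured" criterion; `at_least=k` gives the relaxed
variant).  Success for a window n is `statistic ≤ n`, so the whole
probability grid is the empirical CDF of one integer per replicate —
the default grid of 1..100% of N costs nothing extra.  Monotonicity in
n and anti-monotonicity in m are structural.  Ties have probability
zero under the continuous model; ranking uses a stable order on entry
index for reproducibility.  "Top" means largest; `minimize=True`
inverts both rankings.  Correlations are means of per-replicate Pearson
correlations of values and of ranks (averaging per replicate, not
pooling, matching how mean accuracies are usually reported; the pooled
variant would mix replicate-level location shifts, which do not occur
here since all means are zero).

Independent oracles in the tests: the closed form
`P = 1/2 + arcsin(r*)/π` for N=2, n=m=1 with `r*` derived from Ω, and a
from-scratch sampler using numpy's multivariate-normal (SVD route) with
its own top-set logic.

## Synthetic data generator

The generator emulates the data structure the workflows expect, not any
particular dataset: entries genotyped at P biallelic markers (dosages
Binomial(2, p_j), p_j uniform on a configurable range, optional missing
calls and optional family structure via a shared parental gamete);
true GBVs `u_g = Q_c v` with `v ~ N(0, σ²_g/c)`, so `var(u_g) = Kσ²_g`
holds *exactly* under the model's own kinship — parameter-recovery
tests therefore probe estimation, not model misspecification; GBV×year
effects `MVN(0, Kσ²_gy)` fresh each year; plot yields adding iid
year, location, tester, entry×tester, entry×location, trial, replicate
and block effects and a location-specific residual.  All random draws
are consumed unconditionally and scaled by √variance, so matched-seed
runs that differ only in a variance share one underlying stream — this
is what makes the "higher ρ ⇒ faster-rising curves" comparison a paired
contrast.

Layouts are alpha-design-like: entries split across trials per
location, each trial's entry×tester plots permuted into equally sized
incomplete blocks per replicate.  True alpha arrays are not
constructed; block effects are iid, so layout optimality affects only
efficiency, not correctness of the model fits.  Sparse testing takes a
random entry subset per location at a configurable coverage.  The
multi-cycle program applies truncation selection between GCA stages on
true GBV (default, so tests control truth) or on phenotype means.

Default variances follow the magnitudes reported for hybrid rye
testcross yield where available (σ²_y = 20, σ²_g = 2.0, σ²_gy = 1.4);
the nuisance defaults (location 8, tester 0.5, entry×tester 0.2,
entry×location 0.4, trial 1.0, replicate 0.8, block 0.6, residuals
3.5–6 by location, μ = 100) are field-realistic choices for a
yield-type trait, fixed once.  The testcross genetic model exposes no
tester-specific GCA variance; entry×tester variation is a free
parameter.

What the generator does *not* emulate: linkage/LD structure, dominance
and epistasis, real alpha-array spatial layout, non-random missingness,
and the strong family/pedigree structure of a real breeding pool
(unless `n_families` is set).  Passing recovery tests therefore show
that the estimation machinery is correct under its own assumptions, not
that those assumptions fit any particular crop dataset.

## Study conditions used in the checks

Parameter recovery is assessed on a *fully connected* MET: one cohort
of 300 entries tested in all four years (2 locations × 2 trials × 2
replicates × 2 testers, ≈2,400 plots/year, 800 markers), generating
σ²_g = 2.0, σ²_gy = 1.4 (ρ = 0.588); the mean REML ρ̂ over 20
replicates is required within 0.08 of truth.  With per-year disjoint
cohorts and pedigree-free binomial markers, cross-year kinship is near
zero and ρ is only weakly identified — a property of the synthetic
marker model, not of the estimator — hence the connected design for the
quantitative check (the disjoint-cohort program generator is exercised
by the GCA2 workflow, where the two years genuinely share entries).
The current-year refit identity uses a fresh 300-entry cohort, since ρ
transfers through the variance ratio, not through shared entries.  The
var(ĝ) = D − C identity uses N = 30 entries, 2 locations, 2 replicates
and 10,000 simulated datasets, solved through one precomputed linear
map; the orthant oracle uses S = 10⁶ draws.  The acceptance script runs
a 10-replicate version of the recovery study and a 100-entry end-to-end
assessment at S = 50,000 to keep a full reproduction under a few
minutes.

## Numerical choices

* PSD tolerances: kinship eigenvalues below `1e-10·λ_max` are zero;
  Ω eigenvalues below `−1e-8·λ_max` are an error.
* MME solves use LAPACK Cholesky (`dpotrf`/`dpotrs`) with the triangular
  inverse (`dpotri`) only where traces of the inverse are needed.
* REML convergence: |Δ(−2ℓ)| < 1e-6 and max |∂ℓ/∂log σ²| < 1e-4.
* Degenerate inputs: zero-variance components enter plug-in solves at
  the lower bound `1e-10·var(y)`; single-level factors are dropped by
  the pipelines before model construction; an all-confounded
  coefficient matrix raises naming the candidate terms.
* Seeds: every stochastic routine takes an explicit seed; generators
  derive their streams from `numpy.random.default_rng(seed)` only.

## Known limitations

* Dense linear algebra throughout: comfortable to a few thousand
  entries per fit (the coefficient-matrix dimension is fixed effects +
  transformed random columns); no sparse or out-of-core path.
* Stage-2 residual approximation is diagonal (Smith weighting); the
  full EBLUE covariance is computed but not propagated off-diagonal.
* No spatial residual models or factor-analytic G×E structures.
* The ρ split assumes `σ²_g̃ = σ²_g + σ²_gy` exactly; with strong
  entry×location variance absorbed differently across years this is an
  approximation.
* Boundary SEs (components at zero) are reported as unreliable rather
  than profile-likelihood corrected; asymptotic correlations involving
  a zero estimate are reported as 0 with a flag.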