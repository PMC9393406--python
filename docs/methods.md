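# Methods

## Overview

`cortexlv` implements a data-driven brain–cognition analysis for
longitudinal aging cohorts with a single multimodal imaging wave. Five
vertex-wise cortical metrics — cortical thickness (CT), surface area (SA),
mean diffusivity (MD), fractional anisotropy (FA) and radial diffusivity
(RD), each a vertex × subject table sampled on the cortical mid-surface —
are fused by non-negative matrix factorization (NMF) into spatial
components and subject weights. Cognitive test scores observed over
multiple pre-imaging waves are summarized per subject by mixed-effects
intercepts and slopes. Behavioral partial least squares (PLS) links the
two blocks, and the resulting latent-variable (LV) cognition scores are
used to predict performance at a later follow-up wave.

Because suitable real cohorts are access-controlled, the package ships a
first-class synthetic-cohort generator with planted ground truth, and the
test suite validates every stage by recovery of what was planted.

## Matrix assembly

Each metric table is masked to analyzable vertices, scanner effects are
removed per vertex by OLS on scanner indicators (equivalently, subtraction
of per-scanner vertex means), and each vertex row is z-scored (sample SD,
divisor n−1). Z-scoring removes regional mean differences so that the
factorization captures inter-individual variation only. The five
processed tables are stacked side by side in the fixed order (CT, SA, MD,
FA, RD), subjects in input order within each block, and the whole matrix
is shifted by its global minimum so the NMF input is non-negative. The
shift and the column → (subject, metric) map are stored with the matrix.

Degenerate inputs: a zero-variance vertex is a hard error listing the
offending indices (silent dropping would corrupt column bookkeeping); a
scanner level with one subject is its own group, so that subject's
residuals are exactly zero and a warning is emitted.

## NMF and rank selection

The solver is hierarchical alternating least squares (HALS) on the
Frobenius objective, initialized with plain NNDSVD (positive/negative
parts of the leading singular triplets; zeros are kept, not noise-filled,
to preserve the sparsity the construction creates). Every column update
is a non-negative least-squares step, so the objective is monotone
non-increasing; the per-iteration objective trace is stored. Each outer
iteration computes the two large cross-products once and then applies
several cheap column sweeps (default 8; 16 in the stability scan), which
markedly accelerates convergence at fixed cost. Defaults: `tol = 1e-5`
relative objective change, `max_iter = 500`. Truncated SVDs for the
initialization use a seeded randomized algorithm above a small-size
threshold, so all fits are deterministic given a seed.

Rank selection follows split-half stability: subjects are repeatedly
partitioned into halves (all five metric columns of a subject travel
together), NMF is fit per half per candidate rank, components are matched
across halves by optimal (Hungarian) assignment on cosine similarity, and
stability(k) is the mean matched similarity over splits. The error curve
comes from full-data fits; its gradient is the forward difference — the
error still to be gained by increasing k. A rank qualifies when its
stability is within `stability_margin = 0.05` of the best and its
error-gradient magnitude has fallen below `gradient_frac = 0.25` of the
initial gradient; the smallest qualifying rank is selected. Parsimony is
the right tie-break here: beyond the true dimensionality the error curve
stays flat and extra ranks can drift inside the stability margin by
chance, whereas the first rank past the error elbow that still sits on
the stability plateau is the planted one (verified across seeds). Both
margins are configuration. When no rank satisfies both rules the
stability argmax is returned with a warning; a fully flat error curve
returns the largest candidate with a warning.

Two practical notes, both visible in the tests:

- The min-shift leaves all component profiles sharing a large positive
  background, so the NMF optimum is flat along small mixing directions.
  Even noiseless planted data therefore stabilizes near (not at) 1
  (≈0.98), and under-converged half-fits flatten the stability contrast
  across ranks. The stability scan consequently runs the half-fits to a
  tighter tolerance (`max_iter = 300`, 16 inner sweeps) than a quick
  exploratory fit would.
- For the same reason, non-negative iid noise has non-trivial split-half
  stability (~0.77 at desk scale): its positive mean direction is shared
  by any factorization. Planted structure exceeds it by a clear margin,
  but the gap is smaller than it would be under mean-centered similarity.

Vertex labels threshold each component at 25% of its column maximum
(configurable), with the winner label being the per-vertex argmax.

## Cognitive trajectories

For each test, scores over waves follow

    score_it = b0 + b1·age_i + b2·t_it + b3·age_i·t_it + u0_i + u1_i·t_it + e_it

with baseline age centered at the sample mean, correlated random
intercepts/slopes (u0, u1) ~ N(0, Ψ), and residuals with a continuous
AR(1) correlation, corr(e_is, e_it) = φ^|s−t| with φ per year. The model
is estimated by REML with a purpose-built marginal-likelihood evaluator:
subjects are grouped by identical time patterns, and all per-subject
solves use Woodbury identities so the likelihood and the BLUPs remain
stable when the residual variance collapses (noiseless data). Parameters
are optimized by L-BFGS-B on log/tanh/logit-transformed scales with a
Nelder-Mead polish if the line search stalls; if the serially correlated
fit fails to converge, the model is refit without serial correlation and
flagged. Exact-plane data (zero residual OLS) short-circuits to the
closed-form answer.

The reported `serial_corr` is the residual correlation at the median
within-subject wave gap (the per-year φ is also stored), which makes the
estimate directly comparable with the generator's adjacent-wave setting
under equal spacing and remains meaningful under dropout.

Subject coefficients are the model-implied lines: fixed effects evaluated
at the subject's (centered) baseline age plus the BLUP deviations. BLUPs
are shrunken, so their variance is bounded by the per-subject OLS spread
(tested). The cognition matrix stacks (intercept, slope) per test —
7 tests × 2 = 14 columns — in configured test order.

Subjects with a single observation stay in the fit (they inform fixed
effects) and are flagged; their BLUPs are heavily shrunk. Missing waves
are handled by the likelihood; no imputation.

## Behavioral PLS

Both blocks are column z-scored (so results are scale-free), the
cross-correlation matrix C = X'Y/(n−1) is decomposed by SVD, and
cov_explained_i = s_i²/Σs². The sign gauge is fixed by making the
largest-magnitude element of each cognition salience positive. Subject
brain/cognition scores are the projections of the z-scored blocks onto
the saliences.

Significance uses permutation of the cognition block's rows with the
smoothed estimator p = (1 + #{s_perm ≥ s_obs})/(n_perm + 1), comparing
singular values by position. A Procrustes re-alignment of the permuted
saliences onto the originals is available as a sensitivity toggle but is
off by default: the rotation mixes the permuted singular values, which
systematically shrinks the leading ones relative to the unrotated
observed maximum and makes the test sharply anticonservative (measured
~0.90 null rejection at α = 0.05 versus ~0.03 without rotation, inside
the binomial band).

Reliability uses subject-level bootstrap (joint resampling of both
blocks). Each replicate's saliences are Procrustes-aligned to the
originals; the bootstrap ratio (BSR) of a brain variable is its original
salience over the bootstrap SE of the aligned salience, with |BSR| > 1.96
marking reliable contributors. Cognitive variables are summarized by the
Pearson correlation between each column and the LV's brain scores, with
percentile 2.5/97.5% bootstrap CIs; a CI crossing zero marks the variable
as non-contributing. Degenerate replicates (zero-variance columns) are
redrawn, with an error if more than 10% must be redrawn.

LVs retained for downstream prediction are those with permutation
p < 0.05, capped at 2 (configurable).

## Follow-up prediction

Count-like follow-up scores are square-root transformed and mapped onto
normal quantiles by the rank-based inverse normal transformation with
Blom offset 3/8 (ties receive average ranks; the offset is
configuration). Each transformed score is modelled by OLS on LV1, LV2,
age, sex and education (an inter-wave-interval covariate is
config-gated), with listwise deletion and the per-model n logged.
Coefficients are standardized as b·SD(x)/SD(y); in a univariate model
this equals the Pearson correlation (tested to 1e-10). Significance uses
a strict-inequality Bonferroni threshold α/m, reported to 4 decimals.

Cohort comparisons use Pearson chi-squared on 2×2 proportion tables
without continuity correction (this convention reproduces the reference
statistics 2.27 and 0.46 from the printed counts) and Welch t from
summary statistics with sign group_b − group_a (reproducing |t| = 0.80
for the MOCA comparison). Convenience wrappers give the education-on-LV
standardized slope and the Welch t of LV scores between MOCA ≥ 26 and
MOCA < 26 groups.

## Synthetic cohorts

The generator plants everything the pipeline is asked to recover:

- Spatial components: k contiguous parcels with amplitudes U(0.8, 1.2)
  (one dominant component per vertex); a configurable fraction of
  vertices (default 0.1) receives a secondary loading of U(0.3, 0.6).
- Subject × (component, metric) weights: multiplicative around a positive
  base, B = base·(1 + cv·(ε + coupling·(F·s)·A')), floored at 1e-3, with
  cv = 0.15, ε iid standard normal, F the standardized latent factors, A
  unit-norm brain saliences and s the per-LV strengths.
- Vertex tables: W·H per metric plus per-scanner additive offsets
  (N(0, 0.2) for the second scanner) plus iid Gaussian noise (default SD
  0.05); diffusion metrics floored at 0.
- Trajectories: per-test fixed effects (default intercept per test, age
  0.1/yr, time −0.5/yr, age×time −0.02), random intercept/slope SDs
  (2.0, 0.2) with correlation −0.2, AR(1) residuals (SD 1, adjacent-wave
  correlation 0.3) over 5 waves spaced 5 years. The latent contribution
  to each subject's intercept/slope is expressed in units of that
  column's random-effect SD, so `coupling_strength` is a dimensionless
  effect size (latent SD / idiosyncratic SD).
- Follow-up: the trajectory evaluated 5 years after the last wave plus
  independent noise (SD 1); vocabulary is not administered at follow-up.
- Scores are floored at 0 and rounded to integers by default to mimic
  count-like tests; noiseless validation configurations disable rounding,
  since discretization is itself a noise source.
- Covariates: age at imaging (baseline + 22.5 years), sex ~
  Bernoulli(0.23), education ~ N(14.2, 3²) and MOCA ~ N(27.3, 2.2²)
  (rounded, clipped), independent of the latent factors.

Latent design. Two planted LVs with distinct strengths (1.0, 0.6): LV1 is
a global severity axis (lower baselines, faster decline on every test,
CT/SA/FA down and MD/RD up on its components), LV2 trades fluency/memory
decline against reasoning improvement on the remaining components, with
supports and sign patterns chosen to be exactly orthogonal. The strength
separation matters: with equal strengths the two population singular
values nearly coincide and the sample SVD returns arbitrary rotations of
the planted plane, so no estimator could recover the individual axes. A
dominant first LV also matches what real brain-cognition panels show.

What the generator does not emulate: cortical topography and spatial
autocorrelation, test-specific floor/ceiling psychometrics, practice
effects, non-monotone missingness, and covariate–cognition confounding.
Passing tests demonstrate internal consistency and statistical
calibration of the machinery, not performance on real imaging data.

## Problem sizes used in validation

Desk-scale defaults mirror the aspect ratios of a realistic study: 2000
vertices, 400 subjects, 5 metrics, k_true = 10, 2 LVs, 5 waves plus a
follow-up wave. The acceptance runs use split-half stability over
k ∈ {4, 6, …, 16} with 10 splits; permutation calibration uses 200 null
cohorts at n = 200 with 500 permutations; trajectory coverage uses 100
replicates at 400 subjects × 5 waves; end-to-end sign recovery uses 10
full pipeline runs.

## Known limitations

- The stability statistic operates on raw (uncentered) component maps, so
  its absolute level is inflated by the shared shift background; rank
  selection relies on contrasts across k, which are preserved.
- The AR term is the equally-spaced special case of a continuous ARMA
  family; an MA extension is config-gated and off by default.
- Fixed-effect SEs condition on the estimated variance parameters (the
  usual mixed-model practice); coverage is validated by simulation.
- The NMF objective is non-convex; HALS from NNDSVD is deterministic but
  not guaranteed globally optimal. Small-instance fits are checked
  against a 50-restart oracle in the tests.
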