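# Methods

## Model and conventions

The package works with the additive linear model `y = A x + e` for a
quantitative trait on `n` subjects and `p` SNP markers.

**Standardization.**  Each genotype column (minor-allele dosage 0/1/2) is
centered and scaled to unit variance under the population (1/n) convention,
so `‖A_j‖² = n` exactly for complete columns.  This is the unique convention
under which the coordinate-descent update
`x̂_j ← S(x̂_j + (1/n)A_j'r, λ)` is an exact minimization over coordinate j.
Missing genotypes are excluded from the centering/scaling statistics and
then set to exactly 0 (the column mean).  Mean imputation is the default;
binomial-MAF imputation was considered and not implemented as a separate
path because the two are indistinguishable for the quantities this package
measures at its problem sizes.  Monomorphic markers are rejected with an
error naming the marker — their standardized columns are undefined and the
matrix coherence diverges as MAF → 0, which is also why very rare markers
should be pruned before analysis.  One deliberate exception: when an
experiment subsamples subjects (`GenotypeMatrix.subsample`,
`run_experiment`, `mr_sweep`), a column that happens to be monomorphic
*within the subsample* is mapped to zeros rather than raising, since the
subsample is transient and a zero column is inert (never selected, marginal
p-value 1).  Each analyzed subsample is re-standardized so column norms stay
exact for the solver; standardizing once on the full matrix would differ by
O(1/√n).

**Phenotype simulation.**  Coefficients are drawn from one of two ensembles:
`signs` (all magnitudes 1, the {−1,+1} ensemble) or `hyperexponential`
(rank-i magnitude `exp(−i/τ₁) + exp(−i/τ₂)`, presets (τ₁, τ₂) = (0.05·s, p)
and (0.2·s, p)).  The hyperexponential ensemble is implemented as a
deterministic rank-indexed magnitude curve — the ordered-effect-size reading
— rather than i.i.d. draws from a two-component mixture density truncated to
the top s; both readings are defensible, and the deterministic curve makes
replicates comparable and the decay shape exactly reproducible.  Exactly
⌊s/2⌋ coefficients are flipped negative, chosen uniformly at random:
"half negative" as a hard constraint rather than fair coin flips, which
removes sign-imbalance variance at small s.  The breeding value `g = A x`
is rescaled so its empirical (1/n) variance equals the target h² *exactly*
(not merely in expectation); this makes the realized noise level, and hence
the theoretical terminal penalty, exactly reproducible per replicate.
Because rescaling g rescales the coefficients, the realization exposes the
effective vector `x` (what actually generated the data) and all
coefficient-error metrics compare against it.  Residuals are Gaussian; the
theory backing the penalty bound assumes sub-Gaussian noise, and
heritability-matched simulation never requires anything heavier.

**LD block generator.**  Real LD is block-diagonal-ish; the synthetic
stand-in uses contiguous blocks in which every marker is a perturbed copy of
a shared latent dosage: each entry is independently redrawn from
Binomial(2, maf) with probability `1 − √r`, giving pairwise correlation ≈ r
between block members.  Markers within a block share the block's MAF
(strong LD is only possible between markers of similar frequency).  This is
the simplest structure that reproduces near-diagonal LD bands; it does not
emulate long-range LD, MAF-dependent LD decay, or realistic haplotype
structure, so conclusions about real LD patterns should rest on real
genotype matrices loaded through the PLINK reader.

## Solver

Pathwise cyclic coordinate descent with the soft-threshold rule, objective
`f = (1/2n)‖y − Ax̂‖² + λ‖x̂‖₁`.  Coordinates are visited in fixed order
1..p; residuals are maintained incrementally.  Convergence at each λ is a
fractional objective change below `tol = 1e−4` over one full sweep
(denominator guarded by 1e−12); an optional active-set phase iterates over
the current support between full sweeps and is always certified by a final
full sweep, so it agrees with plain cyclic sweeps at the stated tolerance
(tested).  A sweep cap (default 10,000) flags rather than raises.  The λ
grid has 100 points, geometric, endpoints inclusive, from
`λ_max = (1/n)‖A'y‖∞` down to
`λ_min = (σ_E*/n)·median‖A'e‖∞`, `σ_E* = √(σ_E² + 1/n)`, with the median
taken over 1,000 standard-normal noise draws, recomputed per analyzed
(sub)matrix.  In the noiseless case σ_E* = √(1/n) keeps λ_min positive;
this is known to be conservative and is kept as-is.  `σ_E²` is a user
input — the true value in simulations, an external estimate on real data.
A tiny relative guard (1e−12) in the threshold comparison breaks
floating-point ties toward zero so that λ = λ_max returns the exactly-zero
solution regardless of BLAS accumulation order.  The kernel is numba-jitted;
the λ_min noise GEMM runs in float32 (the median of maxima is insensitive at
~1e−7 relative error).  Correctness anchors: closed-form single-coordinate
solutions, OLS at λ = 0, KKT conditions, a quadratic-programming oracle
(positive/negative splitting + L-BFGS-B), and an external cross-check against
R glmnet during development.

## Phase-plane machinery

`run_experiment` subsamples subjects without replacement, re-standardizes,
draws a model, simulates the phenotype, runs the path to the theoretical
λ_min with σ_E² = 1 − h², and scores the terminal support; replicates
(default 5, 3 in the large sweeps) use independent seed substreams and are
aggregated by medians.  Grid points use n = round(δ·p), s = max(1,
round(ρ·n)), with δ, ρ recomputed from the integers.

**Theoretical boundary.**  `theoretical_boundary` evaluates the asymptotic
weak threshold for signed sparse vectors under Gaussian sensing from its
Gaussian-integral representation
`ρ(δ) = max_{z≥0} [1 − (2/δ)F(z)] / [1 + z² − 2F(z)]`,
`F(z) = (1+z²)Φ(−z) − zφ(z)`, by bounded scalar maximization.  It is
validated in the tests against Monte-Carlo basis-pursuit recovery (linear
programming) on small Gaussian matrices rather than against any tabulation.

**Transition detection** formalizes verbal criteria:

- NE-based: the interpolated crossing of median NE through 0.5 — the
  largest ρ still below 0.5 along a ρ scan, or the first n below 0.5 along
  an n scan.  All-below scans are censored at the scan edge.
- μP-based: normalize the median-p-value trace by its maximum over the
  scan, then take the smallest n after the *last* downward crossing of a
  5% fraction — robust to the characteristic rise-then-fall of the
  μP-value (the penalty loosens as n grows, inflating selections in the
  poor phase before the transition collapses them).
- Plateau-based (for "measures stabilize"): the plateau level is the median
  of the last three grid medians, a point has reached it when within an
  absolute 0.05 band, and the onset is the smallest n after the last point
  outside the band.  A "within 5% of the maximum" rule was rejected because
  with 3-replicate medians a single one-false-positive wiggle near the scan
  end shifts the detected onset by a full grid step or more.

## Problem sizes

The library is exercised at three scales, chosen so each run measures the
scale-free quantities (critical ρ; transition n in proportion to s) sharply:
unit and property tests at p of order 10²–10³; the acceptance-style checks
in `tests/test_acceptance.py` at δ matched to the study design with
p ≈ 2,000–4,000 and s scaled in proportion (the transition coordinates
depend on p only through log p, which is the point being tested); and
`scripts/acceptance.py` at the full study design, p = 8,027 with n up to
8,000 and 3 replicates per grid point.

## Known limitations

- The phase-plane claims are demonstrated on independent-column synthetic
  matrices; real genotype data add LD, relatedness and population structure
  that the block generator only caricatures.  Passing tests show the method
  and machinery behave as the theory predicts on such matrices, not that any
  particular real dataset is in the favorable phase.
- The terminal-λ lasso estimate is deliberately not debiased; its NE
  therefore includes the full soft-threshold shrinkage λ per active
  coordinate.  With noise this shrinkage bound, `NE ≳ λ_min·√(s/h²)`, can
  dominate the coefficient error even while *selection* (PPV, FPR,
  μP-value) is essentially perfect — which is exactly the
  selection-before-fitting separation the package is built to exhibit.
- Covariate adjustment, dominance/epistasis, binary traits, elastic-net and
  Bayesian shrinkage variants, and genomic-control corrections are out of
  scope.
- Cross-validated penalty selection is provided for comparison but costs a
  factor k in compute; the theoretical bound is the default throughout.
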