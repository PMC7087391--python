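# Methods

## Model

Phenotypes are modeled as `y = 1μ + Xa + e` with a flat prior on the
general mean (the only fixed effect), `e ~ N(0, Iσ²ₑ)`, and the BayesCπ
spike-and-slab prior on marker effects: `a_j = 0` with probability `π`,
else `a_j ~ N(0, σ²ₐ)` with a common slab variance.  Priors:
`σ²ₑ ~ νₑS²ₑχ⁻²(νₑ)`, `σ²ₐ ~ νₐS²ₐχ⁻²(νₐ)`, `π ~ Uniform(0,1)`.  Here `π`
is the *null-effect* probability, so the inclusion-count conditional is
`π | m ~ Beta(p − m + 1, m + 1)` with `m = Σδ_j` included markers.

The conditional for a single effect, given everything else, is
`N(r_j/(c_j + σ²ₑ/σ²ₐ), σ²ₑ/(c_j + σ²ₑ/σ²ₐ))` with `c_j = X_j'X_j` and
`r_j = X_j'(y − 1μ − Σ_{j'≠j}X_{j'}a_{j'})`.  The indicator is drawn from
its marginal odds with the effect integrated out:

```
ℓ_j = −½ log((c_j σ²ₐ + σ²ₑ)/σ²ₑ) + r_j² σ²ₐ / (2σ²ₑ(c_j σ²ₐ + σ²ₑ))
P(δ_j = 1) = (1−π) e^{ℓ_j} / ((1−π) e^{ℓ_j} + π)
```

computed in log-odds form with a ±700 clip to avoid overflow.  A unit test
checks this closed form against numerical integration of the two marginal
likelihoods.

## Conventional sampler: two computational variants

Variant I keeps the length-`n` residual `e = y − 1μ − Xa` current
(O(np) time per iteration, O(np) memory); variant II works entirely from
the precomputed crossproducts `X'X`, `X'y` (O(p²) time, O(p²) memory) and
reconstructs `e'e` algebraically for the variance update.  Both variants
consume pre-drawn uniform/normal arrays in the same order, so given one
seed they produce the same chain up to floating-point roundoff — this
equivalence is asserted in tests.  Markers are updated in ascending index
order (fixed, not randomized) to keep that comparison meaningful.  The
maintained residual of variant I is audited against a fresh
`y − 1μ − Xa` every 1000 iterations (tolerance 1e-6) and the audit
failure is a hard error.  The inner sweep is compiled with numba; a pure
Python fallback with identical semantics runs if numba is unavailable.

## Orthogonal data augmentation

`d` is the largest eigenvalue of `W_o'W_o` plus a jitter of 0.001
(configurable).  `M = I·d − W_o'W_o` is factored by Cholesky
(`W_a = L'`); because `M`'s smallest eigenvalue equals the jitter by
construction this succeeds in practice, but a symmetric-eigendecomposition
fallback clamps eigenvalues in `[−1e-8·d, 0)` to zero and errors (naming
the offending eigenvalue, suggesting a larger jitter) below that.  Any
`W_a` with `W_a'W_a = M` yields the same posterior; the Cholesky
orientation is fixed for reproducibility.  Orthogonality is quantified as
`max |offdiag(W_c'W_c)| / d` and must stay below 1e-6.

The grouped variant partitions markers into contiguous blocks
(default 1000) and orthogonalizes each block's columns with its own
`d_i`; cross-group columns stay correlated, so groups are processed
sequentially with a residual-carried right-hand side while all effects
*within* a group are drawn independently.  In the grouped model there is
no augmented intercept row: `μ` is drawn from its observed-data
conditional, and the residual-variance update has `νₑ + n + p` degrees of
freedom (the `p` augmented rows).

## Augmented (BayesXII) sampler

Per iteration: (1) draw `μ` and all `a_j` from their mutually independent
conditionals (the only per-iteration data dependence is `X̃'ỹ`, one
(p+1)×(p+1) matrix-vector product); (2) refresh `ỹ ~ N(J̃μ + X̃a, Iσ²ₑ)`;
(3) update variances and `π`.  The residual-variance conditional uses both
residual blocks, `σ²ₑ ~ (νₑS²ₑ + e'e + ẽ'ẽ)/χ²(νₑ + n + p + 1)` — the
degrees of freedom follow from reading the augmented rows as part of one
joint model with `[e; ẽ] ~ N(0, Iσ²ₑ)`, and a Kolmogorov–Smirnov test
pins the implementation to exactly that scaled inverse-χ² law.  The
indicator rule reuses the conventional likelihood ratio with `c_j`
replaced by `d` and `r_j = X_j'y + X̃_j'ỹ`; this extension (the augmented
model's own single-site rule applied to orthogonal columns) is validated
by the posterior-equivalence tests against the conventional sampler and
the closed-form conjugate oracle.  `ỹ` is initialized at its conditional
mean `J̃μ₀ + X̃a₀`.

`e'e` is computed from crossproducts via the identity
`X'X = I·d − X̃'X̃` (exact up to the orthogonality defect, < 1e-6·d), so
each iteration is O(p²) regardless of `n` — the point of the method.

Randomness is keyed per `(seed, chain, iteration)`; worker threads map
over fixed 512-row tiles of the matvecs.  Because the tiling, not the
worker count, defines the arithmetic, any `workers` value gives
bit-identical chains; tests assert `workers=1` equals `workers=4`
exactly.  This makes "parallel" a testable contract rather than a
wall-clock claim; multi-node message-passing execution is out of scope.

## Starting values and default hyperparameters

Chains start from dispersed marker effects
`a_j ~ N(0, σ²ₐ⁰)` with `σ²ₐ⁰ = σ²_g / ((1−π) Σ 2p_i(1−p_i))` (the
standard partition of genetic variance across included markers), all
indicators included, `μ = ȳ`, and `σ²ₑ⁰ = var(y)(1 − h²-guess)`.
Defaults: `νₑ = νₐ = 4`, `S²ₐ = σ²ₐ⁰`, `S²ₑ = var(y)(1 − h²-guess)` with
an h²-guess of 0.5 when no estimate is supplied — the conventions of the
GenSel/JWAS family of genomic-prediction software.  Chain `c` of a run
draws from stream `(master_seed, c)`, so multiple chains have distinct
starting values and paths by construction.

## Synthetic data generator

The generator emulates the classical benchmark design for these samplers:
founders → long random mating → expansion → QTL trait.  Defaults are the
benchmark's own constants (100 founders, 100 generations, expansion to
60,000, ~42,000 loci, 5% QTL, genetic variance 1.0, h² = 0.3,
50,000/10,000 split); tests and the acceptance script use smaller
configurations (20 generations, 200–1000 loci, cohorts of 700–5200) so
everything runs in minutes on one CPU.

Design choices where the benchmark design is underspecified:

* **Founders are synthetic**, not real phased haplotypes: per-locus
  allele frequencies `~ Uniform(0.05, 0.95)`, haplotype alleles Bernoulli
  at linkage equilibrium.  LD then accrues through generations of drift at
  small constant size, which is the feature of real data the samplers are
  sensitive to.
* **Recombination**: crossover count per chromosome `~ Poisson(length in
  Morgans)`, positions uniform, no interference, no mutation, no
  selection; genome of 10 × 1 Morgan chromosomes with evenly spaced loci
  (all configurable).
* **QTL scaling is exact**: effects are N(0,1) multiplied by one scalar so
  the population variance (denominator `n`) of `X_qtl·effects` over the
  final generation equals the target exactly; rescaling is idempotent.
* **Monomorphic loci are dropped** (based on training-set frequency), not
  carried as zero columns, because the single-site conditional divides by
  `X_j'X_j`.  Test matrices are centered with training means.

What the generator does **not** emulate: real LD structure from a specific
genome, minor-allele-frequency spectra shaped by mutation/selection,
non-additive effects, population structure or pedigree.  Passing tests
therefore show sampler correctness and calibration on drift-LD additive
architectures, not performance claims for any real population.

## Diagnostics

PSRF follows the classic two-stage formula: `W` = mean within-chain
variance, `B = n·var(chain means)`, `V̂ = ((n−1)/n)W + B/n`,
`PSRF = √(V̂/W)`, floored at 1.0 (the unfloored statistic falls below 1
when `B ≈ 0` because `V̂` underestimates the stationary variance).
Convergence is declared at `PSRF(σ²ₐ) < 1.1`, computed after a default
20% burn-in.  Prediction accuracy is the Pearson correlation of test-set
EBVs with mean-adjusted phenotypes (`y_test − μ̂`; the general mean is the
model's only fixed effect).  Between-sampler agreement is the Pearson
correlation of the two methods' test-set EBV vectors, each from
posterior-mean effects after burn-in.

## Convergence vs sample size: a caveat

The augmented sampler needs more iterations than the conventional one,
and fewer as `n` grows at fixed `p` — the latent block carries `p+1`
pseudo-observations whose weight shrinks relative to the data.  The
package measures this as iterations until the augmented sampler's
test-set EBVs correlate ≥ 0.99 (sustained over two consecutive 250-
iteration checkpoints) with a converged conventional reference.  At
`p = 1000` this decreases sharply from `n = 1000` to `n = 5000` in every
replicate.  It does **not** decrease from `n = 200` to `n = 1000`: in the
strongly under-determined regime (`n ≪ p`) both samplers' EBVs are
shrinkage-dominated and highly correlated almost immediately, so the
fixed-threshold crossing happens early for reasons unrelated to mixing
speed, while `n ≈ p` is the genuinely hardest regime for both samplers.
The monotone-decrease test in the acceptance suite reflects the idealized
expectation and currently fails at that first step; the measured rank
averages and this interpretation are the package's honest account of the
effect at desk scale.

## Numerical and degenerate-input policy

64-bit accumulation throughout; crossproducts formed once from the
centered matrix.  Monomorphic columns, empty marker groups, non-partition
groupings, non-finite design entries, `h² ∉ (0,1)`, oversized train/test
splits, and augmentation/genotype mismatches (marker count or provenance
hash) all raise immediately with specific messages.  A chain aborts with
its iteration index if any sampled state becomes non-finite.  Zero
variance on either side of a correlation yields NaN with a warning rather
than an exception.
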