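# Methods

## Model and assumptions

`spermsel` simulates one breeding season of a closed population with an equal
sex ratio in which fertilization success is biased by the morphological fit
between a male's sperm size and a female's sperm-storage-organ size — a
mechanism of cryptic female choice. The assumptions are deliberately minimal:

- Copulations are random with respect to both traits; mating itself carries no
  selection. Every egg is fertilized, so the preference is selectively neutral
  for females.
- All ejaculates contain equal sperm numbers, each pair copulates once, and
  there is no precedence by copulation order; a male's success with a female
  depends only on his fit score *relative to her other partners*.
- One generation: trait values are drawn fresh each replicate (no inheritance,
  no evolution across seasons).

Traits live on a common standardized scale. Sperm size y ~ N(mu_M, sigma_M^2)
across males, storage-organ size x ~ N(mu_F, sigma_F^2) across females; draws
are never clipped. The fit score is the Gaussian preference
U(x, y) = exp(-(x - y)^2 / (2 sigma_U^2)), maximal when sperm exactly match
the organ; all females share the same preference *function* but differ in
their preferred phenotype because the function is self-referential.

## Simulation procedure

1. **Population.** Draw n_males sperm sizes and n_females organ sizes
   (defaults 200/200, mu_F = mu_M = 0, sigma_M = sigma_U = 1).
2. **Mating.** n_partners rounds; each round is a uniform random permutation
   pairing females to males, redrawn in full whenever any female would
   receive a male she already has. Every female thus gets n_partners distinct
   males and every male n_partners distinct females. Redraws are generated in
   batches (ranking i.i.d. uniforms row-wise), which leaves the law — a
   uniform permutation conditioned on avoiding all previous pairs — unchanged.
   The per-round redraw cap defaults to 200,000 because the expected redraw
   count in the last of 10 rounds at 200x200 is already ~e^9 ~ 8,000; the cap
   exists only to catch infeasible configurations.
3. **Fertilization.** For each female, each of her eggs_per_female eggs
   (default 5) independently draws a sire among her partners with probability
   proportional to his fit score — a loaded raffle, draws with replacement
   across eggs. Drawing eggs independently is the natural reading of a raffle
   repeated per egg, and with 1–2 partners and 5 eggs replacement is forced in
   any case; a single multinomial draw would be operationally identical.
4. **Selection gradients.** Offspring counts are divided by their mean
   (relative fitness w; the mean is fixed at eggs_per_female x
   n_females / n_males by egg conservation), sperm size is standardized to
   the *realized* sample mean 0 and sample SD 1 (n-1 denominator), and w is
   regressed by OLS on z and z^2. The raw z^2 coefficient is reported as the
   quadratic gradient gamma — no doubling is applied, matching the
   extract-the-coefficient convention rather than the doubled
   stabilizing-selection variant; the choice rescales gamma by a constant and
   affects no sign or regime conclusion. With constant fitness (always the
   case at n_partners = 1, where every male sires exactly one clutch) there
   is no selection and both gradients are returned as exact zeros rather than
   lstsq float residue.

## Experiment and effect sizes

The factorial design crosses sigma_F in {0.5, 1, 1.5, 2} with n_partners in
{1, 2, 3, 5, 10}, 1000 replicate populations per cell. Each condition is
summarized by the median and the empirical 2.5%/97.5% quantiles of gamma
(linear interpolation of order statistics; the probabilities are exposed as
an option). Effects are quantified by classical eta-squared
(SS_effect / SS_total) from a balanced two-way fixed-effects ANOVA with both
predictors categorical and an interaction term — classical rather than
partial, so the three effect shares plus the residual share sum to 1. In a
balanced design sequential and marginal sums of squares coincide; the ANOVA
is fitted with statsmodels and checked in the tests against an explicit
cell-mean sums-of-squares decomposition. Effect sizes are reported instead of
p-values because replicate count is arbitrary; eta-squared estimates a ratio
of variance components that does not drift with the number of replicates,
which is why a reduced run gives nearly the same values as the full design.

## Analytical model

When every female samples every male, the raffle's normalizer becomes
V(x) = integral M(y) U(x, y) dy — the total fit score female x assigns to the
male population — and a male of size y obtains relative success
R(y) = integral F(x) U(x, y) / V(x) dx. Both are Gaussian integrals:

    V(x) = sigma_U / sqrt(sigma_M^2 + sigma_U^2)
           * exp(-x^2 / (2 (sigma_M^2 + sigma_U^2)))
    R(y) = (sigma_M^2 + sigma_U^2) / sqrt(K)
           * exp(-y^2 (sigma_M^2 + sigma_U^2 - sigma_F^2) / (2 K)),
    K    = sigma_F^2 sigma_M^2 + sigma_M^2 sigma_U^2 + sigma_U^4 > 0.

The implementation treats the defining integrals as the source of truth: the
closed forms above are verified against adaptive quadrature
(`numerical_total_fit`, `numerical_relative_success`, scipy QUADPACK,
integration spans covering at least 10 SDs of every Gaussian involved, error
raised on non-convergence) and against the exact normalization
integral M(y) R(y) dy = 1. The sign of d = sigma_F^2 - (sigma_M^2 + sigma_U^2)
classifies the regime: bell-shaped R with R(0) > 1 (stabilizing) for d < 0,
R identically 1 (no selection) at d = 0, U-shaped R with R(0) < 1
(disruptive) for d > 0. Exact equality is measure-zero in floats, so the
"none" call uses a tolerance |d| <= 1e-12 by default, exposed as
`AnalyticalParams.none_tol`.

## Variants

- `winner_take_all`: one weighted draw sires a female's whole clutch.
- `storage_threshold` in [0, 1): partners with fit score below the cutoff are
  treated as not stored and excluded from the raffle. If *all* of a female's
  partners fall below the cutoff her eggs are fertilized by a uniform raffle
  among them, preserving the all-eggs-fertilized assumption.
- Asymmetric promiscuity: `n_partners_female` / `n_partners_male` (given
  together, with n_females*n_partners_female == n_males*n_partners_male) are
  realized by shuffling male copulation stubs and dealing them to females,
  whole deal redrawn on any within-female duplicate. This gives exact
  copulation counts on both sides; at high degree the duplicate probability
  makes rejection slow, so the variant is intended for the low-promiscuity
  settings it exists to explore.
- Unequal trait means (mu_F != mu_M) are exposed for drift-style
  explorations; defaults are equal.
- Pure floating-point underflow of every weight in a row (|x - y| >> sigma_U)
  triggers a uniform-raffle fallback with a RuntimeWarning: the raffle needs
  a positive total, and relative fit is undefined when all weights are
  identically zero.

## Randomness and reproducibility

All randomness flows from one master seed. Replicate r of grid cell c uses
`default_rng(SeedSequence(master_seed, spawn_key=(c, r)))`, so any replicate
is reproducible in isolation and replicate-level parallelism cannot change
results; the gradients table is bitwise-reproducible from the manifest
(config snapshot, master seed, seed scheme, package version). Output tables
are TSV with floats at %.17g, which round-trips IEEE doubles.

## What the generator does and does not emulate

The simulator *is* the study system: it generates the exact conditions the
analysis targets (i.i.d. Gaussian traits, equal ejaculates, single-once
copulations, complete fertilization). Real populations violate several of
these — sperm numbers and copulation order matter empirically, preferences
may be open-ended, storage organs vary within females, and traits are
heritable across generations. Passing tests therefore demonstrate the logic
of the fit-based cryptic-choice mechanism under its own assumptions, not that
any particular taxon follows it.

## Problem sizes and numerical choices

The test suite runs the factorial design at 250 replicates per cell, enough
that the eta-squared estimates are stable (they match the 1000-replicate
values to well within the stochastic tolerances used); the acceptance script
runs the full 1000. The quantile at the knife-edge condition
(sigma_F = 2, 10 partners) deserves a caveat: the population 2.5% quantile of
gamma sits within ~0.005 of zero there, so whether a finite run's interval
"excludes zero" is sensitive to Monte Carlo noise in a way the eta-squared
values are not.

Quadrature tolerances are epsabs = epsrel ~ 1e-12 (1e-13 for the inner
normalizer when R is integrated with a fully numerical V), chosen an order
below the 1e-8..1e-10 agreement the tests assert. OLS uses lstsq with the
default rcond; designs with fewer than three distinct trait values are
rejected as collinear rather than silently pseudo-inverted.

## Known limitations

- One breeding season only; no evolutionary feedback on trait distributions.
- The analytical model covers the all-males sampling limit, not finite
  partner numbers — the gap between the two is precisely the scientific
  point, but nothing interpolates between them here.
- The asymmetric-promiscuity rejection sampler is impractical at high degrees
  (see above); the symmetric scheme is efficient across the whole published
  grid.
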