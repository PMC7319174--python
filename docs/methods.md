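# Model and methods

`cicadasim` simulates competition between periodical-cicada life-cycle
lengths in a patch-structured population.  This note documents the model,
the parameter choices and their rationale, the numerical methods, and the
known limitations.

## The yearly life cycle

Each patch holds a pool of underground nymphs.  One simulated year applies
eight phases in fixed order:

1. **Growth.** Every nymph ages by one year, and any nymph below the target
   body size `s*` adds an increment drawn from a log-normal distribution
   `exp(N(mu, sigma^2))`.  Growth stops at the threshold (further growth is
   irrelevant to emergence).
2. **Emergence.** Nymphs that satisfy their phenotype's emergence rule move
   to the patch's adult pool: an age-based phenotype with cycle length `e`
   emerges at the first opportunity once `age >= e` *and* `size >= s*`; the
   size-based phenotype emerges the summer after first crossing `s*`.  A
   population-wide delay (below) blocks this phase entirely.
3. **Predation.** Each patch's emerging adults suffer density-dependent
   mortality under a Holling type II functional response (below).
4. **Migration.** Each surviving adult independently moves with probability
   `migration_prob` to a patch chosen uniformly at random (the origin patch
   included).  Migration is what couples the patches: stray adults mate in
   their destination patch.
5. **Reproduction.** Every adult is female; males are assumed present with
   genotype frequencies identical to the females.  Each female mates with
   one male drawn uniformly (with replacement) from her current patch's
   adult pool and produces exactly `fecundity` offspring.  An offspring
   receives one allele drawn uniformly from each parent; each transmitted
   allele mutates independently with probability `mutation_prob`.
6. **Adult death.** No adult survives its emergence year.
7. **Recruitment.** Newborns compete for underground feeding cells under a
   safe-site model (below) in the patch where they were produced.
8. **Delay update.** If no delay is active, a new population-wide delay
   starts with probability `p_delay`; an active delay counts down.  A delay
   drawn at the end of year `t` blocks emergence in years `t+1 .. t+d`;
   eligible nymphs keep growing and all emerge when the delay expires.  New
   delays cannot start while one is active.

A simulation starts with a burn-in (default 2,000 years) during which
migration and mutation are off, delays cannot start, and predator density
ramps linearly from zero over the first 1,000 years, so each patch settles
into demographic equilibrium before the patches interact.

## Genetics

One diploid locus.  An allele either codes for size-based emergence or for
age-based emergence with a fixed integer cycle length.  Size-based emergence
is dominant.  Two age-based alleles yield an age-based phenotype whose cycle
is the *average* of the two allele cycles, rounded up or down with equal
probability when the average is a half-integer.  This averaging makes
between-cycle matings produce hybrid offspring with an intermediate cycle —
the core mechanism of the study.  Mutation of an age-based allele yields the
size-based allele with probability 1/2, otherwise a one-year longer or
shorter cycle (equal odds; a one-year cycle cannot shorten).  Mutation of a
size-based allele yields an age-based allele with cycle drawn uniformly from
1–30.  The ±1 step is deliberately not capped at 30; the 1–30 range applies
only to the size-to-age mutation.

## Predation: Holling type II satiation

During one emergence season the emerging density `n` obeys
`dn/dt = -a p n / (1 + a h n)` with predator density `p`, attack rate `a`
and handling time `h`.  Per-capita survival is `s = n(1)/n(0)`; separation
of variables gives the implicit equation

    ln(s) + a h n0 (s - 1) = -a p,

solved by safeguarded Newton iteration bracketed on `[exp(-a p), 1]` with a
residual tolerance that scales with the conditioning term `a h n0` (a fixed
absolute tolerance is unattainable when `a h n0 ~ 1e7` because of rounding
in the linear term).  Survival rises from `exp(-a p)` for a vanishing group
to 1 for an arbitrarily large one — safety in numbers.  Each adult then
survives by an independent Bernoulli trial at the patch-wide `s`.

## Recruitment: the safe-site model

Established nymphs are invulnerable; each newborn lands in a random feeding
cell among `N` per patch and, if the cell is empty, wins it against
`k ~ Poisson(N0/N)` co-arriving newborns with probability `1/(k+1)`:

    P_est = (1 - N1/N) * sum_{k=0}^{N0-1} e^{-lam} lam^k / k! * 1/(k+1),
    lam = N0/N,

and `P_est = 0` once more than `N` nymphs are established.  The truncated
sum is evaluated exactly through the Poisson-CDF identity
`sum = (F(N0; lam) - e^{-lam})/lam`; the untruncated closed form
`(1 - N1/N)(1 - e^{-lam})/lam` serves as an independent oracle in the test
suite.  Establishment is decided per newborn, so the pool can transiently
exceed `N`.  Because recruitment saturates (`R ≈ N(1 - e^{-lam})`), patch
totals fluctuate tightly around `N`.

## Execution strategies: per-individual and cohort engines

The reference engine (`mode="individual"`) stores every nymph explicitly
and decides everything with per-capita draws.  The production engine
(`mode="cohort"`) exploits exchangeability: a nymph's future depends only on
its genotype class and the first year it becomes eligible to emerge, so
nymphs are aggregated into cohorts keyed by `(alleles, phenotype,
emergence_year)`.

* Growth is replaced by one multinomial draw per recruited group from the
  exact first-crossing-age distribution of the cumulative log-normal
  process, computed by numerically convolving the sub-threshold size
  density on a 4,096-point grid (crossing ages are i.i.d. across nymphs,
  so this is an exact distributional substitution up to grid resolution,
  which matches direct simulation to ~3e-3).
* Bernoulli thinning (predation, recruitment) becomes binomial draws on
  class counts; uniform choices (migration targets, mate choice, allele
  transmission, phenotype rounding) become multinomial/binomial draws.
* For mating, adult classes differing only by phenotype are merged first —
  mate choice and transmission depend on alleles alone.

Every substitution is an exact distributional equivalent of the per-capita
rule; the test suite verifies the two engines are statistically
indistinguishable (two-sample Kolmogorov–Smirnov on replicate distributions
of total emergence and final population size, 200 replicates per engine).

## Coemergence trials (schedule-only)

The companion analysis strips demography away: each cycle is reduced to its
emergence calendar over a horizon, delays are overlaid with mechanics
identical to the engine (geometric inter-delay gaps of at least `d+1`
years; blocked emergences move to the delay's end year and the cycle's
phase resets there), and coemergence is calendar-year equality of at least
two cycles' emergence events.  With a common starting age the coemergence
years of two cycles are exactly the multiples of their least common
multiple — the arithmetic root of the prime-cycle advantage.

With independent random starting ages a cycle `c` emerges in any given year
with probability `1/c`, so its event-level coemergence probability has the
closed form `1 - prod_{j != c}(1 - 1/j)`, which for the 10–20 cycle set is
`1 - 0.45 c/(c-1)` (0.500 at c=10 up to 0.526 at c=20).  The spread is
driven purely by each cycle's exclusion of itself from "the others" and has
nothing to do with primality: the nonprime-minus-prime contrast is zero to
Monte-Carlo precision.  The test suite asserts the closed form.

## Parameters

All defaults live in `src/cicadasim/defaults.yaml` and can be overridden by
a user YAML file or keyword arguments.

| parameter | default | meaning and rationale |
|---|---|---|
| `N` | 10,000 | feeding cells (carrying capacity) per patch |
| `cycle_lengths` | 10–20 | one founding cycle per patch; brackets the 13/17-year cycles of *Magicicada* |
| `initial_fill` | 0.9 | founders per patch as a fraction of `N`; near-capacity start |
| `growth.mu`, `growth.sigma` | ln(0.15)−0.045, 0.3 | mean annual increment 0.15 ⇒ threshold reached in ~7 years, >99.9% by age 10, so all 10–20-year cycles stay strictly periodic |
| `growth.size_threshold` | 1.0 | target body size `s*` (arbitrary scale) |
| `fecundity` | 4 | female offspring per female, deterministic |
| `mutation_prob` | 1e-4 | per transmitted allele |
| `migration_prob` | 0.25 | per surviving adult; see calibration below |
| `predation.a, h, p` | 1.0, 0.01, 4.0 | calibrated so a lone small group (≤1% of `N`) suffers ≥90% mortality (s(100)≈0.047) while a full resident emergence (~`N`) suffers ≤10% (s(10,000)≈0.96) |
| `predation.ramp_years` | 1,000 | linear predator ramp during burn-in |
| `burn_in_years` | 2,000 | migration/mutation off, delays off |
| `main_years` | 50,000 | full-scale experiment length |
| `p_delay`, `d` | 0, 10 | delay probability per year and delay length |

**Calibration of the migration rate.**  Because recruitment saturates,
resident patches are extremely robust: the hybrid load a coemergence
imposes on a resident population scales like `2·migration_prob/n_patches`,
and below about `migration_prob = 0.2` no invasion ever occurs — the
metapopulation freezes in its initial configuration regardless of starting
ages, which contradicts the regime this model is built to explore
(synchronized subpopulations must be able to displace one another through
hybridization while randomly phased ones remain stable).  The default is
the smallest probed rate (grid 0.1/0.15/0.2/0.25/0.3/0.5) that robustly
produces that regime pair: at 0.25 common-start runs end in fixation of one
cycle while random-age runs keep at least nine of eleven founders; at 0.5
even random-age runs destabilize.  The calibration used only these regime
diagnostics and was frozen before any quantitative comparisons.

## Measurement conventions

* **Prime-cycle proportion**: fraction of individuals whose *phenotype*
  cycle length is prime (11, 13, 17, 19 within 10–20); size-based
  phenotypes count as nonprime.
* **Genotype class**: heterozygote means two unequal alleles (including
  SIZE/AGE pairs).
* **Mortality by class**: total deaths over total emergence size within the
  measurement window — from migration onset (or from the first delay, in
  delay scenarios) until the patch's founding cycle loses plurality or the
  run ends.  Ties in the plurality test count as held.
* **Fixation**: a single phenotype holds ≥99% of all individuals at the end
  of a run.
* Patch composition is recorded as a step function (a census record per
  change year), which the time-averaged heterozygote proportions and the
  invasion detector consume with exact year weighting.

## Problem sizes

Full-scale experiments (30 replicates × 50,000 post-burn-in years) are what
the defaults describe and run in a few hours on one core.  The packaged
acceptance script and the end-to-end tests replay each experiment at 10
replicates × 20,000 post-burn-in years, which preserves every qualitative
regime; the delay scenarios see proportionally fewer delays (about two at
`p_delay = 1e-4`), so their averages are noisier than the full-scale ones.

## What the synthetic scenarios do and do not show

The simulations are a theoretical experiment, not a fit to field data: all
patches share identical `N`, predator pressure and growth conditions, and
"years" have no climate variability beyond the delay mechanism.  Passing
tests demonstrate that the hybridization mechanism behaves as designed
(hybrids emerge out of phase, in small numbers, and are predated
disproportionately; delays partially synchronize the population and tip
competition toward prime cycles).  They do not calibrate absolute rates to
real *Magicicada* demography — the growth, predation and migration
constants are order-of-magnitude stand-ins chosen by the regime criteria
above.

## Known limitations

* Nymphs never die underground except by failing to establish; there is no
  age-dependent underground mortality.
* Predator density is exogenous (no predator population dynamics).
* The density scale of the predation ODE is raw adult counts on a common
  patch area; `a` and `h` must be recalibrated if `N` changes materially
  (the test fixtures do so).
* Clonal mode copies the mother's genotype but still applies mutation when
  `mutation_prob > 0`, and re-resolves the phenotype from the genotype
  (distributionally identical to inheriting the mother's rounding draw).
* The per-individual engine is intended for small instances; the cohort
  engine is the production path.
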