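# Methods

This note documents the modelling assumptions, numerical choices and known
limitations behind `inclufit`.  It is written for users who want to know
exactly what the toolkit computes and what passing its tests does and does
not establish.

## The model

An inclusive-fitness model here is a declarative object: a class structure,
one actor, a list of primary deviations, a set of consanguinity
coefficients, and one compensation pool per deviation.

**Reproductive value is a fixed total.**  Each class `X` holds a fraction
`c_X` of it (`Σ c_X = 1`) and contains `u_X` individuals, so the normal
per-capita share is `c_X/u_X`.  Within a class, an individual's share scales
with its competitive ability relative to the class mean
(`allocate_shares`).  Because the total is fixed, a primary fractional
change `δw/w` in one participant's share forces an equal-and-opposite
change spread over its within-class competitors.  The toolkit generates
those secondary terms automatically; the caller never writes them, and the
unweighted primary + secondary change is exactly zero per class and episode
by construction.

**Weighting by kinship.**  Each change is weighted by the actor's
consanguinity `R` with the affected party (probability of identity by
descent, drawing with replacement for the self-coefficient:
`R_ii = 1` haploid, `(1+f)/2` diploid).  Net effect and bracketed effect are
related by the leading factor `R_ii − R_ik`; per-recipient relatedness is
`r = (R_ij − R_im)/(R_ii − R_ik)`, which can be negative (spite) and is
exactly zero when a recipient is as related to the actor as its compensator
pool is — the formal statement that kin competition can cancel kin benefit.

**First order only (δ-weak selection).**  Deviations are assumed small;
assembly never multiplies two deltas.  Consequences: effects are exactly
linear in the declared deltas (asserted as a property test, exactly for
binary scalings and to 1e-12 otherwise), synergistic payoffs do not appear
at first order, and the effect is entirely a property of the actor (actor
control), which is what licenses reading it as a quantity the actor
maximizes.  Episode labels order deviations in time but carry no
discounting; where a later episode uses different (primed) class weights,
the deviation can carry an explicit per-episode weight override — the type
admits this because the general theory leaves open whether the primed
episode's class weights coincide with the unprimed ones.

**Degenerate inputs.**  `R_ii = R_ik` makes relatedness 0/0 and raises
`UndefinedRelatednessError`.  A negative leading factor is reported with a
`RuntimeWarning` rather than an error, with the effect still computed, since
the sign convention is then inverted but the arithmetic is well defined.
The verdict uses a configurable equilibrium band (default `1e-9` on the
effect scale) because the theory's "zero" is exact algebra evaluated in
floating point.

## Demography

Class sizes `u` are the dominant right eigenvector of the projection matrix,
per-capita reproductive values `v` the dominant left one, and
`c_X ∝ u_X v_X` — equivalently, `c_X` is the probability that the ancestor
of a random distant-future gene sits in class `X` today (the test suite
checks this against an independent backward ancestry Markov chain).  The
eigenpair is computed by deterministic power iteration from the uniform
vector to tolerance 1e-12, which guarantees the positive eigenvector and
bit-reproducible output; primitivity is checked via Wielandt's bound on the
boolean pattern.  Users can also supply `c` and `u` directly ("open"
models) — this is how a post-reproductive class with `c = 0`, whose Leslie
matrix would be non-primitive, is expressed.

## Consanguinity

Pedigree coefficients are computed by recursion over gene transmissions in
explicit pedigrees (diploid and haplodiploid; haplodiploid males transmit a
random maternal allele), not from a lookup table; founders carry a base
cross-kinship equal to the supplied inbreeding coefficient `f`.  Island
coefficients use the standard infinite-island recursion
`F' = (1−m)² [1/n + (1−1/n) F]` with haploid-gamete bookkeeping, iterated
from `F = 0` to 1e-12 (the closed form is kept as a cross-check, not as the
implementation).  Coefficients assume no mutation and no deviant behaviour.
Whether a pool includes the focal individual is always the caller's choice,
encoded in the weights passed to `pool_consanguinity`; helpers cover the
include-self and exclude-self patch pools.

## The cross-check oracle

The neighbour-modulated route evaluates
`Σ_classes weight × [∂w/∂x + r ∂w/∂y]` at `x = y = z = t` by central
differences with one Richardson refinement (default `h = 1e-5`; the
refinement is verified to suppress the `O(h²)` truncation term).  The
relatedness the oracle uses is produced by the consanguinity module from the
same demographic inputs as the inclusive-fitness model — shared primitives
*below* the level being tested, so the two routes can disagree if either
assembly is wrong.  `cross_check` passes when signs agree at every grid
point outside a noise band (default 1e-9, which also masks points where one
curve is pure floating-point noise) and, when either curve crosses zero,
when the two bisection ESS estimates agree to 1e-6.  A crossing seen by only
one route fails.  ESS solving is plain bisection to 1e-10: slow but
monotone, derivative-free and reproducible.

## Simulator

Haploid clonal Wright–Fisher island model: `P` patches of `n` breeders,
fecundity perturbed by the social payoff times a small trait step
`delta_trait`, offspring dispersal with probability `m` (migrants land
uniformly over all patches), and local regulation by sampling `n` breeders
per patch in proportion to parental fecundity.  Within a patch individuals
of the same type are exchangeable, so the state is the per-patch mutant
count and the per-generation update is a vector of binomial draws; all
replicates advance in lockstep from one seeded generator, making runs
bit-reproducible.  Fixation probabilities carry 95% Wilson intervals, and
the invasion test is three-valued: agreement, contradiction, or
inconclusive when the interval straddles `1/N` (underpowered runs are never
counted as failures).  Default problem sizes in the tests (100 breeders,
10,000 replicates, trait step 0.01) were chosen so that the favoured and
disfavoured helping cases sit several intervals away from neutrality while
a full run completes in seconds.

What the simulator emulates — and what it does not: it realizes exactly the
inelastic island demography the analytic models assume (fecundity selection,
non-overlapping generations, infinite-allele-free clonal transmission), so
agreement validates the sign logic of the assembly, not the realism of any
particular organism.  Diploidy, overlapping generations, finite-patch
corrections beyond those the model itself induces, and elastic patch output
are not simulated; the elastic analytic models are validated against the
neighbour-modulated oracle only.

## Gallery design choices

Each worked model is built from the canonical formulation of its phenomenon
and validated by the two internal oracles.

* **Synergy**: the bonus `D` applies only when both interactants deviate;
  the NM twin writes it as `D(x−z)(y−z)` so that it vanishes upon
  differentiation at the resident point, mirroring its first-order
  invisibility in the assembly.
* **Viscous helping**: benefits go to a random patch-mate (or, optionally,
  to the whole patch as a public good — the variant used for simulator
  validation because its invasion threshold `B/n = C` has two accessible
  sides).  In the inelastic case the compensator pool is local with weight
  `(1−m)²`, i.e. `R = (1−m)²[R_ii/n + (1−1/n)F]`; at equilibrium that
  expression *is* the island recursion, so the pool coefficient is set equal
  to `F` itself.  Using the identity keeps the cancellation exact instead of
  leaving an `O(iteration-residual)` relatedness, which matters near `m = 0`
  where `1 − F` itself is of the residual's order.  The `m = 0` corner is
  degenerate in the strict equilibrium sense (`F → 1`); the reported effect
  there is the `m → 0⁺` limit, which the structural cancellation reproduces
  exactly (effect `−C`, independent of `B`).
* **Age-class altruism**: two-age Leslie demography; both deviations
  compensated globally within their own age class; relatedness enters as
  `R_ij/R_ii`.
* **Sex ratio under local mate competition**: diploid mothers, sons mating
  locally, mated daughters dispersing; converting a daughter into a son is
  expressed as three deviations (a son appears, a daughter disappears, and
  her matings are withdrawn from the patch's sons at a later episode, worth
  `x/(1−x)` son-shares).  Sons and daughters each carry half the total
  reproductive value; mothers appear as a zero-`c` bookkeeping class that
  anchors the actor's own (global, unrelated) compensator pool.  The
  two-episode mapping of the mating-market consequence is this package's
  reconstruction of the standard argument; its ESS matches the classical
  `(n−1)/2n` and the Taylor–Frank twin to 1e-6, which is the criterion we
  rely on.  The haplodiploid variant is deliberately deferred: it requires
  committing to an inbreeding bookkeeping that the diploid case avoids.

## Fixtures and the reference evaluator

Property tests run against seeded random models produced by
`generate_fixture` (1–3 classes, up to 4 deviations, coefficients in valid
ranges, actor pool kept strictly less related than the actor).  Each fixture
ships a sidecar effect computed by `reference_effect`, a deliberately
straight-line expansion of the net primary+secondary sum divided by the
leading factor, kept separate from the core's per-recipient relatedness
assembly so that the two implementations check each other.

## Known limitations

* No classification of behaviours as altruistic/spiteful/selfish/mutualistic:
  the bracketed effect does not separate direct from indirect components in
  a way that supports such labels.
* No genotype-frequency dynamics, stable polymorphisms, allele associations
  or branching-point (second-order stability) analysis; the ESS reported is
  a first-order optimum only.
* Non-additive (large-deviation) interactions are out of scope by design;
  the toolkit will accept any finite delta arithmetically but its answer is
  the first-order one.
* Consanguinity coefficients are identity-by-descent probabilities without
  mutation; regression relatedness under strong inbreeding is not
  implemented — the core consumes exactly the coefficients it is given.
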