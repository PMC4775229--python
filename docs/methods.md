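# Methods

## Life cycle and aggregation process

One generation consists of an aggregation phase (AP), a reproduction phase
(RP) and a dispersal phase (DP).  In the AP the population is partitioned
uniformly at random into patches of `T` individuals.  Within a patch a single
recruiter is drawn uniformly; every other individual gets exactly one chance
to attach to it, with probability `p(z₁, z₂) = √(z₁ z₂)`.  Each patch
therefore yields at most one group (recruiter plus joiners) and a complement
of singletons; a recruiter nobody joined is classified as ungrouped (`n = 1`).
There is no joiner–joiner attachment, no group merging, no spatial structure,
and groups do not persist past one reproductive episode.

The geometric-mean kernel is the symmetric choice that produces no a-priori
assortment: in a monomorphic population of trait `z` the attachment
probability is exactly `z`, and any steeper kernel would assort stickier
types and make adhesion evolve more easily.

### Exact experienced group-size distribution

For a rare mutant `z` among residents `ẑ` (`p = √(z ẑ)`):

* recruiter (probability `1/T`): group size `1 + Binomial(T−1, p)`;
* joiner (probability `(T−1)/T`): attaches with probability `p` into a group
  of size `2 + Binomial(T−2, ẑ)`, otherwise stays alone.

The ungrouped probability is
`u(z, ẑ) = ((T−1)/T)(1−p) + (1/T)(1−p)^{T−1}`; the recruiter-alone term is
kept (both choices are consistent with the large-`T` behaviour, but keeping
it makes the distribution exactly the one the sampler produces).  Its trait
sensitivity is `h(ẑ) = −∂u/∂z|_{z=ẑ} = ((T−1)/(2T))[1 + (1−ẑ)^{T−2}]` — the
factor 1/2 is the derivative of the square-root kernel on the diagonal, and
the kernel's kink at `ẑ = 0` is why gradient evaluations start at
`ẑ ≥ 10⁻³`.  These closed forms are validated three ways: an exhaustive
enumeration oracle for `T ≤ 4` (equality to 1e−12), total-variation agreement
with 10⁵ sampled patches, and recovery of the analytic large-patch limits
(`h → 1/2`, threshold `→ 2c/b`).

## Payoffs and their variants

`linear` — grouped: `b z̄ − C(z)`; ungrouped: `−C(z)`; `C(z) = c z`.
`size_capped` — the benefit is null for groups larger than `αT`.
`diverging_cost` — `C(z) = c z /(1−z)^k`, linear near 0 with a pole at 1.

Parameters and defaults: `T = 100`, `b = 20`, `c = 1` (payoff units),
`α = 0.3`, `k = 1` (`cost_shape`), matching the reference configuration used
throughout the examples; `b` and `c` only matter through `b/c` in every sign
question.

Two robustness facts shaped the defaults of the nonlinear variants:

* **Benefit cap.**  The interior attractor `z⁺` of the capped model is a CSS
  (convergence-stable *and* non-invasible) only when the cap binds well below
  the group sizes a fully adhesive population makes — numerically `α ≲ 0.37`
  at `T = 100, b/c = 20`.  For larger `α` the point stays convergence-stable
  but turns weakly invasible (a branching point with `|S| ≲ 10⁻⁴` in a wide
  neighbourhood, invisible to any finite-population simulation).  Hence the
  default `α = 0.3`; the `α = 0.8` behaviour is asserted in its own test.
* **Diverging cost.**  The repellor + CSS structure holds for `k ≤ 1`; at
  `k = 2` (with `b/c = 20`) the marginal cost rises so fast that no interior
  singular point survives and adhesion is never favoured.

## Adaptive dynamics

Invasion fitness is the mutant-minus-resident expected payoff under the
exact distributions, the mutant's group mean being `(z + (n−1)ẑ)/n`.
Differentiating it at `z = ẑ` reproduces the closed-form gradient
`b ẑ h + b Σ g(n)/n − c` exactly; the test suite enforces agreement of the
closed form with a numeric `∂S/∂z` to 1e−6 on a 50-point grid (central
differences of step 1e−5; a second-order one-sided stencil at the `z = 1`
boundary, where `S(ẑ, ẑ) = 0` supplies the third point).

Singular strategies are bracketed on a 10⁻³ grid and refined by Brent's
method to 1e−9.  Convergence stability is read off the gradient's sign
change; invasibility from a numeric `∂²S/∂z²` with step 10⁻⁴, flagged
degenerate rather than classified when `|∂²S/∂z²| < 10⁻⁶`.  An empty result
is a valid outcome (`b/c` below the bistability ratio).  The limiting
threshold uses the large-`T` gradient `b z/2 − c` (direct benefits vanish,
`h → 1/2`), again by root-finding rather than by formula substitution.

## Social status of mutations

A positive mutation is selected iff `∇S > 0` and altruistic iff
`r_alt(ẑ) b < c`, where `r_alt = Σ_{n≥2} g(n, ẑ, ẑ)/n` is the share of its
own contribution an individual gets back.  The two thresholds are reported
as benefit-to-cost curves `1/r_min = 1/(ẑ h + r_alt)` and `1/r_alt`.  The
"gain from switching" is implemented only through this sign test — the
classification is defined by it.  `r_alt` is cross-checked (to 5 %) against
the grouped fraction divided by the mean group size across groups,
`E[m | m ≥ 2]` with `m = 1 + Binomial(T−1, ẑ)`; the identification is treated
as approximate since it mixes the focal individual's experienced view with
the across-groups view.

## Individual-based model

`N` individuals (divisible by `T`) are permuted into patches, aggregated with
the same single-recruiter sampler, assigned payoffs, and resampled
multinomially in proportion to fitness (global competition; dispersal is
implicit).  Traits are inherited exactly; mutation exists only in the
trait-substitution driver and the free-running `run_population`.

**Payoff-to-fitness map.**  `w_i = π_i − min_j π_j` (plus a vanishing floor;
uniform resampling when all payoffs tie).  A common within-generation shift
cancels in the difference of type means, so the direction of selection
matches the sign of the analytic invasion fitness exactly, for every payoff
variant (including the diverging cost, where payoffs are unbounded below),
with no tunable selection-intensity parameter.  Exponential maps
`exp(s π)` were rejected: they select on payoff variance (mutants with
riskier group lotteries gain `s·∂Var/∂z / 2`), which at any intensity large
enough to resolve selection in feasible runs shifts the empirical singular
point by several hundredths of trait — more than the effect being measured.

**Invasion estimates.**  `⌊f₀N⌋` mutants are seeded at random positions and
run for a horizon of generations (loss and fixation absorb).  The estimate
is the per-generation log-growth of the *replicate-mean* final frequency.
The mean of per-replicate log-slopes would be biased by the −Var/2 drift
term of a near-critical branching process — most mutant lineages shrink
while rare ones boom, so that estimator calls weakly favoured mutants
"repelled".  The standard error is a jackknife on the log of the mean
(robust when few replicates carry the mass), and the verdict compares
`estimate ± 2·stderr` with zero.  Defaults: `f₀ = 0.01`, 10 replicates, 50
generations, `N = 5000`.

Two caveats the estimates exposed, reflected in the defaults of the
validation tests:

* *Rare-mutant regime.*  The analytic `S` is a rare-mutant limit.  At
  `f₀ T ≈ 1` several mutants co-occur per patch and mutual attachment of
  sticky mutants adds a positive frequency-dependent term that can flip
  weakly negative cells (e.g. `S(0.9, 0.05) = −0.10`).  PIP validation
  therefore uses `f₀ = 0.002`; near-diagonal scans are insensitive and keep
  `f₀ = 0.01`.
* *Power.*  Near a singular point the per-generation selection differential
  of a `+0.01` mutant is of the order of the drift noise of a 10×50-replicate
  run, so 2σ verdicts there are legitimately `neutral`.

**Threshold location.**  The empirical sign change along the near-diagonal
(`z = ẑ + 0.01`) is located by a weighted isotonic (pool-adjacent-violators)
fit of the growth estimates over the resident grid — the underlying quantity
is monotone there — taking the midpoint between the last nonpositive and
first positive fitted values, and reporting the median over 25 independent
scans.  Probe runs across seeds put the located threshold at 0.09 ± 0.02
against the analytic `z* = 0.0808`.

**Trait substitution.**  `evolutionary_trajectory` proposes
`z' = clip(ẑ + N(0, σ))` (`σ = 0.02`) and substitutes on a positive growth
estimate (point estimate, not the 2σ verdict — weak selection should slow
the walk, not freeze it) or, in fast mode, on the analytic sign.  Walks
started above the repellor settle within ≈ 0.05 of the interior CSS of the
nonlinear variants at `N = 1000`, 3 replicates × 30 generations per proposal.

**Finite-population effect of patch size.**  With small patches the adhesion
threshold is low in absolute trait units, so mutational fluctuations can
carry a population across it.  The test uses `N = 200`, mutation rate 0.05,
step 0.05, 400 generations from `z*/2`: crossings are consistently more
frequent at `T = 20` than at `T = 100`.

## Problem sizes

Analytic computations are exact sums over `n ≤ T` and run in milliseconds up
to `T = 10⁴` (used for the large-patch limits).  The simulation sizes quoted
above — `N = 5000` for invasion scans, `N = 1000–2000` for PIP grids and
trajectories, 10⁵ patches for distribution checks — keep the full validation
suite at a few minutes on one core while leaving every tested effect several
standard errors above its noise floor, except where weak selection near
singular points is itself the point.

## Known limitations

* All analytics assume the rare-mutant, monomorphic-resident limit; the
  package deliberately provides no polymorphic invasion fitness and only
  flags branching candidates.
* The diverging-cost family and the benefit cap are one-parameter stand-ins
  for "cost explodes near full adhesion" and "too-large groups fail"; the
  location of `z⁺` depends on `α` and `cost_shape` and no quantitative claim
  is made about it.
* The Wright–Fisher map with global competition is one of several defensible
  reproduction schemes; signs of selection are map-invariant (shift-invariant
  map), but time scales and fixation probabilities are not.
* `z = 0` is absorbing for the trait-substitution dynamics (no attachment,
  no selection on `z`), and the selection gradient is undefined there.
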