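"""Individual-based model of the aggregation-reproduction-dispersal cycle.

A finite population of ``N`` individuals goes through discrete
generations.  Each generation: (AP) individuals are randomly permuted into
``N/T`` patches and the single-recruiter aggregation process runs in each;
(RP) every individual collects the net payoff of its realized group and the
next generation is drawn by fitness-proportional multinomial resampling of
the whole population; (DP) groups dissolve.  Traits are inherited exactly;
mutation enters only through the trait-substitution driver
(:func:`evolutionary_trajectory`) or :func:`run_population`.

The payoff-to-fitness map is ``w_i = payoff_i - min_j payoff_j`` (plus a
vanishing floor), i.e. selection proportional to the payoff advantage over
the generation's worst performer.  A common within-generation shift leaves
the difference between type-mean fitnesses equal to the difference between
type-mean payoffs, so the direction of selection matches the sign of the
analytic invasion fitness without any tunable intensity parameter, while
keeping fitness nonnegative for every payoff variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .adaptive_dynamics import PIPGrid, invasion_fitness
from .aggregation import aggregate_patches
from .model_core import ModelParams, net_payoff

__all__ = [
    "Population",
    "ABMConfig",
    "InvasionResult",
    "run_generation",
    "estimate_invasion_fitness",
    "empirical_pip",
    "invasion_threshold_scan",
    "locate_invasion_threshold",
    "evolutionary_trajectory",
    "run_population",
]


@dataclass
class Population:
    """Trait vector of a finite population plus a generation counter."""

    traits: np.ndarray
    generation: int = 0

    def __post_init__(self) -> None:
        self.traits = np.asarray(self.traits, dtype=float)
        if self.traits.ndim != 1:
            raise ValueError("traits must be a 1-D vector")
        if np.any(self.traits < 0) or np.any(self.traits > 1):
            raise ValueError("traits must lie in [0, 1]")

    @property
    def size(self) -> int:
        return self.traits.size


@dataclass(frozen=True)
class ABMConfig:
    """Simulation settings for the individual-based model.

    ``N`` must be divisible by the patch size.  ``f0`` is the initial
    mutant frequency in invasion experiments; ``horizon`` the number of
    generations each replicate runs; ``sigma`` the mutation-step standard
    deviation used by the trait-substitution driver.
    """

    N: int = 5000
    replicates: int = 10
    horizon: int = 50
    f0: float = 0.01
    sigma: float = 0.02

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if not 0 < self.f0 < 1:
            raise ValueError("f0 must lie in (0, 1)")
        if self.replicates < 1 or self.horizon < 1:
            raise ValueError("replicates and horizon must be >= 1")

    def validate_patches(self, params: ModelParams) -> None:
        if self.N % params.T:
            raise ValueError(
                f"population size N={self.N} must be divisible by patch size T={params.T}"
            )


class Verdict(str, Enum):
    INVADES = "invades"
    REPELLED = "repelled"
    NEUTRAL = "neutral"


@dataclass(frozen=True)
class InvasionResult:
    """Empirical invasion-fitness estimate.

    ``estimate`` is the per-generation log-growth rate of the
    replicate-mean mutant frequency (lost replicates contribute zero,
    fixed ones contribute one); the verdict compares
    ``estimate +- 2 stderr`` against zero.
    """

    z_mutant: float
    z_resident: float
    estimate: float
    stderr: float
    replicates: int
    verdict: Verdict


def run_generation(
    pop: Population, params: ModelParams, rng: np.random.Generator
) -> Population:
    """Advance the population by one aggregation-reproduction-dispersal
    cycle.  Returns a new :class:`Population`; traits are only ever copies
    of parental traits."""
    N = pop.size
    if N % params.T:
        raise ValueError(
            f"population size N={N} must be divisible by patch size T={params.T}"
        )
    perm = rng.permutation(N)
    patch_traits = pop.traits[perm].reshape(-1, params.T)
    n_exp, zbar = aggregate_patches(patch_traits, rng)
    payoff = net_payoff(patch_traits, zbar, n_exp, params).ravel()
    flat_traits = patch_traits.ravel()
    w = payoff - payoff.min()
    total = w.sum()
    if total <= 0:  # all payoffs equal: neutral resampling
        parents = rng.integers(N, size=N)
    else:
        parents = rng.choice(N, size=N, p=w / total)
    return Population(traits=flat_traits[parents], generation=pop.generation + 1)


def _replicate_final_frequency(
    z: float,
    z_hat: float,
    params: ModelParams,
    config: ABMConfig,
    rng: np.random.Generator,
) -> float:
    """Mutant frequency after ``horizon`` generations in one replicate.

    Loss and fixation are absorbing, so a replicate that hits either state
    stops early and reports 0 or 1 (its realized trajectory up to
    absorption is what the frequency carries).
    """
    N = config.N
    n_mut = int(round(config.f0 * N))
    traits = np.full(N, float(z_hat))
    traits[rng.choice(N, size=n_mut, replace=False)] = float(z)
    pop = Population(traits=traits)
    for _ in range(config.horizon):
        pop = run_generation(pop, params, rng)
        f = float(np.mean(pop.traits == z))
        if f in (0.0, 1.0):
            return f
    return f


def estimate_invasion_fitness(
    z: float,
    z_hat: float,
    params: ModelParams,
    config: ABMConfig,
    rng: np.random.Generator,
) -> InvasionResult:
    """Estimate the sign of the invasion fitness by direct simulation.

    Seeds ``f0 * N`` mutants of trait ``z`` into a ``z_hat`` resident
    population and measures the mutant frequency's log-growth rate over
    ``replicates`` independent runs.
    """
    config.validate_patches(params)
    if int(round(config.f0 * config.N)) < 1:
        raise ValueError("f0 * N must be at least one individual")
    finals = np.array(
        [
            _replicate_final_frequency(z, z_hat, params, config, rng)
            for _ in range(config.replicates)
        ]
    )
    # log-growth rate of the replicate-mean frequency: E[f] grows iff the
    # mutant's mean fitness exceeds the population's, so this statistic is
    # sign-faithful where a mean of per-replicate log-slopes would carry a
    # negative drift-variance bias (most lineages shrink while rare ones
    # boom).
    f0 = config.f0
    R = config.replicates
    floor = 1.0 / (2 * config.N * R)
    fbar = max(float(finals.mean()), floor)
    estimate = float(np.log(fbar / f0) / config.horizon)
    if R > 1 and finals.std(ddof=1) > 0:
        # jackknife on the log of the mean frequency: robust when the mean
        # is carried by a few surviving replicates
        loo = (finals.sum() - finals) / (R - 1)
        theta = np.log(np.maximum(loo, floor) / f0) / config.horizon
        stderr = float(np.sqrt((R - 1) / R * ((theta - theta.mean()) ** 2).sum()))
    else:
        stderr = 0.0 if fbar == floor or fbar == 1.0 else float("inf")
    if z == z_hat:
        verdict = Verdict.NEUTRAL  # indistinguishable individuals
    elif estimate - 2 * stderr > 0:
        verdict = Verdict.INVADES
    elif estimate + 2 * stderr < 0:
        verdict = Verdict.REPELLED
    else:
        verdict = Verdict.NEUTRAL
    return InvasionResult(
        z_mutant=float(z),
        z_resident=float(z_hat),
        estimate=estimate,
        stderr=stderr,
        replicates=config.replicates,
        verdict=verdict,
    )


def empirical_pip(
    resident_grid,
    mutant_grid,
    params: ModelParams,
    config: ABMConfig,
    rng: np.random.Generator,
) -> PIPGrid:
    """Pairwise invasibility plot estimated from the individual-based
    model: the sign of the estimated mutant growth rate per cell (+1
    invades, -1 repelled, 0 on the diagonal, where mutant and resident are
    indistinguishable)."""
    resident_grid = np.asarray(resident_grid, dtype=float)
    mutant_grid = np.asarray(mutant_grid, dtype=float)
    sign = np.zeros((mutant_grid.size, resident_grid.size), dtype=np.int8)
    for j, z_hat in enumerate(resident_grid):
        for i, z in enumerate(mutant_grid):
            if z == z_hat:
                continue
            res = estimate_invasion_fitness(z, z_hat, params, config, rng)
            sign[i, j] = 0 if res.estimate == 0 else (1 if res.estimate > 0 else -1)
    return PIPGrid(
        resident_grid=resident_grid, mutant_grid=mutant_grid, sign=sign, source="abm"
    )


def invasion_threshold_scan(
    resident_grid,
    params: ModelParams,
    config: ABMConfig,
    rng: np.random.Generator,
    dz: float = 0.01,
) -> tuple[float | None, list[InvasionResult]]:
    """Locate the empirical sign change of invasion fitness along the
    near-diagonal.

    For each resident ``z_hat`` in the (ascending) grid, estimates the
    invasion fitness of the mutant ``z_hat + dz``.  Because the underlying
    near-diagonal invasion fitness is monotone in the resident trait over a
    window around the threshold, the noisy growth estimates are pooled by a
    weighted isotonic (pool-adjacent-violators) fit, and the sign-change
    location is reported as the midpoint between the last grid point with a
    nonpositive fitted value and the first with a positive one.  Point
    estimates rather than 2-sigma verdicts enter the fit: near the singular
    point the per-generation selection differential is far below the drift
    noise of a feasible run, so verdicts there are legitimately 'neutral'
    while the estimate sign still carries the location.  Returns
    ``(midpoint or None, results)``; ``None`` when no crossing exists.
    """
    resident_grid = np.asarray(resident_grid, dtype=float)
    results = [
        estimate_invasion_fitness(z_hat + dz, z_hat, params, config, rng)
        for z_hat in resident_grid
    ]
    estimates = np.array([r.estimate for r in results])
    weights = 1.0 / np.array([max(r.stderr, 1e-3) for r in results]) ** 2
    fitted = _isotonic_fit(estimates, weights)
    neg = np.flatnonzero(fitted <= 0)
    pos = np.flatnonzero(fitted > 0)
    if neg.size == 0 or pos.size == 0:
        return None, results
    return float((resident_grid[neg.max()] + resident_grid[pos.min()]) / 2), results


def locate_invasion_threshold(
    resident_grid,
    params: ModelParams,
    config: ABMConfig,
    seed: int,
    n_scans: int = 25,
    dz: float = 0.01,
) -> tuple[float | None, list[float]]:
    """Empirical threshold location as the median over independent scans.

    A single near-diagonal scan at feasible simulation sizes is dominated
    by drift close to the singular point, so the scan is repeated
    ``n_scans`` times with independent streams spawned from ``seed`` and
    the median of the located sign changes is reported (scans that find no
    crossing are skipped).  Returns ``(median or None, located midpoints)``.
    """
    mids: list[float] = []
    for child in np.random.SeedSequence(seed).spawn(n_scans):
        rng = np.random.default_rng(child)
        mid, _ = invasion_threshold_scan(resident_grid, params, config, rng, dz=dz)
        if mid is not None:
            mids.append(mid)
    if not mids:
        return None, mids
    return float(np.median(mids)), mids


def _isotonic_fit(y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted nondecreasing least-squares fit (pool adjacent violators)."""
    vals = list(map(float, y))
    wts = list(map(float, w))
    blocks = [[i] for i in range(len(vals))]
    k = 0
    while k + 1 < len(vals):
        if vals[k] > vals[k + 1]:
            total = wts[k] + wts[k + 1]
            vals[k] = (vals[k] * wts[k] + vals[k + 1] * wts[k + 1]) / total
            wts[k] = total
            blocks[k] += blocks[k + 1]
            del vals[k + 1], wts[k + 1], blocks[k + 1]
            k = max(k - 1, 0)
        else:
            k += 1
    fitted = np.empty(len(y))
    for v, idx in zip(vals, blocks):
        fitted[idx] = v
    return fitted


def evolutionary_trajectory(
    z0: float,
    params: ModelParams,
    config: ABMConfig,
    rng: np.random.Generator,
    attempts: int = 300,
    mode: str = "abm",
) -> list[tuple[int, float]]:
    """Trait-substitution sequence from initial resident trait ``z0``.

    Each step proposes a mutant ``z' = clip(z_hat + Normal(0, sigma))`` and
    substitutes the resident when the mutant invades — judged either by the
    sign of the individual-based growth estimate (``mode='abm'``; the point
    estimate rather than the 2-sigma verdict, so that weak selection slows
    the walk instead of freezing it) or by the sign of the analytic
    invasion fitness (``mode='analytic'``, fast).  Returns the
    substitution record as ``(attempt_index, resident_trait)`` pairs,
    starting with ``(0, z0)``.
    """
    if not 0 <= z0 <= 1:
        raise ValueError("z0 must lie in [0, 1]")
    z_hat = float(z0)
    record = [(0, z_hat)]
    for k in range(1, attempts + 1):
        z_new = float(np.clip(z_hat + config.sigma * rng.standard_normal(), 0.0, 1.0))
        if z_new == z_hat:
            continue
        if mode == "analytic":
            invades = invasion_fitness(z_new, z_hat, params) > 0
        elif mode == "abm":
            res = estimate_invasion_fitness(z_new, z_hat, params, config, rng)
            invades = res.estimate > 0
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if invades:
            z_hat = z_new
            record.append((k, z_hat))
    return record


def run_population(
    z0: float,
    params: ModelParams,
    config: ABMConfig,
    rng: np.random.Generator,
    generations: int,
    mutation_rate: float = 0.01,
) -> np.ndarray:
    """Free-running polymorphic simulation with per-capita mutation.

    Starts monomorphic at ``z0``; every generation each individual mutates
    with probability ``mutation_rate`` by a Normal(0, sigma) step (clipped
    to [0, 1]).  Returns the mean-trait time series (length
    ``generations + 1``).  Used to probe finite-population effects such as
    stochastic crossing of the adhesion threshold.
    """
    config.validate_patches(params)
    pop = Population(traits=np.full(config.N, float(z0)))
    means = [float(pop.traits.mean())]
    for _ in range(generations):
        pop = run_generation(pop, params, rng)
        hits = rng.random(config.N) < mutation_rate
        if hits.any():
            steps = config.sigma * rng.standard_normal(int(hits.sum()))
            pop.traits[hits] = np.clip(pop.traits[hits] + steps, 0.0, 1.0)
        means.append(float(pop.traits.mean()))
    return np.asarray(means)
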