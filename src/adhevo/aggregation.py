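"""Group formation in patches: analytic distributions and stochastic sampling.

Life cycle of the aggregation phase: the (effectively infinite) population
is scattered into patches of ``T`` individuals.  In each patch a single
*recruiter* is drawn uniformly at random; each of the remaining ``T - 1``
individuals gets one chance to attach to it, succeeding with the geometric
mean of the two adhesivenesses.  A patch therefore produces at most one
group (the recruiter plus its joiners) and a complement of singletons.  A
recruiter that attracts nobody is a singleton too.

This module provides

* the exact group-size distribution experienced by a rare mutant placed
  among residents (:func:`mutant_distribution`), with its closed-form
  ungrouped fraction and derivative sensitivity ``h``;
* a brute-force enumeration oracle for tiny patches
  (:func:`enumerate_mutant_distribution`);
* stochastic patch samplers used by the individual-based model
  (:func:`sample_patch`, :func:`aggregate_patches`).

Experienced group sizes are indexed ``n = 1 .. T`` where ``n = 1`` means
ungrouped.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .model_core import ModelParams, attachment_probability, _check_trait

__all__ = [
    "GroupSizeDistribution",
    "mutant_distribution",
    "enumerate_mutant_distribution",
    "ungrouped_fraction",
    "h_sensitivity",
    "mean_group_size",
    "mean_inverse_size_grouped",
    "sample_patch",
    "aggregate_patches",
    "experienced_size_histogram",
]


@dataclass(frozen=True)
class GroupSizeDistribution:
    """Distribution of group sizes experienced by a focal individual.

    ``probs[k]`` is the probability of ending in a group of size
    ``k + 1`` (so ``probs[0]`` is the ungrouped probability).
    """

    probs: np.ndarray
    z_focal: float
    z_resident: float
    T: int

    @property
    def sizes(self) -> np.ndarray:
        return np.arange(1, self.T + 1)

    @property
    def ungrouped(self) -> float:
        return float(self.probs[0])

    def mean_experienced_size(self) -> float:
        return float(self.probs @ self.sizes)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"n": self.sizes, "probability": self.probs})


def mutant_distribution(z, z_hat, params: ModelParams) -> GroupSizeDistribution:
    """Exact group-size distribution for one ``z``-individual among
    ``T - 1`` residents of trait ``z_hat``.

    With probability ``1/T`` the focal is the recruiter and its group size
    is ``1 + Binomial(T - 1, p)`` where ``p = sqrt(z * z_hat)`` is the
    attachment probability of residents to the mutant recruiter.  With
    probability ``(T - 1)/T`` it is a potential joiner: it attaches with
    probability ``p`` to a resident recruiter whose group then holds
    ``2 + Binomial(T - 2, z_hat)`` members, and otherwise stays alone.
    The monomorphic case is ``z == z_hat``.
    """
    z = float(_check_trait(z))
    z_hat = float(_check_trait(z_hat, "z_hat"))
    T = params.T
    p = attachment_probability(z, z_hat)
    probs = np.zeros(T)
    # focal recruiter: n = 1 + (number of resident joiners)
    probs += binom.pmf(np.arange(T), T - 1, p) / T
    # focal joiner
    probs[0] += (T - 1) / T * (1.0 - p)
    probs[1:] += (T - 1) / T * p * binom.pmf(np.arange(T - 1), T - 2, z_hat)
    return GroupSizeDistribution(probs=probs, z_focal=z, z_resident=z_hat, T=T)


def enumerate_mutant_distribution(z, z_hat, params: ModelParams) -> GroupSizeDistribution:
    """Exhaustive-enumeration oracle for :func:`mutant_distribution`.

    Enumerates every recruiter choice and every attach/fail outcome of the
    ``T - 1`` non-recruiters with exact probability weights (no sampling).
    Exponential in ``T``; restricted to small patches.
    """
    T = params.T
    if T > 12:
        raise ValueError("enumeration oracle is limited to T <= 12")
    z = float(_check_trait(z))
    z_hat = float(_check_trait(z_hat, "z_hat"))
    traits = np.array([z] + [z_hat] * (T - 1))
    probs = np.zeros(T)
    for rec in range(T):
        others = [i for i in range(T) if i != rec]
        p_attach = [attachment_probability(traits[i], traits[rec]) for i in others]
        for outcome in itertools.product([0, 1], repeat=T - 1):
            w = 1.0 / T
            for att, pa in zip(outcome, p_attach):
                w *= pa if att else (1.0 - pa)
            gsize = 1 + sum(outcome)
            # focal individual is index 0
            if rec == 0:
                n_focal = gsize if gsize >= 2 else 1
            else:
                joined = outcome[others.index(0)]
                n_focal = gsize if joined else 1
            probs[n_focal - 1] += w
    return GroupSizeDistribution(probs=probs, z_focal=z, z_resident=z_hat, T=T)


def ungrouped_fraction(z, z_hat, params: ModelParams) -> float:
    """Probability ``u(z, z_hat)`` that a ``z``-mutant stays alone.

    Closed form ``((T-1)/T) (1-p) + (1/T) (1-p)^(T-1)`` with
    ``p = sqrt(z * z_hat)``; the second term is the recruiter-alone event.
    """
    T = params.T
    p = attachment_probability(z, z_hat)
    return float((T - 1) / T * (1.0 - p) + (1.0 - p) ** (T - 1) / T)


def h_sensitivity(z_hat, params: ModelParams, method: str = "closed") -> float:
    """Sensitivity ``h(z_hat) = -du(z, z_hat)/dz`` at ``z = z_hat``.

    Measures how strongly a marginal increase in adhesiveness reduces the
    chance of staying ungrouped; always positive.  Closed form
    ``h = (T-1)/(2T) * [1 + (1 - z_hat)^(T-2)]`` (the square-root attachment
    kernel contributes the factor 1/2).  ``method='fd'`` recomputes it by
    central finite difference on :func:`ungrouped_fraction` as a
    self-consistency check.
    """
    z_hat = float(z_hat)
    if not 0 < z_hat <= 1:
        raise ValueError(
            "h is undefined at z_hat = 0 (square-root kink); need 0 < z_hat <= 1"
        )
    T = params.T
    if method == "closed":
        return float((T - 1) / (2 * T) * (1.0 + (1.0 - z_hat) ** (T - 2)))
    if method == "fd":
        eps = 1e-7 * max(z_hat, 1e-3)
        lo = max(z_hat - eps, 0.0)
        hi = min(z_hat + eps, 1.0)
        du = ungrouped_fraction(hi, z_hat, params) - ungrouped_fraction(lo, z_hat, params)
        return float(-du / (hi - lo))
    raise ValueError(f"unknown method {method!r}")


def mean_group_size(z_hat, params: ModelParams) -> float:
    """Average size of realized groups (size >= 2), across groups.

    A patch nucleates a group of size ``m = 1 + Binomial(T-1, z_hat)``;
    conditioning on ``m >= 2`` discards recruiter-alone patches.
    """
    z_hat = float(_check_trait(z_hat, "z_hat"))
    if z_hat == 0:
        raise ValueError("no groups form at z_hat = 0")
    T = params.T
    k = np.arange(T)  # number of joiners
    pk = binom.pmf(k, T - 1, z_hat)
    p_none = pk[0]
    return float(((1 + k[1:]) * pk[1:]).sum() / (1.0 - p_none))


def mean_inverse_size_grouped(z_hat, params: ModelParams) -> float:
    """``sum_{n>=2} g(n, z_hat, z_hat) / n`` in the monomorphic population.

    This is the per-capita weight of a focal individual's own contribution
    to its group benefit: it equals the direct-benefit term of the selection
    gradient (divided by b) and the altruism threshold ratio ``r_alt``.
    """
    d = mutant_distribution(z_hat, z_hat, params)
    return float((d.probs[1:] / d.sizes[1:]).sum())


# ---------------------------------------------------------------------------
# stochastic samplers
# ---------------------------------------------------------------------------


def aggregate_patches(traits: np.ndarray, rng: np.random.Generator):
    """Run the aggregation phase on a batch of patches.

    Parameters
    ----------
    traits : ndarray, shape (P, T)
        Trait values of the individuals in each of P patches.
    rng : numpy Generator

    Returns
    -------
    n_exp : ndarray (P, T) int
        Experienced group size per individual (1 = ungrouped).
    zbar : ndarray (P, T) float
        Mean trait of the individual's group (the trait itself if
        ungrouped).
    """
    traits = np.asarray(traits, dtype=float)
    P, T = traits.shape
    rec = rng.integers(T, size=P)
    rows = np.arange(P)
    rec_trait = traits[rows, rec]
    p_attach = np.sqrt(traits * rec_trait[:, None])
    member = rng.random((P, T)) < p_attach
    member[rows, rec] = True
    gsize = member.sum(axis=1)
    # a recruiter with no joiners is a singleton
    lone = gsize == 1
    member[lone, rec[lone]] = False
    gsize = member.sum(axis=1)
    gsum = (traits * member).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        gmean = np.where(gsize > 0, gsum / np.maximum(gsize, 1), 0.0)
    n_exp = np.where(member, gsize[:, None], 1)
    zbar = np.where(member, gmean[:, None], traits)
    return n_exp.astype(np.int64), zbar


def sample_patch(traits, rng: np.random.Generator) -> np.ndarray:
    """Sample the aggregation outcome of a single patch.

    Returns integer group labels per individual: members of the nucleated
    group (if it has size >= 2) share label 0; singletons get distinct
    labels 1, 2, ...  The patch must contain exactly T individuals with
    traits in [0, 1].
    """
    traits = _check_trait(np.asarray(traits, dtype=float))
    if traits.ndim != 1:
        raise ValueError("traits must be a 1-D vector of length T")
    n_exp, _ = aggregate_patches(traits[None, :], rng)
    in_group = n_exp[0] > 1
    labels = np.zeros(traits.shape[0], dtype=np.int64)
    labels[~in_group] = np.arange(1, (~in_group).sum() + 1)
    return labels


def experienced_size_histogram(
    z: float, params: ModelParams, n_patches: int, rng: np.random.Generator
) -> np.ndarray:
    """Empirical experienced-group-size distribution in a monomorphic
    population, from ``n_patches`` sampled patches.

    Returns a probability vector over ``n = 1 .. T`` (normalized over the
    ``n_patches * T`` individual observations).
    """
    T = params.T
    traits = np.full((n_patches, T), float(z))
    n_exp, _ = aggregate_patches(traits, rng)
    counts = np.bincount(n_exp.ravel() - 1, minlength=T)
    return counts / counts.sum()
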