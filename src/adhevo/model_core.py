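"""Core model: parameters, attachment probability, and payoff variants.

The model describes a population of microbes carrying a continuous
adhesiveness trait ``z`` in [0, 1].  Adhesiveness plays a double role: it
sets the probability of joining a group during an aggregation phase, and it
determines the public-goods benefit shared within the group.  Carrying the
trait has an individual cost.

Three payoff variants are supported:

``linear``
    A grouped individual of trait ``z`` in a group of mean trait ``zbar``
    receives ``b * zbar - c * z``; an ungrouped individual only pays the
    cost, ``-c * z``.
``size_capped``
    As ``linear``, but the group benefit is null for groups larger than
    ``alpha * T`` (e.g. fruiting bodies that topple over when too big).
``diverging_cost``
    As ``linear``, but the individual cost is ``c * z / (1 - z)**cost_shape``
    — linear for small ``z``, diverging as ``z`` approaches 1 (a trade-off
    between glue production and other cell functions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "PayoffVariant",
    "ModelParams",
    "attachment_probability",
    "individual_cost",
    "benefit_active",
    "net_payoff",
]


class PayoffVariant(str, Enum):
    """Selector for the payoff structure."""

    LINEAR = "linear"
    SIZE_CAPPED = "size_capped"
    DIVERGING_COST = "diverging_cost"


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the aggregation/payoff model.

    Parameters
    ----------
    T : int
        Patch size: number of individuals randomly assembled per patch
        during the aggregation phase.  Must be >= 2.
    b : float
        Benefit coefficient (payoff units), > 0.
    c : float
        Cost coefficient (payoff units), > 0.
    variant : PayoffVariant or str
        Payoff variant; see module docstring.
    alpha : float
        Fraction in (0, 1]; groups larger than ``alpha * T`` yield no
        benefit under the ``size_capped`` variant.  Ignored otherwise.
        The default 0.3 makes the cap bind well below the group sizes a
        fully adhesive population produces, which is what gives the capped
        model its interior evolutionary endpoint (see docs/methods.md).
    cost_shape : float
        Exponent of the diverging-cost pole, > 0.  The cost family is
        ``c * z / (1 - z)**cost_shape``: linear near 0 for every shape, with
        a pole at ``z = 1``.  Ignored unless variant is ``diverging_cost``.
    """

    T: int = 100
    b: float = 20.0
    c: float = 1.0
    variant: PayoffVariant = PayoffVariant.LINEAR
    alpha: float = 0.3
    cost_shape: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "variant", PayoffVariant(self.variant))
        if int(self.T) != self.T or self.T < 2:
            raise ValueError(f"patch size T must be an integer >= 2, got {self.T}")
        object.__setattr__(self, "T", int(self.T))
        if not self.b > 0:
            raise ValueError(f"benefit coefficient b must be > 0, got {self.b}")
        if not self.c > 0:
            raise ValueError(f"cost coefficient c must be > 0, got {self.c}")
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must lie in (0, 1], got {self.alpha}")
        if not self.cost_shape > 0:
            raise ValueError(f"cost_shape must be > 0, got {self.cost_shape}")

    @property
    def bc_ratio(self) -> float:
        """Benefit-to-cost ratio b/c."""
        return self.b / self.c

    @property
    def benefit_cap(self) -> float:
        """Largest group size that still yields a benefit (size_capped)."""
        return self.alpha * self.T


def _check_trait(z, name: str = "z") -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if np.any(z < 0) or np.any(z > 1):
        raise ValueError(f"trait {name} must lie in [0, 1]")
    return z


def attachment_probability(z1, z2):
    """Probability that an individual of trait ``z1`` sticks to a recruiter
    of trait ``z2``.

    The geometric mean ``sqrt(z1 * z2)`` is the unique symmetric choice that
    precludes a-priori assortment between identical individuals: a
    monomorphic population of trait ``z`` attaches with probability exactly
    ``z``.  Accepts scalars or arrays (broadcast).
    """
    z1 = _check_trait(z1, "z1")
    z2 = _check_trait(z2, "z2")
    out = np.sqrt(z1 * z2)
    return float(out) if out.ndim == 0 else out


def individual_cost(z, params: ModelParams):
    """Cost C(z) paid by an individual of trait ``z``.

    Linear and size-capped variants use ``C(z) = c * z``.  The diverging
    variant uses ``C(z) = c * z / (1 - z)**cost_shape``; at ``z = 1`` the
    cost is ``inf`` (returned as a sentinel, not raised).
    """
    z = _check_trait(z)
    if params.variant is PayoffVariant.DIVERGING_COST:
        with np.errstate(divide="ignore"):
            out = params.c * z / (1.0 - z) ** params.cost_shape
    else:
        out = params.c * z
    return float(out) if np.ndim(out) == 0 else out


def benefit_active(n, params: ModelParams):
    """Whether a group of size ``n`` yields a benefit to its members.

    Size 1 means ungrouped and never yields a benefit.  Under
    ``size_capped`` the benefit is additionally null for ``n > alpha * T``.
    """
    n = np.asarray(n)
    active = n >= 2
    if params.variant is PayoffVariant.SIZE_CAPPED:
        active = active & (n <= params.benefit_cap)
    return bool(active) if active.ndim == 0 else active


def net_payoff(z, zbar, n, params: ModelParams):
    """Net payoff of a ``z``-individual in a group of size ``n`` with mean
    trait ``zbar`` (including the focal individual).

    Ungrouped individuals (``n = 1``) pay only the cost.  Accepts scalars or
    broadcastable arrays.
    """
    z = _check_trait(z)
    n_arr = np.asarray(n)
    if np.any(n_arr < 1) or np.any(n_arr > params.T):
        raise ValueError(f"group size n must lie in [1, T={params.T}]")
    active = benefit_active(n_arr, params)
    benefit = np.where(active, params.b * np.asarray(zbar, dtype=float), 0.0)
    out = benefit - individual_cost(z, params)
    return float(out) if np.ndim(out) == 0 else out
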