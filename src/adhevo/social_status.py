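"""Social status of adhesion-increasing mutations: altruistic or directly
beneficial.

A slightly more adhesive mutation is *selected* when the selection gradient
is positive.  Independently of selection, it is *altruistic* when the
marginal return the mutant draws from its own extra contribution (its gain
from switching, in the group structure shaped by the resident) fails to
cover the marginal cost, i.e. when ``r_alt(z_hat) * b < c`` with
``r_alt = sum_{n>=2} g(n)/n``; otherwise it is *directly beneficial*.

Because both thresholds are ratios of b to c, the regimes are summarized by
two curves of benefit-to-cost ratio against the resident trait:
``1/r_min``, above which the mutation is selected, and ``1/r_alt``, below
which it is altruistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.optimize import brentq

from .adaptive_dynamics import selection_gradient, zstar_threshold
from .aggregation import h_sensitivity, mean_inverse_size_grouped
from .model_core import ModelParams

__all__ = [
    "MutationClass",
    "StatusCurves",
    "r_alt",
    "inv_r_min",
    "classify_mutation",
    "status_curves",
    "status_switch_point",
]


class MutationClass(str, Enum):
    NOT_SELECTED = "not_selected"
    ALTRUISTIC = "altruistic"
    DIRECTLY_BENEFICIAL = "directly_beneficial"


@dataclass(frozen=True)
class StatusCurves:
    """Benefit-to-cost threshold curves along a resident-trait grid.

    ``inv_r_min`` — minimal b/c for a positive mutation to be selected
    (tends to ``2 / z_hat`` for large patches).
    ``inv_r_alt`` — maximal b/c for the mutation to be altruistic (equals
    the patch size ``T`` at ``z_hat = 1``; diverges as ``z_hat`` goes to 0,
    where no direct benefit exists).
    """

    zhat_grid: np.ndarray
    inv_r_min: np.ndarray
    inv_r_alt: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "zhat": self.zhat_grid,
                "inv_r_min": self.inv_r_min,
                "inv_r_alt": self.inv_r_alt,
            }
        )


def r_alt(z_hat: float, params: ModelParams) -> float:
    """Altruism ratio ``sum_{n>=2} g(n, z_hat, z_hat) / n``.

    The reciprocal of an effective group size: the fraction of its own
    contribution a focal individual gets back.  Zero at ``z_hat = 0`` and
    ``1/T`` at ``z_hat = 1``.
    """
    if z_hat == 0:
        return 0.0
    return mean_inverse_size_grouped(z_hat, params)


def inv_r_min(z_hat: float, params: ModelParams) -> float:
    """Minimal benefit-to-cost ratio at which a slightly more adhesive
    mutant is favored: ``1 / (z_hat h(z_hat) + r_alt(z_hat))``, the b/c at
    which the selection gradient crosses zero.
    """
    return 1.0 / (z_hat * h_sensitivity(z_hat, params) + r_alt(z_hat, params))


def classify_mutation(z_hat: float, params: ModelParams) -> MutationClass:
    """Fate and status of an infinitesimal adhesion-increasing mutation.

    ``not_selected`` when the selection gradient at ``z_hat`` is <= 0.
    Otherwise ``altruistic`` if ``r_alt * b < c``, else
    ``directly_beneficial``.  The altruism label itself is defined
    regardless of selection; use :func:`r_alt` and
    :func:`~adhevo.adaptive_dynamics.selection_gradient` directly for the
    two independent booleans.
    """
    if selection_gradient(z_hat, params) <= 0:
        return MutationClass.NOT_SELECTED
    if r_alt(z_hat, params) * params.b < params.c:
        return MutationClass.ALTRUISTIC
    return MutationClass.DIRECTLY_BENEFICIAL


def status_curves(zhat_grid, params: ModelParams) -> StatusCurves:
    """Evaluate the selection (``1/r_min``) and altruism (``1/r_alt``)
    threshold curves on a grid of resident traits in (0, 1]."""
    zhat_grid = np.asarray(zhat_grid, dtype=float)
    if np.any(zhat_grid <= 0) or np.any(zhat_grid > 1):
        raise ValueError("status curves require 0 < z_hat <= 1")
    imin = np.array([inv_r_min(z, params) for z in zhat_grid])
    with np.errstate(divide="ignore"):
        ialt = np.array(
            [
                np.inf if (ra := r_alt(z, params)) == 0 else 1.0 / ra
                for z in zhat_grid
            ]
        )
    return StatusCurves(zhat_grid=zhat_grid, inv_r_min=imin, inv_r_alt=ialt)


def status_switch_point(params: ModelParams) -> float | None:
    """Resident trait at which selected mutations switch from altruistic to
    directly beneficial, i.e. where ``r_alt(z_hat) b = c``.

    Exists in ``(z*, 1)`` only when ``b/c`` exceeds the altruism ceiling at
    full adhesion (``b/c > 1/r_alt(1) = T`` for the linear model); returns
    ``None`` otherwise.
    """
    f = lambda z: r_alt(z, params) * params.b - params.c
    z_lo = zstar_threshold(params)
    if z_lo is None:
        z_lo = 1e-3
    if f(z_lo) >= 0 or f(1.0) <= 0:
        return None
    return float(brentq(f, z_lo, 1.0, xtol=1e-9))
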