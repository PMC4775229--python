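"""Invasion fitness, selection gradient, singular strategies and PIPs.

Adaptive-dynamics layer of the model: a monomorphic resident population of
trait ``z_hat`` is challenged by a rare mutant of trait ``z``.  The
invasion fitness ``S(z, z_hat)`` is the expected-payoff advantage of the
mutant over the resident, where expectations run over the exact group-size
distributions produced by the aggregation process.  Its derivative in the
mutant trait at the resident value (the selection gradient) drives gradual
trait substitution; its zeros are the singular strategies, classified here
by convergence stability and invasibility.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.optimize import brentq

from .aggregation import (
    h_sensitivity,
    mean_inverse_size_grouped,
    mutant_distribution,
)
from .model_core import ModelParams, PayoffVariant, net_payoff

__all__ = [
    "SingularPoint",
    "PIPGrid",
    "expected_mutant_payoff",
    "invasion_fitness",
    "selection_gradient",
    "find_singular_points",
    "zstar_threshold",
    "zstar_limit",
    "critical_bc_ratio_limit",
    "analytic_pip",
]

#: second-derivative magnitude below which invasibility is not called
DEGENERATE_TOL = 1e-6


class SingularLabel(str, Enum):
    GARDEN_OF_EDEN = "garden_of_eden"
    CSS = "CSS"
    REPELLOR = "repellor"
    BRANCHING_CANDIDATE = "branching_candidate"


@dataclass(frozen=True)
class SingularPoint:
    """A zero of the selection gradient, with its classification.

    ``convergence_stable`` — the gradient switches from positive to
    negative across the point (trait substitution converges to it).
    ``invasible`` — the second derivative of invasion fitness in the mutant
    trait is positive at the point (nearby mutants can invade).
    ``degenerate`` — the second derivative is too small to call; the
    invasibility flag is then not meaningful.
    """

    z_star: float
    convergence_stable: bool
    invasible: bool
    second_derivative: float
    degenerate: bool = False

    @property
    def label(self) -> SingularLabel:
        if self.invasible:
            return (
                SingularLabel.BRANCHING_CANDIDATE
                if self.convergence_stable
                else SingularLabel.REPELLOR
            )
        return (
            SingularLabel.CSS if self.convergence_stable else SingularLabel.GARDEN_OF_EDEN
        )


@dataclass(frozen=True)
class PIPGrid:
    """Sign matrix of invasion fitness over a (resident, mutant) grid.

    ``sign[i, j]`` is the sign of ``S(mutant_grid[i], resident_grid[j])``
    (+1 mutant invades, -1 repelled, 0 neutral).
    """

    resident_grid: np.ndarray
    mutant_grid: np.ndarray
    sign: np.ndarray
    source: str = "analytic"

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.sign, index=self.mutant_grid, columns=self.resident_grid
        )


def expected_mutant_payoff(z: float, z_hat: float, params: ModelParams) -> float:
    """Expected payoff of a rare ``z``-mutant among ``z_hat``-residents.

    The mutant's group of size ``n`` contains the mutant plus ``n - 1``
    residents, so its group mean trait is ``(z + (n - 1) z_hat) / n``.
    """
    d = mutant_distribution(z, z_hat, params)
    n = d.sizes
    zbar = (z + (n - 1) * z_hat) / n
    return float(d.probs @ net_payoff(z, zbar, n, params))


def invasion_fitness(z: float, z_hat: float, params: ModelParams) -> float:
    """Invasion fitness ``S(z, z_hat)``: expected payoff of a rare mutant
    minus the expected payoff of a resident.  Exactly zero at ``z == z_hat``.
    """
    return expected_mutant_payoff(z, z_hat, params) - expected_mutant_payoff(
        z_hat, z_hat, params
    )


def _numeric_gradient(z_hat: float, params: ModelParams, step: float = 1e-5) -> float:
    """Numeric dS/dz at z = z_hat.

    Central difference in the interior; a second-order one-sided stencil
    when the trait boundary truncates it (S(z_hat, z_hat) = 0 supplies the
    third point for free).
    """
    z_max = 1.0
    if params.variant is PayoffVariant.DIVERGING_COST:
        z_max = 1.0 - 1e-9
    if step <= z_hat and z_hat + step <= z_max:
        s_lo = invasion_fitness(z_hat - step, z_hat, params)
        s_hi = invasion_fitness(z_hat + step, z_hat, params)
        return (s_hi - s_lo) / (2 * step)
    if z_hat + step > z_max:
        s1 = invasion_fitness(z_hat - step, z_hat, params)
        s2 = invasion_fitness(z_hat - 2 * step, z_hat, params)
        return (-4.0 * s1 + s2) / (2 * step)
    s1 = invasion_fitness(z_hat + step, z_hat, params)
    s2 = invasion_fitness(z_hat + 2 * step, z_hat, params)
    return (4.0 * s1 - s2) / (2 * step)


def selection_gradient(
    z_hat: float, params: ModelParams, method: str = "auto"
) -> float:
    """Selection gradient ``dS(z, z_hat)/dz`` at ``z = z_hat``.

    For the linear variant the closed form is

        ``b * z_hat * h(z_hat) + b * sum_{n>=2} g(n)/n - c``

    whose three terms are the gain from improved recruitment into groups,
    the direct benefit of the mutant's own contribution, and the marginal
    cost.  Other variants (and ``method='numeric'``) use a central finite
    difference of the invasion fitness.
    """
    z_hat = float(z_hat)
    if not 0 < z_hat <= 1:
        raise ValueError("selection gradient requires 0 < z_hat <= 1")
    if method == "auto":
        method = "closed" if params.variant is PayoffVariant.LINEAR else "numeric"
    if method == "closed":
        if params.variant is not PayoffVariant.LINEAR:
            raise ValueError("closed-form gradient only exists for the linear variant")
        h = h_sensitivity(z_hat, params)
        direct = mean_inverse_size_grouped(z_hat, params)
        return float(params.b * z_hat * h + params.b * direct - params.c)
    if method == "numeric":
        return _numeric_gradient(z_hat, params)
    raise ValueError(f"unknown method {method!r}")


def _second_derivative(z_star: float, params: ModelParams, step: float = 1e-4) -> float:
    """Numeric d2S/dz2 in the mutant direction at (z_star, z_star)."""
    lo = max(z_star - step, 0.0)
    hi = min(z_star + step, 1.0)
    if params.variant is PayoffVariant.DIVERGING_COST:
        hi = min(hi, 1.0 - 1e-7)
    # non-uniform three-point second difference (robust near the borders)
    h1 = z_star - lo
    h2 = hi - z_star
    s_lo = invasion_fitness(lo, z_star, params)
    s_hi = invasion_fitness(hi, z_star, params)
    return 2.0 * (h1 * s_hi + h2 * s_lo) / (h1 * h2 * (h1 + h2))


def find_singular_points(
    params: ModelParams,
    grid_step: float = 1e-3,
    z_min: float = 1e-3,
    xtol: float = 1e-9,
) -> list[SingularPoint]:
    """Locate and classify all interior zeros of the selection gradient.

    Brackets sign changes on a uniform grid over ``(z_min, z_max)`` and
    refines each bracket with Brent's method.  ``z_max`` is 1 except under
    the diverging cost, whose gradient has a pole at 1.  An empty list is a
    valid outcome (e.g. b/c below the bistability threshold).
    """
    z_max = 1.0
    if params.variant is PayoffVariant.DIVERGING_COST:
        z_max = 1.0 - 1e-6
    grid = np.arange(z_min, z_max + grid_step / 2, grid_step)
    grid[-1] = min(grid[-1], z_max)
    vals = np.array([selection_gradient(z, params) for z in grid])
    points: list[SingularPoint] = []
    for i in np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0):
        root = brentq(
            lambda z: selection_gradient(z, params), grid[i], grid[i + 1], xtol=xtol
        )
        descending = vals[i] > 0 > vals[i + 1]
        d2 = _second_derivative(root, params)
        degenerate = abs(d2) < DEGENERATE_TOL
        points.append(
            SingularPoint(
                z_star=float(root),
                convergence_stable=bool(descending),
                invasible=bool(d2 > 0) and not degenerate,
                second_derivative=float(d2),
                degenerate=degenerate,
            )
        )
    return sorted(points, key=lambda p: p.z_star)


def zstar_threshold(params: ModelParams) -> float | None:
    """Repelling interior threshold ``z*`` separating decay to asociality
    from runaway adhesion (linear variant).

    Returns the non-convergence-stable root of the selection gradient, or
    ``None`` when no interior threshold exists (``b/c`` at or below the
    bistability boundary).  ``z*`` is bounded above by ``2c/b`` and
    increases toward it with patch size.
    """
    points = find_singular_points(params)
    for p in points:
        if not p.convergence_stable:
            return p.z_star
    return None


def zstar_limit(b: float, c: float) -> float | None:
    """Threshold ``z*`` in the infinite-patch limit.

    As ``T`` grows the direct-benefit term vanishes and ``h`` tends to 1/2,
    leaving the limiting gradient ``b z / 2 - c``; its root is found by
    Brent bracketing.  Returns ``None`` if the root leaves (0, 1]
    (``b <= 2c``).
    """
    grad = lambda z: b * z / 2.0 - c
    if grad(1.0) <= 0:
        return None
    return float(brentq(grad, 1e-12, 1.0, xtol=1e-12))


def critical_bc_ratio_limit() -> float:
    """Benefit-to-cost ratio at which the interior threshold reaches the
    boundary ``z = 1`` in the infinite-patch limit (the onset of
    bistability), solved from the limiting gradient at ``z = 1``.
    """
    boundary = lambda r: r * 1.0 / 2.0 - 1.0  # limiting gradient at z=1, c=1
    return float(brentq(boundary, 0.1, 10.0, xtol=1e-12))


def analytic_pip(
    resident_grid, mutant_grid, params: ModelParams, tol: float = 1e-12
) -> PIPGrid:
    """Sign of the analytic invasion fitness over a (resident, mutant) grid."""
    resident_grid = np.asarray(resident_grid, dtype=float)
    mutant_grid = np.asarray(mutant_grid, dtype=float)
    sign = np.zeros((mutant_grid.size, resident_grid.size), dtype=np.int8)
    for j, z_hat in enumerate(resident_grid):
        for i, z in enumerate(mutant_grid):
            s = invasion_fitness(z, z_hat, params)
            sign[i, j] = 0 if abs(s) < tol else (1 if s > 0 else -1)
    return PIPGrid(
        resident_grid=resident_grid,
        mutant_grid=mutant_grid,
        sign=sign,
        source="analytic",
    )
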