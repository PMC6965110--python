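"""Mean fixation times from the diffusion approximation.

Solves the boundary-value problem for the product quantity theta(p)
(= fixation probability x mean time to fixation, in generations):

    M(p) theta'(p) + (1/2) V(p) theta''(p) = -u(p),   theta(0) = theta(1) = 0,

with u(p) the fixation probability, and M, V the Kimura diploid drift and
variance terms (which carry both the heterozygote and homozygote selection
coefficients, unlike the haploid pair).  The mean time to fixation among
lineages that do fix is then ``tau(p0) = theta(p0) / u(p0)``.

In the drift limit (N*s -> 0) tau from a single mutant approaches the
classical 4N generations; with strong selection it drops well below that.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded

from .popgen_core import (
    FixationResult,
    Population,
    SelectionScheme,
    fixation_probability_quadrature,
    fixation_profile,
    mean_change_kimura,
    variance_kimura,
)

__all__ = [
    "TimeSolverConfig",
    "solve_theta",
    "conditional_fixation_time",
    "generations_to_years",
    "fixation_time_table",
]


@dataclass(frozen=True)
class TimeSolverConfig:
    """Mesh and reporting settings for the fixation-time solver.

    ``grid_points`` interior nodes are placed uniformly on (0, 1); the
    singular endpoints (V -> 0) carry the exact boundary values.
    ``generation_years`` converts generations to calendar years for human
    populations (typical range 25-30 years per generation).
    """

    grid_points: int = 2000
    tolerance: float = 1e-8
    generation_years: float = 25.0

    def __post_init__(self) -> None:
        if self.grid_points < 100:
            raise ValueError("grid_points must be >= 100")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if not 1.0 <= self.generation_years <= 100.0:
            raise ValueError("generation_years must lie in [1, 100]")


def solve_theta(
    scheme: SelectionScheme,
    pop: Population,
    config: TimeSolverConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the theta boundary-value problem on a uniform mesh.

    Returns ``(p, theta)`` including the endpoints, where theta(0)=theta(1)=0
    exactly.  Second-order central differences yield a tridiagonal system;
    a strongly advection-dominated mesh (cell Peclet number >> 1, i.e. very
    large N*s for the chosen resolution) triggers a warning to refine.
    """
    config = config or TimeSolverConfig()
    n = config.grid_points
    h = 1.0 / (n + 1)
    p_full = np.linspace(0.0, 1.0, n + 2)
    p_int = p_full[1:-1]

    M = np.array([mean_change_kimura(p, scheme) for p in p_int])
    V = np.array([variance_kimura(p, pop.Ne) for p in p_int])
    if np.any(V <= 0):
        raise ArithmeticError("variance term vanished at an interior node")

    peclet = np.max(np.abs(M) * h / V)
    if peclet > 2.0:
        warnings.warn(
            f"cell Peclet number {peclet:.1f} > 2; the central-difference "
            f"solution may oscillate — increase grid_points (currently {n})",
            stacklevel=2,
        )

    u = fixation_profile(scheme, pop, p_full)[1:-1]

    lower = V / (2.0 * h * h) - M / (2.0 * h)  # theta_{i-1}
    diag = -V / (h * h)                        # theta_i
    upper = V / (2.0 * h * h) + M / (2.0 * h)  # theta_{i+1}
    rhs = -u

    ab = np.zeros((3, n))
    ab[0, 1:] = upper[:-1]
    ab[1, :] = diag
    ab[2, :-1] = lower[1:]
    theta_int = solve_banded((1, 1), ab, rhs)

    if np.min(theta_int) < -config.tolerance * max(1.0, np.max(np.abs(theta_int))):
        raise ArithmeticError(
            f"theta went negative (min {np.min(theta_int):.3e}); mesh with "
            f"{n} nodes cannot resolve this (N, s) — increase grid_points"
        )
    theta = np.empty(n + 2)
    theta[0] = theta[-1] = 0.0
    theta[1:-1] = np.clip(theta_int, 0.0, None)
    return p_full, theta


def conditional_fixation_time(
    scheme: SelectionScheme,
    pop: Population,
    p0: float | None = None,
    config: TimeSolverConfig | None = None,
) -> FixationResult:
    """Mean generations to fixation given fixation, from initial frequency p0.

    p0 defaults to 1/(2N), a single heterozygous mutant.  Returns a
    :class:`FixationResult` with theta(p0), p_fix(p0) and their ratio.
    """
    config = config or TimeSolverConfig()
    if p0 is None:
        p0 = pop.p0_single_mutant
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie strictly inside (0, 1)")

    mesh, theta = solve_theta(scheme, pop, config)
    # interpolate tau = theta/u rather than theta itself: near p=0 theta bends
    # on the selection scale 1/(2 N s) while tau varies slowly, so this stays
    # accurate for p0 = 1/(2N) below the mesh spacing
    u_mesh = fixation_profile(scheme, pop, mesh)
    interior = slice(1, -1)
    tau_mesh = theta[interior] / u_mesh[interior]
    tau_p0 = float(np.interp(p0, mesh[interior], tau_mesh))
    if scheme.is_neutral:
        p_fix = p0
    else:
        p_fix = fixation_probability_quadrature(p0, scheme, pop, rtol=config.tolerance)
    theta_p0 = tau_p0 * p_fix
    if p_fix <= config.tolerance * 1e-4:
        raise ArithmeticError(
            f"fixation probability {p_fix:.3e} is numerically zero; "
            "the conditional fixation time is undefined"
        )
    return FixationResult(
        p_fix=p_fix,
        theta=theta_p0,
        t_conditional=theta_p0 / p_fix,
        method="bvp",
    )


def generations_to_years(t: float, generation_years: float) -> float:
    """Convert a duration in generations to calendar years."""
    if t < 0:
        raise ValueError("t must be nonnegative")
    return t * generation_years


def fixation_time_table(
    schemes: list[SelectionScheme],
    pops: list[Population],
    config: TimeSolverConfig | None = None,
    *,
    years_low: float = 25.0,
    years_high: float = 30.0,
) -> pd.DataFrame:
    """Fixation probability and time over a (scheme x population) grid.

    Per-cell solver failures are recorded in the ``error`` column rather than
    aborting the sweep (some strong-selection cells are numerically out of
    reach at a given mesh).
    """
    rows = []
    for pop in pops:
        for scheme in schemes:
            row: dict = {
                "N": pop.N,
                "s_het": scheme.s_het if scheme.mode == "constant" else scheme.k_het,
                "s_hom": scheme.s_hom if scheme.mode == "constant" else scheme.k_hom,
                "mode": scheme.mode,
            }
            try:
                res = conditional_fixation_time(scheme, pop, config=config)
                row.update(
                    p_fix=res.p_fix,
                    theta=res.theta,
                    t_conditional=res.t_conditional,
                    years_low=generations_to_years(res.t_conditional, years_low),
                    years_high=generations_to_years(res.t_conditional, years_high),
                    error="",
                )
            except (ArithmeticError, ValueError) as exc:
                row.update(
                    p_fix=np.nan,
                    theta=np.nan,
                    t_conditional=np.nan,
                    years_low=np.nan,
                    years_high=np.nan,
                    error=str(exc),
                )
            rows.append(row)
    return pd.DataFrame(rows)
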