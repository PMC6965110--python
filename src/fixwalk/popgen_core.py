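"""Selection schemes, diffusion drift/variance terms, and fixation probabilities.

The diffusion approximation describes the per-generation change of the mutant
allele frequency ``p`` by a drift term ``M(p)`` (mean change) and a variance
term ``V(p)``.  The probability that a mutant lineage starting at frequency
``p0`` eventually fixes is the stationary absorption probability

    u(p0) = int_0^p0 G(x) dx / int_0^1 G(x) dx,
    G(x)  = exp( - int_0^x 2 M(y) / V(y) dy ),

which reduces to a closed form in the haploid / semidominant case.  Two M/V
parameterizations are supported: the haploid pair (exact for a haploid
population, equivalent to a diploid with ``s_AA = 2 s_aA``) and Kimura's
diploid pair, which carries separate heterozygote and homozygote selection
coefficients and is the one used for fixation-time calculations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate

__all__ = [
    "SelectionScheme",
    "Population",
    "FixationResult",
    "mean_change_haploid",
    "variance_haploid",
    "mean_change_kimura",
    "variance_kimura",
    "fixation_probability_closed",
    "fixation_probability_quadrature",
    "fixation_probability_frequency_dependent",
    "fixation_profile",
]

#: below this magnitude a selection coefficient is treated as exactly neutral
#: (analytic limits instead of 0/0 divisions)
NEUTRAL_EPS = 1e-12


def _check_frequency(p: float, name: str = "p") -> float:
    p = float(p)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {p!r}")
    return p


@dataclass(frozen=True)
class SelectionScheme:
    """Genotype fitness specification for a biallelic locus.

    The wild type has fitness 1; heterozygote and homozygote mutants have
    fitnesses ``1 + s_het`` and ``1 + s_hom``.  In ``frequency_dependent``
    mode the coefficients grow linearly with the mutant frequency:
    ``s_het(p) = k_het * p`` and ``s_hom(p) = k_hom * p``, modelling an
    advantage (e.g. communicative) that only pays off once carriers are
    common.
    """

    s_het: float = 0.0
    s_hom: float = 0.0
    mode: str = "constant"
    k_het: float = 0.0
    k_hom: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("constant", "frequency_dependent"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "constant":
            if self.s_het < -1.0 or self.s_hom < -1.0:
                raise ValueError("selection coefficients must be >= -1 (fitness 1+s >= 0)")
            if self.s_het > 1.0 or self.s_hom > 1.0:
                warnings.warn(
                    "selection coefficient exceeds 1 (carriers more than twice as "
                    "fit as wild type); results are extrapolations",
                    stacklevel=3,
                )
        else:
            # s(p) = k*p on p in [0,1] attains extremes at the endpoints
            if self.k_het < -1.0 or self.k_hom < -1.0:
                raise ValueError("frequency-dependent slopes must keep fitness nonnegative")
            if self.k_het > 1.0 or self.k_hom > 1.0:
                warnings.warn(
                    "frequency-dependent slope exceeds 1; effective s(p) exceeds 1 "
                    "at high frequency",
                    stacklevel=3,
                )

    # -- convenience constructors -------------------------------------------------

    @classmethod
    def dominant(cls, s: float) -> "SelectionScheme":
        """Full dominance: one copy of the mutant suffices (s_hom = s_het = s)."""
        return cls(s_het=s, s_hom=s)

    @classmethod
    def semidominant(cls, s_het: float) -> "SelectionScheme":
        """Additive / no-dominance case (s_hom = 2 s_het); equivalent to haploid."""
        return cls(s_het=s_het, s_hom=2.0 * s_het)

    @classmethod
    def recessive(cls, s_hom: float) -> "SelectionScheme":
        """Recessive: heterozygotes gain nothing (s_het = 0)."""
        return cls(s_het=0.0, s_hom=s_hom)

    @classmethod
    def frequency_dependent(cls, k_het: float, k_hom: float) -> "SelectionScheme":
        """Linear frequency dependence: s_het(p) = k_het p, s_hom(p) = k_hom p."""
        return cls(mode="frequency_dependent", k_het=k_het, k_hom=k_hom)

    @classmethod
    def neutral(cls) -> "SelectionScheme":
        return cls()

    # -- evaluation ---------------------------------------------------------------

    def coefficients_at(self, p: float) -> tuple[float, float]:
        """Effective (s_het, s_hom) at mutant frequency ``p``."""
        if self.mode == "constant":
            return self.s_het, self.s_hom
        return self.k_het * p, self.k_hom * p

    @property
    def is_neutral(self) -> bool:
        if self.mode == "constant":
            return abs(self.s_het) < NEUTRAL_EPS and abs(self.s_hom) < NEUTRAL_EPS
        return abs(self.k_het) < NEUTRAL_EPS and abs(self.k_hom) < NEUTRAL_EPS


@dataclass(frozen=True)
class Population:
    """Census size N (diploid individuals) and effective size Ne (defaults to N)."""

    N: int
    Ne: int | None = None

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2 diploid individuals")
        if self.Ne is None:
            object.__setattr__(self, "Ne", self.N)
        if self.Ne < 2:
            raise ValueError("Ne must be >= 2")

    @property
    def n_alleles(self) -> int:
        return 2 * self.N

    @property
    def p0_single_mutant(self) -> float:
        """Initial frequency of one heterozygous mutant: 1/(2N)."""
        return 1.0 / (2 * self.N)


@dataclass(frozen=True)
class FixationResult:
    """Fixation probability and mean-time summary for one (scheme, N, p0).

    ``theta`` is the product quantity fixation-probability x time (generations);
    ``t_conditional = theta / p_fix`` is the mean time to fixation among
    lineages that do fix.
    """

    p_fix: float
    theta: float = 0.0
    t_conditional: float = 0.0
    method: str = "closed_form"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_fix <= 1.0:
            raise ValueError("p_fix must lie in [0, 1]")
        if self.theta < 0 or self.t_conditional < 0:
            raise ValueError("times must be nonnegative")
        if self.method not in ("closed_form", "quadrature", "bvp", "monte_carlo"):
            raise ValueError(f"unknown method tag {self.method!r}")


# -- drift and variance terms ----------------------------------------------------


def mean_change_haploid(p: float, s_het: float) -> float:
    """Haploid per-generation mean change M(p) = p(1-p) s / (1 + s p)."""
    p = _check_frequency(p)
    denom = 1.0 + s_het * p
    if denom <= 0.0:
        raise ValueError("1 + s_het*p must be positive")
    return p * (1.0 - p) * s_het / denom


def variance_haploid(p: float, s_het: float, N: int) -> float:
    """Haploid per-generation variance V(p) = [p(1-p)/(2N)] (2+s)/(1+sp)."""
    p = _check_frequency(p)
    if N < 2:
        raise ValueError("N must be >= 2")
    denom = 1.0 + s_het * p
    if denom <= 0.0:
        raise ValueError("1 + s_het*p must be positive")
    return p * (1.0 - p) / (2.0 * N) * (2.0 + s_het) / denom


def mean_change_kimura(p: float, scheme: SelectionScheme) -> float:
    """Kimura diploid drift M(p) = p(1-p)(s_aA + (s_AA - 2 s_aA) p).

    Frequency-dependent schemes are evaluated at the current frequency.
    """
    p = _check_frequency(p)
    s_het, s_hom = scheme.coefficients_at(p)
    return p * (1.0 - p) * (s_het + (s_hom - 2.0 * s_het) * p)


def variance_kimura(p: float, Ne: int) -> float:
    """Kimura diploid variance V(p) = p(1-p)/(2 Ne)."""
    p = _check_frequency(p)
    if Ne < 2:
        raise ValueError("Ne must be >= 2")
    return p * (1.0 - p) / (2.0 * Ne)


# -- fixation probabilities -------------------------------------------------------


def fixation_probability_closed(p0: float, s_het: float, N: int) -> float:
    """Closed-form fixation probability of the haploid/semidominant diffusion.

    p_fix = (1 - exp(-4N (s/(2+s)) p0)) / (1 - exp(-4N s/(2+s))); the neutral
    limit s -> 0 is p0, handled analytically.
    """
    p0 = _check_frequency(p0, "p0")
    if N < 2:
        raise ValueError("N must be >= 2")
    if s_het <= -1.0:
        raise ValueError("s_het must exceed -1")
    if abs(s_het) < NEUTRAL_EPS:
        return p0
    a = 4.0 * N * s_het / (2.0 + s_het)
    # expm1 keeps precision when a*p0 is tiny (single mutant, weak selection)
    num = -math.expm1(-a * p0)
    den = -math.expm1(-a)
    return num / den


def _psi_kimura(p: float, scheme: SelectionScheme, Ne: int) -> float:
    """2 M(p)/V(p) for the Kimura pair; the p(1-p) factors cancel."""
    s_het, s_hom = scheme.coefficients_at(p)
    return 4.0 * Ne * (s_het + (s_hom - 2.0 * s_het) * p)


def _psi_haploid(p: float, scheme: SelectionScheme, N: int) -> float:
    """2 M(p)/V(p) for the haploid pair; constant in p for constant s."""
    s_het, _ = scheme.coefficients_at(p)
    return 4.0 * N * s_het / (2.0 + s_het)


def _psi_for(scheme: SelectionScheme, pop: Population, drift: str):
    if drift == "kimura":
        return lambda p: _psi_kimura(p, scheme, pop.Ne)
    if drift == "haploid":
        return lambda p: _psi_haploid(p, scheme, pop.N)
    raise ValueError(f"unknown drift parameterization {drift!r}")


def fixation_probability_quadrature(
    p0: float,
    scheme: SelectionScheme,
    pop: Population,
    *,
    drift: str = "kimura",
    rtol: float = 1e-8,
) -> float:
    """Fixation probability by adaptive quadrature of the stationary solution.

    Computes ``u(p0) = int_0^p0 G / int_0^1 G`` with
    ``G(x) = exp(-int_0^x 2M/V dy)``.  The inner exponent is accumulated in
    log space and shifted by its minimum before exponentiation, so strong
    selection (N*s >> 1) underflows gracefully instead of overflowing.

    Parameters
    ----------
    drift:
        ``"kimura"`` (default) uses the diploid M/V pair carrying both
        coefficients; ``"haploid"`` substitutes the haploid pair (for
        constant coefficients this reproduces the closed form exactly).
    """
    p0 = _check_frequency(p0, "p0")
    if p0 == 0.0:
        return 0.0
    if p0 == 1.0:
        return 1.0
    if scheme.is_neutral:
        return p0

    psi = _psi_for(scheme, pop, drift)

    def exponent(x: float) -> float:
        val, _ = integrate.quad(psi, 0.0, x, epsabs=0.0, epsrel=rtol, limit=200)
        return val

    # shift by the minimum of the exponent so exp() never overflows; psi is
    # smooth and low-order, so a coarse scan brackets the minimum well
    scan = np.linspace(0.0, 1.0, 41)
    h_scan = np.array([exponent(x) for x in scan])
    shift = float(h_scan.min())

    def integrand(x: float) -> float:
        return math.exp(-(exponent(x) - shift))

    # guide the subdivision toward the boundary layer at 0 when selection is
    # strong (the integrand decays on scale 1/(N*s))
    scale = max(abs(psi(0.0)), abs(psi(0.5)), abs(psi(1.0)))
    breaks = sorted(
        {min(0.999999, k / scale) for k in (1.0, 3.0, 10.0, 30.0)} if scale > 10 else set()
    )

    def _quad(a: float, b: float) -> float:
        pts = [x for x in breaks if a < x < b] or None
        val, err = integrate.quad(
            integrand, a, b, points=pts, epsabs=0.0, epsrel=rtol, limit=500
        )
        if val != 0.0 and not math.isfinite(val):
            raise ArithmeticError(
                f"quadrature failed on [{a}, {b}]: value={val}, err={err}"
            )
        return val

    numer = _quad(0.0, p0)
    denom = numer + _quad(p0, 1.0)
    if denom <= 0.0:
        raise ArithmeticError("quadrature normalization vanished; check M/V inputs")
    return min(1.0, max(0.0, numer / denom))


def fixation_probability_frequency_dependent(
    p0: float,
    k_het: float,
    k_hom: float,
    pop: Population,
    *,
    drift: str = "kimura",
    rtol: float = 1e-8,
) -> float:
    """Fixation probability when s_het(p) = k_het p and s_hom(p) = k_hom p.

    Positive frequency dependence means a rare mutant has almost no advantage
    and must first spread by drift, so the result is far below the
    constant-coefficient case with the same endpoint coefficients.
    """
    if k_het < 0 or k_hom < 0:
        raise ValueError("slopes must be nonnegative")
    scheme = SelectionScheme.frequency_dependent(k_het, k_hom)
    return fixation_probability_quadrature(p0, scheme, pop, drift=drift, rtol=rtol)


def fixation_profile(
    scheme: SelectionScheme,
    pop: Population,
    grid: np.ndarray,
    *,
    drift: str = "kimura",
    refine: int = 8,
) -> np.ndarray:
    """Vectorized u(p) on an increasing grid over [0, 1].

    Same stationary solution as :func:`fixation_probability_quadrature` but
    computed once by cumulative integration on a refined copy of the grid;
    used by the fixation-time solver, which needs u at every mesh node.
    """
    grid = np.asarray(grid, dtype=float)
    if grid[0] != 0.0 or grid[-1] != 1.0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must increase strictly from 0 to 1")
    if scheme.is_neutral:
        return grid.copy()
    fine = np.linspace(0.0, 1.0, refine * (len(grid) - 1) + 1)
    psi = _psi_for(scheme, pop, drift)
    psi_vals = np.array([psi(x) for x in fine])
    h = integrate.cumulative_trapezoid(psi_vals, fine, initial=0.0)
    g = np.exp(-(h - h.min()))
    cum = integrate.cumulative_trapezoid(g, fine, initial=0.0)
    u_fine = cum / cum[-1]
    return np.interp(grid, fine, u_fine)
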