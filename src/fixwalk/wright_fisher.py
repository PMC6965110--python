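"""Forward-time diploid Wright-Fisher simulator.

Serves as the independent Monte-Carlo oracle for the diffusion results.
Each generation, genotype frequencies follow Hardy-Weinberg random mating,
selection reweights genotypes (fitnesses 1, 1+s_aA, 1+s_AA), and the next
generation's 2N allele copies are drawn binomially from the post-selection
expected frequency.  Frequency-dependent schemes evaluate their coefficients
at the current frequency each generation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .popgen_core import Population, SelectionScheme

__all__ = [
    "WFRun",
    "wf_next_frequency",
    "run_to_absorption",
    "estimate_fixation_statistics",
    "FixationEstimate",
]


@dataclass(frozen=True)
class WFRun:
    """Outcome of one simulated lineage: absorbed state, time, optional path."""

    fixed: bool
    generations: int
    censored: bool = False
    trajectory: np.ndarray | None = None


def _expected_frequency(p: float, scheme: SelectionScheme) -> float:
    """Post-selection expected mutant-allele frequency under random mating."""
    s_het, s_hom = scheme.coefficients_at(p)
    if 1.0 + s_het < 0.0 or 1.0 + s_hom < 0.0:
        raise ValueError("genotype fitness 1+s must be nonnegative")
    q = 1.0 - p
    w_hom = p * p * (1.0 + s_hom)
    w_het = p * q * (1.0 + s_het)  # half the heterozygote mass, carrying one A
    w_bar = w_hom + 2.0 * w_het + q * q
    return (w_hom + w_het) / w_bar


def wf_next_frequency(
    p: float,
    scheme: SelectionScheme,
    N: int,
    rng: np.random.Generator,
) -> float:
    """One Wright-Fisher generation: returns the next allele frequency.

    The boundaries 0 and 1 are absorbing (no recurrent mutation).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if p == 0.0 or p == 1.0:
        return p
    p_star = _expected_frequency(p, scheme)
    return rng.binomial(2 * N, p_star) / (2.0 * N)


def run_to_absorption(
    p0: float,
    scheme: SelectionScheme,
    pop: Population,
    rng: np.random.Generator,
    max_generations: int | None = None,
    *,
    record_trajectory: bool = False,
) -> WFRun:
    """Iterate until the mutant allele fixes or is lost.

    Runs hitting ``max_generations`` (default 100 N) are flagged as censored,
    never silently counted as losses.
    """
    if max_generations is None:
        max_generations = 100 * pop.N
    if max_generations < 1:
        raise ValueError("max_generations must be >= 1")
    p = float(p0)
    traj = [p] if record_trajectory else None
    gen = 0
    while 0.0 < p < 1.0 and gen < max_generations:
        p = wf_next_frequency(p, scheme, pop.N, rng)
        gen += 1
        if traj is not None:
            traj.append(p)
    censored = 0.0 < p < 1.0
    return WFRun(
        fixed=(p == 1.0),
        generations=gen,
        censored=censored,
        trajectory=np.array(traj) if traj is not None else None,
    )


@dataclass(frozen=True)
class FixationEstimate:
    """Monte-Carlo estimates of fixation probability and conditional time."""

    p_fix: float
    p_fix_se: float
    t_conditional: float | None
    t_conditional_se: float | None
    n_replicates: int
    n_fixed: int
    n_censored: int


def estimate_fixation_statistics(
    p0: float,
    scheme: SelectionScheme,
    pop: Population,
    replicates: int,
    rng: np.random.Generator,
    max_generations: int | None = None,
) -> FixationEstimate:
    """Replicate :func:`run_to_absorption` and aggregate.

    The fixation probability carries a binomial standard error; the
    conditional fixation time averages over fixed runs only and is reported
    as unavailable (None) when no run fixed.
    """
    if replicates < 100:
        raise ValueError("need >= 100 replicates for meaningful errors")
    n_fixed = 0
    n_censored = 0
    fix_times: list[int] = []
    for _ in range(replicates):
        run = run_to_absorption(p0, scheme, pop, rng, max_generations)
        if run.censored:
            n_censored += 1
        elif run.fixed:
            n_fixed += 1
            fix_times.append(run.generations)
    p_hat = n_fixed / replicates
    se = float(np.sqrt(p_hat * (1.0 - p_hat) / replicates))
    if fix_times:
        t_arr = np.asarray(fix_times, dtype=float)
        t_mean = float(t_arr.mean())
        t_se = float(t_arr.std(ddof=1) / np.sqrt(len(t_arr))) if len(t_arr) > 1 else None
    else:
        t_mean = None
        t_se = None
    return FixationEstimate(
        p_fix=p_hat,
        p_fix_se=se,
        t_conditional=t_mean,
        t_conditional_se=t_se,
        n_replicates=replicates,
        n_fixed=n_fixed,
        n_censored=n_censored,
    )
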