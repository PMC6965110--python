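"""Synthetic beneficial-effect tables with the structure the analysis assumes.

Real measurements of beneficial fitness effects *at occurrence* exist only
for fast-evolving organisms (e.g. site-directed mutagenesis in RNA viruses);
this module generates stand-in data with the same statistical structure so
the fitting and accumulation stages run with no external download:

* "random" effects — i.i.d. exponential draws with mean E[Delta_1], the
  occurrence spectrum of beneficial mutations;
* "preobserved" effects — draws from the improvement distribution, i.e.
  the occurrence spectrum filtered by the probability of going to fixation,
  which shifts mass toward larger effects.

All generators are pure functions of their spec (including its seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .mutation_spectrum import EffectSample, ImprovementDistribution, sample_improvement

__all__ = ["SyntheticSpec", "generate_random_effects", "generate_preobserved_effects", "bin_effects"]

#: default bin edges spanning the range where viral beneficial effects
#: concentrate (0 to ~0.4), at the granularity typical of such datasets
DEFAULT_BIN_EDGES = np.arange(0.0, 0.45, 0.05)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic effects dataset.

    ``e_delta1`` is the true mean beneficial effect E[Delta_1]; ``N`` the
    population size entering the fixation filter for preobserved effects
    (``math.inf`` selects the large-population mode).  Defaults mirror the
    working point of the analysis: E[Delta_1] = 1/30, N = 1500.
    """

    e_delta1: float = 1.0 / 30.0
    n_random: int = 1000
    n_preobserved: int = 1000
    N: float = 1500
    bin_edges: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.e_delta1 <= 0:
            raise ValueError("E[Delta_1] must be positive")
        if self.n_random < 0 or self.n_preobserved < 0:
            raise ValueError("sample counts must be nonnegative")
        if math.isfinite(self.N) and self.N < 2:
            raise ValueError("N must be >= 2 (or inf)")


def generate_random_effects(spec: SyntheticSpec) -> EffectSample:
    """Exponential occurrence draws: i.i.d. with mean e_delta1."""
    rng = np.random.default_rng(spec.seed)
    effects = rng.exponential(scale=spec.e_delta1, size=spec.n_random)
    return EffectSample(effects=effects, kind="random")


def generate_preobserved_effects(spec: SyntheticSpec) -> EffectSample:
    """Occurred-and-fixed draws from the improvement distribution.

    Uses a seed stream distinct from the random-effects generator so the two
    samples from one spec are independent.
    """
    rng = np.random.default_rng([spec.seed, 1])
    dist = ImprovementDistribution(alpha=1.0 / spec.e_delta1, N=spec.N)
    if spec.n_preobserved == 0:
        effects = np.empty(0)
    else:
        effects = sample_improvement(dist, rng, size=spec.n_preobserved)
    return EffectSample(effects=effects, kind="preobserved")


def bin_effects(
    sample: EffectSample,
    bin_edges: np.ndarray | None = None,
    *,
    overflow: str = "error",
) -> EffectSample:
    """Attach bin counts to a sample.

    ``overflow`` controls effects outside the edges: "error" (default)
    rejects them, "drop" excludes them from the counts (the total is then
    not preserved), "clip" assigns them to the first/last bin.
    """
    edges = np.asarray(DEFAULT_BIN_EDGES if bin_edges is None else bin_edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    if overflow not in ("error", "drop", "clip"):
        raise ValueError(f"unknown overflow policy {overflow!r}")
    effects = sample.effects
    outside = (effects < edges[0]) | (effects > edges[-1])
    if overflow == "error" and np.any(outside):
        raise ValueError(
            f"{int(outside.sum())} effects fall outside the bin range "
            f"[{edges[0]}, {edges[-1]}]; pass overflow='drop' or 'clip'"
        )
    binned = effects
    if overflow == "clip":
        # nudge inside the closed range so histogram assigns extreme values
        binned = np.clip(effects, edges[0], edges[-1])
    counts, _ = np.histogram(binned, bins=edges)
    return EffectSample(
        effects=sample.effects,
        kind=sample.kind,
        bin_edges=edges,
        bin_counts=counts.astype(float),
    )
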