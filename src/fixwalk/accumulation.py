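"""Monte-Carlo accumulation of improvements up to a target total fitness gain.

An adaptive walk is simulated by drawing improvement sizes (effects of
mutations that occur and fix) from the improvement distribution and summing
them until the running total reaches the target gain m.  Because steps are
discrete, the expected number of steps exceeds m divided by the mean step:
the final step overshoots the threshold.  The headline question is how many
improvements a total gain of m = 1 requires and how large the biggest step
in each walk is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mutation_spectrum import ImprovementDistribution, sample_improvement

__all__ = ["AccumulationRun", "AccumulationSummary", "accumulate", "accumulate_many", "summarize"]


@dataclass(frozen=True)
class AccumulationRun:
    """Ordered improvement sizes of one walk; the last step crosses m."""

    steps: tuple[float, ...]
    m: float

    def __post_init__(self) -> None:
        if self.m < 0:
            raise ValueError("target m must be nonnegative")
        if any(s <= 0 for s in self.steps):
            raise ValueError("improvement sizes must be positive")
        if self.m > 0:
            if self.total < self.m:
                raise ValueError("walk stopped before reaching m")
            if self.total - self.steps[-1] >= self.m:
                raise ValueError("walk overshot: threshold crossed before final step")

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    @property
    def total(self) -> float:
        return float(sum(self.steps))

    @property
    def max_step(self) -> float:
        return max(self.steps) if self.steps else 0.0


@dataclass(frozen=True)
class AccumulationSummary:
    """Histograms and moments of step counts and maximal step sizes."""

    n_runs: int
    params: dict
    n_steps_edges: np.ndarray
    n_steps_hist: np.ndarray
    max_step_edges: np.ndarray
    max_step_hist: np.ndarray
    mean_n_steps: float
    mean_max_step: float
    quantiles_n_steps: dict
    quantiles_max_step: dict

    def to_dict(self) -> dict:
        return {
            "n_runs": self.n_runs,
            "params": self.params,
            "n_steps": {
                "edges": self.n_steps_edges.tolist(),
                "counts": self.n_steps_hist.tolist(),
                "mean": self.mean_n_steps,
                "quantiles": self.quantiles_n_steps,
            },
            "max_step": {
                "edges": self.max_step_edges.tolist(),
                "counts": self.max_step_hist.tolist(),
                "mean": self.mean_max_step,
                "quantiles": self.quantiles_max_step,
            },
        }


def accumulate(
    m: float,
    dist: ImprovementDistribution,
    rng: np.random.Generator,
) -> AccumulationRun:
    """Draw improvements until their sum reaches m; return the full walk."""
    if m < 0:
        raise ValueError("target m must be nonnegative")
    steps: list[float] = []
    total = 0.0
    while total < m:
        s = sample_improvement(dist, rng)
        steps.append(s)
        total += s
    return AccumulationRun(steps=tuple(steps), m=m)


def accumulate_many(
    m: float,
    dist: ImprovementDistribution,
    n_runs: int,
    rng: np.random.Generator,
) -> list[AccumulationRun]:
    if n_runs < 1:
        raise ValueError("need at least one run")
    return [accumulate(m, dist, rng) for _ in range(n_runs)]


def summarize(
    runs: list[AccumulationRun],
    *,
    params: dict | None = None,
    max_step_bin_width: float = 0.05,
) -> AccumulationSummary:
    """Aggregate walks into histograms of n_steps and max_step.

    n_steps uses unit-width integer bins; max_step uses fixed-width bins
    (default 0.05) from 0 up past the largest observed step.
    """
    if not runs:
        raise ValueError("no runs to summarize")
    n_steps = np.array([r.n_steps for r in runs])
    max_steps = np.array([r.max_step for r in runs])

    ns_edges = np.arange(n_steps.min(), n_steps.max() + 2) - 0.5
    ns_hist, _ = np.histogram(n_steps, bins=ns_edges)

    upper = max(1.0, float(max_steps.max()))
    n_bins = int(np.ceil(upper / max_step_bin_width + 1e-9))
    ms_edges = np.arange(n_bins + 1) * max_step_bin_width
    ms_hist, _ = np.histogram(max_steps, bins=ms_edges)

    qs = (0.05, 0.25, 0.5, 0.75, 0.95)
    return AccumulationSummary(
        n_runs=len(runs),
        params=dict(params or {}),
        n_steps_edges=ns_edges,
        n_steps_hist=ns_hist,
        max_step_edges=ms_edges,
        max_step_hist=ms_hist,
        mean_n_steps=float(n_steps.mean()),
        mean_max_step=float(max_steps.mean()),
        quantiles_n_steps={q: float(np.quantile(n_steps, q)) for q in qs},
        quantiles_max_step={q: float(np.quantile(max_steps, q)) for q in qs},
    )
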