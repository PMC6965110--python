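"""Beneficial-effect spectrum and the compound improvement distribution.

Extreme value theory (Gumbel domain) predicts that when the wild type is
already near the top of the local fitness landscape, the fitness effects s of
beneficial mutations are exponentially distributed,

    p(s) = alpha exp(-alpha s),   alpha = 1 / E[Delta_1],

where E[Delta_1] is the expected fitness gap between the best and second-best
possible mutants.  An *improvement* is the compound event of a beneficial
mutation occurring and going to fixation; its size distribution is the
occurrence density weighted by the fixation probability of a single mutant.
A closed-form approximation of the improvement CDF is

    CDF(s) = 1 - (exp(-alpha s)/beta) [ 1/alpha
             - exp(-2s)/(2+alpha)
             + exp(-(N+1)s)/(N(N+alpha+1)) ],

with beta the normalization making CDF(0)=0.  A large-population mode drops
the 1/(N(N+alpha+1)) term.  This module also fits the exponential rate to
observed effect tables by maximum likelihood (raw effects) or least squares
(binned frequencies).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "EffectDistribution",
    "ImprovementDistribution",
    "EffectSample",
    "effect_pdf",
    "improvement_beta",
    "improvement_cdf",
    "sample_improvement",
    "fit_exponential_mle",
    "fit_exponential_lsq",
    "read_effects_table",
    "write_effects_table",
]


@dataclass(frozen=True)
class EffectDistribution:
    """Exponential occurrence distribution of beneficial effects.

    ``e_delta1`` is E[Delta_1], the mean effect; the rate is
    ``alpha = 1/e_delta1``.  ``se`` carries the estimation standard error
    when the object comes from a fitter (None for exact specifications).
    """

    e_delta1: float
    se: float | None = None

    def __post_init__(self) -> None:
        if self.e_delta1 <= 0:
            raise ValueError("E[Delta_1] must be positive")

    @property
    def alpha(self) -> float:
        return 1.0 / self.e_delta1

    @property
    def mean(self) -> float:
        return self.e_delta1


def effect_pdf(s, dist: EffectDistribution):
    """Occurrence density alpha * exp(-alpha s) of a beneficial effect s >= 0."""
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("effect sizes must be nonnegative")
    out = dist.alpha * np.exp(-dist.alpha * s)
    return float(out) if out.ndim == 0 else out


def improvement_beta(alpha: float, N: float) -> float:
    """Normalization beta of the improvement CDF, from CDF(0) = 0.

    beta = 1/alpha - 1/(2+alpha) + 1/(N(N+alpha+1)); N = inf drops the last
    term (large-effective-population mode).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    beta = 1.0 / alpha - 1.0 / (2.0 + alpha)
    if math.isfinite(N):
        if N < 2:
            raise ValueError("N must be >= 2 (or inf)")
        beta += 1.0 / (N * (N + alpha + 1.0))
    return beta


@dataclass(frozen=True)
class ImprovementDistribution:
    """Size distribution of improvements (mutations that occur *and* fix).

    ``N`` is the diploid population size entering the fixation-probability
    weight; ``N = inf`` selects the large-population closed form.  ``beta``
    is derived from (alpha, N) unless supplied.
    """

    alpha: float
    N: float = math.inf
    beta: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.beta is None:
            object.__setattr__(self, "beta", improvement_beta(self.alpha, self.N))


def improvement_cdf(s, dist: ImprovementDistribution):
    """Cumulative probability that an improvement has size <= s."""
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("improvement sizes must be nonnegative")
    a, N, beta = dist.alpha, dist.N, dist.beta
    bracket = 1.0 / a - np.exp(-2.0 * s) / (2.0 + a)
    if math.isfinite(N):
        bracket = bracket + np.exp(-(N + 1.0) * s) / (N * (N + a + 1.0))
    out = 1.0 - np.exp(-a * s) / beta * bracket
    out = np.clip(out, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def _cdf_scalar(s: float, a: float, N: float, beta: float) -> float:
    """Scalar improvement CDF without array overhead (hot path of the sampler)."""
    bracket = 1.0 / a - math.exp(-2.0 * s) / (2.0 + a)
    if math.isfinite(N):
        bracket += math.exp(-(N + 1.0) * s) / (N * (N + a + 1.0))
    return 1.0 - math.exp(-a * s) / beta * bracket


def sample_improvement(
    dist: ImprovementDistribution,
    rng: np.random.Generator,
    size: int | None = None,
):
    """Draw improvement sizes by inverse-CDF root finding.

    Returns a scalar when ``size`` is None, else an array of that length.
    Draws are strictly positive (the CDF has no atom at 0).
    """
    n = 1 if size is None else int(size)
    u = rng.random(n)
    out = np.empty(n)
    a, N, beta = dist.alpha, dist.N, dist.beta
    for i, ui in enumerate(u):
        # upper bracket: the tail is dominated by exp(-alpha s)/(alpha beta)
        hi = max(1.0, -math.log(max(1e-300, (1.0 - ui) * a * beta)) / a + 1.0)
        while _cdf_scalar(hi, a, N, beta) < ui:
            hi *= 2.0
            if hi > 1e6:
                raise ArithmeticError("inverse-CDF bracket expansion failed")
        out[i] = brentq(lambda x: _cdf_scalar(x, a, N, beta) - ui, 0.0, hi, xtol=1e-12)
    return float(out[0]) if size is None else out


@dataclass(frozen=True)
class EffectSample:
    """A set of beneficial-effect observations, raw and/or binned.

    ``kind`` distinguishes "random" effects (as they occur, the ones that
    identify E[Delta_1]) from "preobserved" effects (seen after occurrence
    and fixation, hence biased toward larger values).
    """

    effects: np.ndarray
    kind: str = "random"
    bin_edges: np.ndarray | None = None
    bin_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        effects = np.asarray(self.effects, dtype=float)
        object.__setattr__(self, "effects", effects)
        if self.kind not in ("random", "preobserved"):
            raise ValueError(f"unknown sample kind {self.kind!r}")
        if np.any(effects <= 0):
            raise ValueError("all effects must be positive")
        if (self.bin_edges is None) != (self.bin_counts is None):
            raise ValueError("bin_edges and bin_counts must be given together")
        if self.bin_edges is not None:
            edges = np.asarray(self.bin_edges, dtype=float)
            counts = np.asarray(self.bin_counts, dtype=float)
            if np.any(np.diff(edges) <= 0):
                raise ValueError("bin edges must be strictly increasing")
            if len(counts) != len(edges) - 1:
                raise ValueError("need one count per bin")
            if np.any(counts < 0):
                raise ValueError("bin counts must be nonnegative")
            object.__setattr__(self, "bin_edges", edges)
            object.__setattr__(self, "bin_counts", counts)

    def __len__(self) -> int:
        return len(self.effects)


def fit_exponential_mle(sample: EffectSample) -> EffectDistribution:
    """Maximum-likelihood exponential fit: E[Delta_1] equals the sample mean.

    The large-sample standard error of the mean of an exponential is
    mean/sqrt(n); with a single observation it is undefined (None).
    """
    if len(sample) == 0:
        raise ValueError("cannot fit an empty sample")
    if sample.kind != "random":
        warnings.warn(
            "fitting E[Delta_1] to a non-'random' sample conflates occurrence "
            "with fixation and biases the estimate upward",
            stacklevel=2,
        )
    mean = float(np.mean(sample.effects))
    n = len(sample)
    se = mean / math.sqrt(n) if n > 1 else None
    return EffectDistribution(e_delta1=mean, se=se)


def fit_exponential_lsq(
    sample: EffectSample,
    *,
    fit_density: bool = False,
    alpha_bounds: tuple[float, float] = (1e-3, 1e4),
) -> EffectDistribution:
    """Least-squares exponential fit to binned effect data.

    By default minimizes the squared difference between observed bin
    *frequencies* and the exponential model's bin probabilities
    ``exp(-alpha e_i) - exp(-alpha e_{i+1})``.  With ``fit_density=True`` it
    instead fits the density evaluated at bin midpoints to the observed
    count density (counts / (total * width)).
    """
    if sample.bin_edges is None:
        raise ValueError("least-squares fitting needs binned data")
    edges = sample.bin_edges
    counts = sample.bin_counts
    if len(counts) < 3:
        raise ValueError("need at least 3 bins to fit")
    total = counts.sum()
    if total <= 0:
        raise ValueError("bins are empty")

    if fit_density:
        mids = 0.5 * (edges[:-1] + edges[1:])
        widths = np.diff(edges)
        observed = counts / (total * widths)

        def ssq(alpha: float) -> float:
            return float(np.sum((alpha * np.exp(-alpha * mids) - observed) ** 2))
    else:
        observed = counts / total

        def ssq(alpha: float) -> float:
            model = np.exp(-alpha * edges[:-1]) - np.exp(-alpha * edges[1:])
            return float(np.sum((model - observed) ** 2))

    # the objective is flat (to machine precision) once exp(-alpha*edge)
    # underflows in every bin but the first, so a blind bounded search can
    # stall on that plateau: locate the basin on a log grid, then refine
    grid = np.geomspace(alpha_bounds[0], alpha_bounds[1], 400)
    best = grid[int(np.argmin([ssq(a) for a in grid]))]
    res = minimize_scalar(
        ssq,
        bounds=(best / 2.0, best * 2.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:
        raise ArithmeticError(f"least-squares optimizer failed: {res.message}")
    return EffectDistribution(e_delta1=1.0 / res.x)


# -- effects-table I/O ------------------------------------------------------------
# Format: delimited text, header row with an `effect` column and an optional
# integer `count` column; lines beginning with '#' are comments.


def _sniff_delimiter(path) -> str:
    """First non-comment line decides: comma, tab, semicolon, or whitespace."""
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                for sep in (",", "\t", ";"):
                    if sep in line:
                        return sep
                return r"\s+"
    return ","


def read_effects_table(path, kind: str = "random") -> EffectSample:
    """Read an effects table; a `count` column replicates each effect."""
    try:
        df = pd.read_csv(path, comment="#", sep=_sniff_delimiter(path), engine="python")
    except (pd.errors.ParserError, ValueError, OSError) as exc:
        raise ValueError(f"malformed effects table {path}: {exc}") from exc
    if "effect" not in df.columns:
        raise ValueError(f"effects table {path} lacks an 'effect' column (header required)")
    effects = df["effect"].to_numpy(dtype=float)
    bad = np.nonzero(~np.isfinite(effects) | (effects <= 0))[0]
    if bad.size:
        # +2: one for the header row, one for 1-based numbering
        raise ValueError(
            f"non-positive or non-numeric effect at line {bad[0] + 2} of {path}"
        )
    if "count" in df.columns:
        counts = df["count"].to_numpy()
        if np.any(counts < 0) or np.any(counts != np.floor(counts)):
            raise ValueError(f"counts in {path} must be nonnegative integers")
        effects = np.repeat(effects, counts.astype(int))
    return EffectSample(effects=effects, kind=kind)


def write_effects_table(sample: EffectSample, path) -> None:
    """Write the raw effects of a sample as a two-column delimited table."""
    pd.DataFrame({"effect": sample.effects}).to_csv(path, index=False)
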