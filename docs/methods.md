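# Methods

## Model

A biallelic locus in a randomly mating diploid population of census size N
(effective size Ne, default Ne = N).  Wild type has fitness 1; heterozygote
and homozygote mutants have fitnesses 1 + s_aA and 1 + s_AA.  Dominance
classes are encoded as constructors on `SelectionScheme`: dominant
(s_AA = s_aA), semidominant (s_AA = 2 s_aA, equivalent to a haploid model),
recessive (s_aA = 0).  Positive frequency dependence — an advantage that
only pays once carriers are common, as expected for a communicative trait —
is modelled linearly: s_aA(p) = k_het p, s_AA(p) = k_hom p.  A new mutation
starts as a single heterozygote, p0 = 1/(2N).  Selection coefficients up to
s = 1 (carriers leaving on average twice the offspring of wild type) are the
intended range; larger values are accepted with a warning because the
diffusion machinery is an extrapolation there.

## Fixation probability

Two drift/variance parameterizations of the diffusion are provided:

* **Kimura diploid pair** (default): M(p) = p(1−p)(s_aA + (s_AA − 2 s_aA)p),
  V(p) = p(1−p)/(2Ne).  This is the only displayed form that carries both
  genotype coefficients, so it also serves the recessive and
  frequency-dependent cases (coefficients evaluated at the current p).
* **Haploid pair** (`drift="haploid"`): M(p) = p(1−p) s/(1+sp),
  V(p) = [p(1−p)/2N](2+s)/(1+sp).  Its stationary solution has the closed
  form implemented in `fixation_probability_closed`; the quadrature route in
  this mode reproduces it to machine precision, which is the package's
  route-equivalence check.

The two pairs are *not* interchangeable: the haploid variance carries a
factor (2+s)/(1+sp) ≈ 2 at low frequency, i.e. it describes a reproduction
scheme with offspring variance near 2.  A binomial-resampling Wright–Fisher
process has offspring variance near 1 and is matched by the Kimura pair —
our simulator confirms this directly (semidominant s = 0.1, N = 1500:
Kimura route 0.181, haploid/closed form 0.091, Wright–Fisher ≈ 0.18).  The
Kimura pair is therefore the default; the haploid pair is retained as the
closed form's exact counterpart and for comparison.

The stationary solution u(p0) = ∫₀^p0 G / ∫₀¹ G, G = exp(−∫ 2M/V), is
computed by adaptive quadrature (scipy `quad`, relative tolerance 1e−8,
configurable).  The inner exponent is accumulated separately and shifted by
its minimum before exponentiation, so N·s ≫ 1 produces graceful underflow
of the integrand rather than overflow; breakpoints on the selection length
scale 1/(N·s) guide the subdivision through the boundary layer at p = 0.
For whole-profile evaluation (needed by the time solver) the same quantity
is computed once by cumulative trapezoidal integration on an 8× refined
grid.

## Fixation time

ϑ(p) — the product of fixation probability and mean fixation time — solves
M ϑ′ + ½V ϑ″ = −u(p) with ϑ(0) = ϑ(1) = 0.  The mean time among lineages
that fix is τ(p0) = ϑ(p0)/u(p0).  (Some texts call τ the *conditional*
time and ϑ appears only as an intermediate; both are exposed, named by
formula, on `FixationResult`.)

Numerics: second-order central finite differences on a uniform mesh of
(0, 1), default 2000 interior nodes, endpoints imposed exactly (V → 0 there,
so the singular rows are never assembled); the tridiagonal system is solved
with a banded LU.  The solver warns when the cell Péclet number max|M|h/V
exceeds 2 (very large N·s at a given resolution), where central differences
may oscillate; the remedy is more nodes.  Because ϑ bends on the selection
scale 1/(2Ns) near p = 0 while τ(p) = ϑ/u varies slowly there, the solver
interpolates τ on the mesh (constant extrapolation below the first node)
and reconstructs ϑ(p0) = τ(p0)·u(p0); this keeps p0 = 1/(2N) accurate even
when it falls below the mesh spacing.  Validation: the neutral case has the
exact solution ϑ(p) = −4Ne(1−p)ln(1−p), matched to <0.1%; the solution
agrees with scipy's adaptive `solve_bvp` to <0.1%; and the drift limit
τ(1/(2N)) → 4N generations is reproduced within 10% for N from 100 to 1500.

A qualitative note the Wright–Fisher oracle confirms: for a *dominant*
beneficial mutation at N·s ≈ 1 the conditional fixation time is slightly
*longer* than the neutral 4N (e.g. N = 100, s = 0.01: ≈ 420 vs ≈ 400
generations), because the allele's advantage plateaus near fixation and the
final approach is pure drift.  Monotone decrease of τ with s holds from
moderate s upward.

## Wright–Fisher oracle

Each generation: Hardy–Weinberg genotype frequencies, selection reweighting,
then a binomial draw of the 2N allele copies from the post-selection
expected frequency p* = [p²(1+s_AA) + p(1−p)(1+s_aA)] / w̄.  This binomial
kernel is the package's oracle definition (genotypes are not individually
tracked; no mutation, no structure).  Runs hitting the generation cap
(default 100N) are flagged censored, never counted as losses.

Agreement between diffusion and simulator is a *model* comparison, not just
a numerical one: the diffusion neglects O(s²) terms, so its absorption
probability deviates from the discrete process as selection strengthens
(dominant s = 0.5, N = 100: diffusion 0.629 vs simulation ≈ 0.583).  Tests
therefore assert 3-SE agreement in the weak-to-moderate regime (s ≈ 0.05,
where the measured bias is within ~1 SE at 10⁵ replicates) and
bounded relative error (10%) at moderate s; at s near 1 the diffusion
figures should be read as approximations good to tens of percent.

## Effect spectrum and improvements

Occurrence spectrum: p(s) = α e^{−αs}, α = 1/E[Δ₁], the extreme-value
(Gumbel-domain) prediction when the wild type is already near-optimal.  The
working value α = 30 reflects fits to viral mutation data (maximum
likelihood ≈ 1/53, least squares ≈ 1/37; 1/30 is a deliberately
conservative round value that avoids biasing against large effects).

Improvement distribution (effect sizes of mutations that occur *and* fix,
from a single copy):

CDF(s) = 1 − (e^{−αs}/β)[1/α − e^{−2s}/(2+α) + e^{−(N+1)s}/(N(N+α+1))],

with β = 1/α − 1/(2+α) + 1/(N(N+α+1)) fixed by CDF(0) = 0; an N = ∞ mode
drops the N-term (appropriate when the fixation filter is dominated by the
branching-process phase).  The closed form was verified against the
numerically integrated, normalized product of the occurrence density and the
closed-form fixation probability: maximum CDF discrepancy ≈ 7×10⁻⁴ over
s ∈ [0, 1] at (α = 30, N = 1500), asserted in tests at 2×10⁻³; the pointwise
density ratio deviates by up to ~4%, asserted at 10%.  Sampling is by
inverse-CDF bisection (Brent, xtol 1e−12) with an analytic tail bracket; an
independent rejection sampler from the exact product density lives in the
test suite only and is statistically indistinguishable from it.

Fitting: the exponential MLE is the sample mean of "random" (at-occurrence)
effects, SE = mean/√n; fitting "preobserved" effects is allowed but warns,
since it conflates occurrence with fixation.  Least squares fits binned
frequencies to exponential bin probabilities (a density-at-midpoint mode is
available behind `fit_density=True`); because the objective is flat to
machine precision once e^{−α·edge} underflows in all but the first bin, the
optimizer first locates the basin on a 400-point log grid and then refines
with bounded Brent, which is deterministic given data and bounds.

## Accumulation experiment

Walks draw improvements i.i.d. until the running sum reaches the target m;
the final step overshoots by construction, so the mean step count exceeds
m divided by the mean improvement.  Defaults are the analysis' working
point: m = 1, α = 30, N = 1500, 10 000 replicates in the CLI (1000 in the
acceptance script, where the mean is already stable to ~1%).  Histogram
binning: unit-width integer bins for step counts, 0.05-wide bins for the
maximal step, both configurable.  At the working point the mean walk takes
≈ 16 improvements, essentially no walk finishes in one step, and ~98% of
walks contain a largest step between 0.1 and 0.4.

## Synthetic data

`generate_random_effects` draws i.i.d. exponential effects (the occurrence
spectrum); `generate_preobserved_effects` draws from the improvement
distribution via the production sampler (one code path; the rejection
oracle stays in tests).  Both are pure functions of (spec, seed), with
distinct derived streams so the two samples are independent.  The generator
emulates only the *distributional* structure of viral fitness assays —
i.i.d. draws, known truth, optional binning on a 0–0.4 grid.  It does not
emulate measurement error, assay detection thresholds, or the small and
irregular sample sizes of real datasets, so passing recovery tests
demonstrates estimator correctness, not robustness to those artefacts.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| N, Ne | 1500 | hunter-gatherer ethno-linguistic group scale |
| p0 | 1/(2N) | single heterozygous mutant |
| α = 1/E[Δ₁] | 30 | occurrence-spectrum rate (dimensionless fitness) |
| m | 1 | target total fitness gain |
| generation | 25–30 y | conversion of generations to years |
| mesh | 2000 nodes | time-solver grid on (0,1) |
| quadrature rtol | 1e−8 | stationary-solution integrals |

## Limitations

- Single locus, no recurrent mutation, no linkage or epistasis; multiple
  mutations are treated as independent walks, which is an input assumption
  of the accumulation analysis, not derived machinery.
- The diffusion results degrade at s near 1 (see above); the Wright–Fisher
  module is the arbiter there.
- The closed-form improvement CDF inherits the haploid fixation
  approximation; its few-percent density error is documented and tested but
  not removed.
- Time-dependent fixation densities u(p, t) and sojourn distributions are
  out of scope; only absorption probabilities and mean times are computed.
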