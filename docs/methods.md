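# Methods

## The model

`aneudyn` follows a clonal population of N cells through four genotypes:
the euploid wild type (2n), the aneuploid wild type (2n+1, one extra
chromosome), the aneuploid mutant (2n+1*, extra chromosome plus one
beneficial mutation), and the euploid mutant (2n*, standard karyotype plus
the mutation).  Each discrete, non-overlapping generation applies three
operators in a fixed order:

1. **Selection.**  f_i ← f_i·w_i / w̄ with w̄ = Σ_j f_j·w_j.  Fitness is
   relative to the wild type (w_2n ≡ 1); in the default model
   w_2n < w_2n+1 < w_2n+1* < w_2n*, i.e. the extra chromosome is beneficial
   but the refined mutation is better, and carrying both is intermediate.
2. **Mutation and chromosome gain/loss.**  Beneficial mutation at rate μ
   (2n → 2n*, 2n+1 → 2n+1*), chromosome gain/loss at rate δ
   (2n → 2n+1, 2n+1* → 2n*).  Back-mutations are neglected, as are events
   creating less-fit genotypes, unless `allow_back_transitions` is set
   (which adds 2n+1 → 2n and 2n* → 2n+1* at rate δ).  The
   genetic-instability variant multiplies μ inside aneuploid genotypes by
   τ; `loss_multiplier` scales the 2n+1* → 2n* rate independently of δ.
3. **Drift.**  One multinomial resample of N cells.

The within-generation order (selection → transitions → drift) follows the
order in which the operators are defined; nothing in the analysis depends
on cyclic rotations of this order, but fixed-point quantities are reported
on the post-drift state of each generation.

The population size is the harmonic mean of the daily serial-dilution
census (8 doublings from 1.6×10⁶ cells), N = 6.425×10⁶ — the standard
variance-effective size for a fluctuating census.  All simulations start
from N cells of genotype 2n.

**Lineage tracking** splits 2n* by origin into 2nA* (descended from
aneuploid cells via mutation followed by chromosome loss) and 2nM* (direct
mutation from 2n).  This is a 5-state frequency vector, not a genealogy:
lineage identity is completely determined by which inflow created the
mass, so the 5-state deterministic model marginalizes exactly (to
floating-point tolerance, 1e-12) onto the 4-state model, a property the
test suite checks every generation.

**Early stopping.**  Without back-transitions the all-2n* state is
absorbing, and batch runs stop once every replicate reaches it.  In
lineage-tracked mode drift can still exchange 2nA*/2nM* mass after joint
fixation; stopping freezes that exchange.  The F_A mean is unaffected and
the per-replicate share SD changes by ≲0.005 at N = 6.425×10⁶, which is
negligible against the across-replicate spread.

## Event times and the observation likelihood

Fixation of a genotype class means frequency strictly above 0.95; loss
means strictly below 0.05 after fixation.  The aneuploid class is
f(2n+1) + f(2n+1*) (the karyotype an experiment assays); an option
restricts it to 2n+1 alone, which changes nothing material before
generation 450 when 2n+1* is still rare.

The data are four replicate populations in which aneuploidy fixed between
generations 200 and 450, with the two continued replicates losing it by
generations 1,700 and 2,350.  The likelihood of a parameter vector
θ = (μ, δ, w_2n+1, w_2n+1*, w_2n*) is approximated from n_sims simulated
experiments (default 1,000): with W the window event
{200 ≤ T(aneuploid) ≤ 450}, A = {T(2n*) < 1700} and
B = {1700 < T(2n*) < 2350} (2n* fixation is the proxy for aneuploidy
elimination, since f(2n) ≈ 0 by then),

    L(θ) = P(W)⁴ · [1 − P(¬A|W)⁴ − P(¬B|W)⁴ + P(¬A ∧ ¬B|W)⁴].

The bracket is inclusion–exclusion for "at least one of four replicates
lost aneuploidy before the first deadline AND at least one inside the
second window"; it attains its maximum 7/8 at P(A) = P(B) = ½, so
L ≤ 0.875 always.  For the δ = 0 model variant the bracket is evaluated
unconditionally (there is no window event).  Conditional estimates from
fewer than 10 qualifying simulations are flagged in the log but still
returned.  Window boundaries are inclusive, deadline inequalities strict,
exactly as written above.

## ABC-SMC

Inference is sequential ABC with importance resampling.  Priors:
μ ~ U(10⁻⁹, 10⁻⁵), δ ~ U(10⁻⁶, 10⁻²), and a truncated multivariate normal
on the three fitness values constrained to the ordering
w_2n* > w_2n+1* > w_2n+1 > 1.  The fitness prior stands in for an
informative prior estimated from growth curves in the original study; its
default (mean 1.02, sd 0.01 per component, independent) matches the scale
of the posterior fitness values, and all moments are configurable.  The
truncation constant is estimated once by Monte Carlo (2×10⁵ draws, fixed
internal seed) so the prior density is properly normalized.

A particle is accepted at iteration t when 1 − L(θ) < ε_t, where ε_t is
the median of 1 − L over the previous accepted population.  ε₀ = +∞
(accept-all prior iteration): the theoretical floor is 1 − 0.875 = 0.125,
so any finite sub-0.125 starting threshold would reject everything; a
finite ε₀ remains available as a configuration override.  The perturbation
kernel is multivariate normal with covariance equal to the weighted
particle covariance times a scale factor (default 2.0, the common SMC
choice).  A rank-deficient covariance — legitimate with few particles — is
kept as-is and handled as a singular normal on the spanned subspace;
only a zero-spread population triggers a diagonal fallback.  Weights
follow the standard SMC form, W_t(θ) = p(θ) / Σ_i W_{t−1}(θ_i)·K_t(θ|θ_i),
with W₀ ≡ 1.  The particle count is fixed per iteration (default 1,000)
rather than adaptive; per-particle likelihoods always use fresh simulation
seeds and are never cached across ε levels.  The run stops when ε changes
by less than a tolerance (default 0.01) or at an iteration cap, and aborts
with a diagnostic when the acceptance rate falls below a floor.

## Posterior summaries

The posterior is a Gaussian KDE over the weighted particles (Scott
bandwidth by default), truncated to the prior support.  The MAP is the
KDE mode found by Nelder–Mead restarts from the highest-density particles.
HDIs are shortest contiguous intervals over sorted samples; the default
sample count for interval estimation is 10⁵ (the full-scale 5×10⁶ is a
flag away, same algorithm).  WAIC is

    WAIC = −2·log E[L(θ)] + 2·V[log L(θ)]

with expectations over posterior samples and the population (1/n) variance
convention; zero-likelihood samples are dropped with a logged count.

## F_A, the lineage question

F_A is the share of the evolved euploid-mutant population descended from
aneuploid cells.  The primary estimator is the within-class share
f(2nA*) / (f(2nA*) + f(2nM*)) at the end of a lineage-tracked run
(default generation 2,350, the last experimental observation), averaged
over replicates; the population-frequency variant (mean final f(2nA*)) is
reported alongside and is nearly identical once 2n* has fixed.  Replicates
with no 2n* mass at the end carry no lineage information and are excluded
with a logged count (configurable).  Sensitivity sweeps over N, μ, δ, τ
and the loss multiplier report bootstrap CIs over replicates (default
10⁴ resamples).

## Synthetic data and the reduced-scale test regime

The generator simulates lineage-tracked replicates at known parameters
and summarizes them exactly like the real record: the fixation window
spans the replicate aneuploidy fixation times rounded outward to the
assay cadence (default 50 generations), and the loss deadlines are the
2n* fixation times of two randomly chosen replicates.  Records in which
aneuploidy never fixes, or fewer than two replicates reach 2n* fixation,
are flagged degenerate.

Recovery tests use a time-compressed analogue of the inferred dynamics:
μ = 10⁻⁵, δ = 10⁻², w = (1, 1.091, 1.104, 1.117), N = 10⁴, horizon 900.
This is the published-scale parameter point with the selective timescale
compressed roughly fourfold (fitness values raised to the 4th power, rates
multiplied accordingly), preserving the qualitative structure — the
aneuploid wave fixes within ~100 generations, the euploid mutant takes
over hundreds of generations later from a small relative fitness edge —
while a full sweep completes ~25× faster than at publication scale.  The
test suite runs 8 recovery repetitions at 24 particles × 32
simulations/particle × 3 iterations, with coverage assertions set to
binomial tolerances appropriate for that sample size.

What the synthetic generator does **not** emulate: measurement noise in
frequency assays, irregular assay schedules, shared environmental batch
effects across replicates, and any within-replicate demography beyond the
constant-N Wright–Fisher resample.  Passing recovery tests therefore
demonstrate the internal consistency of the simulator–likelihood–inference
loop, not robustness to those real-data complications.

## Numerical choices

- Frequency vectors must sum to 1 within 1e-9 on entry to public
  operations; deterministic recursions preserve the sum to 1e-12;
  post-drift frequencies are exact multiples of 1/N.
- Batch simulations share one numpy Generator across replicates so the
  per-generation update is fully vectorized; single-trajectory runs are
  reproducible from (params, seed).  All user-facing entry points derive
  independent child streams from one master seed.
- The MAP optimizer treats out-of-support points as −∞ and falls back to
  the best particle if no restart converges; a single-particle (or
  zero-spread) population is treated as a point mass.
- Ties at thresholds: all crossings are strict inequalities.

## Known limitations

- The posterior-predictive *spread* of the 2n* fixation time at
  publication-scale N is narrow (SD ≈ 35 generations at the point
  estimates, set by the ~40 effective founder lineages of the mutant
  class), and the median is pinned to the deterministic 0.95-crossing.
  Because the crossing time moves by roughly ±140 generations per ±0.0005
  change in a fitness value, statistics that depend on where the
  fixation-time distribution sits relative to a fixed deadline (the
  fraction fixed by generation 1,700, and the observation likelihood at a
  point estimate) are extremely sensitive to the fourth decimal place of
  the fitness parameters and should not be over-interpreted at any single
  parameter point.
- Likewise, the region of parameter space with non-zero observation
  likelihood is a thin slab under these dynamics, so sequential ABC on the
  real observations needs either large particle counts or an informative
  initialization to locate it; the reduced-scale smoke test documents this
  behaviour rather than hiding it.
- No per-cell genealogy, no deleterious or neutral mutations, at most one
  extra chromosome, and no more than one beneficial mutation per genome.
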