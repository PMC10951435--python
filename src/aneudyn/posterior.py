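"""Posterior summaries, model comparison, and the lineage question F_A.

F_A is the expected share of evolved euploid mutants (2n*) that descended
from aneuploid cells: cells that took the path 2n -> 2n+1 -> 2n+1* -> 2n*
(tracked as 2nA*) rather than mutating directly (2nM*).  It is estimated
from lineage-tracked stochastic simulations run to the end of the
experiment, as the mean over replicates of f(2nA*) / (f(2nA*) + f(2nM*))
at the final generation.

Model comparison uses WAIC on the approximate likelihood,

    WAIC = -2 log E[L(theta)] + 2 V[log L(theta)],

with the expectation and variance taken over posterior samples (population
1/n variance convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .abc_smc import PARAM_NAMES, ParticlePopulation, PriorSpec
from .wf_core import ModelParams, Trajectory, batch_events, fitness_vector

__all__ = [
    "PosteriorDensity",
    "FAResult",
    "map_estimate",
    "hdi",
    "waic",
    "waic_from_likelihoods",
    "PosteriorPredictive",
    "posterior_predictive",
    "compute_FA",
    "FADistribution",
    "fa_posterior",
    "fa_sensitivity",
    "adaptation_time",
]

logger = logging.getLogger(__name__)


class PosteriorDensity:
    """Gaussian-kernel density estimate over weighted posterior particles.

    The density is truncated to the prior support: it is zero outside it.
    The KDE bandwidth follows Scott's rule on the weighted particles (per
    scipy), configurable through ``bw_method``.
    """

    def __init__(
        self,
        population: ParticlePopulation,
        prior: Optional[PriorSpec] = None,
        bw_method=None,
    ):
        self.population = population
        self.prior = prior
        self.free = prior.free_indices if prior is not None else tuple(range(5))
        data = population.thetas[:, list(self.free)].T
        try:
            self.kde = stats.gaussian_kde(
                data, weights=population.weights, bw_method=bw_method
            )
            self.degenerate = False
        except (np.linalg.LinAlgError, ValueError):
            # a single particle (or identical particles) carries no spread:
            # treat the posterior as a point mass at the best particle
            self.kde = None
            self.degenerate = True
            self._point = population.thetas[int(np.argmax(population.weights))]

    def _full_theta(self, x: np.ndarray) -> np.ndarray:
        theta = np.zeros(5)
        theta[list(self.free)] = x
        return theta

    def logpdf(self, theta: np.ndarray) -> float:
        theta = np.asarray(theta, float)
        if self.prior is not None and not self.prior.in_support(theta):
            return -np.inf
        if self.degenerate:
            return 0.0 if np.allclose(theta, self._point) else -np.inf
        return float(self.kde.logpdf(theta[list(self.free)])[0])

    def pdf(self, theta: np.ndarray) -> float:
        return float(np.exp(self.logpdf(theta)))

    def sample(self, n: int, rng=None) -> np.ndarray:
        """Draw theta vectors from the truncated KDE by rejection."""
        rng = np.random.default_rng(rng)
        if self.degenerate:
            return np.tile(self._point, (n, 1))
        out = np.empty((n, 5))
        if self.prior is not None and self.prior.fix_delta_zero:
            out[:, 1] = 0.0
        filled = 0
        attempts = 0
        while filled < n:
            draw = self.kde.resample(
                max(2 * (n - filled), 16), seed=rng).T
            for x in draw:
                theta = self._full_theta(x)
                if self.prior is None or self.prior.in_support(theta):
                    out[filled] = theta
                    filled += 1
                    if filled == n:
                        break
            attempts += draw.shape[0]
            if attempts > 1000 * n + 10000:
                raise RuntimeError("KDE rejection sampling is not converging")
        return out


def map_estimate(post: PosteriorDensity, n_starts: int = 10) -> np.ndarray:
    """Mode of the truncated KDE by multi-start local optimization.

    Starts Nelder-Mead from the highest-density particles; if no start
    converges the best particle itself is returned with a warning.
    """
    pop = post.population
    if post.degenerate:
        return post._point.copy()
    free = list(post.free)
    dens = post.kde.logpdf(pop.thetas[:, free].T)
    order = np.argsort(dens)[::-1][:n_starts]
    best_x, best_val = None, -np.inf

    def neg_logpdf(x):
        theta = post._full_theta(x)
        lp = post.logpdf(theta)
        return -lp if np.isfinite(lp) else 1e12

    for i in order:
        x0 = pop.thetas[i, free]
        res = optimize.minimize(
            neg_logpdf, x0, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 2000},
        )
        if np.isfinite(res.fun) and -res.fun > best_val:
            candidate = post._full_theta(res.x)
            if post.prior is None or post.prior.in_support(candidate):
                best_val = -res.fun
                best_x = candidate
    if best_x is None:
        logger.warning("MAP optimization failed from all starts; "
                       "returning the highest-density particle")
        return pop.thetas[order[0]].copy()
    return best_x


def hdi(samples: Sequence[float], mass: float = 0.5) -> tuple:
    """Shortest contiguous interval containing ``mass`` of the samples."""
    if not (0 < mass <= 1):
        raise ValueError("mass must be in (0, 1]")
    x = np.sort(np.asarray(samples, float))
    n = x.size
    if n < 100:
        raise ValueError("need at least 100 samples for an HDI")
    m = int(np.ceil(mass * n))
    if m >= n:
        return (float(x[0]), float(x[-1]))
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return (float(x[i]), float(x[i + m - 1]))


def waic_from_likelihoods(likelihoods: Sequence[float]) -> float:
    """WAIC = -2 log mean(L) + 2 var(log L), population (1/n) variance.

    Zero likelihoods are dropped with a logged count; if all are zero the
    criterion is undefined.
    """
    L = np.asarray(likelihoods, float)
    n_zero = int(np.sum(L <= 0))
    if n_zero:
        logger.warning("dropping %d zero-likelihood samples from WAIC", n_zero)
        L = L[L > 0]
    if L.size == 0:
        raise ValueError("WAIC undefined: all likelihoods are zero")
    logL = np.log(L)
    return float(-2.0 * np.log(L.mean()) + 2.0 * np.var(logL))


def waic(
    posterior_samples: np.ndarray,
    likelihood_fn: Callable[[np.ndarray], float],
) -> float:
    """Evaluate the likelihood on posterior samples and return the WAIC."""
    L = np.array([likelihood_fn(theta) for theta in np.atleast_2d(posterior_samples)])
    return waic_from_likelihoods(L)


@dataclass
class PosteriorPredictive:
    """Distribution of the 2n* fixation time across simulations."""

    fixation_times: np.ndarray        # nan where 2n* never fixed
    fraction_fixed_by: dict           # deadline -> fraction
    n_sims: int

    def fraction_fixed(self, generation: float) -> float:
        t = self.fixation_times
        return float(np.mean(~np.isnan(t) & (t <= generation)))


def posterior_predictive(
    theta: ModelParams,
    n_sims: int = 10_000,
    rng=None,
    deadlines: tuple = (1700, 2350),
) -> PosteriorPredictive:
    """Simulate the 2n* fixation-time distribution at a parameter vector."""
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    horizon = max(theta.horizon, max(deadlines))
    res = batch_events(theta, n_sims, rng=rng, horizon=horizon)
    pp = PosteriorPredictive(
        fixation_times=res.t_fix_mutant,
        fraction_fixed_by={},
        n_sims=n_sims,
    )
    pp.fraction_fixed_by = {d: pp.fraction_fixed(d) for d in deadlines}
    return pp


@dataclass
class FAResult:
    """Share of the evolved euploid-mutant population of aneuploid descent."""

    fa: float                          # mean within-class share of 2nA*
    fa_population_frequency: float     # mean final population frequency of 2nA*
    per_replicate_share: np.ndarray    # nan where excluded
    final_2nA: np.ndarray
    final_2nM: np.ndarray
    n_excluded: int
    end_generation: int


def compute_FA(
    theta: ModelParams,
    n_reps: int = 100,
    end_generation: int = 2350,
    rng=None,
    exclude_empty: bool = True,
) -> FAResult:
    """F_A from lineage-tracked replicates run to ``end_generation``.

    The primary statistic is the within-class share
    f(2nA*) / (f(2nA*) + f(2nM*)) at the final generation, averaged over
    replicates; the population-frequency variant (mean final f(2nA*)) is
    reported alongside.  Replicates with no 2n* mass at the end carry no
    lineage information and are excluded with a logged count (configurable).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    res = batch_events(
        theta, n_reps, rng=rng, lineage_tracked=True, horizon=end_generation
    )
    fA = res.final_freqs[:, 3]
    fM = res.final_freqs[:, 4]
    total = fA + fM
    share = np.full(n_reps, np.nan)
    nonzero = total > 0
    share[nonzero] = fA[nonzero] / total[nonzero]
    n_excluded = int(np.sum(~nonzero))
    if n_excluded and exclude_empty:
        logger.warning(
            "%d of %d replicates had no 2n* mass at generation %d; excluded",
            n_excluded, n_reps, end_generation,
        )
    if not exclude_empty:
        share[~nonzero] = 0.0
    if np.all(np.isnan(share)):
        raise ValueError("all replicates had zero 2n* mass; F_A undefined")
    return FAResult(
        fa=float(np.nanmean(share)),
        fa_population_frequency=float(fA.mean()),
        per_replicate_share=share,
        final_2nA=fA,
        final_2nM=fM,
        n_excluded=n_excluded if exclude_empty else 0,
        end_generation=end_generation,
    )


@dataclass
class FADistribution:
    """Posterior distribution of F_A over parameter samples."""

    values: np.ndarray
    mode: float
    ci95: tuple
    fraction_above_half: float

    @classmethod
    def from_values(cls, values: np.ndarray) -> "FADistribution":
        values = np.asarray(values, float)
        values = values[~np.isnan(values)]
        if values.size == 0:
            raise ValueError("no F_A values")
        if values.size >= 10 and np.std(values) > 0:
            kde = stats.gaussian_kde(values)
            grid = np.linspace(0, 1, 1001)
            mode = float(grid[np.argmax(kde(grid))])
        else:
            mode = float(np.median(values))
        ci = (float(np.quantile(values, 0.025)),
              float(np.quantile(values, 0.975)))
        return cls(
            values=values,
            mode=mode,
            ci95=ci,
            fraction_above_half=float(np.mean(values > 0.5)),
        )


def fa_posterior(
    population: ParticlePopulation,
    n_samples: int = 200,
    n_reps_per_sample: int = 20,
    end_generation: int = 2350,
    N: int = 6_425_000,
    rng=None,
) -> FADistribution:
    """F_A distribution over weighted resamples of a particle population."""
    from .abc_smc import theta_to_params

    rng = np.random.default_rng(rng)
    idx = rng.choice(population.n_particles, size=n_samples,
                     p=population.weights)
    values = np.full(n_samples, np.nan)
    for j, i in enumerate(idx):
        theta = population.thetas[i]
        params = theta_to_params(theta, N=N, horizon=end_generation)
        try:
            values[j] = compute_FA(
                params, n_reps=n_reps_per_sample,
                end_generation=end_generation, rng=rng,
            ).fa
        except ValueError:
            continue
    return FADistribution.from_values(values)


def fa_sensitivity(
    theta: ModelParams,
    param: str,
    values: Sequence,
    n_reps: int = 50,
    end_generation: int = 2350,
    rng=None,
    n_boot: int = 10_000,
) -> pd.DataFrame:
    """F_A along a one-parameter sweep, with bootstrap confidence intervals.

    ``param`` is one of N, mu, delta, tau, loss_multiplier.  The bootstrap
    resamples replicates (n_boot resamples) for a 95% CI on the mean share.
    """
    if param not in ("N", "mu", "delta", "tau", "loss_multiplier"):
        raise ValueError(f"unsupported sweep parameter {param!r}")
    rng = np.random.default_rng(rng)
    rows = []
    for v in values:
        p = theta.replace(**{param: int(v) if param == "N" else float(v)})
        result = compute_FA(p, n_reps=n_reps, end_generation=end_generation,
                            rng=rng)
        share = result.per_replicate_share
        share = share[~np.isnan(share)]
        boots = rng.choice(share, size=(n_boot, share.size)).mean(axis=1)
        rows.append({
            "param": param,
            "value": v,
            "fa": result.fa,
            "fa_population_frequency": result.fa_population_frequency,
            "ci_low": float(np.quantile(boots, 0.025)),
            "ci_high": float(np.quantile(boots, 0.975)),
            "n_reps": n_reps,
            "n_excluded": result.n_excluded,
        })
    return pd.DataFrame(rows)


def adaptation_time(traj: Trajectory, fraction: float = 0.9999) -> Optional[int]:
    """First generation with mean fitness >= fraction * max fitness."""
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    w = fitness_vector(traj.params, traj.lineage_tracked)
    wbar = traj.mean_fitness_series()
    hits = np.nonzero(wbar >= fraction * w.max())[0]
    return int(hits[0]) if hits.size else None
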