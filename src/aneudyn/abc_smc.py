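"""Sequential ABC (ABC-SMC) over the model parameters.

The parameter vector is theta = (mu, delta, w_2n+1, w_2n+1*, w_2n*).  The
likelihood of a proposal is approximated by simulation
(:mod:`aneudyn.likelihood`) and a proposal is accepted when 1 - L(theta) is
below the current threshold epsilon_t.  Epsilon follows the median schedule:
epsilon_t is the median of 1 - L over the particles accepted at t-1.  The
perturbation kernel is a multivariate normal whose covariance is the
weighted covariance of the previous population times a scale factor.

Importance weights follow the standard SMC form: W_0 = 1 for the prior
iteration and, for t > 0,

    W_t(theta) = p(theta) / sum_i W_{t-1}(theta_i) K_t(theta | theta_i)

with p the prior density and K_t the kernel density.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .likelihood import (
    HEAT_EXPERIMENT,
    Observations,
    approximate_likelihood,
    likelihood_no_aneuploidy,
)
from .wf_core import ModelParams

__all__ = [
    "PARAM_NAMES",
    "PriorSpec",
    "PerturbationKernel",
    "ParticlePopulation",
    "ABCConfig",
    "theta_to_params",
    "sample_prior",
    "fit_kernel",
    "particle_weight",
    "effective_sample_size",
    "run_abc_smc",
]

logger = logging.getLogger(__name__)

PARAM_NAMES = ("mu", "delta", "w_2n+1", "w_2n+1*", "w_2n*")


@dataclass(frozen=True)
class PriorSpec:
    """Prior over theta = (mu, delta, w_2n+1, w_2n+1*, w_2n*).

    mu and delta have independent uniform priors.  The three fitness values
    have a multivariate normal prior truncated to the ordering
    w_2n* > w_2n+1* > w_2n+1 > 1 (the beneficial-aneuploidy ordering, with
    the wild-type fitness fixed at 1).  With ``fix_delta_zero`` the
    aneuploidy rate is pinned at 0 and drops out of the inferred vector
    (the no-aneuploidy model variant).
    """

    mu_bounds: tuple = (1e-9, 1e-5)
    delta_bounds: tuple = (1e-6, 1e-2)
    fitness_mean: tuple = (1.02, 1.02, 1.02)
    fitness_cov: tuple = ((1e-4, 0, 0), (0, 1e-4, 0), (0, 0, 1e-4))
    fix_delta_zero: bool = False

    def __post_init__(self):
        if not (0 <= self.mu_bounds[0] < self.mu_bounds[1]):
            raise ValueError("invalid mu bounds")
        if not (0 <= self.delta_bounds[0] < self.delta_bounds[1]):
            raise ValueError("invalid delta bounds")
        cov = np.asarray(self.fitness_cov, dtype=float)
        if cov.shape != (3, 3):
            raise ValueError("fitness_cov must be 3x3")

    @property
    def free_indices(self) -> tuple:
        """Indices of theta components the inference explores."""
        return (0, 2, 3, 4) if self.fix_delta_zero else (0, 1, 2, 3, 4)

    def _fitness_dist(self):
        return stats.multivariate_normal(
            mean=np.asarray(self.fitness_mean, float),
            cov=np.asarray(self.fitness_cov, float),
        )

    def _ordering_ok(self, w: np.ndarray) -> np.ndarray:
        return (w[..., 2] > w[..., 1]) & (w[..., 1] > w[..., 0]) & (w[..., 0] > 1.0)

    def truncation_mass(self, n_mc: int = 200_000) -> float:
        """Monte-Carlo estimate of the prior mass of the ordering region.

        Cached after the first call; uses a fixed internal seed so the prior
        density is a deterministic function of the spec.
        """
        cached = getattr(self, "_trunc_mass", None)
        if cached is None:
            rng = np.random.default_rng(20240311)
            w = self._fitness_dist().rvs(size=n_mc, random_state=rng)
            cached = float(self._ordering_ok(np.atleast_2d(w)).mean())
            if cached < 1e-6:
                raise ValueError(
                    "fitness ordering region has negligible prior mass; "
                    "check fitness_mean/fitness_cov"
                )
            object.__setattr__(self, "_trunc_mass", cached)
        return cached

    def in_support(self, theta: np.ndarray) -> bool:
        theta = np.asarray(theta, float)
        mu, delta, w = theta[0], theta[1], theta[2:5]
        if not (self.mu_bounds[0] <= mu <= self.mu_bounds[1]):
            return False
        if self.fix_delta_zero:
            if delta != 0:
                return False
        elif not (self.delta_bounds[0] <= delta <= self.delta_bounds[1]):
            return False
        return bool(self._ordering_ok(w))

    def logpdf(self, theta: np.ndarray) -> float:
        """Log prior density (normalized over the truncated support)."""
        if not self.in_support(theta):
            return -np.inf
        theta = np.asarray(theta, float)
        lp = -math.log(self.mu_bounds[1] - self.mu_bounds[0])
        if not self.fix_delta_zero:
            lp -= math.log(self.delta_bounds[1] - self.delta_bounds[0])
        lp += float(self._fitness_dist().logpdf(theta[2:5]))
        lp -= math.log(self.truncation_mass())
        return lp

    def pdf(self, theta: np.ndarray) -> float:
        return float(np.exp(self.logpdf(theta)))

    def sample(self, rng, size: int = 1) -> np.ndarray:
        """Draw theta vectors; the ordering is enforced by rejection."""
        rng = np.random.default_rng(rng)
        out = np.empty((size, 5))
        out[:, 0] = rng.uniform(*self.mu_bounds, size=size)
        if self.fix_delta_zero:
            out[:, 1] = 0.0
        else:
            out[:, 1] = rng.uniform(*self.delta_bounds, size=size)
        dist = self._fitness_dist()
        filled = 0
        attempts = 0
        while filled < size:
            n_draw = max(4 * (size - filled), 16)
            w = np.atleast_2d(dist.rvs(size=n_draw, random_state=rng))
            ok = w[self._ordering_ok(w)]
            take = min(ok.shape[0], size - filled)
            out[filled:filled + take, 2:5] = ok[:take]
            filled += take
            attempts += n_draw
            if attempts > 1e7:
                raise ValueError("fitness-ordering rejection rate too high")
        return out


def theta_to_params(theta: np.ndarray, N: int, horizon: int = 3000,
                    **variant_kwargs) -> ModelParams:
    """Build a ModelParams from a theta vector plus fixed run settings."""
    theta = np.asarray(theta, float)
    return ModelParams(
        mu=float(theta[0]),
        delta=float(theta[1]),
        w=(1.0, float(theta[2]), float(theta[3]), float(theta[4])),
        N=N,
        horizon=horizon,
        **variant_kwargs,
    )


def sample_prior(spec: PriorSpec, rng, size: int = 1) -> np.ndarray:
    return spec.sample(rng, size=size)


@dataclass
class ParticlePopulation:
    """One ABC-SMC iteration: weighted particles with their likelihoods."""

    iteration: int
    thetas: np.ndarray          # (n, 5)
    weights: np.ndarray         # normalized to sum 1
    likelihoods: np.ndarray
    epsilon: float
    n_proposals: int = 0
    seed: Optional[int] = None

    def __post_init__(self):
        self.thetas = np.atleast_2d(np.asarray(self.thetas, float))
        self.weights = np.asarray(self.weights, float)
        total = self.weights.sum()
        if total <= 0:
            raise ValueError("weights must have positive sum")
        self.weights = self.weights / total
        self.likelihoods = np.asarray(self.likelihoods, float)

    @property
    def n_particles(self) -> int:
        return self.thetas.shape[0]

    @property
    def ess(self) -> float:
        return effective_sample_size(self.weights)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.thetas, columns=list(PARAM_NAMES))
        df.insert(0, "iteration", self.iteration)
        df["weight"] = self.weights
        df["L"] = self.likelihoods
        df["epsilon"] = self.epsilon
        return df


class PerturbationKernel:
    """Multivariate-normal perturbation over the free theta components."""

    def __init__(self, cov: np.ndarray, free_indices):
        self.free_indices = tuple(free_indices)
        cov = np.atleast_2d(np.asarray(cov, float))
        diag = np.diag(cov)
        if not np.all(np.isfinite(cov)) or np.any(diag <= 0):
            # a zero-spread (or otherwise degenerate) population cannot
            # define a kernel; fall back to a small diagonal covariance
            floor = np.where(diag > 0, diag, np.maximum(diag.max(), 1e-12))
            cov = np.diag(floor)
            self.diagonal_fallback = True
            logger.warning(
                "degenerate particle covariance; using diagonal fallback")
        else:
            self.diagonal_fallback = False
        # rank-deficient covariances are legitimate (e.g. two particles):
        # the density then lives on the spanned affine subspace
        self._dist = stats.multivariate_normal(
            mean=np.zeros(cov.shape[0]), cov=cov, allow_singular=True)
        u, s, _ = np.linalg.svd(cov)
        self._sqrt = u * np.sqrt(s)
        self.cov = cov

    def perturb(self, theta: np.ndarray, rng) -> np.ndarray:
        rng = np.random.default_rng(rng)
        out = np.asarray(theta, float).copy()
        step = self._sqrt @ rng.standard_normal(len(self.free_indices))
        out[list(self.free_indices)] += step
        return out

    def logpdf(self, theta_new: np.ndarray, theta_old: np.ndarray) -> float:
        d = (np.asarray(theta_new, float) - np.asarray(theta_old, float))
        return float(self._dist.logpdf(d[list(self.free_indices)]))


def fit_kernel(
    population: ParticlePopulation,
    scale: float = 2.0,
    free_indices=None,
) -> PerturbationKernel:
    """Kernel whose covariance is the weighted particle covariance x scale."""
    if population.n_particles < 2:
        raise ValueError("need at least 2 particles to fit a kernel")
    free = tuple(free_indices) if free_indices is not None else tuple(range(5))
    X = population.thetas[:, list(free)]
    cov = np.cov(X.T, aweights=population.weights, ddof=0)
    cov = np.atleast_2d(cov) * scale
    return PerturbationKernel(cov, free)


def particle_weight(
    theta: np.ndarray,
    prior: PriorSpec,
    prev: ParticlePopulation,
    kernel: PerturbationKernel,
) -> float:
    """Unnormalized SMC importance weight of an accepted particle."""
    lp = prior.logpdf(theta)
    if not np.isfinite(lp):
        return 0.0
    log_k = np.array([
        kernel.logpdf(theta, prev.thetas[i]) for i in range(prev.n_particles)
    ])
    log_denom = _logsumexp(np.log(prev.weights + 1e-300) + log_k)
    if not np.isfinite(log_denom):
        raise ZeroDivisionError("perturbation-kernel denominator is zero")
    return float(np.exp(lp - log_denom))


def _logsumexp(a: np.ndarray) -> float:
    m = np.max(a)
    if not np.isfinite(m):
        return m
    return float(m + np.log(np.sum(np.exp(a - m))))


def effective_sample_size(weights) -> float:
    """Kish effective sample size 1 / sum(w_i^2) of normalized weights."""
    w = np.asarray(weights, float)
    w = w / w.sum()
    return float(1.0 / np.sum(w**2))


@dataclass
class ABCConfig:
    """Run settings for the sequential inference."""

    n_particles: int = 1000
    n_sims: int = 1000
    max_iterations: int = 10
    epsilon0: float = np.inf
    epsilon_tolerance: float = 0.01
    kernel_scale: float = 2.0
    min_acceptance_rate: float = 1e-4
    population_size: int = 6_425_000
    horizon: int = 3000
    tau: float = 1.0
    loss_multiplier: float = 1.0
    allow_back_transitions: bool = False

    def params_for(self, theta: np.ndarray) -> ModelParams:
        return theta_to_params(
            theta,
            N=self.population_size,
            horizon=self.horizon,
            tau=self.tau,
            loss_multiplier=self.loss_multiplier,
            allow_back_transitions=self.allow_back_transitions,
        )


def _likelihood_of(theta, obs, config, rng):
    params = config.params_for(theta)
    if params.delta == 0:
        return likelihood_no_aneuploidy(params, obs, n_sims=config.n_sims, rng=rng)
    return approximate_likelihood(params, obs, n_sims=config.n_sims, rng=rng)


def run_abc_smc(
    obs: Observations = HEAT_EXPERIMENT,
    prior: PriorSpec = None,
    config: ABCConfig = None,
    seed: Optional[int] = None,
) -> List[ParticlePopulation]:
    """Sequential ABC: propose, perturb, simulate, accept, weight.

    Iteration 0 accepts draws from the prior under epsilon0 (by default
    +infinity, i.e. accept-all).  Later iterations resample the previous
    population by weight, perturb with the fitted normal kernel, and accept
    a proposal when 1 - L(theta) < epsilon_t, where epsilon_t is the median
    of 1 - L over the previous accepted particles.  Stops when epsilon
    changes by less than ``epsilon_tolerance`` or after ``max_iterations``.
    """
    prior = prior or PriorSpec()
    config = config or ABCConfig()
    master = np.random.SeedSequence(seed)
    populations: List[ParticlePopulation] = []
    epsilon = config.epsilon0
    free = prior.free_indices

    for t in range(config.max_iterations):
        it_seed = master.spawn(1)[0]
        rng = np.random.default_rng(it_seed)
        kernel = None
        prev = populations[-1] if populations else None
        if prev is not None:
            kernel = fit_kernel(prev, scale=config.kernel_scale,
                                free_indices=free)
        thetas, Ls, raw_weights = [], [], []
        n_proposals = 0
        max_proposals = max(
            int(config.n_particles / config.min_acceptance_rate), 1000
        )
        while len(thetas) < config.n_particles:
            n_proposals += 1
            if n_proposals > max_proposals:
                raise RuntimeError(
                    f"iteration {t}: acceptance rate below "
                    f"{config.min_acceptance_rate}; aborting "
                    f"(epsilon={epsilon:.4g}, accepted {len(thetas)})"
                )
            if prev is None:
                theta = prior.sample(rng, size=1)[0]
            else:
                i = rng.choice(prev.n_particles, p=prev.weights)
                theta = kernel.perturb(prev.thetas[i], rng)
                if not prior.in_support(theta):
                    continue
            L = _likelihood_of(theta, obs, config, rng)
            if 1.0 - L < epsilon:
                thetas.append(theta)
                Ls.append(L)
                if prev is None:
                    raw_weights.append(1.0)
                else:
                    raw_weights.append(
                        particle_weight(theta, prior, prev, kernel))
        pop = ParticlePopulation(
            iteration=t,
            thetas=np.array(thetas),
            weights=np.array(raw_weights),
            likelihoods=np.array(Ls),
            epsilon=epsilon,
            n_proposals=n_proposals,
            seed=int(it_seed.generate_state(1)[0] % (2**31)),
        )
        populations.append(pop)
        next_epsilon = float(np.median(1.0 - pop.likelihoods))
        logger.info(
            "iteration %d: epsilon=%.4g, accepted %d/%d, next epsilon=%.4g, "
            "ESS=%.1f",
            t, epsilon, pop.n_particles, n_proposals, next_epsilon, pop.ess,
        )
        if np.isfinite(epsilon) and abs(epsilon - next_epsilon) < config.epsilon_tolerance:
            break
        epsilon = min(epsilon, next_epsilon)
    return populations
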