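"""Synthetic experiment summaries with known ground truth.

Every inference stage can be exercised without external data: a set of
lineage-tracked replicates is simulated at known parameters, their
aneuploidy fixation times define a fixation window (rounded outward to the
assay cadence, mimicking the sparse sampling of a real evolution
experiment), and the 2n* fixation times of two randomly chosen replicates
play the role of the two aneuploidy-loss deadlines.  The resulting record
has exactly the shape of the real observations, so parameter recovery is a
direct test of the likelihood + ABC stack.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .likelihood import EventTimes, Observations
from .wf_core import ModelParams, Trajectory, batch_events, _genotypes

__all__ = [
    "SyntheticExperiment",
    "generate_observations",
    "make_fixture_trajectory",
    "RecoveryConfig",
    "recovery_experiment",
]

logger = logging.getLogger(__name__)


@dataclass
class SyntheticExperiment:
    """Ground-truth parameters plus the derived observation record."""

    theta_true: ModelParams
    n_replicates: int
    aneuploid_fixation_times: np.ndarray
    mutant_fixation_times: np.ndarray
    observations: Optional[Observations]
    degenerate: bool
    seed: Optional[int]
    cadence: int

    @property
    def event_times(self) -> List[EventTimes]:
        out = []
        for t in self.aneuploid_fixation_times:
            out.append(EventTimes(fixation=None if np.isnan(t) else int(t)))
        return out


def generate_observations(
    theta_true: ModelParams,
    n_replicates: int = 4,
    seed=None,
    cadence: int = 50,
    horizon: Optional[int] = None,
) -> SyntheticExperiment:
    """Simulate replicates at known parameters and summarize them.

    The fixation window spans the replicate aneuploidy fixation times,
    rounded outward to multiples of ``cadence`` (the assay interval).  Two
    replicates with a recorded 2n* fixation are drawn at random; their
    fixation times, sorted, become the two loss deadlines.  If aneuploidy
    never fixes in some replicate, or fewer than two replicates reach 2n*
    fixation, the record is degenerate (uninformative) and carries no
    Observations.
    """
    rng = np.random.default_rng(seed)
    res = batch_events(
        theta_true, n_replicates, rng=rng, lineage_tracked=True,
        horizon=horizon,
    )
    t_an = res.t_fix_aneuploid
    t_mut = res.t_fix_mutant
    degenerate = bool(np.any(np.isnan(t_an)))
    observations = None
    if not degenerate:
        lo = int(np.floor(np.nanmin(t_an) / cadence) * cadence)
        hi = int(np.ceil(np.nanmax(t_an) / cadence) * cadence)
        if hi == lo:
            hi = lo + cadence
        candidates = np.nonzero(~np.isnan(t_mut) & (t_mut > hi))[0]
        if candidates.size < 2:
            degenerate = True
        else:
            chosen = rng.choice(candidates, size=2, replace=False)
            d1, d2 = sorted(int(t_mut[i]) for i in chosen)
            if d2 == d1:
                d2 += 1
            try:
                observations = Observations(
                    n_replicates=n_replicates,
                    fixation_window=(lo, hi),
                    loss_deadlines=(d1, d2),
                )
            except ValueError:
                degenerate = True
    if degenerate:
        logger.warning("synthetic experiment is degenerate (uninformative)")
    return SyntheticExperiment(
        theta_true=theta_true,
        n_replicates=n_replicates,
        aneuploid_fixation_times=t_an,
        mutant_fixation_times=t_mut,
        observations=observations,
        degenerate=degenerate,
        seed=seed,
        cadence=cadence,
    )


def make_fixture_trajectory(
    points: Sequence,
    params: Optional[ModelParams] = None,
    lineage_tracked: bool = False,
) -> Trajectory:
    """Step-interpolated trajectory from (generation, frequency-vector) pairs.

    Intended for unit tests of event scanning and adaptation times; each
    frequency vector is held constant until the next listed generation.
    """
    gens = [int(g) for g, _ in points]
    if gens != sorted(set(gens)) or gens[0] < 0:
        raise ValueError("generations must be strictly increasing and >= 0")
    k = 5 if lineage_tracked else 4
    freqs = []
    for g, f in points:
        f = np.asarray(f, float)
        if f.shape != (k,) or np.any(f < 0) or not np.isclose(f.sum(), 1.0):
            raise ValueError(f"invalid frequency vector at generation {g}")
        freqs.append(f)
    horizon = gens[-1]
    out = np.zeros((horizon + 1, k))
    out[:, 0] = 1.0
    for (g, f) in zip(gens, freqs):
        out[g:] = f
    if params is None:
        params = ModelParams(mu=0.0, delta=0.0, horizon=max(horizon, 1))
    return Trajectory(out, params, seed=None, lineage_tracked=lineage_tracked)


@dataclass
class RecoveryConfig:
    """Reduced-scale settings for a parameter-recovery experiment."""

    n_particles: int = 50
    n_sims: int = 50
    max_iterations: int = 4
    n_replicates: int = 4
    cadence: int = 50
    horizon: int = 800
    hdi_mass: float = 0.5
    kernel_scale: float = 2.0
    min_acceptance_rate: float = 1e-3


def recovery_experiment(
    theta_true: ModelParams,
    prior,
    config: Optional[RecoveryConfig] = None,
    seed=None,
) -> dict:
    """Generate synthetic observations and try to recover the parameters.

    Runs the full loop (simulate -> summarize -> ABC-SMC -> posterior
    summaries) at reduced scale and reports per-parameter MAP estimates,
    HDI coverage of the truth, and the epsilon trace.
    """
    from .abc_smc import ABCConfig, PARAM_NAMES, run_abc_smc
    from .posterior import PosteriorDensity, hdi, map_estimate

    config = config or RecoveryConfig()
    ss = np.random.SeedSequence(seed)
    gen_seed, abc_seed, kde_seed = ss.spawn(3)
    exp = generate_observations(
        theta_true,
        n_replicates=config.n_replicates,
        seed=gen_seed,
        cadence=config.cadence,
        horizon=config.horizon,
    )
    if exp.degenerate:
        return {"degenerate": True, "experiment": exp}
    abc_config = ABCConfig(
        n_particles=config.n_particles,
        n_sims=config.n_sims,
        max_iterations=config.max_iterations,
        kernel_scale=config.kernel_scale,
        min_acceptance_rate=config.min_acceptance_rate,
        population_size=theta_true.N,
        horizon=config.horizon,
    )
    populations = run_abc_smc(
        exp.observations, prior, abc_config,
        seed=int(abc_seed.generate_state(1)[0] % (2**31)),
    )
    final = populations[-1]
    post = PosteriorDensity(final, prior)
    theta_map = map_estimate(post)
    theta_true_vec = np.array(
        [theta_true.mu, theta_true.delta, *theta_true.w[1:]])
    rng = np.random.default_rng(kde_seed)
    idx = rng.choice(final.n_particles, size=2000, p=final.weights)
    intervals, covered = {}, {}
    for j, name in enumerate(PARAM_NAMES):
        samples = final.thetas[idx, j]
        if np.std(samples) == 0:
            interval = (float(samples[0]), float(samples[0]))
        else:
            interval = hdi(samples, config.hdi_mass)
        intervals[name] = interval
        covered[name] = bool(interval[0] <= theta_true_vec[j] <= interval[1])
    map_log10_error = {
        name: float(np.log10(theta_map[j] / theta_true_vec[j]))
        for j, name in enumerate(PARAM_NAMES)
        if theta_true_vec[j] > 0 and theta_map[j] > 0
    }
    return {
        "degenerate": False,
        "experiment": exp,
        "populations": populations,
        "map": dict(zip(PARAM_NAMES, theta_map)),
        "map_log10_error": map_log10_error,
        "hdi": intervals,
        "covered": covered,
        "epsilon_trace": [p.epsilon for p in populations],
        "terminal_epsilon": float(np.median(1 - final.likelihoods)),
    }
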