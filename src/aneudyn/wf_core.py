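"""Discrete-generation Wright–Fisher model of adaptation via aneuploidy and mutation.

The model follows a population of cells through four genotypes: the euploid
wild type ``2n``; the aneuploid wild type ``2n+1`` (one extra chromosome); the
aneuploid mutant ``2n+1*`` (extra chromosome plus one beneficial mutation);
and the euploid mutant ``2n*`` (standard karyotype plus the mutation).
Each generation applies, in order,

1. selection:      f_i -> f_i * w_i / wbar,   wbar = sum_j f_j w_j
2. transitions:    beneficial mutation at rate mu (2n -> 2n*, 2n+1 -> 2n+1*)
                   and chromosome gain/loss at rate delta
                   (2n -> 2n+1, 2n+1* -> 2n*)
3. drift:          f' ~ Multinomial(N, f) / N

In *lineage-tracked* mode the euploid-mutant class is split by origin:
``2nA*`` descends from aneuploid cells (via 2n+1 -> 2n+1* -> 2n*) and
``2nM*`` arises directly from 2n by mutation.  This is a 5-state frequency
vector, not a per-cell genealogy: lineage identity is fully determined by
which inflow created the 2n* mass.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "STANDARD_GENOTYPES",
    "LINEAGE_GENOTYPES",
    "ModelParams",
    "Trajectory",
    "BatchEvents",
    "map_params",
    "selection_step",
    "mean_fitness",
    "transition_matrix",
    "transition_step",
    "drift_step",
    "simulate",
    "deterministic_trajectory",
    "batch_events",
    "effective_population_size",
    "supply_rates",
]

STANDARD_GENOTYPES = ("2n", "2n+1", "2n+1*", "2n*")
LINEAGE_GENOTYPES = ("2n", "2n+1", "2n+1*", "2nA*", "2nM*")

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the four-genotype Wright–Fisher model.

    Parameters
    ----------
    mu : float
        Beneficial mutation rate per genome per generation.
    delta : float
        Aneuploidy (chromosome gain/loss) rate per generation.
    w : tuple of float
        Relative fitness of (2n, 2n+1, 2n+1*, 2n*); w[0] is fixed at 1 by
        convention and all values must be positive.
    N : int
        Effective population size in cells.
    tau : float
        Multiplier on the mutation rate inside aneuploid genotypes
        (genetic-instability variant; 1 = no effect).
    loss_multiplier : float
        Multiplier on the 2n+1* -> 2n* chromosome-loss rate relative to delta.
    allow_back_transitions : bool
        If True, adds the chromosome events that create less-fit genotypes
        (2n+1 -> 2n and 2n* -> 2n+1*), each at rate delta.
    horizon : int
        Maximum number of generations simulated.
    """

    mu: float
    delta: float
    w: tuple = (1.0, 1.022, 1.025, 1.028)
    N: int = 6_425_000
    tau: float = 1.0
    loss_multiplier: float = 1.0
    allow_back_transitions: bool = False
    horizon: int = 3000

    def __post_init__(self):
        if self.mu < 0 or self.delta < 0:
            raise ValueError("mu and delta must be non-negative")
        if len(self.w) != 4 or any(wi <= 0 for wi in self.w):
            raise ValueError("w must hold 4 positive fitness values")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if self.tau < 0 or self.loss_multiplier < 0:
            raise ValueError("tau and loss_multiplier must be >= 0")
        back = self.delta if self.allow_back_transitions else 0.0
        outflows = {
            "2n": self.mu + self.delta,
            "2n+1": self.tau * self.mu + back,
            "2n+1*": self.loss_multiplier * self.delta,
            "2n*": back,
        }
        for g, out in outflows.items():
            if out > 1:
                raise ValueError(
                    f"total transition probability out of {g} exceeds 1 ({out:g})"
                )
        object.__setattr__(self, "w", tuple(float(wi) for wi in self.w))

    def replace(self, **kwargs) -> "ModelParams":
        return dataclasses.replace(self, **kwargs)


def map_params(**overrides) -> ModelParams:
    """Joint posterior-mode parameter estimates for the heat-stress experiment.

    mu = 2.965e-6 per genome per generation, delta = 1.72e-3 per generation,
    fitness (1, 1.022, 1.025, 1.028), N = 6,425,000 cells.
    """
    kwargs = dict(mu=2.965e-6, delta=1.72e-3,
                  w=(1.0, 1.022, 1.025, 1.028), N=6_425_000)
    kwargs.update(overrides)
    return ModelParams(**kwargs)


def _genotypes(lineage_tracked: bool) -> tuple:
    return LINEAGE_GENOTYPES if lineage_tracked else STANDARD_GENOTYPES


def fitness_vector(params: ModelParams, lineage_tracked: bool = False) -> np.ndarray:
    """Per-genotype fitness; in lineage mode both 2n* lineages share w[3]."""
    w = np.asarray(params.w, dtype=float)
    if lineage_tracked:
        return np.concatenate([w[:3], [w[3], w[3]]])
    return w


def selection_step(f: np.ndarray, w: Sequence[float]) -> np.ndarray:
    """One round of selection: f_i * w_i / wbar (acts along the last axis)."""
    f = np.asarray(f, dtype=float)
    w = np.asarray(w, dtype=float)
    if f.shape[-1] != w.shape[-1]:
        raise ValueError("frequency vector and fitness map have different lengths")
    if np.any(w <= 0):
        raise ValueError("fitness values must be positive")
    if not np.allclose(f.sum(axis=-1), 1.0, atol=_SUM_TOL):
        raise ValueError("frequencies must sum to 1")
    fw = f * w
    return fw / fw.sum(axis=-1, keepdims=True)


def mean_fitness(f: np.ndarray, w: Sequence[float]) -> float:
    """Population mean fitness wbar = sum_j f_j w_j."""
    f = np.asarray(f, dtype=float)
    w = np.asarray(w, dtype=float)
    if f.shape[-1] != w.shape[-1]:
        raise ValueError("frequency vector and fitness map have different lengths")
    if not np.allclose(f.sum(axis=-1), 1.0, atol=_SUM_TOL):
        raise ValueError("frequencies must sum to 1")
    return f @ w


def transition_matrix(params: ModelParams, lineage_tracked: bool = False) -> np.ndarray:
    """Row-stochastic matrix of mutation/aneuploidy flows (rows = source)."""
    mu, delta = params.mu, params.delta
    mu_an = params.tau * mu
    loss = params.loss_multiplier * delta
    back = delta if params.allow_back_transitions else 0.0
    if lineage_tracked:
        # states: 2n, 2n+1, 2n+1*, 2nA*, 2nM*
        M = np.array([
            [1 - delta - mu, delta,            0.0,      0.0,  mu],
            [back,           1 - mu_an - back, mu_an,    0.0,  0.0],
            [0.0,            0.0,              1 - loss, loss, 0.0],
            [0.0,            0.0,              back,     1 - back, 0.0],
            [0.0,            0.0,              back,     0.0,  1 - back],
        ])
    else:
        M = np.array([
            [1 - delta - mu, delta,            0.0,      mu],
            [back,           1 - mu_an - back, mu_an,    0.0],
            [0.0,            0.0,              1 - loss, loss],
            [0.0,            0.0,              back,     1 - back],
        ])
    return M


def transition_step(
    f: np.ndarray, params: ModelParams, lineage_tracked: bool = False
) -> np.ndarray:
    """One round of mutation and chromosome gain/loss."""
    f = np.asarray(f, dtype=float)
    k = 5 if lineage_tracked else 4
    if f.shape[-1] != k:
        raise ValueError(f"expected a {k}-state frequency vector")
    if not np.allclose(f.sum(axis=-1), 1.0, atol=_SUM_TOL):
        raise ValueError("frequencies must sum to 1")
    return f @ transition_matrix(params, lineage_tracked)


def drift_step(f: np.ndarray, N: int, rng: np.random.Generator) -> np.ndarray:
    """Multinomial resampling of N cells; output entries are multiples of 1/N."""
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequencies must be non-negative")
    if N < 1:
        raise ValueError("N must be >= 1")
    return rng.multinomial(int(N), f) / float(N)


@dataclass
class Trajectory:
    """Per-generation genotype frequencies of one simulation run.

    ``frequencies[t]`` is the frequency vector at generation ``t``
    (``frequencies[0]`` is the pure wild-type state).
    """

    frequencies: np.ndarray
    params: ModelParams
    seed: Optional[int] = None
    lineage_tracked: bool = False
    genotypes: tuple = field(default=None)

    def __post_init__(self):
        if self.genotypes is None:
            self.genotypes = _genotypes(self.lineage_tracked)
        self.frequencies = np.asarray(self.frequencies, dtype=float)

    @property
    def n_generations(self) -> int:
        return self.frequencies.shape[0] - 1

    def class_frequency(self, genotype_class: str) -> np.ndarray:
        """Aggregate frequency series of a genotype class.

        Classes: any single genotype label, ``"aneuploid"``
        (2n+1 plus 2n+1*), or ``"2n*"`` which aggregates 2nA* and 2nM* in
        lineage-tracked mode.
        """
        g = self.genotypes
        if genotype_class == "aneuploid":
            idx = [g.index("2n+1"), g.index("2n+1*")]
        elif genotype_class == "2n*" and self.lineage_tracked:
            idx = [g.index("2nA*"), g.index("2nM*")]
        elif genotype_class in g:
            idx = [g.index(genotype_class)]
        else:
            raise ValueError(f"unknown genotype class {genotype_class!r}")
        return self.frequencies[:, idx].sum(axis=1)

    def mean_fitness_series(self) -> np.ndarray:
        w = fitness_vector(self.params, self.lineage_tracked)
        return self.frequencies @ w

    def to_dataframe(self):
        import pandas as pd

        cols = [f"f_{g}".replace("*", "m") for g in self.genotypes]
        df = pd.DataFrame(self.frequencies, columns=cols)
        df.insert(0, "generation", np.arange(self.frequencies.shape[0]))
        return df


def _mutant_indices(lineage_tracked: bool) -> list:
    return [3, 4] if lineage_tracked else [3]


def simulate(
    params: ModelParams,
    seed=None,
    lineage_tracked: bool = False,
    early_stop: bool = True,
) -> Trajectory:
    """Stochastic simulation from the pure-2n state, recording every generation.

    Iterates selection -> transitions -> multinomial drift for up to
    ``params.horizon`` generations.  Once the euploid-mutant class reaches
    frequency 1 the state is absorbing (without back-transitions) and the
    remaining generations are padded with it.  Reproducible from
    ``(params, seed)``.
    """
    rng = np.random.default_rng(seed)
    k = 5 if lineage_tracked else 4
    w = fitness_vector(params, lineage_tracked)
    M = transition_matrix(params, lineage_tracked)
    mut = _mutant_indices(lineage_tracked)
    freqs = np.zeros((params.horizon + 1, k))
    freqs[0, 0] = 1.0
    f = freqs[0]
    can_stop = early_stop and not params.allow_back_transitions
    for t in range(1, params.horizon + 1):
        fm = ((f * w) / (f @ w)) @ M
        f = rng.multinomial(params.N, fm) / params.N
        freqs[t] = f
        if can_stop and f[mut].sum() >= 1.0:
            freqs[t + 1:] = f  # absorbing state
            break
    return Trajectory(freqs, params, seed=seed, lineage_tracked=lineage_tracked)


def deterministic_trajectory(
    params: ModelParams, lineage_tracked: bool = False
) -> Trajectory:
    """Drift-free companion model: selection and transitions only."""
    k = 5 if lineage_tracked else 4
    w = fitness_vector(params, lineage_tracked)
    M = transition_matrix(params, lineage_tracked)
    freqs = np.zeros((params.horizon + 1, k))
    freqs[0, 0] = 1.0
    f = freqs[0]
    for t in range(1, params.horizon + 1):
        f = ((f * w) / (f @ w)) @ M
        freqs[t] = f
    return Trajectory(freqs, params, seed=None, lineage_tracked=lineage_tracked)


@dataclass
class BatchEvents:
    """First-crossing events from a batch of stochastic replicates.

    Times are floats with ``nan`` marking an event that never occurred within
    the horizon.  ``final_freqs[r]`` is the frequency vector of replicate
    ``r`` at the last simulated generation (the absorbing state if the run
    stopped early).
    """

    t_fix_aneuploid: np.ndarray
    t_fix_2n1: np.ndarray
    t_loss_aneuploid: np.ndarray
    t_fix_mutant: np.ndarray
    final_freqs: np.ndarray
    crossover_direct_mutant: Optional[np.ndarray]
    lineage_tracked: bool
    horizon: int
    n_reps: int


def batch_events(
    params: ModelParams,
    n_reps: int,
    rng=None,
    fix_threshold: float = 0.95,
    loss_threshold: float = 0.05,
    lineage_tracked: bool = False,
    crossover_threshold: Optional[float] = None,
    horizon: Optional[int] = None,
) -> BatchEvents:
    """Vectorized batch of stochastic replicates, tracking event times only.

    Records, per replicate: the first generation at which the aneuploid class
    (2n+1 plus 2n+1*) exceeds ``fix_threshold``; the first generation at
    which it drops below ``loss_threshold`` after having fixed; and the first
    generation at which the euploid-mutant class exceeds ``fix_threshold``.
    With ``crossover_threshold`` set (lineage-tracked mode), also records the
    2nM* frequency at the first generation with 2nA* >= the threshold.

    All replicates share one numpy Generator so the inner update is a single
    vectorized operation per generation.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if crossover_threshold is not None and not lineage_tracked:
        raise ValueError("crossover tracking requires lineage_tracked=True")
    rng = np.random.default_rng(rng)
    horizon = params.horizon if horizon is None else int(horizon)
    k = 5 if lineage_tracked else 4
    w = fitness_vector(params, lineage_tracked)
    M = transition_matrix(params, lineage_tracked)
    N = params.N
    an_idx = [1, 2]
    mut_idx = _mutant_indices(lineage_tracked)

    f = np.zeros((n_reps, k))
    f[:, 0] = 1.0
    t_fix_an = np.full(n_reps, np.nan)
    t_fix_2n1 = np.full(n_reps, np.nan)
    t_loss_an = np.full(n_reps, np.nan)
    t_fix_mut = np.full(n_reps, np.nan)
    cross = np.full(n_reps, np.nan) if crossover_threshold is not None else None

    can_stop = not params.allow_back_transitions
    for t in range(1, horizon + 1):
        fm = (f * w / (f @ w)[:, None]) @ M
        f = rng.multinomial(N, fm) / N
        an = f[:, an_idx].sum(axis=1)
        mut = f[:, mut_idx].sum(axis=1)
        np.putmask(t_fix_an, np.isnan(t_fix_an) & (an > fix_threshold), t)
        np.putmask(t_fix_2n1, np.isnan(t_fix_2n1) & (f[:, 1] > fix_threshold), t)
        np.putmask(
            t_loss_an,
            np.isnan(t_loss_an) & ~np.isnan(t_fix_an) & (an < loss_threshold),
            t,
        )
        np.putmask(t_fix_mut, np.isnan(t_fix_mut) & (mut > fix_threshold), t)
        if cross is not None:
            hit = np.isnan(cross) & (f[:, 3] >= crossover_threshold)
            cross[hit] = f[hit, 4]
        if can_stop and np.all(mut >= 1.0):
            break
    return BatchEvents(
        t_fix_aneuploid=t_fix_an,
        t_fix_2n1=t_fix_2n1,
        t_loss_aneuploid=t_loss_an,
        t_fix_mutant=t_fix_mut,
        final_freqs=f,
        crossover_direct_mutant=cross,
        lineage_tracked=lineage_tracked,
        horizon=horizon,
        n_reps=n_reps,
    )


def effective_population_size(census_sizes: Sequence[float]) -> float:
    """Harmonic mean of per-generation census sizes: k / sum(1/x_i)."""
    sizes = np.asarray(list(census_sizes), dtype=float)
    if sizes.size == 0:
        raise ValueError("census size list must be non-empty")
    if np.any(sizes <= 0):
        raise ValueError("census sizes must be positive")
    return sizes.size / np.sum(1.0 / sizes)


def supply_rates(params: ModelParams) -> tuple:
    """(N*delta, N*mu): expected new aneuploid and new euploid-mutant cells
    per generation in a pure wild-type population."""
    return (params.N * params.delta, params.N * params.mu)
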