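"""Simulation-based likelihood of the fixation/loss observations.

The evolution experiment is summarized by replicate-level event windows:
aneuploidy fixed (frequency > 95%) in all four replicate populations between
generations 200 and 450, and in the two replicates that were continued,
aneuploidy was lost (frequency < 5%) by generations 1,700 and 2,350.

Because the fixation-time distribution of a multi-genotype Wright–Fisher
model is intractable, the likelihood is approximated from simulated
experiments.  With W the window event {200 <= T(aneuploid) <= 450}, A the
event {T(2n*) < 1700} and B the event {1700 < T(2n*) < 2350} (2n* fixation
is the proxy for aneuploidy elimination),

    L(theta) = P(W)^4 * [1 - P(!A|W)^4 - P(!B|W)^4 + P(!A & !B|W)^4]

where the fourth powers come from the four independent replicate
populations and the bracket is the inclusion–exclusion probability that at
least one replicate lost aneuploidy by the first deadline AND at least one
lost it inside the second window.  The bracket attains its analytic maximum
7/8 = 0.875 at P(A) = P(B) = 0.5, so L <= 0.875 always.

For the no-aneuploidy model (delta = 0) the same bracket is evaluated
unconditionally, since there is no aneuploid fixation to condition on.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .wf_core import ModelParams, Trajectory, batch_events

__all__ = [
    "LIKELIHOOD_MAX",
    "EventTimes",
    "Observations",
    "HEAT_EXPERIMENT",
    "event_times",
    "replicate_bracket",
    "approximate_likelihood",
    "likelihood_no_aneuploidy",
    "likelihood_surface",
]

logger = logging.getLogger(__name__)

#: Analytic maximum of the approximate likelihood (attained at
#: P(window)=1, P(A)=P(B)=1/2): 1 - (1/2)^4 - (1/2)^4 + 0 = 7/8.
LIKELIHOOD_MAX = 0.875


@dataclass(frozen=True)
class EventTimes:
    """First-crossing times of one genotype class in one trajectory.

    ``fixation`` is the first generation with frequency strictly above the
    fixation threshold; ``loss`` the first generation strictly below the
    loss threshold *after* fixation.  ``None`` marks an event that never
    happened within the horizon.
    """

    fixation: Optional[int] = None
    loss: Optional[int] = None

    def __post_init__(self):
        if self.loss is not None and self.fixation is None:
            raise ValueError("loss time requires a preceding fixation time")
        if (
            self.loss is not None
            and self.fixation is not None
            and self.loss <= self.fixation
        ):
            raise ValueError("fixation must precede loss")


@dataclass(frozen=True)
class Observations:
    """Replicate-level summary of the evolution experiment.

    ``fixation_window`` bounds the aneuploidy fixation times of all
    replicates; ``loss_deadlines`` are the generations by which the two
    continued replicates had lost aneuploidy.
    """

    n_replicates: int = 4
    fixation_window: tuple = (200, 450)
    loss_deadlines: tuple = (1700, 2350)

    def __post_init__(self):
        lo, hi = self.fixation_window
        d1, d2 = self.loss_deadlines
        if not (lo < hi < d1 < d2):
            raise ValueError(
                "require window lower < upper < first deadline < second deadline"
            )
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_replicates": self.n_replicates,
                "fixation_window": list(self.fixation_window),
                "loss_deadlines": list(self.loss_deadlines),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Observations":
        d = json.loads(text)
        return cls(
            n_replicates=d["n_replicates"],
            fixation_window=tuple(d["fixation_window"]),
            loss_deadlines=tuple(d["loss_deadlines"]),
        )


#: The heat-stress evolution experiment: 4 replicates, aneuploidy fixed
#: between generations 200 and 450 in all of them; the two continued
#: replicates lost it by generations 1,700 and 2,350.
HEAT_EXPERIMENT = Observations()


def event_times(
    traj: Trajectory,
    genotype_class: str,
    fix_threshold: float = 0.95,
    loss_threshold: float = 0.05,
) -> EventTimes:
    """Scan a trajectory for the first fixation and subsequent loss crossing."""
    if not (0 < loss_threshold < fix_threshold < 1):
        raise ValueError("require 0 < loss_threshold < fix_threshold < 1")
    freq = traj.class_frequency(genotype_class)
    above = np.nonzero(freq > fix_threshold)[0]
    if above.size == 0:
        return EventTimes()
    t_fix = int(above[0])
    below = np.nonzero(freq[t_fix + 1:] < loss_threshold)[0]
    t_loss = int(t_fix + 1 + below[0]) if below.size else None
    return EventTimes(fixation=t_fix, loss=t_loss)


def replicate_bracket(q_not_early, q_not_late, q_neither, n_replicates: int = 4):
    """Inclusion–exclusion over replicate populations.

    Given per-replicate probabilities of *not* losing aneuploidy by the first
    deadline (``q_not_early``), *not* losing it inside the second window
    (``q_not_late``), and of neither event (``q_neither``), returns the
    probability that at least one of ``n_replicates`` independent replicates
    realizes each event:

        1 - q_not_early^n - q_not_late^n + q_neither^n
    """
    n = n_replicates
    return 1.0 - np.asarray(q_not_early) ** n - np.asarray(q_not_late) ** n \
        + np.asarray(q_neither) ** n


def _deadline_probabilities(t_fix_mutant: np.ndarray, obs: Observations):
    """Per-simulation indicator fractions for the two loss-deadline events."""
    d1, d2 = obs.loss_deadlines
    t = t_fix_mutant
    early = ~np.isnan(t) & (t < d1)
    late = ~np.isnan(t) & (t > d1) & (t < d2)
    q_not_early = np.mean(~early)
    q_not_late = np.mean(~late)
    q_neither = np.mean(~early & ~late)
    return q_not_early, q_not_late, q_neither


def approximate_likelihood(
    theta: ModelParams,
    obs: Observations = HEAT_EXPERIMENT,
    n_sims: int = 1000,
    rng=None,
    aneuploid_class: str = "aneuploid",
    min_conditioning: int = 10,
) -> float:
    """Monte-Carlo approximation of the observation likelihood.

    Runs ``n_sims`` stochastic simulations, estimates the window probability
    P(lo <= T(aneuploid) <= hi) and, conditional on the window event, the
    deadline probabilities for 2n* fixation (the proxy for aneuploidy loss);
    combines them through :func:`replicate_bracket`.

    ``aneuploid_class`` selects whether the window event uses the aneuploid
    class (2n+1 plus 2n+1*, the karyotype the experiment assayed) or the
    2n+1 genotype alone.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if aneuploid_class not in ("aneuploid", "2n+1"):
        raise ValueError("aneuploid_class must be 'aneuploid' or '2n+1'")
    horizon = max(theta.horizon, obs.loss_deadlines[1])
    res = batch_events(theta, n_sims, rng=rng, horizon=horizon)
    t_an = res.t_fix_aneuploid if aneuploid_class == "aneuploid" else res.t_fix_2n1
    lo, hi = obs.fixation_window
    window = ~np.isnan(t_an) & (t_an >= lo) & (t_an <= hi)
    p_window = window.mean()
    n_cond = int(window.sum())
    if n_cond == 0:
        return 0.0
    if n_cond < min_conditioning:
        logger.warning(
            "only %d of %d simulations satisfy the fixation window; "
            "conditional probabilities are low-confidence",
            n_cond,
            n_sims,
        )
    qs = _deadline_probabilities(res.t_fix_mutant[window], obs)
    bracket = replicate_bracket(*qs, n_replicates=obs.n_replicates)
    return float(p_window ** obs.n_replicates * max(bracket, 0.0))


def likelihood_no_aneuploidy(
    theta: ModelParams,
    obs: Observations = HEAT_EXPERIMENT,
    n_sims: int = 1000,
    rng=None,
) -> float:
    """Likelihood of the loss deadlines under the delta=0 model.

    Without aneuploidy there is no fixation window to condition on; the
    replicate bracket is evaluated unconditionally on the 2n* fixation
    times.
    """
    if theta.delta != 0:
        raise ValueError("the no-aneuploidy likelihood requires delta = 0")
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    horizon = max(theta.horizon, obs.loss_deadlines[1])
    res = batch_events(theta, n_sims, rng=rng, horizon=horizon)
    qs = _deadline_probabilities(res.t_fix_mutant, obs)
    bracket = replicate_bracket(*qs, n_replicates=obs.n_replicates)
    return float(max(bracket, 0.0))


def likelihood_surface(
    thetas: Iterable[ModelParams],
    obs: Observations = HEAT_EXPERIMENT,
    n_sims: int = 1000,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Evaluate the likelihood on a grid of parameter vectors.

    Each grid point gets an independent child seed derived from ``seed``;
    points with delta = 0 dispatch to the no-aneuploidy likelihood.  Returns
    a tidy table with the parameter components, L, n_sims and the seed used.
    """
    rows = []
    ss = np.random.SeedSequence(seed)
    for theta in thetas:
        child = ss.spawn(1)[0]
        child_seed = int(child.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(child_seed)
        if theta.delta == 0:
            L = likelihood_no_aneuploidy(theta, obs, n_sims=n_sims, rng=rng)
        else:
            L = approximate_likelihood(theta, obs, n_sims=n_sims, rng=rng)
        rows.append(
            {
                "mu": theta.mu,
                "delta": theta.delta,
                "w_2n+1": theta.w[1],
                "w_2n+1*": theta.w[2],
                "w_2n*": theta.w[3],
                "N": theta.N,
                "L": L,
                "n_sims": n_sims,
                "seed": child_seed,
            }
        )
    return pd.DataFrame(rows)
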