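"""Evolutionary learning loop: trials, collective reward, replicate colonies.

One *learning process* is a sequence of defensive events (trials) against
encounters sampled from a :class:`~stingsim.trial.PredatorProfile`.  The
colony shares a single memory matrix — genetic mixing transmits the average
response to the next generation — so after every trial the shared ``h`` is
updated once with the glow counts of all ``N`` agents and the colony reward
``R = a/N``.  Replicate populations are independent colonies trained with
seeds spawned from one master seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

_log = logging.getLogger(__name__)

from .ps_core import LearningParams, Memory, ParameterError
from .trial import (
    ConfigError,
    PerceptEncoder,
    PredatorProfile,
    _dt_v_steps,
    _kills,
    _simulate,
)

__all__ = [
    "RunConfig",
    "PopulationResult",
    "EnsembleResult",
    "sample_encounters",
    "train_population",
    "train_ensemble",
    "evaluate_performance",
    "windowed_performance",
]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one learning experiment."""

    n_bees: int = 100
    learning: LearningParams = field(default_factory=LearningParams)
    profile: PredatorProfile = None  # type: ignore[assignment]
    encoder: PerceptEncoder = field(default_factory=PerceptEncoder)
    n_replicates: int = 50
    window: int = 500  # trailing trials used for visit counts / windowed stats

    def __post_init__(self) -> None:
        if self.profile is None:
            from .trial import SthDistribution

            object.__setattr__(
                self, "profile", PredatorProfile(SthDistribution.uniform(16, 40))
            )
        if self.n_bees < 1:
            raise ConfigError("n_bees must be >= 1")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if not 0 <= self.window <= max(self.learning.n_trials, 0):
            raise ConfigError("window must satisfy 0 <= window <= n_trials")


@dataclass
class PopulationResult:
    """Outcome of one independently trained colony."""

    memory: Memory
    p_sting: np.ndarray  # converged stinging probability per percept
    visits_window: np.ndarray  # percept visit counts over the trailing window
    rewards: np.ndarray  # reward trajectory, one entry per trial
    window_outcomes: pd.DataFrame  # (s_th, s, q, a) for the trailing window
    seed: object
    config: RunConfig


@dataclass
class EnsembleResult:
    """Replicate colonies aggregated: mean +- sd of the converged strategy."""

    replicates: list[PopulationResult]
    p_mean: np.ndarray
    p_std: np.ndarray
    reached: np.ndarray  # percepts visited at least once in any replicate's window
    config: RunConfig

    @property
    def memories(self) -> list[Memory]:
        return [r.memory for r in self.replicates]

    def p_v_esc(self) -> tuple[float, float]:
        """Mean and sd across replicates of the escape-percept probability."""
        i = self.config.encoder.v_esc_index
        return float(self.p_mean[i]), float(self.p_std[i])


def sample_encounters(
    profile: PredatorProfile, rng: np.random.Generator, size: int
) -> np.ndarray:
    """Vectorised draw of ``size`` encounter thresholds (0 = false alarm)."""
    out = np.zeros(size, dtype=np.int64)
    if profile.r_f > 0:
        true_mask = rng.random(size) >= profile.r_f
    else:
        true_mask = np.ones(size, dtype=bool)
    n_true = int(true_mask.sum())
    dist = profile.sth
    if len(dist.ranges) == 1:
        lo, hi = dist.ranges[0]
        vals = rng.integers(lo, hi + 1, size=n_true)
    else:
        w = np.asarray(dist.weights, dtype=float)
        comp = rng.choice(len(dist.ranges), size=n_true, p=w / w.sum())
        vals = np.empty(n_true, dtype=np.int64)
        for i, (lo, hi) in enumerate(dist.ranges):
            m = comp == i
            vals[m] = rng.integers(lo, hi + 1, size=int(m.sum()))
    out[true_mask] = vals
    return out


def train_population(
    config: RunConfig,
    rng: np.random.Generator | int | None = None,
    log_every: int | None = None,
) -> PopulationResult:
    """Train one colony from the all-ones memory; deterministic given a seed.

    Per trial: sample an encounter, run the sequential defensive event with
    the memory frozen, then apply the single collective update
    ``h <- h - gamma (h - h0) + g R``.
    """
    seed = rng if not isinstance(rng, np.random.Generator) else None
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng if rng is not None else config.learning.seed)
    n = config.n_bees
    enc = config.encoder
    gamma = config.learning.gamma
    n_trials = config.learning.n_trials
    n_percepts = enc.n_percepts
    v_idx = enc.v_esc_index
    bin_of = enc.lookup_table(n)
    dt_v = _dt_v_steps(config.profile.dt_v, n)
    k, t_att = config.profile.k, config.profile.t_att

    h = np.ones((n_percepts, 2))
    rewards = np.empty(n_trials)
    visits = np.zeros(n_percepts, dtype=np.int64)
    win_start = n_trials - config.window
    win_records: list[tuple[int, int, int, int]] = []

    sth_seq = sample_encounters(config.profile, rng, n_trials)
    two_p = 2 * n_percepts
    for i in range(n_trials):
        s_th = int(sth_seq[i])
        p = (h[:, 1] / (h[:, 0] + h[:, 1])).tolist()
        u = rng.random(n).tolist()
        glow_flat = [0] * two_p
        s, t_stop = _simulate(p, bin_of, v_idx, n, s_th, dt_v, u, glow_flat)
        q = _kills(s_th, t_stop, k, t_att, n, s)
        a = n - s - q
        reward = a / n
        g = np.asarray(glow_flat, dtype=np.float64).reshape(n_percepts, 2)
        # h <- h - gamma (h - 1) + g R, as one combined assignment
        h *= 1.0 - gamma
        h += gamma
        if reward > 0.0:
            h += g * reward
        rewards[i] = reward
        if i >= win_start:
            visits += g.sum(axis=1).astype(np.int64)
            win_records.append((s_th, s, q, a))
        if log_every and (i + 1) % log_every == 0:
            _log.info(
                "trial %d/%d: mean reward %.3f",
                i + 1, n_trials, rewards[max(0, i + 1 - log_every): i + 1].mean(),
            )

    memory = Memory(h)
    return PopulationResult(
        memory=memory,
        p_sting=memory.p_sting(),
        visits_window=visits,
        rewards=rewards,
        window_outcomes=pd.DataFrame(win_records, columns=["s_th", "s", "q", "a"]),
        seed=seed,
        config=config,
    )


def replicate_seeds(master_seed: int | None, n_replicates: int) -> list[np.random.SeedSequence]:
    """Independent per-replicate seed sequences spawned from one master seed."""
    return np.random.SeedSequence(master_seed).spawn(n_replicates)


def train_ensemble(
    config: RunConfig, seed: int | None = None, log_every: int | None = None
) -> EnsembleResult:
    """Train ``config.n_replicates`` independent colonies and aggregate.

    Replicate streams are spawned from the master seed (``seed`` argument, or
    ``config.learning.seed``) with a counter-based scheme, so the ensemble is
    reproducible and the replicates are statistically independent.
    """
    master = seed if seed is not None else config.learning.seed
    reps = []
    for ss in replicate_seeds(master, config.n_replicates):
        reps.append(train_population(config, np.random.default_rng(ss), log_every))
    p = np.vstack([r.p_sting for r in reps])
    ddof = 1 if len(reps) > 1 else 0
    return EnsembleResult(
        replicates=reps,
        p_mean=p.mean(axis=0),
        p_std=p.std(axis=0, ddof=ddof),
        reached=np.vstack([r.visits_window for r in reps]).sum(axis=0) > 0,
        config=config,
    )


def _survivor_bound_pct(n: int, s_th: int, k: int, t_att: int) -> float:
    """Optimal % of live bees: the colony cannot do better than delivering one
    sting per step from step 0, paying s_th stingers plus the kills accrued
    before the threshold boundary."""
    min_q = k * max(0, min(s_th, n) - t_att)
    if s_th > n:  # the predator can never be deterred
        min_q = k * max(0, n - t_att)
    best_a = max(0, n - min(s_th, n) - min_q)
    return 100.0 * best_a / n


def evaluate_performance(
    memories: Sequence[Memory],
    sth_grid: Sequence[int],
    profile: PredatorProfile,
    rng: np.random.Generator | int | None = None,
    n_bees: int = 100,
    encoder: PerceptEncoder | None = None,
    n_eval_trials: int = 100,
) -> pd.DataFrame:
    """Performance curves with learning frozen on the given trained memories.

    For each threshold on the grid every memory faces ``n_eval_trials``
    encounters with that exact ``s_th`` (false alarms disabled); the returned
    frame holds mean +- sd across replicates of the percentage of live bees
    and of the total number of stings, plus the analytic optimal-survival
    bound and the over-stinging bound ``s_th + dt_v`` (the most stings that
    can occur before the escape percept activates).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if not memories:
        raise ConfigError("need at least one trained memory")
    enc = encoder or PerceptEncoder()
    from .trial import run_trial

    rows = []
    for s_th in sth_grid:
        live_by_rep, stings_by_rep = [], []
        for mem in memories:
            live, stings = [], []
            for _ in range(n_eval_trials):
                out = run_trial(mem, enc, profile, int(s_th), rng, n_bees)
                live.append(100.0 * out.a / n_bees)
                stings.append(out.s)
            live_by_rep.append(np.mean(live))
            stings_by_rep.append(np.mean(stings))
        ddof = 1 if len(memories) > 1 else 0
        sting_bound = min(s_th + profile.dt_v, n_bees) if s_th > 0 else 0
        rows.append(
            {
                "s_th": int(s_th),
                "survivors_pct_mean": float(np.mean(live_by_rep)),
                "survivors_pct_std": float(np.std(live_by_rep, ddof=ddof)),
                "stings_mean": float(np.mean(stings_by_rep)),
                "stings_std": float(np.std(stings_by_rep, ddof=ddof)),
                "survivors_bound_pct": _survivor_bound_pct(
                    n_bees, int(s_th), profile.k, profile.t_att
                ),
                "stings_bound": float(sting_bound),
            }
        )
    return pd.DataFrame(rows)


def windowed_performance(ensemble: EnsembleResult) -> pd.DataFrame:
    """Performance measured during the trailing window of training itself —
    the running-measurement protocol — aggregated per encountered ``s_th``."""
    n = ensemble.config.n_bees
    per_rep = []
    for r in ensemble.replicates:
        df = r.window_outcomes
        g = df.groupby("s_th").agg(live_pct=("a", lambda x: 100.0 * x.mean() / n),
                                   stings=("s", "mean"))
        per_rep.append(g)
    cat = pd.concat(per_rep, keys=range(len(per_rep)), names=["replicate"])
    agg = cat.groupby("s_th").agg(
        survivors_pct_mean=("live_pct", "mean"),
        survivors_pct_std=("live_pct", "std"),
        stings_mean=("stings", "mean"),
        stings_std=("stings", "std"),
    )
    return agg.reset_index()
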