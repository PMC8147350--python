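"""One defensive event: N sequential decisions against a parametric predator.

The colony's ``N`` agents act one per time step (0-based; agent index equals
step index).  Agent *t* perceives the alarm-pheromone concentration produced
by agents ``0..t-1`` — one unit per past sting — unless the visual escape
percept ``v_ESC`` overrides olfaction.  A predator (when present) kills ``k``
bees per step from ``t_att`` until the cumulative number of stings reaches
its resistance threshold ``s_th``; the bees only *see* it retreat ``dt_v``
steps later.

Timing convention.  Let ``t_stop`` be the first step index at whose *start*
the cumulative sting count is >= ``s_th`` (``N`` if never reached).  The
predator kills during exactly the steps ``t_att <= t < t_stop`` and the
escape percept is active for agents acting at steps ``t >= t_stop + dt_v``.
A trial with ``s_th = 0`` is a false alarm: the threshold holds immediately
(``t_stop = 0``), the kill window is empty (``q = 0``, nothing was actually
attacking) and the disturbance is perceived as gone from step ``dt_v`` on.

Concentration is binned logarithmically: percept 0 is concentration 0 and
percept ``b`` (``1 <= b <= 8`` by default) covers ``[2^(b-1), 2^b - 1]``,
the top bin open-ended.  Powers of two resolve low concentrations finely —
a Weber-Fechner-like sensing — and leave the top bins unreached at N=100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import inf, isinf
from typing import NamedTuple, Sequence

import numpy as np

from .ps_core import CHILL, STING, GlowCounts, Memory, ParameterError, sting_probability

__all__ = [
    "PerceptEncoder",
    "SthDistribution",
    "PredatorProfile",
    "TrialStep",
    "TrialOutcome",
    "encode_percept",
    "sample_encounter",
    "run_trial",
    "reward_of",
]


class ConfigError(ValueError):
    """An environment/configuration value is inadmissible."""


@dataclass(frozen=True)
class PerceptEncoder:
    """Maps (pheromone concentration, escape flag) to a percept index.

    ``n_pheromone_bins`` logarithmic bins (default 9, percepts ``0..8``) plus
    the escape percept ``v_ESC`` as the last row, index ``n_pheromone_bins``.
    """

    n_pheromone_bins: int = 9

    def __post_init__(self) -> None:
        if self.n_pheromone_bins < 2:
            raise ConfigError("need at least two pheromone bins")

    @property
    def n_percepts(self) -> int:
        return self.n_pheromone_bins + 1

    @property
    def v_esc_index(self) -> int:
        return self.n_pheromone_bins

    def bin_of(self, concentration: int) -> int:
        """Logarithmic bin of a concentration: 0 -> 0, c -> floor(log2 c)+1,
        capped at the top pheromone bin."""
        if concentration < 0:
            raise ConfigError(f"concentration must be >= 0, got {concentration}")
        if concentration == 0:
            return 0
        return min(int(concentration).bit_length(), self.n_pheromone_bins - 1)

    def encode(self, concentration: int, v_esc_active: bool = False) -> int:
        """Percept index for one agent; vision overrides olfaction."""
        if v_esc_active:
            # validate even though the result ignores the concentration
            self.bin_of(concentration)
            return self.v_esc_index
        return self.bin_of(concentration)

    def lookup_table(self, max_concentration: int) -> list[int]:
        """Percept index for every concentration ``0..max_concentration``."""
        return [self.bin_of(c) for c in range(max_concentration + 1)]

    def bin_upper_edges(self, n_bees: int) -> list[int]:
        """Upper concentration edge of each pheromone bin (marker positions
        for dose-response curves), capped at the colony size."""
        edges = [0]
        for b in range(1, self.n_pheromone_bins):
            edges.append(min(2**b - 1, n_bees))
        edges[-1] = n_bees  # top bin is open-ended
        return edges

    def percept_names(self) -> list[str]:
        return [f"bin{b}" for b in range(self.n_pheromone_bins)] + ["v_ESC"]


@dataclass(frozen=True)
class SthDistribution:
    """Distribution of predator sting-resistance thresholds.

    A weighted mixture of inclusive integer ranges; a single uniform range is
    the one-component special case.
    """

    ranges: tuple[tuple[int, int], ...]
    weights: tuple[float, ...]

    @classmethod
    def uniform(cls, lo: int, hi: int) -> "SthDistribution":
        return cls(((lo, hi),), (1.0,))

    @classmethod
    def mixture(
        cls, components: Sequence[tuple[tuple[int, int], float]]
    ) -> "SthDistribution":
        ranges = tuple(tuple(r) for r, _ in components)
        weights = tuple(w for _, w in components)
        return cls(ranges, weights)  # type: ignore[arg-type]

    def __post_init__(self) -> None:
        if not self.ranges:
            raise ConfigError("s_th distribution needs at least one range")
        for lo, hi in self.ranges:
            if lo < 1 or hi < lo:
                raise ConfigError(f"invalid s_th range ({lo}, {hi}): need 1 <= lo <= hi")
        if len(self.weights) != len(self.ranges):
            raise ConfigError("one weight per range required")
        if any(w < 0 for w in self.weights) or sum(self.weights) <= 0:
            raise ConfigError("weights must be non-negative and not all zero")

    def sample(self, rng: np.random.Generator) -> int:
        w = np.asarray(self.weights, dtype=float)
        idx = int(rng.choice(len(self.ranges), p=w / w.sum())) if len(w) > 1 else 0
        lo, hi = self.ranges[idx]
        return int(rng.integers(lo, hi + 1))

    @property
    def max_sth(self) -> int:
        return max(hi for _, hi in self.ranges)


@dataclass(frozen=True)
class PredatorProfile:
    """The environmental pressure one colony evolves against.

    Parameters
    ----------
    sth
        Distribution of sting thresholds for true-predator encounters.
    k
        Bees killed per time step while the predator attacks.
    t_att
        Step at which the attack starts (detection lead time of the colony).
    dt_v
        Delay (steps) between the predator desisting and the bees seeing it
        retreat; ``math.inf`` disables the escape percept.
    r_f
        Probability that a defensive event is a false alarm (no predator).
    """

    sth: SthDistribution
    k: int = 1
    t_att: int = 0
    dt_v: float = 10
    r_f: float = 0.0

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ConfigError("k must be >= 0")
        if self.t_att < 0:
            raise ConfigError("t_att must be >= 0")
        if self.dt_v < 0:
            raise ConfigError("dt_v must be >= 0 (or math.inf)")
        if not 0.0 <= self.r_f <= 1.0:
            raise ConfigError(f"r_f must be in [0, 1], got {self.r_f}")


class TrialStep(NamedTuple):
    step: int
    percept: int
    action: int
    concentration: int
    v_esc: bool


@dataclass
class TrialOutcome:
    """Bookkeeping of one defensive event."""

    s: int  # agents that stung (they die: the stinger tears loose)
    q: int  # bees killed by the predator (capped so survivors >= 0)
    a: int  # survivors, N - s - q
    t_stop: int  # first step at whose start cumulative stings >= s_th; N if never
    glow: GlowCounts
    n_bees: int
    s_th: int
    trace: list[TrialStep] | None = None

    @property
    def reward(self) -> float:
        return self.a / self.n_bees


def encode_percept(
    encoder: PerceptEncoder, concentration: int, v_esc_active: bool = False
) -> int:
    """Functional alias for :meth:`PerceptEncoder.encode`."""
    return encoder.encode(concentration, v_esc_active)


def sample_encounter(profile: PredatorProfile, rng: np.random.Generator) -> int:
    """Draw the sting threshold of the next defensive event.

    Returns 0 with probability ``r_f`` (false alarm, no predator), otherwise
    a threshold from the profile's ``s_th`` distribution.
    """
    if profile.r_f > 0 and rng.random() < profile.r_f:
        return 0
    return profile.sth.sample(rng)


def _dt_v_steps(dt_v: float, n: int) -> int:
    """Integer escape delay for a trial of n steps; inf means 'never'."""
    if isinf(dt_v):
        return n  # t - t_stop < n always, so v_ESC never activates
    return int(dt_v)


def _simulate(
    p_sting: Sequence[float],
    bin_of: Sequence[int],
    v_idx: int,
    n: int,
    s_th: int,
    dt_v: int,
    u: Sequence[float],
    glow: list[int],
    trace: list[TrialStep] | None = None,
) -> tuple[int, int]:
    """Tight inner loop of one trial.

    ``glow`` is a flat list of length ``2 * n_percepts`` indexed
    ``2 * percept + action``; it is incremented in place.  Returns
    ``(stings, t_stop)`` with ``t_stop`` the start-of-step boundary at which
    the threshold first held (``n`` if never).
    """
    s = 0
    t_stop = -1
    for t in range(n):
        if t_stop < 0 and s >= s_th:
            t_stop = t
        if t_stop >= 0 and t - t_stop >= dt_v:
            percept = v_idx
        else:
            percept = bin_of[s]
        if u[t] < p_sting[percept]:
            s += 1
            glow[2 * percept + 1] += 1
            action = STING
        else:
            glow[2 * percept] += 1
            action = CHILL
        if trace is not None:
            conc = s - action  # concentration the agent perceived
            trace.append(
                TrialStep(t, percept, action, conc, percept == v_idx)
            )
    if t_stop < 0:
        t_stop = n  # includes 'reached exactly by the last agent'
    return s, t_stop


def run_trial(
    memory: Memory,
    encoder: PerceptEncoder,
    profile: PredatorProfile,
    s_th: int,
    rng: np.random.Generator,
    n_bees: int = 100,
    record_trace: bool = False,
) -> TrialOutcome:
    """Simulate one defensive event; the memory is read, never modified.

    Each of the ``n_bees`` agents decides exactly once via the PS transition
    rule.  Kills are end-of-trial bookkeeping (killed bees still act).
    """
    if memory.n_percepts != encoder.n_percepts:
        raise ConfigError(
            f"memory has {memory.n_percepts} percepts, encoder expects {encoder.n_percepts}"
        )
    if s_th < 0:
        raise ConfigError("s_th must be >= 0")
    p = memory.p_sting().tolist()
    bin_of = encoder.lookup_table(n_bees)
    glow_flat = [0] * (2 * encoder.n_percepts)
    u = rng.random(n_bees).tolist()
    trace: list[TrialStep] | None = [] if record_trace else None
    s, t_stop = _simulate(
        p, bin_of, encoder.v_esc_index, n_bees, s_th,
        _dt_v_steps(profile.dt_v, n_bees), u, glow_flat, trace,
    )
    q = _kills(s_th, t_stop, profile.k, profile.t_att, n_bees, s)
    glow = GlowCounts(np.array(glow_flat, dtype=np.int64).reshape(-1, 2))
    return TrialOutcome(
        s=s, q=q, a=n_bees - s - q, t_stop=t_stop, glow=glow,
        n_bees=n_bees, s_th=s_th, trace=trace,
    )


def _kills(s_th: int, t_stop: int, k: int, t_att: int, n: int, s: int) -> int:
    """Predator kills: k per step over [t_att, t_stop), capped at N - s.

    On a false alarm (s_th = 0) the threshold holds at step 0, the kill
    window is empty and q = 0 — nothing was ever attacking.
    """
    q = k * max(0, min(t_stop, n) - t_att)
    return min(q, n - s)


def reward_of(outcome: TrialOutcome, n_bees: int) -> float:
    """Colony reward ``R = a / N``: the surviving fraction of the colony."""
    return outcome.a / n_bees
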