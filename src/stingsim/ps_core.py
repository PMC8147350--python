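"""Two-layer Projective Simulation machinery shared by all bees in a colony.

A Projective Simulation (PS) agent deliberates over an episodic memory: a
weighted network of percept clips connected to action clips.  For the colony
defence model a two-layer network suffices, so the whole memory is a single
``P x 2`` matrix of positive edge weights *h* — one row per percept (nine
logarithmic alarm-pheromone bins plus the visual escape percept) and one
column per action (``chill``, ``sting``).  The transition probability from
percept *i* to action *j* is ``h[i, j] / sum_k h[i, k]``.

Learning is collective and generational: after each defensive event (trial)
every traversed percept->action edge is reinforced in proportion to how many
of the ``N`` agents traversed it (the glow counts ``g``) and to the colony
reward ``R``, while all weights are damped towards their initial value by the
forgetting rate ``gamma``:

    h'  =  h - gamma * (h - h0) + g * R

With ``h0 = 1``, ``R >= 0`` and ``0 <= gamma < 1`` every weight stays >= 1.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "CHILL",
    "STING",
    "ACTIONS",
    "Memory",
    "GlowCounts",
    "LearningParams",
    "sting_probability",
    "decide",
    "update_memory",
]

CHILL: int = 0
STING: int = 1
ACTIONS: tuple[str, str] = ("chill", "sting")


class ParameterError(ValueError):
    """A learning or model parameter is outside its admissible range."""


@dataclass
class Memory:
    """Shared percept-to-action weight matrix of a colony.

    Parameters
    ----------
    h
        ``(n_percepts, 2)`` array of edge weights, columns ``(chill, sting)``.
    h0
        Initialisation matrix of the same shape; damping pulls ``h`` towards
        it.  Defaults to all ones, which makes every initial decision a fair
        coin flip.
    """

    h: np.ndarray
    h0: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        if self.h.ndim != 2 or self.h.shape[1] != 2:
            raise ParameterError(f"memory must have shape (P, 2), got {self.h.shape}")
        if self.h0 is None:
            self.h0 = np.ones_like(self.h)
        else:
            self.h0 = np.asarray(self.h0, dtype=float)
            if self.h0.shape != self.h.shape:
                raise ParameterError("h and h0 shapes differ")
        if np.any(self.h < 1.0):
            raise ParameterError("all h entries must be >= 1")

    @classmethod
    def initial(cls, n_percepts: int = 10) -> "Memory":
        """All-ones memory: stinging probability 0.5 for every percept."""
        return cls(np.ones((n_percepts, 2)))

    @property
    def n_percepts(self) -> int:
        return self.h.shape[0]

    def p_sting(self) -> np.ndarray:
        """Vector of stinging probabilities, one entry per percept."""
        return self.h[:, STING] / self.h.sum(axis=1)

    def copy(self) -> "Memory":
        return Memory(self.h.copy(), self.h0.copy())

    # -- serialisation ------------------------------------------------------

    def to_csv(self, path: str | Path, percept_names: list[str] | None = None) -> None:
        """Write one row per percept with full-precision hex floats alongside
        decimal values so a round-trip is bit exact."""
        names = percept_names or [f"percept_{i}" for i in range(self.n_percepts)]
        if len(names) != self.n_percepts:
            raise ParameterError("percept_names length mismatch")
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["percept", "h_chill", "h_sting", "h_chill_hex", "h_sting_hex"])
            for name, (hc, hs) in zip(names, self.h):
                w.writerow([name, repr(hc), repr(hs), float(hc).hex(), float(hs).hex()])

    @classmethod
    def from_csv(cls, path: str | Path) -> "Memory":
        rows = []
        with open(path, newline="") as fh:
            for rec in csv.DictReader(fh):
                rows.append(
                    [float.fromhex(rec["h_chill_hex"]), float.fromhex(rec["h_sting_hex"])]
                )
        return cls(np.array(rows))

    def to_json(self) -> str:
        return json.dumps(
            {
                "actions": list(ACTIONS),
                "h": [[v.hex() for v in row] for row in self.h.tolist()],
                "h0": [[v.hex() for v in row] for row in self.h0.tolist()],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Memory":
        doc = json.loads(text)
        decode = lambda rows: np.array(
            [[float.fromhex(v) for v in row] for row in rows]
        )
        return cls(decode(doc["h"]), decode(doc["h0"]))


@dataclass
class GlowCounts:
    """Per-trial counts of agents that traversed each percept->action edge.

    After a full trial of ``N`` sequential decisions the entries sum to ``N``:
    each agent contributes exactly one traversal.
    """

    g: np.ndarray

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g)
        if np.any(self.g < 0):
            raise ParameterError("glow counts must be non-negative")

    @classmethod
    def zeros(cls, n_percepts: int) -> "GlowCounts":
        return cls(np.zeros((n_percepts, 2), dtype=np.int64))

    def total(self) -> int:
        return int(self.g.sum())

    def record(self, percept: int, action: int) -> None:
        self.g[percept, action] += 1

    def reset(self) -> None:
        self.g[:] = 0


@dataclass(frozen=True)
class LearningParams:
    """Forgetting rate, trial budget and seed of one learning process."""

    gamma: float = 0.003
    n_trials: int = 80_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma < 1.0:
            raise ParameterError(f"gamma must be in [0, 1), got {self.gamma}")
        if self.n_trials < 0:
            raise ParameterError("n_trials must be >= 0")


def sting_probability(memory: Memory, percept: int) -> float:
    """Probability that a single agent stings when *percept* is active.

    This is the PS transition rule ``p = h_sting / (h_sting + h_chill)`` for
    the percept's row.  With all weights >= 1 the value lies in (0, 1).
    """
    row = memory.h[percept]
    return float(row[STING] / (row[CHILL] + row[STING]))


def decide(memory: Memory, percept: int, rng: np.random.Generator) -> int:
    """Draw one action for an agent facing *percept*.

    Returns ``STING`` with probability :func:`sting_probability`; bookkeeping
    (glow, pheromone release) is the caller's job.
    """
    return STING if rng.random() < sting_probability(memory, percept) else CHILL


def update_memory(
    memory: Memory,
    glow: GlowCounts | np.ndarray,
    reward: float,
    gamma: float,
) -> Memory:
    """One collective learning step:  ``h' = h - gamma (h - h0) + g R``.

    Damping and reinforcement are a single assignment reading the pre-update
    ``h`` once.  Returns a new :class:`Memory`; the input is untouched.
    """
    if reward < 0:
        raise ParameterError(f"reward must be >= 0, got {reward}")
    if not 0.0 <= gamma < 1.0:
        raise ParameterError(f"gamma must be in [0, 1), got {gamma}")
    g = glow.g if isinstance(glow, GlowCounts) else np.asarray(glow)
    if g.shape != memory.h.shape:
        raise ParameterError(f"glow shape {g.shape} != memory shape {memory.h.shape}")
    h_new = memory.h - gamma * (memory.h - memory.h0) + g * reward
    return Memory(h_new, memory.h0.copy())
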