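"""Named experiments: environmental-pressure comparisons, the converged
escape-percept table, the European/African case study and the aggressive
score used to compare ecotype dose-response data.

Each comparison scenario pairs a baseline colony configuration with variants
that change exactly one environmental pressure (detection lead time, false
alarms, predator resistance or diversity, escape-visibility delay), except
the territory scenario where the detection lead time and the visibility
delay move together as one conceptual parameter — the territory radius.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import inf

import numpy as np
import pandas as pd

from .evolution import (
    EnsembleResult,
    RunConfig,
    evaluate_performance,
    train_ensemble,
)
from .ps_core import LearningParams
from .trial import ConfigError, PerceptEncoder, PredatorProfile, SthDistribution

__all__ = [
    "ScenarioSpec",
    "AggressiveScoreInput",
    "baseline_profile",
    "baseline_config",
    "TABLE1_PROCESSES",
    "table1_config",
    "scenario_table1",
    "scenario_ehb_ahb",
    "aggressive_score",
    "dose_response",
    "SCENARIOS",
    "get_scenario",
]

#: Converged escape-percept stinging probabilities reported for the nine
#: reference learning processes (mean, sd over 50 colonies of 80k trials).
TABLE1_REFERENCE: dict[int, tuple[float, float]] = {
    1: (0.005, 0.002),
    2: (0.023, 0.011),
    3: (0.012, 0.006),
    4: (0.024, 0.010),
    5: (0.018, 0.005),
    6: (0.007, 0.003),
    7: (0.006, 0.002),
    8: (0.007, 0.003),
    9: (0.024, 0.014),
}

#: Parameterisation of the nine processes: (s_th, k, r_f, t_att, dt_v).
TABLE1_PROCESSES: dict[int, dict] = {
    1: dict(sth=(16, 40), k=1, r_f=0.0, t_att=0, dt_v=10),
    2: dict(sth=(16, 40), k=1, r_f=0.0, t_att=60, dt_v=10),
    3: dict(sth=(16, 40), k=1, r_f=0.3, t_att=0, dt_v=10),
    4: dict(sth=(16, 40), k=1, r_f=0.6, t_att=0, dt_v=10),
    5: dict(sth=(7, 16), k=1, r_f=0.0, t_att=0, dt_v=10),
    6: dict(sth="nonuniform", k=1, r_f=0.0, t_att=0, dt_v=10),
    7: dict(sth=(16, 40), k=1, r_f=0.0, t_att=0, dt_v=20),
    8: dict(sth=(16, 40), k=1, r_f=0.0, t_att=10, dt_v=10),
    9: dict(sth=(16, 40), k=1, r_f=0.0, t_att=40, dt_v=40),
}

#: Weak predators four times as frequent as strong ones.
NONUNIFORM_STH = SthDistribution.mixture([((16, 26), 0.8), ((27, 40), 0.2)])


def _sth_dist(spec) -> SthDistribution:
    if spec == "nonuniform":
        return NONUNIFORM_STH
    if isinstance(spec, SthDistribution):
        return spec
    lo, hi = spec
    return SthDistribution.uniform(lo, hi)


def baseline_profile() -> PredatorProfile:
    """Reference predator environment: s_th uniform on (16, 40), k=1,
    t_att=0, dt_v=10, no false alarms."""
    return PredatorProfile(SthDistribution.uniform(16, 40))


def baseline_config(
    n_trials: int = 80_000, n_replicates: int = 50, seed: int | None = None
) -> RunConfig:
    return RunConfig(
        n_bees=100,
        learning=LearningParams(gamma=0.003, n_trials=n_trials, seed=seed),
        profile=baseline_profile(),
        n_replicates=n_replicates,
        window=min(500, n_trials),
    )


def table1_config(
    process: int,
    n_trials: int = 80_000,
    n_replicates: int = 5,
    seed: int | None = None,
) -> RunConfig:
    """RunConfig of one of the nine reference learning processes."""
    if process not in TABLE1_PROCESSES:
        raise ConfigError(f"unknown process number {process}")
    p = TABLE1_PROCESSES[process]
    profile = PredatorProfile(
        sth=_sth_dist(p["sth"]), k=p["k"], t_att=p["t_att"], dt_v=p["dt_v"], r_f=p["r_f"]
    )
    cfg = baseline_config(n_trials=n_trials, n_replicates=n_replicates, seed=seed)
    return replace(cfg, profile=profile)


# ---------------------------------------------------------------------------
# scenario specs


def _leaf_params(config: RunConfig) -> dict:
    pr = config.profile
    return {
        "n_bees": config.n_bees,
        "gamma": config.learning.gamma,
        "n_trials": config.learning.n_trials,
        "sth": (pr.sth.ranges, pr.sth.weights),
        "k": pr.k,
        "t_att": pr.t_att,
        "dt_v": pr.dt_v,
        "r_f": pr.r_f,
    }


def config_diff(a: RunConfig, b: RunConfig) -> set[str]:
    """Names of the leaf parameters on which two configurations differ."""
    pa, pb = _leaf_params(a), _leaf_params(b)
    return {k for k in pa if pa[k] != pb[k]}


@dataclass(frozen=True)
class ScenarioSpec:
    """A baseline configuration plus variants differing in declared fields."""

    name: str
    baseline: RunConfig
    variants: tuple[tuple[str, RunConfig], ...]
    varied: tuple[str, ...]  # leaf fields each variant may change
    description: str = ""

    def __post_init__(self) -> None:
        for label, cfg in self.variants:
            diff = config_diff(self.baseline, cfg)
            if diff != set(self.varied):
                raise ConfigError(
                    f"scenario {self.name!r} variant {label!r} differs from the "
                    f"baseline in {sorted(diff)}, declared {sorted(self.varied)}"
                )


def _comparison(name, varied, variants, description, base_kw=None, **base_profile_kw):
    base = baseline_config()
    if base_profile_kw:
        base = replace(base, profile=replace(base.profile, **base_profile_kw))
    var = tuple(
        (label, replace(base, profile=replace(base.profile, **kw))) for label, kw in variants
    )
    return ScenarioSpec(name, base, var, varied, description)


def _build_scenarios() -> dict[str, "ScenarioSpec"]:
    scen = {}
    scen["baseline"] = ScenarioSpec(
        "baseline", baseline_config(), (), (), "reference colony, no variant"
    )
    scen["guards"] = _comparison(
        "guards", ("t_att",), [("t_att=60", dict(t_att=60))],
        "early predator detection by guard bees",
    )
    scen["false-alarms"] = _comparison(
        "false-alarms", ("r_f",),
        [("r_f=0.3", dict(r_f=0.3)), ("r_f=0.6", dict(r_f=0.6))],
        "predator-free disturbances during evolution",
    )
    scen["weak-predators"] = _comparison(
        "weak-predators", ("sth",),
        [("sth=(7,16)", dict(sth=SthDistribution.uniform(7, 16)))],
        "only easily deterred predators",
    )
    scen["nonuniform"] = _comparison(
        "nonuniform", ("sth",),
        [("nonuniform", dict(sth=NONUNIFORM_STH))],
        "weak predators four times more frequent than strong ones",
    )
    scen["termination"] = _comparison(
        "termination", ("dt_v",), [("dt_v=20", dict(dt_v=20))],
        "slower visual detection of the predator's retreat",
    )
    # territory radius: t_att and dt_v move together
    small = replace(
        baseline_config(), profile=replace(baseline_profile(), t_att=10, dt_v=10)
    )
    large = replace(
        baseline_config(), profile=replace(baseline_profile(), t_att=40, dt_v=40)
    )
    scen["territory"] = ScenarioSpec(
        "territory", small, (("t_att=dt_v=40", large),), ("t_att", "dt_v"),
        "small vs large defended territory (t_att = dt_v = radius)",
    )
    return scen


SCENARIOS: dict[str, ScenarioSpec] = _build_scenarios()
#: Scenario names accepted by the CLI; table1 and ehb-ahb are composite runs.
SCENARIO_NAMES = tuple(SCENARIOS) + ("table1", "ehb-ahb")


def get_scenario(name: str) -> ScenarioSpec:
    try:
        return SCENARIOS[name]
    except KeyError:
        raise ConfigError(
            f"unknown scenario {name!r}; choose from {sorted(SCENARIO_NAMES)}"
        ) from None


# ---------------------------------------------------------------------------
# composite experiments


def scenario_table1(
    n_replicates: int = 5,
    n_trials: int = 80_000,
    seed: int | None = None,
    processes: tuple[int, ...] = tuple(TABLE1_PROCESSES),
    return_ensembles: bool = False,
):
    """Converged escape-percept probabilities for the reference processes.

    Trains ``n_replicates`` colonies per process and tabulates the ensemble
    mean +- sd of the escape-percept stinging probability next to the
    reference values.  Seeds for different processes are decorrelated by
    offsetting the master seed with the process number.
    """
    rows, ensembles = [], {}
    for proc in processes:
        cfg = table1_config(proc, n_trials=n_trials, n_replicates=n_replicates)
        master = None if seed is None else seed * 100 + proc
        ens = train_ensemble(cfg, seed=master)
        mean, std = ens.p_v_esc()
        ref_mean, ref_std = TABLE1_REFERENCE[proc]
        pars = TABLE1_PROCESSES[proc]
        rows.append(
            {
                "process": proc,
                "s_th": str(pars["sth"]),
                "k": pars["k"],
                "r_f": pars["r_f"],
                "t_att": pars["t_att"],
                "dt_v": pars["dt_v"],
                "p_v_esc_mean": mean,
                "p_v_esc_std": std,
                "reference_mean": ref_mean,
                "reference_std": ref_std,
            }
        )
        ensembles[proc] = ens
    table = pd.DataFrame(rows)
    return (table, ensembles) if return_ensembles else table


def ehb_config(n_trials: int = 100_000, n_replicates: int = 3) -> RunConfig:
    """European colonies: frequent false alarms, narrow predator range."""
    return RunConfig(
        n_bees=200,
        learning=LearningParams(gamma=0.003, n_trials=n_trials),
        profile=PredatorProfile(SthDistribution.uniform(15, 25), r_f=0.6),
        n_replicates=n_replicates,
    )


def ahb_config(n_trials: int = 100_000, n_replicates: int = 3) -> RunConfig:
    """African(ized) colonies: rarer false alarms, resistant predators."""
    return RunConfig(
        n_bees=200,
        learning=LearningParams(gamma=0.003, n_trials=n_trials),
        profile=PredatorProfile(SthDistribution.uniform(15, 70), r_f=0.3),
        n_replicates=n_replicates,
    )


def scenario_ehb_ahb(
    n_replicates: int = 3,
    n_trials: int = 100_000,
    seed: int | None = None,
    cross_sth: tuple[int, ...] = (20, 55),
    n_eval_trials: int = 100,
) -> dict:
    """European vs African(ized) case study.

    Trains both ecotype configurations, then evaluates each trained strategy
    (learning frozen) against predators of resistance ``cross_sth`` under the
    ecotype's own environment with false alarms disabled.  Returns the two
    :class:`EnsembleResult` objects and a cross-survival table.
    """
    results = {}
    for label, cfg in (
        ("EHB", ehb_config(n_trials, n_replicates)),
        ("AHB", ahb_config(n_trials, n_replicates)),
    ):
        master = None if seed is None else seed * 100 + (1 if label == "EHB" else 2)
        results[label] = train_ensemble(cfg, seed=master)
    rows = []
    for label, ens in results.items():
        profile = replace(ens.config.profile, r_f=0.0)
        eval_rng = np.random.default_rng(
            None if seed is None else seed * 100 + 7
        )
        perf = evaluate_performance(
            ens.memories, cross_sth, profile, eval_rng,
            n_bees=ens.config.n_bees, encoder=ens.config.encoder,
            n_eval_trials=n_eval_trials,
        )
        for _, r in perf.iterrows():
            rows.append(
                {
                    "colony": label,
                    "s_th": int(r["s_th"]),
                    "survivors_pct_mean": r["survivors_pct_mean"],
                    "survivors_pct_std": r["survivors_pct_std"],
                    "stings_mean": r["stings_mean"],
                }
            )
    results["cross_survival"] = pd.DataFrame(rows)
    return results


# ---------------------------------------------------------------------------
# data transforms


@dataclass(frozen=True)
class AggressiveScoreInput:
    """Percentages of caged-bee responses by intensity category."""

    no_response: float
    weak: float
    moderate: float
    strong: float
    very_strong: float

    def __post_init__(self) -> None:
        vals = (self.no_response, self.weak, self.moderate, self.strong, self.very_strong)
        if any(v < 0 for v in vals):
            raise ConfigError("category percentages must be >= 0")
        if abs(sum(vals) - 100.0) > 0.5:
            raise ConfigError(
                f"category percentages must sum to 100 (+-0.5), got {sum(vals)}"
            )


def aggressive_score(inp: AggressiveScoreInput) -> float:
    """Weighted response score ``A_s = 0 N + 1 W + 2 M + 3 S + 4 V``,
    ranging 0 (all unresponsive) to 400 (all very strong)."""
    return (
        0.0 * inp.no_response
        + 1.0 * inp.weak
        + 2.0 * inp.moderate
        + 3.0 * inp.strong
        + 4.0 * inp.very_strong
    )


def dose_response(ensemble: EnsembleResult) -> pd.DataFrame:
    """Dose-response curve of a trained ensemble: one row per pheromone
    percept that was actually visited during the trailing window, with the
    bin's upper concentration edge as the x-coordinate."""
    enc = ensemble.config.encoder
    edges = enc.bin_upper_edges(ensemble.config.n_bees)
    rows = []
    for b in range(enc.n_pheromone_bins):
        if not ensemble.reached[b]:
            continue
        rows.append(
            {
                "percept": b,
                "bin_upper_edge": edges[b],
                "p_sting_mean": float(ensemble.p_mean[b]),
                "p_sting_std": float(ensemble.p_std[b]),
            }
        )
    return pd.DataFrame(rows, columns=["percept", "bin_upper_edge", "p_sting_mean", "p_sting_std"])
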