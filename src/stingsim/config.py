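"""YAML run-configuration parsing with strict validation.

A config file describes one learning experiment.  Every key is optional;
defaults are the reference colony (N=100, gamma=0.003, 80 000 trials,
s_th uniform on (16, 40), k=1, t_att=0, dt_v=10, r_f=0).  A ``scenario``
key seeds the defaults from a named scenario's baseline instead.  Unknown
keys are rejected and errors carry dotted field paths.

Example::

    scenario: baseline
    n_trials: 20000
    seed: 7
    predator:
      r_f: 0.3
      dt_v: inf
"""

from __future__ import annotations

from dataclasses import replace
from math import inf
from pathlib import Path

import yaml

from .evolution import RunConfig
from .ps_core import LearningParams
from .trial import ConfigError, PerceptEncoder, PredatorProfile, SthDistribution

__all__ = ["load_config", "config_from_dict", "config_to_dict", "save_config"]

_TOP_KEYS = {
    "scenario", "n_bees", "gamma", "n_trials", "seed", "n_replicates",
    "window", "n_pheromone_bins", "predator",
}
_PRED_KEYS = {"s_th", "k", "t_att", "dt_v", "r_f"}


def _fail(path: str, msg: str):
    raise ConfigError(f"{path}: {msg}")


def _require(cond: bool, path: str, msg: str) -> None:
    if not cond:
        _fail(path, msg)


def _number(doc: dict, key: str, default, path: str, lo=None, hi=None,
            hi_incl=None, integer=False):
    val = doc.get(key, default)
    if val is None:
        return None
    _require(isinstance(val, (int, float)) and not isinstance(val, bool),
             f"{path}{key}", f"expected a number, got {val!r}")
    if integer:
        _require(float(val).is_integer(), f"{path}{key}", f"expected an integer, got {val!r}")
        val = int(val)
    if lo is not None:
        _require(val >= lo, f"{path}{key}", f"must be >= {lo}, got {val}")
    if hi is not None:
        _require(val < hi, f"{path}{key}", f"must be < {hi}, got {val}")
    if hi_incl is not None:
        _require(val <= hi_incl, f"{path}{key}", f"must be <= {hi_incl}, got {val}")
    return val


def _parse_sth(raw, path: str) -> SthDistribution:
    try:
        if isinstance(raw, (list, tuple)) and len(raw) == 2 and all(
            isinstance(v, int) for v in raw
        ):
            return SthDistribution.uniform(*raw)
        if isinstance(raw, list):
            comps = []
            for i, item in enumerate(raw):
                _require(isinstance(item, dict) and set(item) <= {"range", "weight"},
                         f"{path}[{i}]", "expected {range: [lo, hi], weight: w}")
                comps.append((tuple(item["range"]), float(item.get("weight", 1.0))))
            return SthDistribution.mixture(comps)
    except ConfigError as err:
        _fail(path, str(err))
    _fail(path, f"cannot interpret s_th specification {raw!r}")


def config_from_dict(doc: dict) -> RunConfig:
    """Build a validated :class:`RunConfig` from a plain mapping."""
    _require(isinstance(doc, dict), "<root>", "config must be a mapping")
    unknown = set(doc) - _TOP_KEYS
    _require(not unknown, "<root>", f"unknown keys {sorted(unknown)}")

    if "scenario" in doc:
        from .scenarios import get_scenario

        base = get_scenario(str(doc["scenario"])).baseline
    else:
        from .scenarios import baseline_config

        base = baseline_config()

    pred_doc = doc.get("predator", {}) or {}
    _require(isinstance(pred_doc, dict), "predator", "must be a mapping")
    unknown = set(pred_doc) - _PRED_KEYS
    _require(not unknown, "predator", f"unknown keys {sorted(unknown)}")

    dt_v = pred_doc.get("dt_v", base.profile.dt_v)
    if isinstance(dt_v, str):
        _require(dt_v in ("inf", ".inf", "Infinity"), "predator.dt_v",
                 f"expected a number or 'inf', got {dt_v!r}")
        dt_v = inf
    else:
        dt_v = _number(pred_doc, "dt_v", base.profile.dt_v, "predator.", lo=0)

    sth = base.profile.sth
    if "s_th" in pred_doc:
        sth = _parse_sth(pred_doc["s_th"], "predator.s_th")
    profile = PredatorProfile(
        sth=sth,
        k=_number(pred_doc, "k", base.profile.k, "predator.", lo=0, integer=True),
        t_att=_number(pred_doc, "t_att", base.profile.t_att, "predator.", lo=0, integer=True),
        dt_v=dt_v,
        r_f=_number(pred_doc, "r_f", base.profile.r_f, "predator.", lo=0.0, hi_incl=1.0),
    )

    n_trials = _number(doc, "n_trials", base.learning.n_trials, "", lo=0, integer=True)
    learning = LearningParams(
        gamma=_number(doc, "gamma", base.learning.gamma, "", lo=0.0, hi=1.0),
        n_trials=n_trials,
        seed=_number(doc, "seed", base.learning.seed, "", integer=True),
    )
    window = _number(doc, "window", min(base.window, n_trials), "", lo=0, integer=True)
    _require(window <= n_trials, "window", f"must be <= n_trials ({n_trials}), got {window}")
    return RunConfig(
        n_bees=_number(doc, "n_bees", base.n_bees, "", lo=1, integer=True),
        learning=learning,
        profile=profile,
        encoder=PerceptEncoder(
            _number(doc, "n_pheromone_bins", base.encoder.n_pheromone_bins, "",
                    lo=2, integer=True)
        ),
        n_replicates=_number(doc, "n_replicates", base.n_replicates, "", lo=1, integer=True),
        window=window,
    )


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML config file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return config_from_dict(doc or {})


def config_to_dict(config: RunConfig) -> dict:
    """Round-trippable plain-dict echo of a configuration."""
    pr = config.profile
    if len(pr.sth.ranges) == 1:
        sth = list(pr.sth.ranges[0])
    else:
        sth = [
            {"range": list(r), "weight": w}
            for r, w in zip(pr.sth.ranges, pr.sth.weights)
        ]
    return {
        "n_bees": config.n_bees,
        "gamma": config.learning.gamma,
        "n_trials": config.learning.n_trials,
        "seed": config.learning.seed,
        "n_replicates": config.n_replicates,
        "window": config.window,
        "n_pheromone_bins": config.encoder.n_pheromone_bins,
        "predator": {
            "s_th": sth,
            "k": pr.k,
            "t_att": pr.t_att,
            "dt_v": "inf" if pr.dt_v == inf else pr.dt_v,
            "r_f": pr.r_f,
        },
    }


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
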