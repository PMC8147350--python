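"""Result serialisation: tidy CSV tables, memory snapshots, JSON summary.

A :class:`ResultBundle` collects everything a run produced together with the
configuration echo and provenance needed to reproduce it bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import config_to_dict, save_config
from .evolution import EnsembleResult, RunConfig
from .ps_core import Memory
from .trial import ConfigError

__all__ = ["ResultBundle", "bundle_from_ensemble", "write_results", "read_results"]


class ResultIOError(IOError):
    """I/O failure while writing or reading a result directory."""


@dataclass
class ResultBundle:
    config: RunConfig
    memories: list[Memory]
    tables: dict[str, pd.DataFrame]  # e.g. p_sting, dose_response, performance
    summary: dict
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.memories:
            raise ConfigError("a result bundle needs at least one replicate memory")


def _p_sting_table(ensemble: EnsembleResult) -> pd.DataFrame:
    names = ensemble.config.encoder.percept_names()
    rows = []
    for i, rep in enumerate(ensemble.replicates):
        for p_idx, name in enumerate(names):
            rows.append(
                {
                    "replicate": i,
                    "percept": p_idx,
                    "percept_name": name,
                    "p_sting": float(rep.p_sting[p_idx]),
                    "visits_window": int(rep.visits_window[p_idx]),
                }
            )
    return pd.DataFrame(rows)


def bundle_from_ensemble(
    ensemble: EnsembleResult,
    seed: int | None = None,
    extra_tables: dict[str, pd.DataFrame] | None = None,
) -> ResultBundle:
    """Package a trained ensemble with its per-percept probability table."""
    mean, std = ensemble.p_v_esc()
    tables = {"p_sting": _p_sting_table(ensemble)}
    if extra_tables:
        tables.update(extra_tables)
    summary = {
        "n_replicates": len(ensemble.replicates),
        "p_v_esc_mean": mean,
        "p_v_esc_std": std,
        "final_reward_mean": float(
            np.mean([r.rewards[-ensemble.config.window:].mean()
                     for r in ensemble.replicates])
        ) if ensemble.config.window else None,
    }
    return ResultBundle(
        config=ensemble.config,
        memories=ensemble.memories,
        tables=tables,
        summary=summary,
        seed=seed,
    )


def write_results(bundle: ResultBundle, out_dir: str | Path) -> list[Path]:
    """Write a bundle to a directory; returns the files written.

    Layout: ``config.yaml``, ``summary.json``, one ``memory_repN.csv`` per
    replicate and one CSV per table.  Re-reading reproduces the tables and
    memories bit-exactly.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as err:
        raise ResultIOError(f"cannot create result directory {out}: {err}") from err
    written = []
    names = bundle.config.encoder.percept_names()
    try:
        cfg_path = out / "config.yaml"
        save_config(bundle.config, cfg_path)
        written.append(cfg_path)
        for i, mem in enumerate(bundle.memories):
            path = out / f"memory_rep{i}.csv"
            mem.to_csv(path, percept_names=names)
            written.append(path)
        for name, table in bundle.tables.items():
            path = out / f"{name}.csv"
            table.to_csv(path, index=False)
            written.append(path)
        summary_path = out / "summary.json"
        doc = {
            "summary": bundle.summary,
            "seed": bundle.seed,
            "config": config_to_dict(bundle.config),
            "provenance": {
                "package": "stingsim",
                "version": __version__,
                "written_utc": datetime.now(timezone.utc).isoformat(),
            },
            "tables": sorted(bundle.tables),
            "n_replicates": len(bundle.memories),
        }
        summary_path.write_text(json.dumps(doc, indent=2))
        written.append(summary_path)
    except OSError as err:
        raise ResultIOError(f"failed writing results under {out}: {err}") from err
    return written


def read_results(out_dir: str | Path) -> ResultBundle:
    """Re-load a result directory written by :func:`write_results`."""
    out = Path(out_dir)
    from .config import load_config

    try:
        doc = json.loads((out / "summary.json").read_text())
        config = load_config(out / "config.yaml")
        memories = []
        for i in range(doc["n_replicates"]):
            memories.append(Memory.from_csv(out / f"memory_rep{i}.csv"))
        tables = {
            name: pd.read_csv(out / f"{name}.csv", float_precision="round_trip")
            for name in doc["tables"]
        }
    except (OSError, KeyError, ValueError) as err:
        raise ResultIOError(f"cannot read result directory {out}: {err}") from err
    return ResultBundle(
        config=config, memories=memories, tables=tables,
        summary=doc["summary"], seed=doc["seed"],
    )
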