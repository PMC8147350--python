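"""Minimal plotting helpers (optional; CSV tables are the primary output)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .evolution import EnsembleResult
from .scenarios import dose_response


def plot_dose_response(ensemble: EnsembleResult, path: str | Path) -> None:
    """Stinging probability vs alarm-pheromone concentration (bin upper
    edges, reached percepts only), mean +- sd across replicate colonies."""
    dr = dose_response(ensemble)
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.errorbar(
        dr["bin_upper_edge"], dr["p_sting_mean"], yerr=dr["p_sting_std"],
        marker="o", capsize=3,
    )
    for lo, hi in ensemble.config.profile.sth.ranges:
        ax.axvspan(lo, hi, alpha=0.12, color="grey")
    ax.set_xlabel("alarm pheromone concentration (units)")
    ax.set_ylabel("probability of stinging $p_s$")
    ax.set_ylim(0, 1)
    ax.set_xscale("symlog", linthresh=1)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
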