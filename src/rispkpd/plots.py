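"""Diagnostic figures: brain-to-plasma ratio panels and predictive-check
bands. PNG or SVG is chosen by the output suffix."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_btp", "plot_vpc"]


def plot_btp(table: pd.DataFrame, path) -> None:
    """Ratio-vs-plasma-concentration panels, one per brain region, scenarios
    overlaid (log-log, as these curves are conventionally read)."""
    regions = list(dict.fromkeys(table["region"]))
    fig, axes = plt.subplots(1, len(regions),
                             figsize=(4.2 * len(regions), 3.6),
                             squeeze=False, sharey=True)
    for ax, region in zip(axes[0], regions):
        sub = table[table["region"] == region]
        for scenario, grp in sub.groupby("scenario"):
            order = np.argsort(grp["C_plasma"].to_numpy())
            ax.plot(grp["C_plasma"].to_numpy()[order],
                    grp["ratio"].to_numpy()[order],
                    "o", ms=3, alpha=0.7, label=scenario)
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel("plasma concentration (nM)")
        ax.set_title(region)
    axes[0][0].set_ylabel("brain : plasma ratio")
    axes[0][-1].legend(fontsize=7, frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_vpc(bands: pd.DataFrame, path,
             observed: pd.DataFrame | None = None) -> None:
    """Median and 90% prediction band against time, one panel per
    (study, dose, observation type) stratum, observations overlaid."""
    strata = list(bands.groupby(["STUDY", "DOSE", "TYPE"]).groups)
    n = len(strata)
    ncol = min(3, n)
    nrow = (n + ncol - 1) // ncol
    fig, axes = plt.subplots(nrow, ncol, figsize=(4.2 * ncol, 3.2 * nrow),
                             squeeze=False)
    for ax, key in zip(axes.flat, strata):
        study, dose, otype = key
        sub = bands[(bands["STUDY"] == study) & (bands["DOSE"] == dose)
                    & (bands["TYPE"] == otype)].sort_values("TIME")
        ax.fill_between(sub["TIME"], sub["p5"], sub["p95"], alpha=0.3,
                        label="90% PI")
        ax.plot(sub["TIME"], sub["median"], "-", label="median")
        if observed is not None:
            obs = observed[(observed["STUDY"] == study)
                           & (observed["DOSE"] == dose)
                           & (observed["TYPE"] == otype)]
            ax.plot(obs["TIME"], obs["DV"], "k.", ms=4, label="observed")
        if otype.startswith("conc"):
            ax.set_yscale("log")
        ax.set_title(f"study {study}, {dose} mg/kg, {otype}", fontsize=9)
        ax.set_xlabel("time (h)")
    for ax in axes.flat[n:]:
        ax.set_visible(False)
    axes.flat[0].legend(fontsize=7, frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
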