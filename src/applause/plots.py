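"""Optional matplotlib renderings of the standard outputs."""

from __future__ import annotations

from pathlib import Path

import numpy as np


def _axes():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_sir_curves(curves, path: str | Path) -> Path:
    """Median started/stopped/currently-clapping fractions with IQR bands."""
    plt = _axes()
    fig, ax = plt.subplots(figsize=(6, 4))
    for name, colour in [("started", "k"), ("stopped", "r"), ("current", "g")]:
        ax.plot(curves["t"], curves[f"{name}_median"], colour, label=name)
        ax.fill_between(
            curves["t"], curves[f"{name}_q25"], curves[f"{name}_q75"],
            color=colour, alpha=0.2, linewidth=0,
        )
    ax.set_xlabel("time since first clap (s)")
    ax.set_ylabel("proportion of audience")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_claps_distribution(dist: dict, path: str | Path) -> Path:
    """Histogram of per-run mean claps with the matched-Poisson overlay."""
    plt = _axes()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(dist["bin_centers"], dist["proportions"], width=0.9, color="0.6",
           label="simulation")
    ax.plot(dist["bin_centers"], dist["poisson_pmf"], "k--", label="matched Poisson")
    if "observed" in dist:
        ax.plot(dist["observed"], np.zeros_like(dist["observed"]), "k*",
                markersize=10, label="observed bouts")
    ax.set_xlabel("mean claps per individual")
    ax.set_ylabel("proportion of runs")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_phase_plane(pp: dict, trajectory, path: str | Path) -> Path:
    """(S, I) vector field, the dI/dt = 0 locus, and one trajectory."""
    plt = _axes()
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.quiver(pp["S"], pp["I"], pp["dS"], pp["dI"], angles="xy", width=0.002,
              color="0.5")
    ax.plot(pp["locus_S"], pp["locus_I"], "b:", label="dI/dt = 0")
    if trajectory is not None:
        ax.plot(trajectory["S"], trajectory["I"], "r-", label="trajectory")
    ax.set_xlabel("S")
    ax.set_ylabel("I")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
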