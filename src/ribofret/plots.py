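"""Figure helpers: FRET histogram with mixture components, TODP heat map,
and example trace panels.  All functions write to a file and never require
a display."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .io import Trace
from .stats import TODP, GaussianMixtureFit

__all__ = ["plot_histogram_with_mixture", "plot_todp", "plot_trace"]


def plot_histogram_with_mixture(
    histogram: tuple[np.ndarray, np.ndarray],
    mixture: GaussianMixtureFit,
    path: str | Path,
) -> None:
    """Pooled idealized-E histogram with the fitted Gaussian components."""
    counts, edges = histogram
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.bar(centers, counts / counts.sum() / width, width=width, color="0.8",
           edgecolor="0.5", label="idealized E")
    x = np.linspace(0, 1, 400)
    colors = ["tab:blue", "tab:green", "tab:red"]
    for w, m, s, c in zip(mixture.weights, mixture.means, mixture.sigmas, colors):
        pdf = w * np.exp(-0.5 * ((x - m) / s) ** 2) / (s * np.sqrt(2 * np.pi))
        ax.plot(x, pdf, color=c, label=f"E~{m:.2f}: {100 * w:.1f}%")
    ax.set_xlabel("FRET efficiency")
    ax.set_ylabel("probability density")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_todp(todp: TODP, path: str | Path) -> None:
    """Transition occupancy density plot as a heat map.

    Off-diagonal mass shows dynamic molecules (initial vs final E of
    at-least-once transitions); diagonal mass shows static molecules.
    """
    fig, ax = plt.subplots(figsize=(4.2, 3.8))
    im = ax.imshow(
        todp.matrix.T,
        origin="lower",
        extent=(0, 1, 0, 1),
        cmap="viridis",
        aspect="equal",
    )
    ax.plot([0, 1], [0, 1], color="w", lw=0.5, alpha=0.5)
    ax.set_xlabel("initial FRET efficiency")
    ax.set_ylabel("final FRET efficiency")
    fig.colorbar(im, ax=ax, label="fraction of molecules")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_trace(trace: Trace, path: str | Path, idealized: np.ndarray | None = None) -> None:
    """Two-panel figure: channel intensities and the FRET efficiency."""
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(7, 4), sharex=True)
    ax1.plot(trace.time, trace.donor, color="tab:green", lw=0.7, label="donor")
    ax1.plot(trace.time, trace.acceptor, color="tab:red", lw=0.7, label="acceptor")
    ax1.set_ylabel("counts")
    ax1.legend(fontsize=8, loc="upper right")
    total = trace.total
    with np.errstate(invalid="ignore", divide="ignore"):
        e = np.where(total > 0, trace.acceptor / total, np.nan)
    ax2.plot(trace.time, e, color="k", lw=0.7, label="E")
    if idealized is not None:
        ax2.plot(trace.time[: len(idealized)], idealized, color="tab:blue", lw=1.2,
                 label="HMM fit")
    ax2.set_ylim(-0.2, 1.2)
    ax2.set_xlabel("time (s)")
    ax2.set_ylabel("FRET efficiency")
    ax2.legend(fontsize=8, loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
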