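"""Optional matplotlib figures: WAVR histograms with fits, group profiles."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .quality import NormalFit
from .stats import GroupSummary


def plot_wavr_histogram(
    values: np.ndarray,
    fits: list[tuple[str, NormalFit]] | None = None,
    cutoff: float | None = None,
    out_path: str | Path | None = None,
):
    """Histogram of WAVR values with optional per-class normal fits."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(values, bins="fd", color="0.7", edgecolor="0.4")
    if fits:
        x = np.linspace(float(np.min(values)), float(np.max(values)), 300)
        for label, fit in fits:
            ax.plot(x, fit.density(x), label=label)
        ax.legend()
    if cutoff is not None:
        ax.axvline(cutoff, color="k", linestyle="--")
    ax.set_xlabel("WAVR")
    ax.set_ylabel("count")
    fig.tight_layout()
    if out_path:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig


def plot_group_profiles(summaries: list[GroupSummary], out_path: str | Path | None = None):
    """Mean radial profile per group, center (r=0) to periphery (r=1)."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 3.5))
    for s in summaries:
        n = len(s.mean_profile)
        r = (np.arange(1, n + 1) - 0.5) / n
        ax1.plot(r, s.mean_profile, marker="o", label=s.group)
    ax1.axhline(1.0, color="0.6", linestyle=":")
    ax1.set_xlabel("normalized radius")
    ax1.set_ylabel("normalized intensity")
    ax1.legend()
    labels = [s.group for s in summaries]
    ax2.bar(labels, [s.mean_rp for s in summaries], yerr=[s.sem_rp for s in summaries], color="0.7")
    ax2.set_ylabel("RP index (mean ± SEM)")
    fig.tight_layout()
    if out_path:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig
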