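"""Figures for the pointwise comparisons: condition-mean traces with SEM
ribbons and a significance raster, one panel pair per channel."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .types import EpochMatrix, PointwiseTestResult, SuppressionInterval


def plot_comparison(a: EpochMatrix, b: EpochMatrix,
                    result: PointwiseTestResult,
                    interval: SuppressionInterval | None = None,
                    out_path: str | Path | None = None):
    """Mean +/- SEM traces of both conditions over the epoch, the stop signal
    at time 0, FDR-significant time points as a raster underneath and the
    qualified interval shaded."""
    fig, (ax, axr) = plt.subplots(
        2, 1, sharex=True, figsize=(7, 5),
        gridspec_kw={"height_ratios": [4, 1]})
    for m, color in ((a, "tab:blue"), (b, "tab:red")):
        mean = m.values.mean(axis=0)
        sem = m.values.std(axis=0, ddof=1) / np.sqrt(m.n_participants)
        ax.plot(m.times, mean, color=color, label=m.condition)
        ax.fill_between(m.times, mean - sem, mean + sem, color=color,
                        alpha=0.25, linewidth=0)
    ax.axvline(0.0, color="k", linestyle="--", linewidth=0.8)
    if interval is not None:
        ax.axvspan(interval.onset, interval.offset, color="gray", alpha=0.2)
    ax.set_ylabel(f"{a.channel} EMG (z)")
    ax.legend(frameon=False)

    sig_times = result.times[result.fdr_mask]
    axr.vlines(sig_times, 0, 1, color="k", linewidth=0.5)
    axr.set_ylim(0, 1)
    axr.set_yticks([])
    axr.set_xlabel("time relative to stop signal (ms)")
    axr.set_ylabel("FDR sig.")
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig
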