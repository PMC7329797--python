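"""Basic diagnostic figures: VPC bands and PTA curves.

Thin matplotlib wrappers; styling is deliberately plain.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .diagnostics import VPCResult
from .pta import PTAResult

__all__ = ["plot_vpc", "plot_pta"]


def plot_vpc(result: VPCResult, ax=None, path=None):
    """Observed percentiles over the simulated 90% confidence bands."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    t = result.bin_times
    labels = ("5th", "median", "95th")
    for i, lab in enumerate(labels):
        ax.fill_between(t, result.band_lo[i], result.band_hi[i], alpha=0.25,
                        label=f"simulated band ({lab})")
        ax.plot(t, result.observed[i], "o-", lw=1.2, ms=4, label=f"observed {lab}")
    ax.set_xlabel("time after dose (h)")
    ax.set_ylabel("concentration (mg/l)")
    ax.legend(fontsize=7)
    if path:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
    return ax


def plot_pta(result: PTAResult, ax=None, path=None, level: float = 90.0):
    """PTA versus MIC on a log2 axis, with uncertainty band when present."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    x = np.log2(result.mic_grid)
    if result.lo is not None and result.hi is not None:
        ax.fill_between(x, result.lo, result.hi, alpha=0.3, label="90% CI")
    ax.plot(x, result.pta, "o-", label=f"PTA ({100 * result.target_fraction:.0f}%T>MIC)")
    ax.axhline(level, color="k", lw=0.8, ls="--")
    ax.set_xticks(x[::2])
    ax.set_xticklabels([f"{m:g}" for m in result.mic_grid[::2]], fontsize=7)
    ax.set_xlabel("MIC (mg/l)")
    ax.set_ylabel("PTA (%)")
    ax.set_ylim(0, 102)
    ax.legend(fontsize=8)
    if path:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
    return ax
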