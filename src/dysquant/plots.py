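"""Optional matplotlib views of section summaries: ECDF curves and
coverage-bin profiles."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from dysquant.fiberquant import BIN_NAMES
from dysquant.summarize import SectionSummary

BIN_LABELS = ("0-25%", "25-50%", "50-75%", "75-100%")


def plot_ecdfs(summaries, labels, metric="intensity", ax=None):
    """Overlay per-section ECDFs of intensity or coverage."""
    if ax is None:
        _, ax = plt.subplots()
    for summary, label in zip(summaries, labels):
        xs, fr = (
            summary.ecdf_intensity if metric == "intensity" else summary.ecdf_coverage
        )
        ax.step(xs, fr, where="post", label=label)
    ax.set_xlabel("mean intensity (AU)" if metric == "intensity" else "coverage (%)")
    ax.set_ylabel("cumulative fraction")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize="small")
    return ax


def plot_bin_profile(summary: SectionSummary, ax=None):
    """Bar chart of coverage-bin fractions with per-bin mean intensity."""
    if ax is None:
        _, ax = plt.subplots()
    fracs = 100 * summary.bin_fractions
    bars = ax.bar(BIN_LABELS, fracs, color="tab:blue")
    for bar, mean in zip(bars, summary.bin_mean_intensity):
        if mean == mean:  # skip NaN (empty bin)
            ax.annotate(
                f"{mean:.0f} AU",
                (bar.get_x() + bar.get_width() / 2, bar.get_height()),
                ha="center",
                va="bottom",
                fontsize="x-small",
            )
    ax.set_ylabel("% of fibers")
    ax.set_xlabel("sarcolemmal coverage bin")
    return ax
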