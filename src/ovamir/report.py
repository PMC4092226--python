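"""Plotting helpers (kept deliberately minimal)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402


def plot_length_histogram(reads_hist: dict[int, int],
                          unique_hist: dict[int, int], path) -> None:
    """Two-panel bar plot of the small-RNA length distribution
    (total reads and unique tags), the standard library QC figure."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.2), sharex=True)
    for ax, hist, title in ((axes[0], reads_hist, "total reads"),
                            (axes[1], unique_hist, "unique tags")):
        ax.bar(list(hist), list(hist.values()), color="#3b6ea5")
        ax.set_xlabel("length (nt)")
        ax.set_title(title)
    axes[0].set_ylabel("count")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
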