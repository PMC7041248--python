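"""Optional QC plots (matplotlib, Agg backend)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_purity_scatter(calls: pd.DataFrame, path) -> None:
    """Barnyard scatter: per-well species-a fraction by plate column parity."""
    fig, ax = plt.subplots(figsize=(5, 4))
    parity = (calls["row"] + calls["col"]) % 2
    for p, marker in ((0, "o"), (1, "s")):
        sub = calls[parity == p]
        ax.scatter(sub.index.map(lambda _: p) + 0.05 * (sub["frac_a"] - 0.5),
                   sub["frac_a"], s=8, alpha=0.5, marker=marker,
                   label=f"(row+col) % 2 == {p}")
    ax.set_ylabel("fraction species A transcripts")
    ax.set_xlabel("planned parity")
    ax.set_xticks([0, 1])
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_beads_histogram(hist: pd.Series, path) -> None:
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar(hist.index.astype(int), hist.to_numpy())
    ax.set_xlabel("beads recovered per well")
    ax.set_ylabel("wells")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_window_series(series: pd.DataFrame, path, value_columns=None) -> None:
    """Sliding-window state fractions (or moving averages) along the ordering."""
    fig, ax = plt.subplots(figsize=(5, 3))
    cols = value_columns or [c for c in series.columns if c != "window_center"]
    x = series["window_center"] if "window_center" in series else series.index
    for c in cols:
        ax.plot(x, series[c], label=str(c))
    ax.set_xlabel("window center (order key)")
    ax.set_ylabel("fraction / mean")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
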