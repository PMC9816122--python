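"""Minimal ratio-spectrum figure."""

from __future__ import annotations

import numpy as np

from .motifs import CLASS_LABELS

__all__ = ["plot_ratio_spectrum"]


def plot_ratio_spectrum(ratio, surrogate_ratios=None, ax=None):
    """Bar plot of M/E_c - 1 per motif class, optional surrogate boxes.

    ``ratio`` is the 14-vector of constituent-controlled ratios;
    ``surrogate_ratios`` an optional (n_surrogates, 14) array drawn as
    box-and-whisker plots behind the bars.  Returns the axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    x = np.arange(len(CLASS_LABELS))
    if surrogate_ratios is not None:
        ax.boxplot(
            np.asarray(surrogate_ratios),
            positions=x,
            whis=(0, 100),
            medianprops={"color": "tab:blue"},
        )
    ax.bar(x, np.asarray(ratio), color="tab:red", alpha=0.6, zorder=3)
    ax.axhline(0.0, color="black", lw=0.8)
    ax.set_xticks(x, CLASS_LABELS)
    ax.set_xlabel("motif class")
    ax.set_ylabel(r"$M/E_c - 1$")
    return ax
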