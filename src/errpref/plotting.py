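"""Figure helpers: criteria maps, grand-average ErrP traces, transfer bars."""

from __future__ import annotations

import numpy as np

from .criteria import CriteriaMap, TransferResults

__all__ = ["plot_criteria_map", "plot_grand_average", "plot_transfer"]


def plot_criteria_map(cmap: CriteriaMap, ax=None, boundary=None, **imshow_kw):
    """Heatmap of a criteria map over (efficiency, comfort); empty cells blank.

    ``boundary`` may be a fitted :class:`~errpref.criteria.CriteriaResults`
    whose decision boundary is drawn as a dashed line.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    extent = [cmap.eff_edges[0], cmap.eff_edges[-1],
              cmap.comfort_edges[0], cmap.comfort_edges[-1]]
    im = ax.imshow(np.ma.masked_invalid(cmap.values).T, origin="lower",
                   extent=extent, aspect="auto", vmin=0, vmax=1,
                   cmap=imshow_kw.pop("cmap", "RdBu_r"), **imshow_kw)
    if boundary is not None:
        b, we, wc = boundary.params
        e = np.linspace(extent[0], extent[1], 100)
        c = -(b + we * e) / wc
        ax.plot(e, c, "k--")
        ax.set_ylim(extent[2], extent[3])
    ax.set_xlabel("energy efficiency (path length)")
    ax.set_ylabel("comfort (min. clearance)")
    return im


def plot_grand_average(data, labels, times, ch_index, ax=None):
    """Erroneous-minus-correct grand averages at one channel."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    labels = np.asarray(labels, dtype=bool)
    ax.plot(times, data[labels, ch_index].mean(axis=0), label="erroneous")
    ax.plot(times, data[~labels, ch_index].mean(axis=0), label="correct")
    ax.axvline(0.0, color="k", lw=0.5)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("amplitude (uV)")
    ax.legend()
    return ax


def plot_transfer(results: TransferResults, ax=None):
    """Bar chart of the 2x2 transfer accuracies with SEM error bars."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    cells = [(s, c) for s in results.table.columns.levels[0]
             for c in ("intra", "inter")]
    means = [results.cell_mean(*cell) for cell in cells]
    sems = [results.cell_sem(*cell) for cell in cells]
    x = np.arange(len(cells))
    ax.bar(x, means, yerr=sems, capsize=3)
    ax.set_xticks(x, [f"{s}\n{c}" for s, c in cells])
    ax.set_ylabel("accuracy (%)")
    return ax
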