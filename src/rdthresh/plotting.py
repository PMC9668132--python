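"""Diagnostic figure: binned outcome means, fitted curves, thresholds."""

from __future__ import annotations

import warnings

import numpy as np

from ._exceptions import ExtrapolationWarning
from .data import RDDataset
from .llr import effect_curve, fit_both_sides


def plot_policy(data: RDDataset, report: dict, path: str) -> None:
    """Scatter of binned means (sized by count) with the one-sided fits and
    vertical lines at the current, optimal, and conservative thresholds."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    h = report["bandwidth"]
    c = report["threshold"]
    bw = report["defaults_used"]["bin_width"]
    edges = np.arange(data.x.min(), data.x.max() + bw, bw)
    idx = np.clip(np.digitize(data.x, edges) - 1, 0, len(edges) - 2)
    mids, means, counts = [], [], []
    for i in range(len(edges) - 1):
        sel = idx == i
        if sel.any():
            mids.append(0.5 * (edges[i] + edges[i + 1]))
            means.append(float(data.y[sel].mean()))
            counts.append(int(sel.sum()))
    fig, ax = plt.subplots(figsize=(7, 4.5))
    sizes = 8 + 80 * np.asarray(counts) / max(counts)
    ax.scatter(mids, means, s=sizes, alpha=0.6, label="binned means")

    below, above = fit_both_sides(data, h)
    for fitted, lo, hi in ((below, c - h, c), (above, c, c + h)):
        grid = np.linspace(lo, hi, 50)
        ax.plot(grid, fitted.predict(grid), lw=2)
    curve = effect_curve(below, above, h)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ExtrapolationWarning)
        grid = np.linspace(c - h, c + h, 100)
        ax.plot(grid, curve.value(grid), "--", lw=1, label="effect curve")

    policy = report["policy"]
    ax.axvline(c, color="k", lw=1, label=f"current c = {c:g}")
    ax.axvline(policy["c_star"], color="tab:green", lw=1.5,
               label=f"optimal = {policy['c_star']:.3g}")
    if policy["c_alpha"] is not None:
        ax.axvline(policy["c_alpha"], color="tab:orange", lw=1.5,
                   label=f"conservative = {policy['c_alpha']:.3g}")
    ax.set_xlabel("running variable")
    ax.set_ylabel("outcome")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
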