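"""Diagnostic plots: per-screen fitness comparison and two-screen GIS grid.

Both plot functions return ``(figure, layers)`` where ``layers`` is a plain
dict of the arrays actually drawn, so tests can assert on the data layers
(point counts, classifications, line parameters) without rasterising
anything.  Input records are never mutated.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .gis import Q_THRESHOLD, STRONG_THRESHOLD, fit_comparison_regression

_SUPPRESSOR_COLOR = "#cc2222"
_ENHANCER_COLOR = "#22aa22"
_NEUTRAL_COLOR = "#888888"


def fitness_plot(records: pd.DataFrame, path: str | Path | None = None,
                 q_threshold: float = Q_THRESHOLD):
    """Scatter of per-gene mean query fitness against control fitness.

    ``records`` is a GIS table (normalised scale): control mean = ``mu``,
    query mean = ``mu + gis``.  The dashed grey identity is the line of
    equal growth; the solid grey OLS line is the expected query fitness
    given control fitness.  Suppressors are red, enhancers green; markers
    are open when p < 0.05 only and filled when q < ``q_threshold``.
    """
    if records.empty:
        raise ValueError("no records to plot")
    x = records["mu"].to_numpy(float)
    y = (records["mu"] + records["gis"]).to_numpy(float)
    slope, intercept = fit_comparison_regression(x, y)

    colors = np.where(records["classification"] == "suppressor", _SUPPRESSOR_COLOR,
                      np.where(records["classification"] == "enhancer",
                               _ENHANCER_COLOR, _NEUTRAL_COLOR))
    filled = (records["q"] < q_threshold).to_numpy()
    open_only = (records["p"] < 0.05).to_numpy() & ~filled

    fig, ax = plt.subplots(figsize=(6, 6))
    lim = max(x.max(), y.max()) * 1.05
    ax.plot([0, lim], [0, lim], ls="--", color="grey", lw=1,
            label="equal growth")
    xs = np.array([0, lim])
    ax.plot(xs, intercept + slope * xs, color="grey", lw=1.5,
            label="expected fitness")
    ax.scatter(x[~filled & ~open_only], y[~filled & ~open_only], s=8,
               c=colors[~filled & ~open_only], alpha=0.4)
    ax.scatter(x[open_only], y[open_only], s=16, facecolors="none",
               edgecolors=colors[open_only])
    ax.scatter(x[filled], y[filled], s=16, c=colors[filled])
    ax.set_xlabel("control normalised fitness")
    ax.set_ylabel("query normalised fitness")
    ax.legend(frameon=False)
    if path is not None:
        fig.savefig(path, dpi=150)
    layers = {"x": x, "y": y, "colors": colors, "filled": filled,
              "open": open_only, "slope": slope, "intercept": intercept}
    return fig, layers


def gis_comparison_plot(records_a: pd.DataFrame, records_b: pd.DataFrame,
                        path: str | Path | None = None,
                        q_threshold: float = Q_THRESHOLD,
                        strong_threshold: float = STRONG_THRESHOLD,
                        groups: pd.DataFrame | None = None):
    """Scatter of GIS in screen A (y) against screen B (x).

    Only genes significant (q < threshold) in either screen are drawn, as in
    the published comparison plot; the dashed rectangle marks the arbitrary
    +/- ``strong_threshold`` effect-size cutoff.  ``groups`` may supply an
    (orf, group) annotation used to colour selected gene sets.
    """
    a = records_a.set_index("orf")
    b = records_b.set_index("orf")
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("GIS tables share no ORFs")
    a, b = a.loc[shared], b.loc[shared]
    sig = (a["q"] < q_threshold) | (b["q"] < q_threshold)
    ga = a.loc[sig, "gis"].to_numpy(float)
    gb = b.loc[sig, "gis"].to_numpy(float)
    both = ((a["q"] < q_threshold) & (b["q"] < q_threshold))[sig].to_numpy()

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.scatter(gb[~both], ga[~both], s=14, c="white", edgecolors="black")
    ax.scatter(gb[both], ga[both], s=14, facecolors="none", edgecolors="black")
    t = strong_threshold
    ax.plot([-t, t, t, -t, -t], [-t, -t, t, t, -t], ls="--", color="black", lw=1)
    if groups is not None:
        g = groups.set_index("orf")["group"]
        orfs = a.index[sig]
        for grp, color in zip(sorted(g.unique()), plt.cm.tab10.colors):
            mask = np.array([g.get(o) == grp for o in orfs])
            if mask.any():
                ax.scatter(gb[mask], ga[mask], s=20, color=color, label=str(grp))
        ax.legend(frameon=False, fontsize=7)
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("GIS (screen B)")
    ax.set_ylabel("GIS (screen A)")
    if path is not None:
        fig.savefig(path, dpi=150)
    layers = {"gis_a": ga, "gis_b": gb, "both_significant": both,
              "rectangle": t, "orfs": list(a.index[sig])}
    return fig, layers
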