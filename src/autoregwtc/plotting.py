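"""Cosmetic heatmap rendering of a coherence field."""

from __future__ import annotations

import numpy as np

from .significance import SignificanceMap
from .wavelet import WTCField


def plot_wtc(field: WTCField, sig: SignificanceMap | None = None, ax=None):
    """Heatmap of squared coherence over time and period.

    Shades the cone of influence, and outlines significant regions when a
    significance map is supplied.  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4))
    t = field.times
    per = field.periods
    mesh = ax.pcolormesh(t, per, field.r2.T, vmin=0.0, vmax=1.0, cmap="jet", shading="auto")
    if sig is not None:
        ax.contour(t, per, sig.sig_mask.T.astype(float), levels=[0.5], colors="k", linewidths=1.0)
    ax.plot(t, field.coi, "w--", linewidth=1.0)
    ax.fill_between(t, field.coi, per.max(), color="white", alpha=0.4)
    ax.set_yscale("log", base=2)
    ax.set_ylim(per.min(), per.max())
    ax.invert_yaxis()
    ax.set_xlabel("time (min)")
    ax.set_ylabel("period (min)")
    plt.colorbar(mesh, ax=ax, label="$R^2$")
    return ax
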