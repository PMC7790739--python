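"""Figure helpers: profile lines with dispersion bands and velocity
box-whisker plots along the crypt axis."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .observables import Profile

__all__ = ["plot_profile", "plot_velocity_whiskers"]


def plot_profile(profile: Profile, ax=None, label: str | None = None,
                 color=None, ylabel: str = ""):
    """Line + shaded dispersion band against crypt height fraction."""
    if ax is None:
        _, ax = plt.subplots()
    x = profile.centers
    line, = ax.plot(x, profile.value, label=label, color=color)
    ax.fill_between(x, profile.lower, profile.upper, alpha=0.25,
                    color=line.get_color(), linewidth=0)
    ax.set_xlabel("height (fraction of crypt)")
    if ylabel:
        ax.set_ylabel(ylabel)
    if label:
        ax.legend()
    return ax


def plot_velocity_whiskers(profile: Profile, ax=None, color="C0"):
    """Box (quartiles) and whisker (extremes) plot of cell speeds."""
    if ax is None:
        _, ax = plt.subplots()
    width = 0.6 * (profile.edges[1] - profile.edges[0])
    for c, med, q1, q3, lo, hi, n in zip(profile.centers, profile.value,
                                         profile.lower, profile.upper,
                                         profile.vmin, profile.vmax,
                                         profile.n):
        if n == 0 or np.isnan(med):
            continue
        ax.add_patch(plt.Rectangle((c - width / 2, q1), width, q3 - q1,
                                   fill=False, edgecolor=color))
        ax.plot([c - width / 2, c + width / 2], [med, med], color=color)
        ax.plot([c, c], [q3, hi], color=color, linewidth=0.8)
        ax.plot([c, c], [lo, q1], color=color, linewidth=0.8)
    ax.set_xlabel("height (fraction of crypt)")
    ax.set_ylabel("cell speed (diameters/h)")
    ax.autoscale_view()
    return ax
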