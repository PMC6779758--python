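"""Minimal matplotlib plots mirroring the standard figure styles:
mean-with-SEM-stripe curves and traversal-count profiles with the zone
boundary marked."""

from __future__ import annotations

import numpy as np


def plot_curve(curve, ax=None, label=None, color=None):
    """Mean curve with an SEM stripe (displacement, speed or length curves)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = curve.grid if hasattr(curve, "grid") else curve.lengths
    line, = ax.plot(x, curve.mean, label=label, color=color)
    ax.fill_between(x, curve.mean - curve.sem, curve.mean + curve.sem,
                    alpha=0.3, color=line.get_color(), linewidth=0)
    return ax


def plot_profile(profile, ax=None):
    """Traversal counts vs. radius; aggregate interior shaded, boundary marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    outside = ~profile.aggregate_mask
    ax.plot(profile.radii[outside], profile.counts[outside], "o-")
    ax.axvspan(0, profile.aggregate_radius, alpha=0.2, color="green")
    ax.axvline(profile.boundary_radius, linestyle="--", color="k")
    ax.set_xlabel("radius (µm)")
    ax.set_ylabel("sprout traversals")
    ax.set_ylim(bottom=0)
    return ax


def show_cylinder_maps(maps, ax=None):
    """Rolled-out cylinder surfaces side by side, ordered by perimeter."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    offset = 0
    for m in maps:
        rows, cols = np.nonzero(m.surface)
        ax.plot(cols + offset, rows, ",k")
        offset += m.n_theta + 10
    ax.set_xlabel("arc samples (cylinders side by side)")
    ax.set_ylabel("z slice")
    return ax
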