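"""Minimal matplotlib scatter rendering of labelled clouds."""

from __future__ import annotations

import numpy as np

from .cloud import CLASS_NAMES, LabeledPointCloud

_COLORS = {0: "tab:red", 1: "tab:green", 2: "tab:brown"}


def plot_cloud(cloud: LabeledPointCloud, path=None, title: str = "",
               point_size: float = 2.0):
    """3-D scatter of a (labelled) cloud; saves to ``path`` if given,
    otherwise returns the matplotlib figure."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(6, 6))
    ax = fig.add_subplot(projection="3d")
    if cloud.has_labels:
        for c, name in enumerate(CLASS_NAMES):
            sel = cloud.labels == c
            if sel.any():
                ax.scatter(*cloud.coords[sel].T, s=point_size,
                           c=_COLORS[c], label=name)
        ax.legend(loc="upper right")
    else:
        ax.scatter(*cloud.coords.T, s=point_size, c="gray")
    ax.set_title(title)
    ax.set_box_aspect(np.ptp(cloud.coords, axis=0) + 1e-9)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig
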