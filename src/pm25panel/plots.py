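"""Rendering helpers for the reporting stage.

Thin matplotlib wrappers around the data objects the analysis modules
already produce: the Kuznets scatter with polynomial fits and cluster
ellipses (mortality axis inverted, as usual for bad health outcomes) and
the sundew plot comparing two competing predictions observation by
observation.  All plot data stays available as arrays/DataFrames; these
functions only draw.
"""

from __future__ import annotations

import numpy as np

from .kuznets import ClusterEllipse, KuznetsCurve, sundew_plot_data

__all__ = ["plot_kuznets", "plot_sundew"]


def plot_kuznets(
    curve: KuznetsCurve,
    labels=None,
    ellipses: list[ClusterEllipse] | None = None,
    title: str = "Environmental Kuznets curve",
    path=None,
):
    """Scatter + degree-1..4 fits + average curve (+ cluster ellipses)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse as MplEllipse

    fig, ax = plt.subplots(figsize=(7, 5))
    if labels is None:
        ax.scatter(curve.x, curve.y, c="k", s=25, zorder=3)
    else:
        ax.scatter(curve.x, curve.y, c=np.asarray(labels), cmap="tab10",
                   s=25, zorder=3)
    for d, style in ((1, ":"), (2, "--"), (3, "-."), (4, ":")):
        ax.plot(curve.grid, np.polyval(curve.fits[d], curve.grid),
                style, lw=0.8, alpha=0.6, label=f"degree {d}")
    ax.plot(curve.grid, curve.average_curve, "r-", lw=1.8,
            label="mean of degrees 2-4")
    for ell in ellipses or []:
        ax.add_patch(MplEllipse(
            ell.center, 2 * ell.axes[0], 2 * ell.axes[1],
            angle=np.degrees(ell.tilt), fill=False, ls="--", lw=0.8,
        ))
    ax.invert_yaxis()  # higher mortality plots lower
    ax.set_xlabel("composite index (z)")
    ax.set_ylabel("PM2.5 mortality (z, inverted)")
    ax.set_title(title)
    ax.legend(fontsize=8)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_sundew(obs, pred_a, pred_b, names=("model A", "model B"), path=None):
    """Two competing predictions with per-observation error tentacles."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = sundew_plot_data(obs, pred_a, pred_b)
    order = np.argsort(data["obs"].to_numpy())
    x = np.arange(len(order))
    fig, ax = plt.subplots(figsize=(8, 5))
    o = data["obs"].to_numpy()[order]
    a = data["pred_a"].to_numpy()[order]
    b = data["pred_b"].to_numpy()[order]
    ax.plot(x, o, "k-", lw=1.2, label="observed")
    ax.vlines(x, np.minimum(o, a), np.maximum(o, a), colors="tab:blue",
              lw=0.6, alpha=0.6)
    ax.vlines(x, np.minimum(o, b), np.maximum(o, b), colors="tab:orange",
              lw=0.6, alpha=0.6)
    ax.scatter(x, a, s=6, c="tab:blue", label=names[0])
    ax.scatter(x, b, s=6, c="tab:orange", label=names[1])
    ax.set_xlabel("observations (sorted by observed value)")
    ax.set_ylabel("mortality (z)")
    ax.set_title("Sundew comparison of competing predictions")
    ax.legend(fontsize=8)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
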