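"""Thin plotting layer: score scatters with group ellipses and extreme-shape glyphs.

Figures are side outputs only; no analysis reads them back.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from . import shape_space as ss


def score_plot(
    space,
    pcs=(0, 1),
    groups=None,
    level: float = 0.95,
    path=None,
    extreme_glyphs: bool = True,
):
    """Scatter of two PC scores with per-group data ellipses.

    ``groups`` maps specimen_id -> label; extreme shapes of each axis are
    drawn as small glyphs at the axis ends.
    """
    i, j = pcs
    fig, ax = plt.subplots(figsize=(7, 6))
    xy = space.scores.iloc[:, [i, j]]
    if groups is None:
        ax.scatter(xy.iloc[:, 0], xy.iloc[:, 1], s=12, alpha=0.6)
    else:
        labels = np.array([groups.get(sid, "other") for sid in xy.index])
        for lab in np.unique(labels):
            sel = labels == lab
            ax.scatter(xy.iloc[sel, 0], xy.iloc[sel, 1], s=12, alpha=0.6, label=lab)
            if sel.sum() >= 3:
                try:
                    ell = ss.confidence_ellipse(
                        xy.iloc[sel].to_numpy(), level=level, group=str(lab)
                    )
                    poly = ell.polygon()
                    ax.plot(poly[:, 0], poly[:, 1], lw=1)
                except Exception:  # degenerate group: skip its ellipse
                    pass
        ax.legend(fontsize=8)
    if extreme_glyphs:
        for comp, place in ((i, "x"), (j, "y")):
            lo, hi = ss.extreme_shape(space, comp, n_points=128)
            for shape, sign in ((lo, -1), (hi, 1)):
                pts = shape.points
                scale = 0.12 * (
                    xy.iloc[:, 0].max() - xy.iloc[:, 0].min() + 1e-12
                ) / (np.ptp(pts[:, 0]) + 1e-12)
                pts = pts * scale
                if place == "x":
                    offset = (sign * xy.iloc[:, 0].abs().max(), xy.iloc[:, 1].min())
                else:
                    offset = (xy.iloc[:, 0].min(), sign * xy.iloc[:, 1].abs().max())
                ax.plot(pts[:, 0] + offset[0], pts[:, 1] + offset[1], lw=0.8, color="k")
    ax.set_xlabel(f"PC{i + 1} ({space.variance_fraction[i]:.1%})")
    ax.set_ylabel(f"PC{j + 1} ({space.variance_fraction[j]:.1%})")
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
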