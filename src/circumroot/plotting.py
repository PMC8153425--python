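"""Small plotting helpers for traces and growth-response surfaces."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_tip_trace", "plot_growth_surface"]


def plot_tip_trace(result, ax=None, plane=None):
    """Tip trajectory of a run (x-z projection), magenta like the figures."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(result.tip[:, 0], result.tip[:, 2], color="magenta", lw=1.0)
    ax.plot(*result.tip[-1, [0, 2]], "k.", ms=4)
    if plane is not None:
        x = ax.get_xlim()
        z = np.asarray(plane.point)[2]
        ax.axhline(z, color="0.5", lw=2)
        ax.set_xlim(x)
    ax.set_xlabel("x (D)")
    ax.set_ylabel("z (D)")
    ax.set_aspect("equal")
    return ax


def plot_growth_surface(surfaces, ax=None):
    """Heatmap of the stimulus growth-response surface G_s over (d, phi)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    im = ax.pcolormesh(
        np.degrees(surfaces.phi_grid), surfaces.d_grid, surfaces.G_s,
        shading="auto", cmap="jet",
    )
    ax.set_xlabel("phi (deg)")
    ax.set_ylabel("d (D)")
    plt.colorbar(im, ax=ax, label="G_s (D/h)")
    return ax
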