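"""Optional rendering of curvature landscapes (matplotlib, Agg-safe).

Two-panel layout: occupancy over (s_norm, theta) next to the analytic
radius-of-curvature map on the same axes, plus a one-panel free-energy
profile over the radius of curvature.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .curvature_stats import CurvatureLandscape

__all__ = ["plot_landscape", "plot_free_energy"]


def plot_landscape(landscape: CurvatureLandscape, path: str | Path) -> Path:
    """Write the occupancy + curvature-map panels to an image file."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    extent = (
        landscape.s_edges[0],
        landscape.s_edges[-1],
        landscape.theta_edges[0],
        landscape.theta_edges[-1],
    )
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.4), sharey=True)
    im1 = ax1.imshow(
        landscape.occupancy.T, origin="lower", aspect="auto", extent=extent, cmap="viridis"
    )
    ax1.set_xlabel("$s_{norm}$")
    ax1.set_ylabel(r"$\theta$ (deg)")
    ax1.set_title("occupancy")
    fig.colorbar(im1, ax=ax1, label="counts")

    R = np.where(np.isfinite(landscape.curvature_map), landscape.curvature_map, np.nan)
    im2 = ax2.imshow(
        R.T, origin="lower", aspect="auto", extent=extent, cmap="magma",
        vmax=np.nanquantile(R, 0.95),
    )
    ax2.set_xlabel("$s_{norm}$")
    ax2.set_title("radius of curvature $R(s,\\theta)$ (nm)")
    fig.colorbar(im2, ax=ax2, label="nm")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_free_energy(landscape: CurvatureLandscape, path: str | Path) -> Path:
    """Write the F(R) profile (k_BT vs nm, log-x, finite bins) to a file."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if landscape.free_energy is None or landscape.R_edges is None:
        raise ValueError("landscape has no free-energy profile")
    centres = np.sqrt(landscape.R_edges[:-1] * landscape.R_edges[1:])
    F = landscape.free_energy[: len(centres)]
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    ax.plot(centres, F, "o-", ms=3)
    ax.set_xscale("log")
    ax.set_xlabel("radius of curvature R (nm)")
    ax.set_ylabel("F(R) ($k_BT$)")
    ax.axhline(0.0, color="0.6", lw=0.8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
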