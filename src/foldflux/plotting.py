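"""Optional diagnostic plots (cosmetic; nothing downstream depends on them)."""

from __future__ import annotations

import numpy as np

from .grids import FluxGrid2D


def plot_streamlines_over_map(
    grid: FluxGrid2D,
    background: str = "free_energy",
    levels: np.ndarray | None = None,
    ax=None,
):
    """Stream-function contours over the free-energy or vorticity map.

    Returns the matplotlib axes; requires grid.F / grid.omega / grid.psi to
    be computed beforehand.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    field = grid.F if background == "free_energy" else grid.omega
    if field is None or grid.psi is None:
        raise ValueError("compute F/omega and psi before plotting")
    extent = [
        grid.spec.origin[0],
        grid.spec.origin[0] + (grid.spec.dims[0] - 1) * grid.spec.spacing[0],
        grid.spec.origin[1],
        grid.spec.origin[1] + (grid.spec.dims[1] - 1) * grid.spec.spacing[1],
    ]
    im = ax.imshow(
        np.ma.filled(field, np.nan).T,
        origin="lower",
        extent=extent,
        aspect="auto",
        cmap="viridis" if background == "free_energy" else "RdBu_r",
    )
    if levels is None:
        levels = np.linspace(grid.psi.min(), grid.psi.max(), 9)[1:-1]
    g1 = grid.spec.axis_coords(0)
    g2 = grid.spec.axis_coords(1)
    ax.contour(g1, g2, grid.psi.T, levels=levels, colors="k", linewidths=0.7)
    ax.set_xlabel("G1 (Å)")
    ax.set_ylabel("G2 (Å)")
    plt.colorbar(
        im, ax=ax,
        label="F (kBT)" if background == "free_energy" else "ω (Å⁻² μs⁻¹)",
    )
    return ax


def plot_loglog_fit(x, y, fit, ax=None, xlabel="l (Å)", ylabel="C(l)"):
    """Log-log data with its fitted power law."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.loglog(x, y, "o", ms=4)
    xs = np.linspace(fit.fit_range[0], fit.fit_range[1], 50)
    ax.loglog(xs, np.exp(fit.log_prefactor) * xs**fit.exponent, "--",
              label=f"slope {fit.exponent:.2f}")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.legend()
    return ax
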