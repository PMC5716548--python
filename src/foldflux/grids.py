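"""Regular-grid containers for probability-flux fields.

Grid nodes sit at ``origin + i * spacing`` per axis.  The cell of node ``i``
is the half-open box ``[node - Δ/2, node + Δ/2)``; a point landing exactly on
a cell boundary belongs to the lower-index cell.  Crossing planes (3D) /
lines (2D) pass through the nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["GridSpec", "FluxGrid3D", "FluxGrid2D", "save_flux_grid", "load_flux_grid"]


@dataclass(frozen=True)
class GridSpec:
    """Origin (Å), spacing Δg (Å) and node counts per axis."""

    origin: tuple[float, ...]
    spacing: tuple[float, ...]
    dims: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.origin) == len(self.spacing) == len(self.dims)):
            raise ValueError("origin, spacing and dims must have equal length")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if any(d < 2 for d in self.dims):
            raise ValueError("need at least 2 nodes per axis")

    @property
    def ndim(self) -> int:
        return len(self.dims)

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing[axis] * np.arange(self.dims[axis])

    def to_index_units(self, points: np.ndarray) -> np.ndarray:
        """Continuous node-index coordinates u = (g - origin) / Δ."""
        return (np.asarray(points, dtype=float) - np.asarray(self.origin)) / np.asarray(
            self.spacing
        )

    def cell_index(self, points: np.ndarray) -> np.ndarray:
        """Containing-cell index; exact boundaries go to the lower-index cell."""
        u = self.to_index_units(points)
        return np.ceil(u - 0.5).astype(int)

    def contains(self, points: np.ndarray) -> np.ndarray:
        idx = self.cell_index(np.atleast_2d(points))
        dims = np.asarray(self.dims)
        return np.all((idx >= 0) & (idx < dims), axis=-1)

    @staticmethod
    def from_data(
        points: np.ndarray, spacing: float | tuple[float, ...], pad_cells: int = 1
    ) -> "GridSpec":
        """Smallest grid (integer-aligned origin) covering ``points`` plus padding."""
        points = np.asarray(points, dtype=float)
        ndim = points.shape[1]
        spacing = (
            (float(spacing),) * ndim
            if np.isscalar(spacing)
            else tuple(float(s) for s in spacing)
        )
        lo = np.floor(points.min(axis=0) / spacing) - pad_cells
        hi = np.ceil(points.max(axis=0) / spacing) + pad_cells
        dims = (hi - lo + 1).astype(int)
        return GridSpec(
            origin=tuple(lo * np.asarray(spacing)),
            spacing=spacing,
            dims=tuple(int(d) for d in dims),
        )


def _check_probability(p: np.ndarray, visits: np.ndarray) -> None:
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("probabilities must sum to 1")
    if np.any((visits == 0) & (p > 0)):
        raise ValueError("p must be 0 wherever visits = 0")


@dataclass
class FluxGrid3D:
    """3D flux field j (Å⁻² μs⁻¹ per component), visit counts and probability p."""

    spec: GridSpec
    j: np.ndarray  # (3, n1, n2, n3)
    visits: np.ndarray  # (n1, n2, n3) frame counts
    p: np.ndarray  # (n1, n2, n3), sums to 1 over visited cells
    m_trajectories: int
    mfpt: float  # t̄_f, μs

    def __post_init__(self) -> None:
        if self.spec.ndim != 3 or self.j.shape != (3, *self.spec.dims):
            raise ValueError("j must have shape (3, *dims) on a 3-axis grid")
        if not np.all(np.isfinite(self.j)):
            raise ValueError("flux components must be finite")
        _check_probability(self.p, self.visits)

    @property
    def occupied(self) -> np.ndarray:
        return self.visits > 0


@dataclass
class FluxGrid2D:
    """2D flux field J (Å⁻¹ μs⁻¹) with optional derived scalar fields.

    ``F`` is the free energy −ln p in k_BT units (masked where p = 0),
    ``omega`` the vorticity ∂J2/∂G1 − ∂J1/∂G2, ``psi`` the stream function.
    """

    spec: GridSpec
    J: np.ndarray  # (2, n1, n2)
    visits: np.ndarray
    p: np.ndarray
    m_trajectories: int
    mfpt: float
    F: np.ndarray | None = None  # masked array, k_BT
    omega: np.ndarray | None = None
    psi: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.spec.ndim != 2 or self.J.shape != (2, *self.spec.dims):
            raise ValueError("J must have shape (2, *dims) on a 2-axis grid")
        if not np.all(np.isfinite(self.J)):
            raise ValueError("flux components must be finite")
        _check_probability(self.p, self.visits)

    @property
    def occupied(self) -> np.ndarray:
        return self.visits > 0


def save_flux_grid(grid: FluxGrid3D | FluxGrid2D, path: str | Path) -> Path:
    """Portable .npz container with grid-spec metadata and units."""
    path = Path(path)
    flux = grid.j if isinstance(grid, FluxGrid3D) else grid.J
    extras = {}
    if isinstance(grid, FluxGrid2D):
        for name in ("F", "omega", "psi"):
            value = getattr(grid, name)
            if value is not None:
                extras[name] = np.ma.filled(value, np.nan)
    np.savez(
        path,
        flux=flux,
        visits=grid.visits,
        p=grid.p,
        origin=np.asarray(grid.spec.origin),
        spacing=np.asarray(grid.spec.spacing),
        dims=np.asarray(grid.spec.dims),
        m_trajectories=np.array([grid.m_trajectories]),
        mfpt=np.array([grid.mfpt]),
        units=np.array(["angstrom", "microsecond"]),
        **extras,
    )
    return path


def load_flux_grid(path: str | Path) -> FluxGrid3D | FluxGrid2D:
    with np.load(path, allow_pickle=False) as data:
        spec = GridSpec(
            origin=tuple(data["origin"]),
            spacing=tuple(data["spacing"]),
            dims=tuple(int(d) for d in data["dims"]),
        )
        common = dict(
            spec=spec,
            visits=data["visits"],
            p=data["p"],
            m_trajectories=int(data["m_trajectories"][0]),
            mfpt=float(data["mfpt"][0]),
        )
        if spec.ndim == 3:
            return FluxGrid3D(j=data["flux"], **common)
        grid = FluxGrid2D(J=data["flux"], **common)
        for name in ("F", "omega", "psi"):
            if name in data:
                arr = data[name]
                grid.__setattr__(
                    name, np.ma.masked_invalid(arr) if np.any(np.isnan(arr)) else arr
                )
        return grid


def export_nonzero_cells_csv(grid: FluxGrid3D | FluxGrid2D, path: str | Path) -> Path:
    """Tidy CSV of visited cells: node coordinates, flux components, p."""
    flux = grid.j if isinstance(grid, FluxGrid3D) else grid.J
    mask = grid.occupied | np.any(flux != 0, axis=0)
    idx = np.argwhere(mask)
    coords = np.asarray(grid.spec.origin) + idx * np.asarray(grid.spec.spacing)
    ndim = grid.spec.ndim
    cols = {f"g{k + 1}": coords[:, k] for k in range(ndim)}
    cols |= {f"j{k + 1}": flux[k][mask] for k in range(ndim)}
    cols["p"] = grid.p[mask]
    pd.DataFrame(cols).to_csv(path, index=False)
    return Path(path)
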