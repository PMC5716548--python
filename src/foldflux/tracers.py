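"""Passive tracers, streamlines and stream-tube pathway fractions.

A passive tracer follows dg/dτ = j(g) through the trilinearly interpolated
flux field (fixed-step RK4).  In 2D, streamlines are contours of the stream
function Ψ, and the flow between two contour levels C1 < C2 is the fraction
(C2 − C1)/Π of the total flow Π through a reference cross-section.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .grids import FluxGrid2D, FluxGrid3D

__all__ = [
    "OutOfDomainError",
    "TracerPath",
    "StreamTubeSet",
    "interpolate_flux",
    "integrate_tracer",
    "extract_streamlines",
    "pathway_fractions",
]


class OutOfDomainError(ValueError):
    """Point outside the grid hull; integrators use it as a stop condition."""


@dataclass
class TracerPath:
    points: np.ndarray  # (n_points, ndim), Å
    termination: str  # reached_target | left_domain | stagnated | max_steps


@dataclass
class StreamTubeSet:
    """Stream-function boundary levels and per-tube flow fractions (sum to 1)."""

    levels: np.ndarray
    fractions: np.ndarray

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if np.any(self.fractions < -1e-12):
            raise ValueError("tube fractions must be non-negative")
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError("tube fractions must sum to 1")


def interpolate_flux(grid: FluxGrid3D | FluxGrid2D, point: np.ndarray) -> np.ndarray:
    """Multilinear interpolation of the flux vector from the surrounding nodes.

    Exact for fields multilinear in g; raises :class:`OutOfDomainError`
    outside the node hull.
    """
    point = np.asarray(point, dtype=float)
    spec = grid.spec
    u = spec.to_index_units(point)
    dims = np.asarray(spec.dims)
    if np.any(u < 0) or np.any(u > dims - 1):
        raise OutOfDomainError(f"point {point} outside grid hull")
    i0 = np.minimum(np.floor(u).astype(int), dims - 2)
    frac = u - i0
    flux = grid.j if isinstance(grid, FluxGrid3D) else grid.J
    ndim = spec.ndim
    out = np.zeros(ndim)
    for corner in range(2**ndim):
        offsets = [(corner >> ax) & 1 for ax in range(ndim)]
        weight = np.prod(
            [frac[ax] if o else 1.0 - frac[ax] for ax, o in enumerate(offsets)]
        )
        if weight == 0.0:
            continue
        idx = tuple(i0[ax] + offsets[ax] for ax in range(ndim))
        out += weight * flux[(slice(None), *idx)]
    return out


def integrate_tracer(
    grid: FluxGrid3D | FluxGrid2D,
    start: np.ndarray,
    step: float,
    max_steps: int = 10000,
    target_region: tuple[np.ndarray, float] | None = None,
    stagnation_eps: float | None = None,
) -> TracerPath:
    """Fixed-step RK4 integration of dg/dτ = j(g).

    Stops on entering the target ball (center, radius), leaving the domain,
    |j| < stagnation_eps (default 1e-9 of the field RMS over visited cells),
    or after ``max_steps`` steps.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if stagnation_eps is None:
        flux = grid.j if isinstance(grid, FluxGrid3D) else grid.J
        occ = grid.occupied | np.any(flux != 0, axis=0)
        rms = np.sqrt(np.mean(flux[:, occ] ** 2)) if np.any(occ) else 0.0
        stagnation_eps = 1e-9 * rms if rms > 0 else 1e-30

    def in_target(point):
        if target_region is None:
            return False
        center, radius = target_region
        return float(np.linalg.norm(point - np.asarray(center))) <= radius

    g = np.asarray(start, dtype=float).copy()
    points = [g.copy()]
    termination = "max_steps"
    for _ in range(max_steps):
        if in_target(g):
            termination = "reached_target"
            break
        try:
            k1 = interpolate_flux(grid, g)
            if float(np.linalg.norm(k1)) < stagnation_eps:
                termination = "stagnated"
                break
            k2 = interpolate_flux(grid, g + 0.5 * step * k1)
            k3 = interpolate_flux(grid, g + 0.5 * step * k2)
            k4 = interpolate_flux(grid, g + step * k3)
        except OutOfDomainError:
            termination = "left_domain"
            break
        g = g + (step / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        points.append(g.copy())
    else:
        if in_target(g):
            termination = "reached_target"
    return TracerPath(np.asarray(points), termination)


def extract_streamlines(
    grid: FluxGrid2D, levels: np.ndarray
) -> dict[float, list[np.ndarray]]:
    """Marching-squares contours of Ψ at the given levels, in physical (G1, G2).

    A level outside the Ψ range yields an empty list, not an error.
    """
    if grid.psi is None:
        raise ValueError("stream function not computed; call compute_stream_function")
    origin = np.asarray(grid.spec.origin)
    spacing = np.asarray(grid.spec.spacing)
    out: dict[float, list[np.ndarray]] = {}
    for level in np.atleast_1d(levels):
        level = float(level)
        if level < grid.psi.min() or level > grid.psi.max():
            out[level] = []
            continue
        contours = measure.find_contours(grid.psi, level)
        out[level] = [origin + c * spacing for c in contours]
    return out


def pathway_fractions(
    grid: FluxGrid2D,
    boundary_levels: np.ndarray,
    section_index: int | None = None,
    normalization: str = "flow",
) -> StreamTubeSet:
    """Flow fractions of the stream tubes cut by ``boundary_levels``.

    The total flow Π is the trapezoid integral of J_G1 along the reference
    G1 = const cross-section (grid midpoint column by default).  Tubes tile
    [min Ψ, max Ψ] on that section; internal boundaries are the given sorted
    levels, and tube i carries (C_{i+1} − C_i)/Π of the flow.

    With ``normalization='flow'`` the divisor is Π itself, which equals the
    Ψ span whenever J_G1 is non-negative on the section (the stream-tube
    picture of a well-directed flow).  For noisy fields with sign-changing
    J_G1 the span exceeds Π and the strict identity cannot hold; pass
    ``normalization='span'`` to divide by Ψ_max − Ψ_min instead, which keeps
    the fractions a partition of unity by construction.
    """
    if grid.psi is None:
        raise ValueError("stream function not computed; call compute_stream_function")
    if section_index is None:
        section_index = grid.spec.dims[0] // 2
    column = grid.psi[section_index]
    total = float(np.trapezoid(grid.J[0][section_index], dx=grid.spec.spacing[1]))
    if total == 0.0:
        raise ValueError("degenerate flow: zero total flux through the cross-section")
    lo, hi = float(column.min()), float(column.max())
    if normalization == "span":
        total = hi - lo
    elif normalization != "flow":
        raise ValueError("normalization must be 'flow' or 'span'")
    inner = [lev for lev in np.sort(np.atleast_1d(boundary_levels)) if lo < lev < hi]
    levels = np.array([lo, *inner, hi])
    fractions = np.diff(levels) / total
    return StreamTubeSet(levels, fractions)
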