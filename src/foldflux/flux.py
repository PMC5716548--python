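"""Probability-flux estimation from signed plane crossings.

For each consecutive frame pair (g', g'') of every trajectory, the straight
segment between them is intersected with every node plane g_k = const it
passes.  Each crossing is assigned to the transverse elementary cell
containing the intersection point and counted with the sign of the motion
along axis k.  Component k of the flux at node g is then

    j_k(g) = (n_+ - n_-) / (M · t̄_f · ΔA)

with M the number of trajectories, t̄_f the mean first-passage time and ΔA
the transverse cell measure (Δg_a Δg_b in 3D, Δg_a in 2D).  For a complete
first-passage ensemble this bookkeeping is exactly conservative: every
separating plane carries net flow 1/t̄_f and every source/sink-free box has
zero net outflow.

Crossing conventions (declared, since sub-cell details are a free choice):
planes pass through grid nodes; a segment moving up crosses the integer
planes in (u', u''] and one moving down those in [u'', u') (index units), so
a frame sitting exactly on a plane is counted once per passage; crossings
landing exactly on a transverse cell boundary belong to the lower-index
cell; a segment lying within a plane contributes no crossing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .grids import FluxGrid2D, FluxGrid3D, GridSpec
from .trajectories import TrajectoryEnsemble

__all__ = [
    "compute_flux_3d",
    "compute_flux_2d",
    "compute_free_energy",
    "compute_vorticity",
    "compute_stream_function",
    "box_net_outflow",
    "BoxFluxResult",
]


def _segment_crossings(a: np.ndarray, b: np.ndarray):
    """Signed integer-plane crossings of 1D segments a -> b (index units).

    Returns (segment_id, plane_index, sign, s) arrays where s in [0, 1] is
    the fractional position of the crossing along the segment.
    """
    up = b > a
    down = b < a
    # planes in (a, b] going up, [b, a) going down
    n_up = np.where(up, np.floor(b) - np.floor(a), 0.0)
    n_down = np.where(down, np.ceil(a) - np.ceil(b), 0.0)
    counts = (n_up + n_down).astype(int)
    first = np.where(up, np.floor(a) + 1.0, np.ceil(b))
    total = int(counts.sum())
    if total == 0:
        empty = np.empty(0)
        return empty.astype(int), empty.astype(int), empty, empty
    seg_id = np.repeat(np.arange(len(a)), counts)
    # offset of each crossing within its segment
    starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
    offsets = np.arange(total) - np.repeat(starts, counts)
    planes = np.repeat(first, counts) + offsets
    sign = np.where(up[seg_id], 1.0, -1.0)
    s = (planes - a[seg_id]) / (b[seg_id] - a[seg_id])
    return seg_id, planes.astype(int), sign, s


def _to_lower_cell(u: np.ndarray) -> np.ndarray:
    """Half-open cell assignment [node-1/2, node+1/2); boundary -> lower cell."""
    return np.ceil(u - 0.5).astype(int)


def _accumulate_flux(ensemble: TrajectoryEnsemble, spec: GridSpec):
    """Raw signed crossing counts per component and frame counts per cell."""
    ndim = spec.ndim
    dims = spec.dims
    counts = [np.zeros(dims) for _ in range(ndim)]
    visits = np.zeros(dims)
    for traj in ensemble.trajectories:
        u = spec.to_index_units(traj.frames)  # (n_frames, ndim)
        if not np.all(np.isfinite(u)):
            raise ValueError("NaN/inf frame encountered")
        cells = _to_lower_cell(u)
        np.add.at(visits, tuple(cells.T), 1.0)
        for k in range(ndim):
            seg_id, planes, sign, s = _segment_crossings(u[:-1, k], u[1:, k])
            if len(seg_id) == 0:
                continue
            index = [None] * ndim
            index[k] = planes
            for ax in range(ndim):
                if ax == k:
                    continue
                pos = u[:-1, ax][seg_id] + s * (u[1:, ax][seg_id] - u[:-1, ax][seg_id])
                index[ax] = _to_lower_cell(pos)
            np.add.at(counts[k], tuple(index), sign)
    return counts, visits


def _check_in_grid(ensemble: TrajectoryEnsemble, spec: GridSpec, out_of_bounds: str):
    pooled = ensemble.pooled_frames()
    if not np.all(np.isfinite(pooled)):
        raise ValueError("trajectory frames contain NaN/inf")
    inside = spec.contains(pooled)
    if np.all(inside):
        return spec
    if out_of_bounds == "grow":
        return GridSpec.from_data(pooled, spec.spacing)
    raise ValueError(
        f"{int((~inside).sum())} frames fall outside the grid "
        "(pass out_of_bounds='grow' to expand it)"
    )


def _estimate(
    ensemble: TrajectoryEnsemble,
    spec: GridSpec,
    mfpt: float | None,
    out_of_bounds: str,
):
    if ensemble.n_trajectories == 0:
        raise ValueError("empty ensemble")
    spec = _check_in_grid(ensemble, spec, out_of_bounds)
    mfpt = ensemble.mfpt if mfpt is None else float(mfpt)
    counts, visits = _accumulate_flux(ensemble, spec)
    transverse = [
        np.prod([spec.spacing[a] for a in range(spec.ndim) if a != k])
        for k in range(spec.ndim)
    ]
    M = ensemble.n_trajectories
    flux = np.stack(
        [counts[k] / (M * mfpt * transverse[k]) for k in range(spec.ndim)]
    )
    p = visits / visits.sum()
    return spec, flux, visits, p, M, mfpt


def compute_flux_3d(
    ensemble: TrajectoryEnsemble,
    spec: GridSpec,
    mfpt: float | None = None,
    out_of_bounds: str = "error",
) -> FluxGrid3D:
    """Estimate the 3D flux field j(g) from a cv3 ensemble.

    ``mfpt`` defaults to the ensemble mean first-passage time.  With
    ``out_of_bounds='grow'`` the grid is enlarged to cover all frames.
    """
    if ensemble.feature_dim != 3:
        raise ValueError("compute_flux_3d needs 3-component frames")
    spec, flux, visits, p, M, mfpt = _estimate(ensemble, spec, mfpt, out_of_bounds)
    return FluxGrid3D(spec=spec, j=flux, visits=visits, p=p, m_trajectories=M, mfpt=mfpt)


def compute_flux_2d(
    ensemble: TrajectoryEnsemble,
    spec: GridSpec,
    mfpt: float | None = None,
    out_of_bounds: str = "error",
) -> FluxGrid2D:
    """2D analogue of :func:`compute_flux_3d`: node lines and elementary segments."""
    if ensemble.feature_dim != 2:
        raise ValueError("compute_flux_2d needs 2-component frames")
    spec, flux, visits, p, M, mfpt = _estimate(ensemble, spec, mfpt, out_of_bounds)
    return FluxGrid2D(spec=spec, J=flux, visits=visits, p=p, m_trajectories=M, mfpt=mfpt)


def compute_free_energy(p: np.ndarray, temperature_scale: float = 1.0) -> np.ma.MaskedArray:
    """Free energy F = −kT ln p in k_BT units, offset so min F = 0; masked at p = 0."""
    p = np.asarray(p, dtype=float)
    if np.all(p == 0):
        raise ValueError("all-zero probability field")
    masked = np.ma.masked_where(p <= 0, p)
    F = -temperature_scale * np.ma.log(masked)
    return F - F.min()


def compute_vorticity(grid: FluxGrid2D) -> np.ndarray:
    """ω = ∂J_G2/∂G1 − ∂J_G1/∂G2 by central differences (one-sided at edges).

    Negative vorticity is clockwise motion in the (G1, G2) plane.
    """
    if any(d < 3 for d in grid.spec.dims):
        raise ValueError("vorticity needs at least a 3x3 grid")
    d1, d2 = grid.spec.spacing
    omega = np.gradient(grid.J[1], d1, axis=0) - np.gradient(grid.J[0], d2, axis=1)
    grid.omega = omega
    return omega


def compute_stream_function(grid: FluxGrid2D) -> np.ndarray:
    """Ψ(G1, G2) = ∫ J_G1 dG2' from the lower G2 boundary (trapezoid rule)."""
    psi = cumulative_trapezoid(grid.J[0], dx=grid.spec.spacing[1], axis=1, initial=0.0)
    grid.psi = psi
    return psi


@dataclass
class BoxFluxResult:
    """Net outflow (μs⁻¹) through a grid-aligned box boundary."""

    net_outflow: float
    contains_source: bool  # some trajectory starts inside the box
    contains_sink: bool  # some trajectory ends inside the box


def box_net_outflow(
    ensemble: TrajectoryEnsemble,
    lo: np.ndarray,
    hi: np.ndarray,
    mfpt: float | None = None,
) -> BoxFluxResult:
    """Signed crossing flux through the faces of the box [lo, hi].

    Counts every segment crossing of each face (crossing point inside the
    face's transverse extent, half-open at the upper edge) with outward sign,
    normalized by M t̄_f.  Exactly 0 when the box contains neither the source
    nor the sink of a complete first-passage ensemble; −1/t̄_f around the sink.
    """
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    ndim = len(lo)
    mfpt = ensemble.mfpt if mfpt is None else float(mfpt)
    net = 0.0
    contains_source = contains_sink = False

    def inside(point):
        return bool(np.all(point >= lo) and np.all(point < hi))

    for traj in ensemble.trajectories:
        f = traj.frames
        contains_source |= inside(f[0])
        contains_sink |= inside(f[-1])
        for k in range(ndim):
            a, b = f[:-1, k], f[1:, k]
            for face_value, outward in ((lo[k], -1.0), (hi[k], 1.0)):
                crossing = ((a < face_value) & (face_value <= b)) | (
                    (b <= face_value) & (face_value < a)
                )
                if not np.any(crossing):
                    continue
                s = (face_value - a[crossing]) / (b[crossing] - a[crossing])
                sign = np.where(b[crossing] > a[crossing], 1.0, -1.0)
                ok = np.ones(len(s), dtype=bool)
                for ax in range(ndim):
                    if ax == k:
                        continue
                    pos = f[:-1, ax][crossing] + s * (f[1:, ax][crossing] - f[:-1, ax][crossing])
                    ok &= (pos >= lo[ax]) & (pos < hi[ax])
                net += float(np.sum(sign[ok])) * outward
    net /= ensemble.n_trajectories * mfpt
    return BoxFluxResult(net, contains_source, contains_sink)
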