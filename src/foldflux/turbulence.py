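"""Turbulence-style statistics of probability-flux fields.

Implements the flow-characterization toolbox: fractal coarse-graining curves
G_k(L) with their scaling index D_k, longitudinal structure functions
C_ll(l) and C_lll(l) (K41 predicts l^(2/3) and l in the inertial range),
prefactor scaling of block-summed fields, the periodogram "variance
spectrum" (K41: k^(-5/3)), the time-resolved flux variance with its rate
ε_pf and diffusion coefficient ε_pf/6, and exponential first-passage-time
fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .grids import FluxGrid3D, GridSpec
from .trajectories import TrajectoryEnsemble

__all__ = [
    "ScalingFit",
    "fit_power_law",
    "CoarseGrainCurve",
    "coarse_grain_curve",
    "StructureFunctions",
    "structure_functions",
    "directed_to_stochastic_sign_check",
    "VarianceSeries",
    "flux_variance_series",
    "time_variance",
    "prefactor_scaling",
    "variance_spectrum",
    "DegenerateSpectrumError",
    "FptFit",
    "fpt_fit",
    "msd_slope",
]


# ---------------------------------------------------------------------------
# power-law fitting

@dataclass
class ScalingFit:
    """Least-squares line in (log x, log y): y ~ x^exponent."""

    exponent: float
    log_prefactor: float
    fit_range: tuple[float, float]
    stderr: float
    n_points: int


def fit_power_law(
    x: np.ndarray, y: np.ndarray, fit_range: tuple[float, float] | None = None
) -> ScalingFit:
    """Fit y = A x^D by linear regression in log-log space.

    Non-positive values inside the range are excluded with a warning; fewer
    than 3 surviving points is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if fit_range is None:
        fit_range = (float(np.min(x)), float(np.max(x)))
    in_range = (x >= fit_range[0]) & (x <= fit_range[1])
    positive = (x > 0) & (y > 0) & np.isfinite(y)
    if np.any(in_range & ~positive):
        warnings.warn(
            f"excluding {int(np.sum(in_range & ~positive))} non-positive/invalid "
            "points from power-law fit",
            stacklevel=2,
        )
    keep = in_range & positive
    if keep.sum() < 3:
        raise ValueError("need at least 3 positive points in the fit range")
    res = stats.linregress(np.log(x[keep]), np.log(y[keep]))
    return ScalingFit(
        exponent=float(res.slope),
        log_prefactor=float(res.intercept),
        fit_range=fit_range,
        stderr=float(res.stderr) if np.isfinite(res.stderr) else 0.0,
        n_points=int(keep.sum()),
    )


# ---------------------------------------------------------------------------
# fractal coarse-graining G_k(L)

@dataclass
class CoarseGrainCurve:
    """G_k(L) over tile sizes L, with the fitted fractal index D_k."""

    k: int
    L_values: np.ndarray
    G_values: np.ndarray  # masked where no occupied tile exists
    region: tuple[float, float] | None
    fit: ScalingFit | None


def coarse_grain_curve(
    grid: FluxGrid3D,
    k: int,
    L_values: tuple[int, ...] = (1, 2, 3, 4, 5),
    region: tuple[float, float] | None = None,
) -> CoarseGrainCurve:
    """Coarse-grained flow ratio G_k(L) = ⟨|J_L| / j̄⟩ across g_k cross-sections.

    Each cross-section perpendicular to axis k is tiled with non-overlapping
    L x L squares anchored at the lower corner of the (region-restricted)
    domain.  |J_L| is the magnitude of the summed elementary j_k over the
    square; j̄ is the RMS of j_k over the *visited* cells of the same square;
    only tiles containing visited cells enter the average.  ``region``
    restricts g1 to the half-open interval (lo, hi].  D = 2 for uniform flow;
    sparser, more turbulent flow gives smaller D.
    """
    spec = grid.spec
    axes_t = [a for a in range(3) if a != k]
    g1_nodes = spec.axis_coords(0)
    if region is not None:
        g1_keep = (g1_nodes > region[0]) & (g1_nodes <= region[1])
    else:
        g1_keep = np.ones(spec.dims[0], dtype=bool)
    g1_idx = np.nonzero(g1_keep)[0]
    if g1_idx.size == 0:
        raise ValueError("region selects no g1 nodes")

    jk = grid.j[k]
    occ = grid.occupied
    # move axis k first: sections[s] is a 2D cross-section over axes_t
    jk_sec = np.moveaxis(jk, k, 0)
    occ_sec = np.moveaxis(occ, k, 0)
    if k == 0:
        jk_sec = jk_sec[g1_idx]
        occ_sec = occ_sec[g1_idx]
    else:
        # g1 is a transverse axis of the cross-sections; restrict its extent
        g1_pos = axes_t.index(0)
        jk_sec = np.compress(g1_keep, jk_sec, axis=1 + g1_pos)
        occ_sec = np.compress(g1_keep, occ_sec, axis=1 + g1_pos)

    spacing_t = [spec.spacing[a] for a in axes_t]
    G_vals = np.ma.masked_all(len(L_values))
    for li, L in enumerate(L_values):
        n = (int(round(L / spacing_t[0])), int(round(L / spacing_t[1])))
        if min(n) < 1 or n[0] > jk_sec.shape[1] or n[1] > jk_sec.shape[2]:
            continue
        t1 = (jk_sec.shape[1] // n[0]) * n[0]
        t2 = (jk_sec.shape[2] // n[1]) * n[1]
        if t1 == 0 or t2 == 0:
            continue
        jb = jk_sec[:, :t1, :t2].reshape(
            jk_sec.shape[0], t1 // n[0], n[0], t2 // n[1], n[1]
        )
        ob = occ_sec[:, :t1, :t2].reshape(jb.shape)
        n_occ = ob.sum(axis=(2, 4))  # visited cells per tile
        J_L = np.abs(np.sum(jb, axis=(2, 4)))
        sq_sum = np.sum(jb**2 * ob, axis=(2, 4))
        occupied_tiles = n_occ > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            jbar = np.sqrt(sq_sum / np.where(occupied_tiles, n_occ, 1))
        valid = occupied_tiles & (jbar > 0)
        if not np.any(valid):
            continue
        G_vals[li] = float(np.mean(J_L[valid] / jbar[valid]))

    fit = None
    L_arr = np.asarray(L_values, dtype=float)
    good = ~np.ma.getmaskarray(G_vals)
    if good.sum() >= 3:
        fit = fit_power_law(L_arr[good], np.ma.compressed(G_vals))
    return CoarseGrainCurve(k=k, L_values=L_arr, G_values=G_vals, region=region, fit=fit)


# ---------------------------------------------------------------------------
# structure functions

@dataclass
class StructureFunctions:
    """Binned longitudinal structure functions with per-bin pair counts."""

    l_bins: np.ndarray  # Å, bin centers (multiples of Δg)
    C_ll: np.ndarray  # masked where count = 0
    C_lll: np.ndarray
    counts: np.ndarray


def _occupied_nodes(grid: FluxGrid3D):
    mask = grid.occupied
    idx = np.argwhere(mask)
    vals = grid.j[:, mask].T  # (N, 3)
    return idx, vals


def structure_functions(
    grid: FluxGrid3D,
    l_max: float,
    max_pairs: int = 1_000_000,
    seed: int = 0,
    direction_axis: int | None = None,
    n_samples: int = 2_000_000,
) -> StructureFunctions:
    """Longitudinal flux-increment moments ⟨δj_∥(l)^2⟩ and ⟨δj_∥(l)^3⟩.

    δj_∥ = [j(g + l) − j(g)] · l/|l| over pairs of visited nodes, binned by
    |l| rounded to the nearest Δg (isotropic average).  δj_∥ is invariant
    under swapping the pair endpoints, so unordered pairs are well defined.
    Pairs are enumerated exhaustively when the pair count is below
    ``max_pairs``, otherwise ``n_samples`` random pairs are drawn with the
    given seed.  ``direction_axis`` keeps only pairs separated purely along
    that axis (used by closed-form fixtures).
    """
    spec = grid.spec
    dg = float(spec.spacing[0])
    if not np.allclose(spec.spacing, dg):
        raise ValueError("structure functions require isotropic spacing")
    idx, vals = _occupied_nodes(grid)
    N = idx.shape[0]
    if N < 2:
        raise ValueError("need at least 2 occupied cells")
    n_bins = int(round(l_max / dg)) + 1
    sum2 = np.zeros(n_bins)
    sum3 = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)

    def accumulate(ia: np.ndarray, ib: np.ndarray) -> None:
        lvec = (idx[ib] - idx[ia]) * dg
        if direction_axis is not None:
            other = [a for a in range(3) if a != direction_axis]
            keep = np.all(lvec[:, other] == 0, axis=1) & (
                lvec[:, direction_axis] != 0
            )
            ia, ib, lvec = ia[keep], ib[keep], lvec[keep]
        lnorm = np.linalg.norm(lvec, axis=1)
        keep = (lnorm > 0) & (lnorm <= l_max + 0.5 * dg)
        if not np.any(keep):
            return
        ia, ib, lvec, lnorm = ia[keep], ib[keep], lvec[keep], lnorm[keep]
        delta = vals[ib] - vals[ia]
        dpar = np.einsum("ij,ij->i", delta, lvec) / lnorm
        bins = np.clip(np.round(lnorm / dg).astype(int), 0, n_bins - 1)
        np.add.at(sum2, bins, dpar**2)
        np.add.at(sum3, bins, dpar**3)
        np.add.at(counts, bins, 1)

    if direction_axis is not None:
        # enumerate pairs within each grid line along the axis; random
        # sampling would almost never draw an exactly-aligned pair
        other = [a for a in range(3) if a != direction_axis]
        key = idx[:, other[0]] * (idx[:, other[1]].max() + 1) + idx[:, other[1]]
        order = np.argsort(key, kind="stable")
        sorted_key = key[order]
        run_starts = np.flatnonzero(
            np.concatenate(([True], sorted_key[1:] != sorted_key[:-1]))
        )
        run_ends = np.concatenate((run_starts[1:], [len(sorted_key)]))
        ia_list, ib_list = [], []
        for s, e in zip(run_starts, run_ends):
            if e - s < 2:
                continue
            a, b = np.triu_indices(e - s, k=1)
            ia_list.append(order[s:e][a])
            ib_list.append(order[s:e][b])
        if ia_list:
            ia_all = np.concatenate(ia_list)
            ib_all = np.concatenate(ib_list)
            if len(ia_all) > max_pairs:
                rng = np.random.default_rng(seed)
                pick = rng.choice(len(ia_all), size=max_pairs, replace=False)
                ia_all, ib_all = ia_all[pick], ib_all[pick]
            for start in range(0, len(ia_all), 500_000):
                sl = slice(start, start + 500_000)
                accumulate(ia_all[sl], ib_all[sl])
    elif (total_pairs := N * (N - 1) // 2) <= max_pairs:
        ia, ib = np.triu_indices(N, k=1)
        for start in range(0, len(ia), 500_000):
            sl = slice(start, start + 500_000)
            accumulate(ia[sl], ib[sl])
    else:
        rng = np.random.default_rng(seed)
        for start in range(0, n_samples, 500_000):
            m = min(500_000, n_samples - start)
            ia = rng.integers(0, N, m)
            ib = rng.integers(0, N, m)
            accumulate(ia, ib)

    if counts.sum() == 0:
        raise ValueError("no valid node pairs within l_max")
    valid = counts > 0
    C_ll = np.ma.masked_all(n_bins)
    C_lll = np.ma.masked_all(n_bins)
    C_ll[valid] = sum2[valid] / counts[valid]
    C_lll[valid] = sum3[valid] / counts[valid]
    return StructureFunctions(
        l_bins=np.arange(n_bins) * dg, C_ll=C_ll, C_lll=C_lll, counts=counts
    )


def directed_to_stochastic_sign_check(
    grid: FluxGrid3D,
    l_range: tuple[float, float] | None = None,
    seed: int = 0,
) -> tuple[int, float]:
    """Sign of C_lll averaged over the directed-to-stochastic transition range.

    A well-directed flow feeding a stochastic region gives negative
    longitudinal third moments irrespective of which endpoint sits in which
    region (the projection flips with l).  Returns (sign, mean C_lll).
    """
    extent = max(
        (d - 1) * s for d, s in zip(grid.spec.dims, grid.spec.spacing)
    )
    if l_range is None:
        l_range = (0.25 * extent, 0.75 * extent)
    sf = structure_functions(grid, l_max=l_range[1], seed=seed)
    in_range = (sf.l_bins >= l_range[0]) & (sf.l_bins <= l_range[1]) & (sf.counts > 0)
    if not np.any(in_range):
        raise ValueError("no populated bins in the requested range")
    weights = sf.counts[in_range]
    mean_c3 = float(np.average(np.asarray(sf.C_lll[in_range]), weights=weights))
    return int(np.sign(mean_c3)), mean_c3


# ---------------------------------------------------------------------------
# time-resolved flux variance, ε_pf and the diffusion coefficient

@dataclass
class VarianceSeries:
    """Δσ²_pf(Δt) with the fitted rate ε_pf and diffusion coefficient ε_pf/6."""

    dt_values: np.ndarray  # μs
    dvar_values: np.ndarray
    eps_pf: float | None
    diffusion_coefficient: float | None
    fit_range_max: float
    sigma2: np.ndarray = field(default=None)  # σ²_pf per window (masked)
    window_dt: float = 0.0


def flux_variance_series(
    window_fields: list[np.ndarray | None],
    window_volumes: np.ndarray,
    window_dt: float,
    fit_range_max: float | None = None,
) -> VarianceSeries:
    """Variance dynamics from a per-window sequence of flux samples.

    ``window_fields[w]`` holds the flux vectors over the occupied cells of
    window w, shape (n_cells, ndim), or None for windows with no data.
    ``window_volumes`` is V(τ) per window, expressed as a fraction of the
    maximum occupied volume.  σ²_pf(τ) is the spatial variance of the flux
    components about their mean, divided by V(τ); Δσ²(Δt) is its mean
    forward increment; ε_pf the slope of the linear fit for
    Δt <= fit_range_max; the diffusion coefficient is exactly ε_pf / 6.
    """
    n_win = len(window_fields)
    sigma2 = np.ma.masked_all(n_win)
    for w, vals in enumerate(window_fields):
        if vals is None or len(vals) == 0 or window_volumes[w] <= 0:
            continue
        dev = vals - vals.mean(axis=0)
        sigma2[w] = float(np.sum(dev**2) / len(vals)) / float(window_volumes[w])
    dt_values, dvar = [], []
    for m in range(1, n_win):
        diffs = sigma2[m:] - sigma2[:-m]
        if diffs.count() == 0:
            continue
        dt_values.append(m * window_dt)
        dvar.append(float(diffs.mean()))
    dt_values = np.asarray(dt_values)
    dvar = np.asarray(dvar)
    if fit_range_max is None:
        fit_range_max = float(dt_values[-1]) if len(dt_values) else 0.0
    keep = dt_values <= fit_range_max
    eps = diff_coef = None
    if keep.sum() >= 3:
        res = stats.linregress(dt_values[keep], dvar[keep])
        eps = float(res.slope)
        diff_coef = eps / 6.0
    return VarianceSeries(
        dt_values=dt_values,
        dvar_values=dvar,
        eps_pf=eps,
        diffusion_coefficient=diff_coef,
        fit_range_max=fit_range_max,
        sigma2=sigma2,
        window_dt=window_dt,
    )


def time_variance(
    ensemble: TrajectoryEnsemble,
    spec: GridSpec,
    window_frames: int = 5,
    fit_range_max: float | None = None,
) -> VarianceSeries:
    """Time-resolved flux variance of a cv3 ensemble aligned at initiation.

    Trajectories are cut into tumbling windows of ``window_frames`` frames;
    the instantaneous flux in window w is estimated from the signed plane
    crossings of the segments inside that window across all trajectories,
    normalized by M, the window duration and the transverse cell area.  V(τ)
    is the occupied-cell count as a fraction of its maximum over windows.
    ``fit_range_max`` defaults to the 95th percentile of the first-passage
    times.
    """
    from .flux import _accumulate_flux  # shared crossing enumeration
    from .trajectories import Trajectory

    if window_frames < 2:
        raise ValueError("window_frames must be >= 2")
    if ensemble.feature_dim != 3:
        raise ValueError("time_variance needs a cv3 ensemble")
    if fit_range_max is None:
        fit_range_max = float(np.percentile(ensemble.first_passage_times, 95))
    window_dt = window_frames * ensemble.frame_interval
    M = ensemble.n_trajectories
    area = [
        np.prod([spec.spacing[a] for a in range(3) if a != k]) for k in range(3)
    ]
    n_win = max(
        (t.n_frames - 1 + window_frames - 1) // window_frames
        for t in ensemble.trajectories
    )
    fields: list[np.ndarray | None] = []
    volumes = np.zeros(n_win)
    for w in range(n_win):
        subtrajs = []
        for traj in ensemble.trajectories:
            seg = traj.frames[w * window_frames : (w + 1) * window_frames + 1]
            if seg.shape[0] >= 2:
                subtrajs.append(Trajectory(seg, 1.0))
        if not subtrajs:
            fields.append(None)
            continue
        sub = TrajectoryEnsemble(subtrajs, ensemble.frame_interval, "cv3")
        counts, visits = _accumulate_flux(sub, spec)
        occ = visits > 0
        n_occ = int(occ.sum())
        if n_occ == 0:
            fields.append(None)
            continue
        jvals = np.stack(
            [counts[k][occ] / (M * window_dt * area[k]) for k in range(3)], axis=1
        )
        fields.append(jvals)
        volumes[w] = n_occ
    vmax = volumes.max()
    if vmax == 0:
        raise ValueError("no window contains any transitions")
    return flux_variance_series(fields, volumes / vmax, window_dt, fit_range_max)


# ---------------------------------------------------------------------------
# prefactor scaling of block-summed fields

def _block_sum_field(grid: FluxGrid3D, L: int) -> FluxGrid3D:
    """Coarse field: component k summed over L x L transverse cells at stride-L planes."""
    spec = grid.spec
    nc = min(d // L for d in spec.dims)
    dims_c = (nc, nc, nc)
    j_c = np.zeros((3, *dims_c))
    for k in range(3):
        jk = np.moveaxis(grid.j[k], k, 0)
        planes = jk[::L][:nc, : nc * L, : nc * L]
        summed = planes.reshape(nc, nc, L, nc, L).sum(axis=(2, 4))
        j_c[k] = np.moveaxis(summed, 0, k)
    vis = grid.visits[: nc * L, : nc * L, : nc * L]
    vis_c = vis.reshape(nc, L, nc, L, nc, L).sum(axis=(1, 3, 5))
    p_c = vis_c / vis_c.sum() if vis_c.sum() > 0 else vis_c
    spec_c = GridSpec(
        origin=tuple(grid.spec.origin),
        spacing=tuple(L * s for s in spec.spacing),
        dims=dims_c,
    )
    return FluxGrid3D(
        spec=spec_c, j=j_c, visits=vis_c, p=p_c,
        m_trajectories=grid.m_trajectories, mfpt=grid.mfpt,
    )


def prefactor_scaling(
    grid: FluxGrid3D,
    L_values: tuple[int, ...] = (1, 2, 4),
    l_range: tuple[float, float] | None = None,
    seed: int = 0,
    direction_axis: int | None = None,
) -> tuple[ScalingFit, ScalingFit]:
    """Exponents of A_ll(L) and A_lll(L), the structure-function prefactors.

    The field is block-summed over L x L transverse squares (stride L along
    the component's own axis), the structure functions recomputed on the
    coarse grid, and A(L) taken as the mean ratio to the L0 = 1 baseline over
    the common l bins in ``l_range``.  For a flow of transversal fractal
    index D, consistency of the two self-similarities demands
    A_ll ~ L^(2D) and A_lll ~ L^(3D).
    """
    extent = min((d - 1) * s for d, s in zip(grid.spec.dims, grid.spec.spacing))
    if l_range is None:
        l_range = (max(L_values) * float(grid.spec.spacing[0]), 0.5 * extent)
    base = structure_functions(
        grid, l_max=l_range[1], seed=seed, direction_axis=direction_axis
    )
    A_ll, A_lll = [], []
    for L in L_values:
        coarse = grid if L == 1 else _block_sum_field(grid, L)
        sf = structure_functions(
            coarse, l_max=l_range[1], seed=seed, direction_axis=direction_axis
        )
        ratios2, ratios3 = [], []
        for bi, l in enumerate(sf.l_bins):
            if not (l_range[0] <= l <= l_range[1]) or sf.counts[bi] == 0:
                continue
            b_idx = int(round(l / grid.spec.spacing[0]))
            if b_idx >= len(base.l_bins) or base.counts[b_idx] == 0:
                continue
            c2_base = base.C_ll[b_idx]
            c3_base = base.C_lll[b_idx]
            if c2_base and abs(c2_base) > 0:
                ratios2.append(float(sf.C_ll[bi] / c2_base))
            if c3_base and abs(c3_base) > 0:
                ratios3.append(float(sf.C_lll[bi] / c3_base))
        A_ll.append(np.mean(ratios2) if ratios2 else np.nan)
        A_lll.append(np.mean(ratios3) if ratios3 else np.nan)
    L_arr = np.asarray(L_values, dtype=float)
    fit_ll = fit_power_law(L_arr, np.asarray(A_ll))
    fit_lll = fit_power_law(L_arr, np.abs(np.asarray(A_lll)))
    return fit_ll, fit_lll


# ---------------------------------------------------------------------------
# variance spectrum

class DegenerateSpectrumError(ValueError):
    """Band dominated by a single mode; a power-law fit is meaningless."""


def variance_spectrum(
    transects: np.ndarray,
    dx: float = 1.0,
    band: tuple[int, int] | None = None,
) -> tuple[ScalingFit, np.ndarray, np.ndarray]:
    """Power-law slope of the averaged periodogram of 1D flux transects.

    Transects must be evenly sampled with length >= 256.  The fit runs over
    wavenumber indices ``band`` (default [4, length // 8]).  A Hurst-1/3
    stationary-increment process gives the Kolmogorov-form slope −5/3.
    Returns (fit, frequencies, mean periodogram).
    """
    transects = np.atleast_2d(np.asarray(transects, dtype=float))
    n = transects.shape[1]
    if n < 256:
        raise ValueError("transects must have length >= 256")
    freqs, power = signal.periodogram(transects, fs=1.0 / dx, detrend="constant")
    mean_power = power.mean(axis=0)
    if band is None:
        band = (4, n // 8)
    lo, hi = band
    band_power = mean_power[lo : hi + 1]
    if band_power.max() > 0.5 * band_power.sum():
        raise DegenerateSpectrumError(
            "a single mode dominates the band; refusing the power-law fit"
        )
    fit = fit_power_law(freqs[lo : hi + 1], band_power)
    return fit, freqs, mean_power


# ---------------------------------------------------------------------------
# first-passage-time fits

@dataclass
class FptFit:
    """Exponential fit of first-passage times: MLE mean and empirical CDF."""

    times: np.ndarray  # sorted, μs
    waiting_time: float  # fitted exponential mean, μs
    cdf: np.ndarray  # empirical CDF values at `times`

    def exponential_cdf(self, t: float | np.ndarray) -> float | np.ndarray:
        """CDF of the fitted exponential at time t."""
        return 1.0 - np.exp(-np.asarray(t, dtype=float) / self.waiting_time)


def fpt_fit(source: TrajectoryEnsemble | np.ndarray) -> FptFit:
    """Maximum-likelihood exponential fit (sample mean) of first-passage times."""
    times = (
        source.first_passage_times
        if isinstance(source, TrajectoryEnsemble)
        else np.asarray(source, dtype=float)
    )
    if len(times) < 5:
        raise ValueError("need at least 5 first-passage times")
    if np.any(times <= 0):
        raise ValueError("first-passage times must be positive")
    times = np.sort(times)
    ecdf = np.arange(1, len(times) + 1) / len(times)
    return FptFit(times=times, waiting_time=float(times.mean()), cdf=ecdf)


# ---------------------------------------------------------------------------
# mean-squared-displacement slope (Brownian-diffusion relation)

def msd_slope(positions: np.ndarray, dt: float) -> float:
    """Slope of the ensemble mean squared displacement vs time.

    ``positions`` has shape (n_steps + 1, n_walkers, ndim) with the initial
    positions first.  For isotropic Brownian motion in d dimensions the slope
    equals 2 d D, i.e. 6 D in 3D — the divisor behind the ε_pf/6 relation.
    """
    disp = positions - positions[0]
    msd = np.mean(np.sum(disp**2, axis=-1), axis=1)
    t = dt * np.arange(len(msd))
    res = stats.linregress(t, msd)
    return float(res.slope)
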