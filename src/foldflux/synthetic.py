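"""Synthetic inputs with known ground truth.

Every generator here stands in for data the analysis consumes: first-passage
trajectory ensembles from a funnel-like overdamped Langevin process, flux
fields with prescribed increment scaling (Hurst-1/3, so δj ~ l^(1/3)) or
prescribed fractal support dimension, closed-form uniform/shear/vortex
fields, toy multi-model structures for the contact extractor, and a
two-channel flow for stream-tube bookkeeping.  All randomness flows through
one seeded generator per call; reruns with the same seed are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from .grids import FluxGrid2D, FluxGrid3D, GridSpec
from .structures import MultiModelStructure
from .trajectories import Trajectory, TrajectoryEnsemble

__all__ = [
    "FunnelModelParams",
    "simulate_funnel_ensemble",
    "FieldRecipe",
    "generate_field",
    "generate_toy_structure",
    "generate_two_channel_flow",
    "generate_fbm_transects",
    "simulate_brownian_walkers",
]


# ---------------------------------------------------------------------------
# funnel-like first-passage ensemble

@dataclass
class FunnelModelParams:
    """Overdamped Langevin funnel: constant-speed radial pull plus noise.

    Defaults emulate the study conditions of a fast-folding miniprotein run:
    frames every 20 ps (2e-5 μs), absorbing native ball of radius 2 Å, and a
    drift/noise balance whose quasi-stationary search cloud (≈ noise²/2/drift
    ≈ 4 Å) exceeds the absorbing radius, which makes absorption an
    approximately Poissonian event and the first-passage times near
    exponential with mean of order 0.03–0.05 μs.
    """

    unfolded_center: tuple[float, float, float] = (22.0, 20.0, 14.0)
    native_center: tuple[float, float, float] = (30.0, 24.0, 18.0)
    drift_strength: float = 550.0  # Å/μs, speed of the pull toward the native center
    noise_amplitude: float = 60.0  # Å/√μs per component
    frame_interval: float = 2e-5  # μs (20 ps)
    native_radius: float = 2.0  # Å
    max_frames: int = 200_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.native_radius <= 0:
            raise ValueError("native_radius must be positive")
        if self.noise_amplitude < 0:
            raise ValueError("noise_amplitude must be non-negative")
        if np.allclose(self.unfolded_center, self.native_center):
            raise ValueError("unfolded and native centers must be distinct")


def simulate_funnel_ensemble(
    params: FunnelModelParams, n_traj: int
) -> TrajectoryEnsemble:
    """Simulate n_traj first-passage runs ending inside the native ball.

    Update rule per frame: g ← g + v·(native − g)/|native − g|·dt + σ√dt·N(0, I).
    A run exceeding ``max_frames`` is dropped with a warning (it would bias
    the MFPT); in the ballistic limit (σ = 0) the first-passage time is
    exactly distance/drift_strength rounded up to the frame grid.
    """
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    rng = np.random.default_rng(params.seed)
    native = np.asarray(params.native_center, dtype=float)
    dt = params.frame_interval
    sqrt_dt = np.sqrt(dt)
    trajectories: list[Trajectory] = []
    n_dropped = 0
    for _ in range(n_traj):
        g = np.asarray(params.unfolded_center, dtype=float).copy()
        frames = [g.copy()]
        absorbed = False
        for _ in range(params.max_frames):
            delta = native - g
            dist = float(np.linalg.norm(delta))
            drift = params.drift_strength * delta / dist if dist > 0 else 0.0
            g = g + drift * dt + params.noise_amplitude * sqrt_dt * rng.standard_normal(3)
            frames.append(g.copy())
            if float(np.linalg.norm(g - native)) <= params.native_radius:
                absorbed = True
                break
        if not absorbed:
            n_dropped += 1
            continue
        arr = np.asarray(frames)
        trajectories.append(Trajectory(arr, (arr.shape[0] - 1) * dt))
    if n_dropped:
        warnings.warn(
            f"{n_dropped} trajectories exceeded max_frames and were excluded",
            stacklevel=2,
        )
    if not trajectories:
        raise ValueError("no trajectory reached the native state within max_frames")
    return TrajectoryEnsemble(trajectories, dt, "cv3")


# ---------------------------------------------------------------------------
# flux-field fixtures

@dataclass
class FieldRecipe:
    """Recipe for a synthetic flux field; ``parameters`` depend on ``kind``.

    kinds: uniform (value), shear (slope, axis), kolmogorov (hurst),
    fractal_support (box_dimension, axis, value), vortex2d (centers,
    strengths, core_sigma), directed_to_stochastic (channel_value,
    noise_sigma).
    """

    kind: str
    dims: tuple[int, ...]
    spacing: float = 1.0
    parameters: dict = field(default_factory=dict)
    seed: int = 0


def _full_grid_3d(spec: GridSpec, j: np.ndarray) -> FluxGrid3D:
    visits = np.ones(spec.dims)
    return FluxGrid3D(
        spec=spec, j=j, visits=visits, p=visits / visits.sum(),
        m_trajectories=1, mfpt=1.0,
    )


def _spectral_selfsimilar_3d(dims: tuple[int, ...], hurst: float, rng) -> np.ndarray:
    """One self-similar scalar field with stationary increments (spectral synthesis).

    Periodic synthesis with power spectrum |k|^-(2H+3) on a padded grid,
    cropped to ``dims`` to suppress wrap-around correlations.
    """
    pad = tuple(int(np.ceil(1.5 * d)) for d in dims)
    f = [np.fft.fftfreq(n) for n in pad]
    # discrete-Laplacian spectral symbol 4 sin^2(π f) per axis instead of the
    # continuum (2π f)^2: matches lattice increments below the Nyquist scale,
    # removing the small-l smoothness bias of plain |k|^-(2H+3) synthesis
    sym = (
        (4 * np.sin(np.pi * f[0]) ** 2)[:, None, None]
        + (4 * np.sin(np.pi * f[1]) ** 2)[None, :, None]
        + (4 * np.sin(np.pi * f[2]) ** 2)[None, None, :]
    )
    amp = np.zeros_like(sym)
    nonzero = sym > 0
    amp[nonzero] = sym[nonzero] ** (-(2 * hurst + 3) / 4.0)
    noise = rng.standard_normal(pad) + 1j * rng.standard_normal(pad)
    fld = np.fft.ifftn(amp * noise).real
    fld = fld[: dims[0], : dims[1], : dims[2]]
    return fld / fld.std()


def _fractal_support_2d(shape: tuple[int, int], box_dim: float, rng) -> np.ndarray:
    """Random dyadic-cascade subset of a 2D section with box dimension box_dim.

    At refinement level ℓ exactly round(2^(box_dim ℓ)) squares survive (drawn
    uniformly from the children of the previous level), so the grid-aligned
    box counts follow N(s) = s^box_dim by construction.
    """
    size = min(shape)
    levels = int(np.floor(np.log2(size)))
    squares = [(0, 0)]  # surviving squares at the current level, index coords
    for level in range(1, levels + 1):
        children = [
            (2 * i + di, 2 * j + dj)
            for (i, j) in squares
            for di in (0, 1)
            for dj in (0, 1)
        ]
        target = int(round(2 ** (box_dim * level)))
        target = max(1, min(target, len(children)))
        pick = rng.choice(len(children), size=target, replace=False)
        squares = [children[q] for q in sorted(pick)]
    mask = np.zeros((2**levels, 2**levels), dtype=bool)
    for i, j in squares:
        mask[i, j] = True
    out = np.zeros(shape, dtype=bool)
    out[: mask.shape[0], : mask.shape[1]] = mask
    return out


def generate_field(recipe: FieldRecipe) -> FluxGrid3D | FluxGrid2D:
    """Build the synthetic flux field described by ``recipe`` (seeded)."""
    rng = np.random.default_rng(recipe.seed)
    dims = tuple(recipe.dims)
    spec = GridSpec(
        origin=(0.0,) * len(dims), spacing=(recipe.spacing,) * len(dims), dims=dims
    )
    p = recipe.parameters
    if recipe.kind == "uniform":
        value = p.get("value", 1.0)
        j = np.zeros((3, *dims))
        j[0] = value
        return _full_grid_3d(spec, j)
    if recipe.kind == "shear":
        slope = p.get("slope", 1.0)
        axis = p.get("axis", 0)
        coords = spec.axis_coords(axis)
        shape = [1, 1, 1]
        shape[axis] = dims[axis]
        j = np.zeros((3, *dims))
        j[0] = slope * coords.reshape(shape)
        return _full_grid_3d(spec, j)
    if recipe.kind == "kolmogorov":
        hurst = p.get("hurst", 1.0 / 3.0)
        j = np.stack(
            [_spectral_selfsimilar_3d(dims, hurst, rng) for _ in range(3)]
        )
        return _full_grid_3d(spec, j)
    if recipe.kind == "fractal_support":
        box_dim = p["box_dimension"]
        axis = p.get("axis", 0)
        value = p.get("value", 1.0)
        # optional smooth positive ramp along a transverse axis: keeps the
        # flux same-sign but gives the field nonzero large-scale increments,
        # so structure-function prefactor ratios are well defined
        ramp = p.get("ramp_slope", 0.0)
        ramp_axis = p.get("ramp_axis", (axis + 1) % 3)
        j = np.zeros((3, *dims))
        visits = np.zeros(dims)
        sec_shape = tuple(d for a, d in enumerate(dims) if a != axis)
        jk = np.moveaxis(j[axis], axis, 0)
        vk = np.moveaxis(visits, axis, 0)
        shape = [1, 1, 1]
        shape[ramp_axis] = dims[ramp_axis]
        magnitude = value + ramp * spec.axis_coords(ramp_axis).reshape(shape)
        if np.any(magnitude <= 0):
            raise ValueError("ramp makes the flux change sign; reduce ramp_slope")
        mag_k = np.moveaxis(np.broadcast_to(magnitude, dims), axis, 0)
        style = p.get("style", "cascade")
        line_support = None
        if style == "lines":
            # deterministic parallel lines along the second transverse axis:
            # box dimension is exactly 1 at tile sizes below the line spacing
            spacing_cells = int(p.get("line_spacing", max(8, sec_shape[0] // 4)))
            line_support = np.zeros(sec_shape, dtype=bool)
            line_support[::spacing_cells, :] = True
        elif style != "cascade":
            raise ValueError(f"unknown fractal_support style {style!r}")
        for s in range(dims[axis]):
            support = (
                line_support
                if line_support is not None
                else _fractal_support_2d(sec_shape, box_dim, rng)
            )
            jk[s][support] = mag_k[s][support]
            vk[s][support] = 1.0
        if visits.sum() == 0:
            raise ValueError("empty fractal support")
        return FluxGrid3D(
            spec=spec, j=j, visits=visits, p=visits / visits.sum(),
            m_trajectories=1, mfpt=1.0,
        )
    if recipe.kind == "vortex2d":
        if len(dims) != 2:
            raise ValueError("vortex2d needs a 2-axis recipe")
        centers = p.get("centers", [tuple((d - 1) * recipe.spacing / 2 for d in dims)])
        strengths = p.get("strengths", [1.0] * len(centers))
        sigma = p.get("core_sigma", 0.25 * (dims[0] - 1) * recipe.spacing)
        x = spec.axis_coords(0)[:, None]
        y = spec.axis_coords(1)[None, :]
        J = np.zeros((2, *dims))
        for (cx, cy), s in zip(centers, strengths):
            envelope = np.exp(-(((x - cx) ** 2 + (y - cy) ** 2) / (2 * sigma**2)))
            J[0] += -s * (y - cy) * envelope
            J[1] += s * (x - cx) * envelope
        visits = np.ones(dims)
        return FluxGrid2D(
            spec=spec, J=J, visits=visits, p=visits / visits.sum(),
            m_trajectories=1, mfpt=1.0,
        )
    if recipe.kind == "directed_to_stochastic":
        channel = p.get("channel_value", 1.0)
        noise = p.get("noise_sigma", 0.1)
        split = p.get("split_index", dims[0] // 2)
        j = np.zeros((3, *dims))
        j[0, :split] = channel
        j[:, split:] = noise * rng.standard_normal((3, dims[0] - split, *dims[1:]))
        return _full_grid_3d(spec, j)
    raise ValueError(f"unsupported field kind: {recipe.kind!r}")


# ---------------------------------------------------------------------------
# toy structures

def generate_toy_structure(
    n_residues: int,
    n_models: int,
    contact_plan: list[tuple[int, int]],
    seed: int = 0,
    cutoff: float = 6.5,
) -> MultiModelStructure:
    """Multi-model structure realizing exactly the planned native contacts.

    Residues are spread far apart (pairwise > cutoff), then each planned
    pair (i, j) is realized by placing j near i in every model.  The realized
    structure is verified against the plan; a geometrically contradictory
    plan raises instead of silently returning the wrong contacts.
    """
    rng = np.random.default_rng(seed)
    plan = {(min(i, j), max(i, j)) for i, j in contact_plan}
    for i, j in plan:
        if not (0 <= i < j < n_residues):
            raise ValueError(f"pair ({i},{j}) out of range")
        if j - i < 2:
            raise ValueError(f"pair ({i},{j}) violates neighbor exclusion")
    spread = 4.0 * cutoff
    models = []
    for _ in range(n_models):
        base = np.arange(n_residues)[:, None] * np.array([spread, 0.0, 0.0])
        base = base + rng.normal(0, 0.5, size=(n_residues, 3))
        for i, j in sorted(plan):
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            base[j] = base[i] + 0.6 * cutoff * direction
        models.append(base)
    structure = MultiModelStructure(np.stack(models))
    realized = _consensus_contacts(structure, cutoff)
    if realized != plan:
        raise ValueError(
            f"infeasible contact plan: realized {sorted(realized)} vs "
            f"planned {sorted(plan)}"
        )
    return structure


def _consensus_contacts(structure: MultiModelStructure, cutoff: float) -> set:
    coords = structure.models
    dist = np.linalg.norm(coords[:, :, None, :] - coords[:, None, :, :], axis=-1)
    within = np.all(dist < cutoff, axis=0)
    n = structure.residue_count
    return {
        (i, j) for i in range(n) for j in range(i + 2, n) if within[i, j]
    }


# ---------------------------------------------------------------------------
# two-channel flow

def generate_two_channel_flow(
    ratio: float,
    dims: tuple[int, int] = (32, 32),
    spacing: float = 1.0,
    band_width: int = 8,
    gap: int = 6,
) -> FluxGrid2D:
    """Two disjoint uniform +G1 bands carrying flow fractions ratio and 1 − ratio."""
    if not 0 < ratio < 1:
        raise ValueError("ratio must lie in (0, 1)")
    n1, n2 = dims
    if 2 * band_width + gap > n2 - 2:
        raise ValueError("bands overlap: shrink band_width or gap")
    spec = GridSpec(origin=(0.0, 0.0), spacing=(spacing, spacing), dims=dims)
    J = np.zeros((2, n1, n2))
    lo1 = 1
    hi1 = lo1 + band_width
    lo2 = hi1 + gap
    hi2 = lo2 + band_width
    # trapezoid integral of a flat-top band of height h over band_width cells,
    # including the two half-cells ramping to zero, is h * band_width * spacing
    width = band_width * spacing
    J[0, :, lo1:hi1] = ratio / width
    J[0, :, lo2:hi2] = (1.0 - ratio) / width
    visits = (J[0] != 0).astype(float)
    return FluxGrid2D(
        spec=spec, J=J, visits=visits, p=visits / visits.sum(),
        m_trajectories=1, mfpt=1.0,
    )


# ---------------------------------------------------------------------------
# 1D transects and Brownian walkers

def generate_fbm_transects(
    n_transects: int, length: int, hurst: float = 1.0 / 3.0, seed: int = 0
) -> np.ndarray:
    """Self-similar transects with stationary increments of the given Hurst index.

    Exact circulant embedding (Davies-Harte) of fractional Gaussian noise,
    cumulatively summed; the periodogram of such transects follows
    k^-(2H + 1), i.e. k^(-5/3) at H = 1/3.
    """
    rng = np.random.default_rng(seed)
    n = length
    k = np.arange(n + 1)
    gamma = 0.5 * (
        np.abs(k + 1) ** (2 * hurst)
        - 2 * np.abs(k) ** (2 * hurst)
        + np.abs(k - 1) ** (2 * hurst)
    )
    circ = np.concatenate([gamma, gamma[-2:0:-1]])
    eig = np.fft.fft(circ).real
    eig = np.clip(eig, 0.0, None)  # tiny negatives from roundoff
    m = len(circ)
    out = np.empty((n_transects, n))
    for t in range(n_transects):
        z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
        fgn = np.fft.fft(np.sqrt(eig / (2 * m)) * z)[:n].real * np.sqrt(2)
        out[t] = np.cumsum(fgn)
    return out


def simulate_brownian_walkers(
    n_walkers: int,
    n_steps: int,
    dt: float,
    diffusion_coefficient: float,
    seed: int = 0,
    ndim: int = 3,
) -> np.ndarray:
    """Isotropic Brownian paths, shape (n_steps + 1, n_walkers, ndim).

    Per-step displacement is N(0, 2 D dt) per component, so the mean squared
    displacement grows as 2 d D t (6 D t in 3D).
    """
    rng = np.random.default_rng(seed)
    steps = rng.normal(
        0.0,
        np.sqrt(2.0 * diffusion_coefficient * dt),
        size=(n_steps, n_walkers, ndim),
    )
    paths = np.zeros((n_steps + 1, n_walkers, ndim))
    paths[1:] = np.cumsum(steps, axis=0)
    return paths
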