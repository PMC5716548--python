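"""End-to-end analysis orchestration with a config file and JSON/CSV report.

Stages: (contacts →) features → PCA → 3D/2D flux → free energy, vorticity,
stream function, stream tubes → coarse-graining curves, structure functions,
time variance, first-passage fit.  Identical config + seeds give a
bit-identical JSON summary.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .collective import fit_pca, project, reduce_to_2d
from .flux import (
    compute_flux_2d,
    compute_flux_3d,
    compute_free_energy,
    compute_stream_function,
    compute_vorticity,
)
from .grids import save_flux_grid
from .structures import extract_native_contacts, read_pdb_models, write_contacts_csv
from .synthetic import FunnelModelParams, simulate_funnel_ensemble
from .tracers import pathway_fractions
from .trajectories import FormatSpec, TrajectoryEnsemble, read_trajectories
from .turbulence import coarse_grain_curve, fpt_fit, structure_functions, time_variance

__all__ = ["AnalysisConfig", "ConfigError", "run_full_analysis"]

log = logging.getLogger("foldflux.pipeline")

EXIT_MISSING_INPUT = 3
EXIT_INVALID_CONFIG = 4
EXIT_DEGENERATE_DATA = 5


class ConfigError(ValueError):
    pass


@dataclass
class AnalysisConfig:
    """Configuration of a full run; defaults mirror the standard protocol:
    Δg = 1 Å grid, 6.5 Å contact cutoff, L ≤ 5 Å coarse-graining, g1 regions
    (10,30], (30,50], (50,70].
    """

    # inputs: either trajectory files (+ optional pdb for contacts) or simulate
    trajectory_paths: list[str] = field(default_factory=list)
    pdb_path: str | None = None
    simulate: bool = True
    n_trajectories: int = 100
    frame_interval: float = 2e-5  # μs
    # analysis parameters
    grid_spacing: float = 1.0  # Å
    contact_cutoff: float = 6.5  # Å
    neighbor_exclusion: int = 2
    pca_components: int = 3
    regions: list[tuple[float, float]] = field(
        default_factory=lambda: [(10.0, 30.0), (30.0, 50.0), (50.0, 70.0)]
    )
    L_values: list[int] = field(default_factory=lambda: [1, 2, 3, 4, 5])
    l_max: float = 20.0  # Å, structure-function range
    window_frames: int = 5
    fit_range_max: float | None = None  # μs; default = 95th FPT percentile
    stream_tube_boundaries: list[float] = field(default_factory=list)
    seed: int = 0
    output_dir: str = "foldflux_out"

    def validate(self) -> None:
        if not self.simulate and not self.trajectory_paths:
            raise ConfigError("either enable simulate or provide trajectory_paths")
        for p in self.trajectory_paths:
            if not Path(p).exists():
                raise ConfigError(f"trajectory path does not exist: {p}")
        if self.pdb_path and not Path(self.pdb_path).exists():
            raise ConfigError(f"pdb path does not exist: {self.pdb_path}")
        if self.grid_spacing <= 0:
            raise ConfigError("grid_spacing must be positive")
        if self.pca_components < 3:
            raise ConfigError("pca_components must be >= 3")
        if self.window_frames < 2:
            raise ConfigError("window_frames must be >= 2")
        if any(L <= 0 for L in self.L_values):
            raise ConfigError("L_values must be positive")

    @staticmethod
    def from_yaml(path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in AnalysisConfig.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = AnalysisConfig(**raw)
        cfg.regions = [tuple(r) for r in cfg.regions]
        return cfg

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("output_dir")  # where results land does not affect them
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage(name: str, t0: float, **shapes) -> None:
    desc = " ".join(f"{k}={v}" for k, v in shapes.items())
    log.info("stage=%s elapsed=%.2fs %s", name, time.monotonic() - t0, desc)


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run every stage and write the report bundle; returns the JSON summary."""
    config.validate()
    t0 = time.monotonic()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "provenance": {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "version": __version__,
        }
    }

    # --- contacts (only when a structure is provided)
    if config.pdb_path:
        structure = read_pdb_models(config.pdb_path)
        contacts = extract_native_contacts(
            structure, config.contact_cutoff, config.neighbor_exclusion
        )
        write_contacts_csv(contacts, outdir / "native_contacts.csv")
        summary["n_native_contacts"] = len(contacts)
        _stage("contacts", t0, n_contacts=len(contacts))

    # --- input ensemble
    if config.simulate:
        params = FunnelModelParams(
            frame_interval=config.frame_interval, seed=config.seed
        )
        ensemble = simulate_funnel_ensemble(params, config.n_trajectories)
    else:
        spec = FormatSpec(frame_interval=config.frame_interval)
        ensemble = read_trajectories(config.trajectory_paths, spec)
    summary["n_trajectories"] = ensemble.n_trajectories
    summary["mfpt_us"] = ensemble.mfpt
    _stage("input", t0, M=ensemble.n_trajectories, dim=ensemble.feature_dim)

    # --- collective variables
    space = fit_pca(ensemble, config.pca_components)
    cv3 = project(ensemble, space)
    cv3.feature_kind = "cv3"
    if space.n_components > 3:
        cv3 = cv3.map_frames(lambda f: f[:, :3])
        cv3.feature_kind = "cv3"
    cv2, weights = reduce_to_2d(cv3, space)
    summary["pca_variance_fractions"] = [
        float(x) for x in space.explained_variance_fractions[:3]
    ]
    summary["cv2_weights"] = [weights.w2, weights.w3]
    _stage("pca", t0, fractions=summary["pca_variance_fractions"])

    # --- flux fields
    from .grids import GridSpec

    spec3 = GridSpec.from_data(cv3.pooled_frames(), config.grid_spacing)
    grid3 = compute_flux_3d(cv3, spec3)
    spec2 = GridSpec.from_data(cv2.pooled_frames(), config.grid_spacing)
    grid2 = compute_flux_2d(cv2, spec2)
    grid2.F = compute_free_energy(grid2.p)
    compute_vorticity(grid2)
    compute_stream_function(grid2)
    save_flux_grid(grid3, outdir / "flux3d.npz")
    save_flux_grid(grid2, outdir / "flux2d.npz")
    _stage("flux", t0, dims3=spec3.dims, dims2=spec2.dims)

    # --- stream tubes
    try:
        boundaries = (
            np.asarray(config.stream_tube_boundaries)
            if config.stream_tube_boundaries
            else np.quantile(
                grid2.psi[grid2.spec.dims[0] // 2], [0.5]
            )  # default: split at the median stream-function level
        )
        tubes = pathway_fractions(grid2, boundaries, normalization="span")
        summary["pathway_fractions"] = [float(x) for x in tubes.fractions]
    except ValueError as exc:
        summary["pathway_fractions"] = None
        log.warning("stream tubes unavailable: %s", exc)
    _stage("geometry", t0)

    # --- turbulence statistics
    curves = []
    for k in range(3):
        for region in config.regions:
            lo = grid3.spec.axis_coords(0).min()
            hi = grid3.spec.axis_coords(0).max()
            if region[1] <= lo or region[0] >= hi:
                continue
            curve = coarse_grain_curve(
                grid3, k, tuple(config.L_values), region=region
            )
            curves.append(
                {
                    "k": k + 1,
                    "region": list(region),
                    "D": curve.fit.exponent if curve.fit else None,
                    "stderr": curve.fit.stderr if curve.fit else None,
                }
            )
    summary["fractal_indices"] = curves
    pd.DataFrame(curves).to_csv(outdir / "fractal_indices.csv", index=False)

    sf = structure_functions(grid3, l_max=config.l_max, seed=config.seed)
    sf_df = pd.DataFrame(
        {
            "l": sf.l_bins,
            "C_ll": np.ma.filled(sf.C_ll, np.nan),
            "C_lll": np.ma.filled(sf.C_lll, np.nan),
            "count": sf.counts,
        }
    )
    sf_df.to_csv(outdir / "structure_functions.csv", index=False)
    populated = sf.counts > 0
    if populated.sum() >= 3:
        from .turbulence import fit_power_law

        lpos = sf.l_bins > 0
        fit2 = fit_power_law(
            sf.l_bins[lpos & populated], np.ma.filled(sf.C_ll, np.nan)[lpos & populated]
        )
        summary["structure_function_slopes"] = {"C_ll": fit2.exponent}
    else:
        summary["structure_function_slopes"] = None

    var = time_variance(
        cv3, spec3, window_frames=config.window_frames,
        fit_range_max=config.fit_range_max,
    )
    summary["eps_pf"] = var.eps_pf
    summary["diffusion_coefficient"] = var.diffusion_coefficient
    pd.DataFrame({"dt_us": var.dt_values, "dvar": var.dvar_values}).to_csv(
        outdir / "variance_series.csv", index=False
    )

    fit = fpt_fit(ensemble)
    summary["waiting_time_us"] = fit.waiting_time
    pd.DataFrame({"t_us": fit.times, "ecdf": fit.cdf}).to_csv(
        outdir / "fpt_cdf.csv", index=False
    )
    _stage("stats", t0)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
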