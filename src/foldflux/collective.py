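"""Collective-variable construction by principal component analysis.

The contact-distance space is rotated onto the eigenvectors of its pooled
covariance (centered, not standardized: all features share Å units), keeping
the leading components as collective variables g = (g1, g2, g3).  A 2D space
G = (G1, G2) takes G1 = g1 and folds g2, g3 into G2 with eigenvalue-
proportional weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .trajectories import TrajectoryEnsemble

__all__ = [
    "CollectiveVariableSpace",
    "CvSpec2D",
    "fit_pca",
    "project",
    "reduce_to_2d",
    "save_cv_space",
    "load_cv_space",
]


@dataclass
class CollectiveVariableSpace:
    """Centered orthonormal PCA basis: mean, eigenvectors (rows), eigenvalues (Å²)."""

    mean: np.ndarray
    eigenvectors: np.ndarray  # (n_components, feature_dim), rows orthonormal
    eigenvalues: np.ndarray  # non-increasing, >= 0
    total_variance: float  # trace of the pooled covariance

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.eigenvectors.ndim != 2:
            raise ValueError("eigenvectors must be 2D (n_components, feature_dim)")
        gram = self.eigenvectors @ self.eigenvectors.T
        if not np.allclose(gram, np.eye(len(self.eigenvalues)), atol=1e-8):
            raise ValueError("eigenvectors are not orthonormal")
        if np.any(np.diff(self.eigenvalues) > 1e-12) or np.any(self.eigenvalues < -1e-12):
            raise ValueError("eigenvalues must be non-negative and non-increasing")

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    @property
    def explained_variance_fractions(self) -> np.ndarray:
        return self.eigenvalues / self.total_variance


@dataclass
class CvSpec2D:
    """Weights folding (g2, g3) into G2; non-negative, summing to 1."""

    w2: float
    w3: float

    def __post_init__(self) -> None:
        if self.w2 < 0 or self.w3 < 0:
            raise ValueError("weights must be non-negative")
        if abs(self.w2 + self.w3 - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")


def fit_pca(ensemble: TrajectoryEnsemble, n_components: int) -> CollectiveVariableSpace:
    """Eigendecomposition of the pooled-frame covariance (centered only).

    Eigenpairs sorted by decreasing eigenvalue; each eigenvector's sign is
    fixed so its largest-magnitude component is positive (reproducibility).
    """
    data = ensemble.pooled_frames()
    if data.shape[0] < 2:
        raise ValueError("need at least 2 pooled frames for PCA")
    if n_components > data.shape[1]:
        raise ValueError("n_components exceeds feature_dim")
    mean = data.mean(axis=0)
    cov = np.cov(data - mean, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order].T  # rows = components
    for row in evecs:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    return CollectiveVariableSpace(
        mean=mean,
        eigenvectors=evecs[:n_components],
        eigenvalues=evals[:n_components],
        total_variance=float(np.trace(cov)),
    )


def project(
    ensemble: TrajectoryEnsemble, space: CollectiveVariableSpace
) -> TrajectoryEnsemble:
    """Center each frame and project onto the retained eigenvectors (units stay Å)."""
    if ensemble.feature_dim != space.mean.shape[0]:
        raise ValueError(
            f"feature_dim {ensemble.feature_dim} does not match basis "
            f"dimension {space.mean.shape[0]}"
        )
    kind = "cv3" if space.n_components == 3 else ensemble.feature_kind
    out = ensemble.map_frames(lambda f: (f - space.mean) @ space.eigenvectors.T)
    out.feature_kind = kind
    return out


def reduce_to_2d(
    cv3_ensemble: TrajectoryEnsemble, space: CollectiveVariableSpace
) -> tuple[TrajectoryEnsemble, CvSpec2D]:
    """G1 = g1; G2 = w2*g2 + w3*g3 with w_i = λ_i / (λ2 + λ3)."""
    if cv3_ensemble.feature_kind != "cv3" or cv3_ensemble.feature_dim != 3:
        raise ValueError("input must be a 3-component cv3 ensemble")
    lam2, lam3 = float(space.eigenvalues[1]), float(space.eigenvalues[2])
    denom = lam2 + lam3
    if denom <= 0:
        raise ValueError("degenerate space: λ2 + λ3 = 0")
    weights = CvSpec2D(lam2 / denom, lam3 / denom)
    mat = np.array([[1.0, 0.0, 0.0], [0.0, weights.w2, weights.w3]])
    out = cv3_ensemble.map_frames(lambda f: f @ mat.T)
    out.feature_kind = "cv2"
    return out, weights


def save_cv_space(space: CollectiveVariableSpace, path: str | Path) -> Path:
    path = Path(path)
    np.savez(
        path,
        mean=space.mean,
        eigenvectors=space.eigenvectors,
        eigenvalues=space.eigenvalues,
        total_variance=np.array([space.total_variance]),
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_cv_space(path: str | Path) -> CollectiveVariableSpace:
    with np.load(path) as data:
        return CollectiveVariableSpace(
            mean=data["mean"],
            eigenvectors=data["eigenvectors"],
            eigenvalues=data["eigenvalues"],
            total_variance=float(data["total_variance"][0]),
        )
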