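"""Trajectory containers and delimited-text I/O.

A first-passage folding run is a time-ordered sequence of feature vectors
(inter-residue distances or collective-variable coordinates, both in Å)
stored at a fixed frame interval.  The ensemble of such runs is the raw
input to every flux estimate downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "TrajectoryEnsemble",
    "FormatSpec",
    "read_trajectories",
    "write_trajectories",
]

FEATURE_KINDS = ("distances", "cv3", "cv2")


class TrajectoryFormatError(ValueError):
    """Malformed trajectory file (ragged rows, non-numeric cells)."""


@dataclass
class Trajectory:
    """One time-ordered run; ``frames`` is (n_frames, feature_dim) in Å."""

    frames: np.ndarray
    first_passage_time: float  # μs; (n_frames - 1) * frame_interval for complete runs

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 2 or self.frames.shape[0] < 2:
            raise ValueError("a trajectory needs >= 2 frames")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("trajectory frames must be finite")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class TrajectoryEnsemble:
    """M trajectories sharing feature dimension, kind and frame interval."""

    trajectories: list[Trajectory]
    frame_interval: float  # μs between stored frames
    feature_kind: str = "distances"

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.feature_kind not in FEATURE_KINDS:
            raise ValueError(f"feature_kind must be one of {FEATURE_KINDS}")
        dims = {t.frames.shape[1] for t in self.trajectories}
        if len(dims) > 1:
            raise ValueError(f"trajectories disagree on feature_dim: {sorted(dims)}")

    @property
    def n_trajectories(self) -> int:
        return len(self.trajectories)

    @property
    def feature_dim(self) -> int:
        return self.trajectories[0].frames.shape[1]

    @property
    def first_passage_times(self) -> np.ndarray:
        return np.array([t.first_passage_time for t in self.trajectories])

    @property
    def mfpt(self) -> float:
        """Mean first-passage time t̄_f in μs."""
        return float(np.mean(self.first_passage_times))

    def pooled_frames(self) -> np.ndarray:
        return np.concatenate([t.frames for t in self.trajectories], axis=0)

    def map_frames(self, fn) -> "TrajectoryEnsemble":
        """New ensemble with ``fn`` applied to each trajectory's frame array."""
        new = [
            Trajectory(fn(t.frames), t.first_passage_time) for t in self.trajectories
        ]
        return TrajectoryEnsemble(new, self.frame_interval, self.feature_kind)


@dataclass
class FormatSpec:
    """How to read delimited trajectory files.

    ``delimiter`` None means any whitespace.  ``trajectory_column`` names an
    id column splitting one file into several runs (frames keep file order
    within each id).
    """

    frame_interval: float  # μs
    delimiter: str | None = None
    comment: str = "#"
    trajectory_column: str | int | None = None
    feature_kind: str = "distances"


def _read_table(path: Path, spec: FormatSpec) -> np.ndarray:
    rows: list[list[float]] = []
    width: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(spec.comment):
                continue
            cells = line.split(spec.delimiter) if spec.delimiter else line.split()
            if width is None:
                width = len(cells)
            elif len(cells) != width:
                raise TrajectoryFormatError(
                    f"{path}: line {lineno} has {len(cells)} columns, expected {width}"
                )
            try:
                rows.append([float(c) for c in cells])
            except ValueError as exc:
                raise TrajectoryFormatError(
                    f"{path}: line {lineno}: non-numeric cell ({exc})"
                ) from None
    if not rows:
        raise TrajectoryFormatError(f"{path}: no data rows")
    return np.asarray(rows)


def read_trajectories(
    paths: Iterable[str | Path], format_spec: FormatSpec
) -> TrajectoryEnsemble:
    """Read one trajectory per file (or split by an id column) into an ensemble.

    Each non-comment row is a frame; the first-passage time of a complete run
    is ``(n_frames - 1) * frame_interval``.
    """
    trajectories: list[Trajectory] = []
    for path in paths:
        path = Path(path)
        if spec_uses_id := format_spec.trajectory_column is not None:
            df = pd.read_csv(
                path,
                sep=format_spec.delimiter or r"\s+",
                comment=format_spec.comment,
            )
            col = format_spec.trajectory_column
            if isinstance(col, int):
                col = df.columns[col]
            for _, group in df.groupby(col, sort=False):
                frames = group.drop(columns=[col]).to_numpy(dtype=float)
                trajectories.append(_make_trajectory(frames, format_spec))
        if not spec_uses_id:
            frames = _read_table(path, format_spec)
            trajectories.append(_make_trajectory(frames, format_spec))
    return TrajectoryEnsemble(
        trajectories, format_spec.frame_interval, format_spec.feature_kind
    )


def _make_trajectory(frames: np.ndarray, spec: FormatSpec) -> Trajectory:
    fpt = (frames.shape[0] - 1) * spec.frame_interval
    return Trajectory(frames, fpt)


def write_trajectories(
    ensemble: TrajectoryEnsemble, directory: str | Path, prefix: str = "traj"
) -> list[Path]:
    """Write one whitespace-delimited text file per trajectory; returns paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, traj in enumerate(ensemble.trajectories):
        path = directory / f"{prefix}_{i:04d}.txt"
        header = (
            f"frame_interval_us={ensemble.frame_interval} "
            f"feature_kind={ensemble.feature_kind}"
        )
        np.savetxt(path, traj.frames, header=header)
        paths.append(path)
    return paths
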