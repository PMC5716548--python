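"""Multi-model structures, native contacts, and inter-residue distance features.

The native-contact definition follows the usual NMR-ensemble consensus rule:
a residue pair (not sequence neighbors) is a native contact when its Cα-Cα
distance is below the cutoff in *every* model of the ensemble.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .trajectories import Trajectory, TrajectoryEnsemble

__all__ = [
    "MultiModelStructure",
    "NativeContactSet",
    "read_pdb_models",
    "write_pdb_models",
    "extract_native_contacts",
    "build_distance_features",
    "write_contacts_csv",
    "read_contacts_csv",
]

DEFAULT_CONTACT_CUTOFF = 6.5  # Å
DEFAULT_NEIGHBOR_EXCLUSION = 2  # j - i >= 2, i.e. exclude sequence neighbors


@dataclass
class MultiModelStructure:
    """Cα coordinates of an NMR-style multi-model structure.

    ``models`` has shape (n_models, n_residues, 3) in Å.
    """

    models: np.ndarray

    def __post_init__(self) -> None:
        self.models = np.asarray(self.models, dtype=float)
        if self.models.ndim != 3 or self.models.shape[2] != 3:
            raise ValueError("models must have shape (n_models, n_residues, 3)")
        if self.models.shape[0] < 1:
            raise ValueError("need at least one model")
        if not np.all(np.isfinite(self.models)):
            raise ValueError("coordinates must be finite")

    @property
    def n_models(self) -> int:
        return self.models.shape[0]

    @property
    def residue_count(self) -> int:
        return self.models.shape[1]


@dataclass
class NativeContactSet:
    """Unique residue pairs (i, j), 0-based, i < j, j - i >= neighbor_exclusion."""

    pairs: list[tuple[int, int]]
    cutoff: float = DEFAULT_CONTACT_CUTOFF
    neighbor_exclusion: int = DEFAULT_NEIGHBOR_EXCLUSION

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        self.pairs = [(int(i), int(j)) for i, j in self.pairs]
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("contact pairs must be unique")
        for i, j in self.pairs:
            if not i < j:
                raise ValueError(f"pair ({i},{j}) must have i < j")
            if j - i < self.neighbor_exclusion:
                raise ValueError(
                    f"pair ({i},{j}) violates neighbor exclusion {self.neighbor_exclusion}"
                )

    def __len__(self) -> int:
        return len(self.pairs)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.pairs, dtype=int).reshape(-1, 2)


def read_pdb_models(path: str | Path) -> MultiModelStructure:
    """Read Cα coordinates of every MODEL in a PDB file (Biopython parser)."""
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # NMR PDBs trigger benign parser warnings
        structure = PDBParser(QUIET=True).get_structure("s", str(path))
    models = []
    for model in structure:
        coords = [
            residue["CA"].coord
            for chain in model
            for residue in chain
            if "CA" in residue
        ]
        models.append(np.asarray(coords, dtype=float))
    if not models:
        raise ValueError(f"{path}: no models found")
    counts = {m.shape[0] for m in models}
    if len(counts) != 1:
        raise ValueError(f"{path}: models have differing residue counts {sorted(counts)}")
    return MultiModelStructure(np.stack(models))


def write_pdb_models(structure: MultiModelStructure, path: str | Path) -> Path:
    """Write a Cα-only multi-model PDB (MODEL/ENDMDL records)."""
    path = Path(path)
    with open(path, "w") as fh:
        for m in range(structure.n_models):
            fh.write(f"MODEL     {m + 1:4d}\n")
            for r in range(structure.residue_count):
                x, y, z = structure.models[m, r]
                fh.write(
                    f"ATOM  {r + 1:5d}  CA  GLY A{r + 1:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")
    return path


def extract_native_contacts(
    structure: MultiModelStructure,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    neighbor_exclusion: int = DEFAULT_NEIGHBOR_EXCLUSION,
) -> NativeContactSet:
    """Pairs whose Cα-Cα distance is below ``cutoff`` in every model.

    Only pairs with ``j - i >= neighbor_exclusion`` are considered, so direct
    sequence neighbors (always in contact through the backbone) are excluded.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    coords = structure.models  # (M, N, 3)
    diff = coords[:, :, None, :] - coords[:, None, :, :]
    dist = np.linalg.norm(diff, axis=-1)  # (M, N, N)
    within_all = np.all(dist < cutoff, axis=0)
    n = structure.residue_count
    ii, jj = np.triu_indices(n, k=max(neighbor_exclusion, 1))  # never pair i with itself
    keep = within_all[ii, jj]
    pairs = list(zip(ii[keep].tolist(), jj[keep].tolist()))
    return NativeContactSet(pairs, cutoff=cutoff, neighbor_exclusion=neighbor_exclusion)


def build_distance_features(
    coordinate_trajectories: list[np.ndarray],
    contacts: NativeContactSet,
    frame_interval: float,
) -> TrajectoryEnsemble:
    """Per-frame Euclidean Cα-Cα distances of the contact pairs, in Å.

    ``coordinate_trajectories`` is a list of (n_frames, n_residues, 3) arrays.
    Feature k of frame t is the distance of contact pair k at that frame.
    """
    pairs = contacts.as_array()
    if len(pairs) == 0:
        raise ValueError("contact set is empty")
    trajectories = []
    for coords in coordinate_trajectories:
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("each trajectory must have shape (n_frames, n_residues, 3)")
        if pairs.max() >= coords.shape[1]:
            raise ValueError(
                f"contact index {pairs.max()} out of range for "
                f"{coords.shape[1]} residues"
            )
        d = np.linalg.norm(
            coords[:, pairs[:, 0], :] - coords[:, pairs[:, 1], :], axis=-1
        )
        trajectories.append(Trajectory(d, (coords.shape[0] - 1) * frame_interval))
    return TrajectoryEnsemble(trajectories, frame_interval, "distances")


def write_contacts_csv(contacts: NativeContactSet, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            "# native contacts: 0-based residue indices, i < j; "
            f"cutoff={contacts.cutoff} A, neighbor_exclusion={contacts.neighbor_exclusion}\n"
        )
        fh.write("i,j\n")
        for i, j in contacts.pairs:
            fh.write(f"{i},{j}\n")
    return path


def read_contacts_csv(
    path: str | Path,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    neighbor_exclusion: int = DEFAULT_NEIGHBOR_EXCLUSION,
) -> NativeContactSet:
    arr = np.loadtxt(path, delimiter=",", skiprows=2, dtype=int, ndmin=2)
    pairs = [(int(i), int(j)) for i, j in arr]
    return NativeContactSet(pairs, cutoff=cutoff, neighbor_exclusion=neighbor_exclusion)
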