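"""Core containers for trajectories and topologies.

Coordinates are always in angstroms and the z axis is the bilayer normal
by convention. A :class:`Topology` is carried separately from the
coordinate frames because electron-density profiling needs per-atom
atomic numbers and partial charges, which PDB records cannot hold.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np

__all__ = ["AtomRecord", "Topology", "Frame", "Trajectory"]


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity plus the per-atom quantities downstream stages need.

    ``z_number`` is the atomic number Z and ``partial_charge`` the
    force-field partial charge in elementary-charge units; together they
    determine the electron count an atom contributes to a density profile.
    """

    index: int
    name: str
    res_name: str
    res_id: int
    chain: str
    element: str
    z_number: int
    partial_charge: float
    mass: float

    def __post_init__(self) -> None:
        if self.z_number < 1:
            raise ValueError(f"atom {self.index}: z_number must be >= 1, got {self.z_number}")
        if self.mass <= 0:
            raise ValueError(f"atom {self.index}: mass must be > 0, got {self.mass}")


@dataclass
class Topology:
    """Ordered atom metadata; order matches the coordinate rows of every frame."""

    atoms: Sequence[AtomRecord]
    box: Optional[Tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        idx = [a.index for a in self.atoms]
        if idx != list(range(len(idx))):
            raise ValueError("atom indices must be unique and contiguous from 0")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    def electrons(self, charge_sign: float = -1.0) -> np.ndarray:
        """Electron count per atom, Z + charge_sign * q (default Z - q)."""
        return np.array([a.z_number + charge_sign * a.partial_charge for a in self.atoms])


@dataclass
class Frame:
    """One set of Cartesian coordinates (N x 3, angstrom)."""

    coords: np.ndarray
    frame_index: int = 0
    time_ps: Optional[float] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be N x 3, got shape {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"frame {self.frame_index}: non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def copy(self) -> "Frame":
        return Frame(self.coords.copy(), self.frame_index, self.time_ps)


@dataclass
class Trajectory:
    """A topology plus an ordered sequence of frames with a uniform atom count."""

    topology: Topology
    frames: Sequence[Frame] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("trajectory must contain at least one frame")
        n = self.topology.n_atoms
        for f in self.frames:
            if f.n_atoms != n:
                raise ValueError(
                    f"frame {f.frame_index} has {f.n_atoms} atoms, topology has {n}"
                )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    def coords_array(self) -> np.ndarray:
        """All coordinates as a (n_frames, n_atoms, 3) array."""
        return np.stack([f.coords for f in self.frames])


def concat_trajectories(parts: Iterable[Trajectory]) -> Trajectory:
    parts = list(parts)
    if not parts:
        raise ValueError("no trajectories to concatenate")
    topo = parts[0].topology
    frames = []
    for p in parts:
        if p.topology.n_atoms != topo.n_atoms:
            raise ValueError("mismatched atom counts across trajectories")
        frames.extend(p.frames)
    frames = [replace(f, frame_index=i) for i, f in enumerate(frames)]
    return Trajectory(topo, frames)
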