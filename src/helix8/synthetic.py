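"""Synthetic stand-ins for the membrane-simulation inputs.

Three generators cover everything the pipeline consumes:

* an idealized amphipathic helix (backbone N/CA/C/O on calibrated
  cylindrical offsets) whose i -> i+4 hydrogen bonds can be broken one
  at a time from either terminus, emulating terminal fraying;
* bilayer leaflets as Gaussian point clouds in z (phosphate-, carbonyl-
  and sterol-like species) with controllable leaflet separation, for
  electron-density profiling;
* Gaussian-mixture clouds in the (RMSD, Rg) feature plane emulating the
  2-state and 6-state conformational landscapes.

All generators are pure functions of (spec, seed): reruns are
bit-identical.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from .core import AtomRecord, Frame, Topology, Trajectory
from .metrics import FeatureSeries

__all__ = [
    "H8_SEQUENCE_FULL",
    "H8_CORE_SEQUENCE",
    "HelixBuildSpec",
    "BilayerSpecies",
    "BilayerSpec",
    "MixtureComponent",
    "MixtureSpec",
    "build_ideal_helix",
    "perturb_unfold",
    "generate_helix_trajectory",
    "generate_bilayer",
    "generate_feature_cloud",
]

#: the full putative helix-8 segment of mGluR2, residues 817-834
H8_SEQUENCE_FULL = "ILFQPQKNVVSHRAPTS"
#: the analyzed helical core, residues 817-827 (11 residues, 7 i->i+4 bonds)
H8_CORE_SEQUENCE = H8_SEQUENCE_FULL[:11]

_AA_3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}

# Cylindrical offsets of backbone atoms relative to the CA trace,
# calibrated against a helix built from standard internal coordinates
# (phi=-57, psi=-47; scripts/calibrate_helix_geometry.py):
# (radius A, phase offset deg, z offset A). With the default rise/twist
# they put every O(i)..N(i+4) pair at ~2.85 A.
_BACKBONE_OFFSETS = {
    "N": (1.616, -25.70, -0.920),
    "C": (1.725, 25.79, 1.070),
    "O": (1.974, 19.41, 2.253),
}
_BACKBONE_ATOMS = ("N", "CA", "C", "O")
_ATOM_PROPS = {  # element, Z, mass (amu)
    "N": ("N", 7, 14.007),
    "CA": ("C", 6, 12.011),
    "C": ("C", 6, 12.011),
    "O": ("O", 8, 15.999),
}


@dataclass(frozen=True)
class HelixBuildSpec:
    """Geometry of the idealized helix (defaults: canonical alpha-helix)."""

    sequence: str = H8_CORE_SEQUENCE
    rise_per_residue: float = 1.5
    twist_per_residue: float = 100.0
    ca_radius: float = 2.3
    start_res_id: int = 817

    def __post_init__(self) -> None:
        if len(self.sequence) < 5:
            raise ValueError("sequence must have >= 5 residues for an i->i+4 bond")
        bad = [c for c in self.sequence if c.upper() not in _AA_3]
        if bad:
            raise ValueError(f"unknown residue letters: {bad}")

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def n_reference_bonds(self) -> int:
        return self.n_residues - 4

    @property
    def res_id_range(self) -> Tuple[int, int]:
        return (self.start_res_id, self.start_res_id + self.n_residues - 1)


def build_ideal_helix(spec: HelixBuildSpec = HelixBuildSpec()) -> Trajectory:
    """Build a one-frame ideal helix with backbone atoms N, CA, C, O.

    CA atoms sit on a cylinder (``ca_radius``) around the z axis with the
    given rise and twist per residue; N, C, O are placed at fixed
    calibrated cylindrical offsets from each CA. The topology carries
    element-correct atomic numbers and zero partial charges.
    """
    atoms: List[AtomRecord] = []
    coords: List[np.ndarray] = []
    idx = 0
    for i, letter in enumerate(spec.sequence.upper()):
        res_id = spec.start_res_id + i
        res_name = _AA_3[letter]
        theta0 = np.radians(spec.twist_per_residue * i)
        z0 = spec.rise_per_residue * i
        for name in _BACKBONE_ATOMS:
            if name == "CA":
                r, th, z = spec.ca_radius, theta0, z0
            else:
                dr, dphi, dz = _BACKBONE_OFFSETS[name]
                # radial/axial offsets scale with the spec so that stretching
                # the helix (e.g. 3x rise) separates the bonded partners
                r = dr * spec.ca_radius / 2.3
                th = theta0 + np.radians(dphi)
                z = z0 + dz * spec.rise_per_residue / 1.5
            coords.append(np.array([r * np.cos(th), r * np.sin(th), z]))
            element, znum, mass = _ATOM_PROPS[name]
            atoms.append(
                AtomRecord(idx, name, res_name, res_id, "A", element, znum, 0.0, mass)
            )
            idx += 1
    topo = Topology(atoms)
    return Trajectory(topo, [Frame(np.array(coords), frame_index=0)])


def perturb_unfold(
    helix: Frame,
    n_break: int,
    mode: str = "c_term",
    spec: HelixBuildSpec = HelixBuildSpec(),
    stretch: float = 2.0,
) -> Frame:
    """Deterministically fray a terminus so exactly ``n_break`` bonds break.

    The outermost ``n_break`` residues are displaced along the helix axis
    with a progressively growing shift (``stretch`` A per displaced
    residue, extending the backbone), which takes exactly the ``n_break``
    most terminal O(i)..N(i+4) contacts beyond the H-bond cutoff while
    leaving the remaining ones untouched. Requires the frame in build
    orientation (helix axis = z).
    """
    n_bonds = spec.n_reference_bonds
    if not 0 <= n_break <= n_bonds:
        raise ValueError(f"n_break must be in [0, {n_bonds}], got {n_break}")
    if mode not in ("c_term", "n_term"):
        raise ValueError(f"mode must be 'c_term' or 'n_term', got {mode!r}")
    out = helix.copy()
    if n_break == 0:
        return out
    n_res = spec.n_residues
    n_bb = len(_BACKBONE_ATOMS)
    if helix.n_atoms != n_res * n_bb:
        raise ValueError("frame does not match the helix build spec")
    for k in range(n_break):
        # k-th displaced residue counted from the fraying terminus inward
        if mode == "c_term":
            res_pos = n_res - 1 - k
            dz = stretch * (n_break - k)
        else:
            res_pos = k
            dz = -stretch * (n_break - k)
        sl = slice(res_pos * n_bb, (res_pos + 1) * n_bb)
        out.coords[sl, 2] += dz
    return out


def generate_helix_trajectory(
    schedule: Sequence[Tuple[int, int]],
    spec: HelixBuildSpec = HelixBuildSpec(),
    seed: int = 0,
    jitter_sd: float = 0.05,
    rigid_motion: bool = True,
    mode: str = "c_term",
) -> Trajectory:
    """Concatenate frayed-helix frames per a (n_break, n_frames) schedule.

    Every frame is a ``perturb_unfold`` output plus seeded Gaussian
    coordinate jitter (default 0.05 A, far below the H-bond cutoff
    margin) and, optionally, a random rigid-body rotation/translation to
    exercise the superposition step downstream.
    """
    if not schedule:
        raise ValueError("schedule must be nonempty")
    base = build_ideal_helix(spec)
    rng = np.random.default_rng(seed)
    frames: List[Frame] = []
    fi = 0
    for n_break, n_frames in schedule:
        ref = perturb_unfold(base.frames[0], n_break, mode=mode, spec=spec)
        for _ in range(n_frames):
            X = ref.coords + rng.normal(0.0, jitter_sd, ref.coords.shape)
            if rigid_motion:
                R = Rotation.random(rng=rng).as_matrix()
                t = rng.uniform(-10.0, 10.0, 3)
                X = X @ R.T + t
            frames.append(Frame(X, frame_index=fi))
            fi += 1
    return Trajectory(base.topology, frames)


@dataclass(frozen=True)
class BilayerSpecies:
    """One point-atom species with mirrored leaflet Gaussians in z."""

    label: str  # residue label, e.g. "PO4"
    atom_name: str  # e.g. "P"
    atoms_per_leaflet: int
    leaflet_mean_z: float  # +z leaflet mean; the -z leaflet mirrors it
    leaflet_sd_z: float
    z_number: int
    partial_charge: float = 0.0
    mass: float = 30.974

    def __post_init__(self) -> None:
        if self.atoms_per_leaflet < 1:
            raise ValueError("atoms_per_leaflet must be >= 1")
        if self.leaflet_sd_z < 0:
            raise ValueError("leaflet_sd_z must be >= 0")


@dataclass(frozen=True)
class BilayerSpec:
    species: Tuple[BilayerSpecies, ...]
    box: Tuple[float, float] = (94.0, 94.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("bilayer spec needs at least one species")
        if self.box[0] * self.box[1] <= 0:
            raise ValueError("box cross-sectional area must be positive")


def generate_bilayer(spec: BilayerSpec, n_frames: int = 1) -> Trajectory:
    """Sample bilayer point atoms: z ~ Normal per leaflet, x/y uniform.

    One random stream (seeded by ``spec.seed``) is consumed sequentially
    across frames, so frames differ but the whole trajectory is a pure
    function of the spec.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    lx, ly = spec.box
    atoms: List[AtomRecord] = []
    idx = 0
    for sp in spec.species:
        for _leaflet in (1, -1):
            for _ in range(sp.atoms_per_leaflet):
                atoms.append(
                    AtomRecord(
                        idx,
                        sp.atom_name,
                        sp.label[:4],
                        idx % 9999 + 1,
                        "M",
                        sp.atom_name[:1],
                        sp.z_number,
                        sp.partial_charge,
                        sp.mass,
                    )
                )
                idx += 1
    zmax = max(abs(sp.leaflet_mean_z) + 6 * sp.leaflet_sd_z for sp in spec.species)
    topo = Topology(atoms, box=(lx, ly, 2 * zmax))
    rng = np.random.default_rng(spec.seed)
    frames = []
    for fi in range(n_frames):
        blocks = []
        for sp in spec.species:
            for leaflet in (1, -1):
                n = sp.atoms_per_leaflet
                xy = rng.uniform([0, 0], [lx, ly], size=(n, 2))
                z = rng.normal(leaflet * sp.leaflet_mean_z, sp.leaflet_sd_z, n)
                blocks.append(np.column_stack([xy, z]))
        frames.append(Frame(np.vstack(blocks), frame_index=fi))
    return Trajectory(topo, frames)


@dataclass(frozen=True)
class MixtureComponent:
    weight: float
    mean_rmsd: float
    mean_rg: float
    sd_rmsd: float
    sd_rg: float
    correlation: float = 0.0


@dataclass(frozen=True)
class MixtureSpec:
    components: Tuple[MixtureComponent, ...]
    n_samples: int = 4000
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.array([c.weight for c in self.components])
        if len(w) == 0 or np.any(w <= 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("component weights must be positive and sum to 1")
        for c in self.components:
            if c.sd_rmsd <= 0 or c.sd_rg <= 0:
                raise ValueError("component sds must be > 0")
            if not -1 < c.correlation < 1:
                raise ValueError("|correlation| must be < 1")


def generate_feature_cloud(spec: MixtureSpec) -> FeatureSeries:
    """Draw (RMSD, Rg) samples from the Gaussian mixture.

    RMSD draws are reflected at zero (an RMSD cannot be negative); with
    component means several sds above zero this is a negligible
    truncation.
    """
    rng = np.random.default_rng(spec.seed)
    weights = np.array([c.weight for c in spec.components])
    labels = rng.choice(len(weights), size=spec.n_samples, p=weights)
    out = np.empty((spec.n_samples, 2))
    for k, c in enumerate(spec.components):
        m = labels == k
        n = int(m.sum())
        if n == 0:
            continue
        cov = np.array(
            [
                [c.sd_rmsd**2, c.correlation * c.sd_rmsd * c.sd_rg],
                [c.correlation * c.sd_rmsd * c.sd_rg, c.sd_rg**2],
            ]
        )
        out[m] = rng.multivariate_normal([c.mean_rmsd, c.mean_rg], cov, size=n)
    out[:, 0] = np.abs(out[:, 0])
    return FeatureSeries(np.arange(spec.n_samples), out[:, 0], out[:, 1])
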