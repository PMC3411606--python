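"""Per-frame helix observables.

Three observables drive the whole analysis:

* **helicity** — the fraction of reference i -> i+4 backbone hydrogen
  bonds still intact, reported as a percentage. For an 11-residue helical
  segment there are 7 reference bonds, so values fall on the lattice
  0, 14.29, 28.57, ..., 100.
* **RMSD** from the starting structure after optimal rigid superposition
  of the helix backbone (Kabsch algorithm).
* **radius of gyration** of the helix heavy atoms (mass-weighted by
  default).

The (RMSD, Rg) pairs per frame form the 2-D feature space in which
conformational states are identified.
"""
from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd

from .core import Frame, Topology, Trajectory
from .select import select

__all__ = [
    "HelixDefinition",
    "HBondCriterion",
    "HelicityResult",
    "FeatureSeries",
    "detect_backbone_hbonds",
    "helicity_percent",
    "kabsch_superpose",
    "radius_of_gyration",
    "compute_features",
]

#: membrane-buried face of the amphipathic helix, main-text residue set
HYDROPHOBIC_FACE_MAIN: Set[int] = {821, 822, 824, 825, 826, 828, 829}
#: alternative residue set as labelled in the supplementary structure figure
HYDROPHOBIC_FACE_ALT: Set[int] = {821, 823, 824, 825, 826, 829, 830}


@dataclass(frozen=True)
class HBondCriterion:
    """Backbone H-bond test: heavy-atom O(i)...N(i+4) distance cutoff.

    Synthetic topologies carry no hydrogens, so the default is a plain
    3.5 A donor-acceptor distance. With ``require_hydrogen`` the bond
    must additionally have an N-H...O angle >= ``min_NHO_angle`` degrees.
    """

    max_ON_distance: float = 3.5
    require_hydrogen: bool = False
    min_NHO_angle: float = 120.0

    def __post_init__(self) -> None:
        if self.max_ON_distance <= 0:
            raise ValueError("max_ON_distance must be > 0")


@dataclass
class HelixDefinition:
    """The helical segment under analysis.

    ``reference_bonds`` are (acceptor_res_id, donor_res_id) pairs, i.e.
    O(i) -> N(i+4), frozen from the starting structure. The default
    segment is the 11-residue helical core 817-827, giving 7 bonds.
    """

    res_id_range: Tuple[int, int] = (817, 827)
    reference_bonds: List[Tuple[int, int]] = field(default_factory=list)
    hydrophobic_face: Set[int] = field(default_factory=lambda: set(HYDROPHOBIC_FACE_MAIN))

    def __post_init__(self) -> None:
        lo, hi = self.res_id_range
        if not self.reference_bonds:
            self.reference_bonds = [(i, i + 4) for i in range(lo, hi - 3)]
        for acc, don in self.reference_bonds:
            if not (lo <= acc <= hi and lo <= don <= hi):
                raise ValueError(
                    f"reference bond ({acc},{don}) outside residue range {lo}-{hi}"
                )
        if not self.reference_bonds:
            raise ValueError("reference_bonds must be nonempty")

    @property
    def reference_count(self) -> int:
        return len(self.reference_bonds)

    @classmethod
    def from_reference_frame(
        cls,
        frame: Frame,
        topology: Topology,
        res_id_range: Tuple[int, int] = (817, 827),
        criterion: Optional[HBondCriterion] = None,
        **kwargs,
    ) -> "HelixDefinition":
        """Freeze the reference bond set from the bonds intact in a frame."""
        trial = cls(res_id_range=res_id_range, **kwargs)
        bonds = detect_backbone_hbonds(frame, topology, trial, criterion or HBondCriterion())
        if not bonds:
            raise ValueError("reference frame has no intact i->i+4 backbone H-bonds")
        return cls(res_id_range=res_id_range, reference_bonds=bonds, **kwargs)


@dataclass(frozen=True)
class HelicityResult:
    percent_folded: float
    intact_bonds: Tuple[Tuple[int, int], ...]
    reference_count: int

    def __str__(self) -> str:
        return f"{self.percent_folded:.2f}% folded ({len(self.intact_bonds)}/{self.reference_count} H-bonds)"


@dataclass
class FeatureSeries:
    """Per-frame (RMSD, Rg) records, the 2-D space of the density analysis."""

    frame_index: np.ndarray
    rmsd: np.ndarray
    rg: np.ndarray
    run: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        self.rmsd = np.asarray(self.rmsd, dtype=float)
        self.rg = np.asarray(self.rg, dtype=float)
        if not (len(self.frame_index) == len(self.rmsd) == len(self.rg)):
            raise ValueError("frame_index, rmsd, rg must have equal length")
        if self.run is None:
            self.run = np.zeros(len(self.rmsd), dtype=int)
        else:
            self.run = np.asarray(self.run, dtype=int)
        if not np.all(np.isfinite(self.rmsd)) or not np.all(np.isfinite(self.rg)):
            raise ValueError("non-finite feature values")
        if np.any(self.rmsd < 0) or np.any(self.rg <= 0):
            raise ValueError("rmsd must be >= 0 and rg > 0")

    def __len__(self) -> int:
        return len(self.rmsd)

    @property
    def points(self) -> np.ndarray:
        """(n, 2) array of (rmsd, rg) pairs."""
        return np.column_stack([self.rmsd, self.rg])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame": self.frame_index, "rmsd_A": self.rmsd, "rg_A": self.rg, "run": self.run}
        )

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "FeatureSeries":
        df = pd.read_csv(path, sep="\t")
        run = df["run"].to_numpy() if "run" in df.columns else None
        return cls(df["frame"].to_numpy(), df["rmsd_A"].to_numpy(), df["rg_A"].to_numpy(), run)

    @classmethod
    def concatenate(cls, parts: Sequence["FeatureSeries"]) -> "FeatureSeries":
        if not parts:
            raise ValueError("nothing to concatenate")
        return cls(
            np.concatenate([p.frame_index for p in parts]),
            np.concatenate([p.rmsd for p in parts]),
            np.concatenate([p.rg for p in parts]),
            np.concatenate([p.run for p in parts]),
        )


def _backbone_atom_map(topology: Topology, helixdef: HelixDefinition, atom_name: str) -> dict:
    lo, hi = helixdef.res_id_range
    out = {}
    for a in topology.atoms:
        if a.name == atom_name and lo <= a.res_id <= hi:
            out[a.res_id] = a.index
    return out


def detect_backbone_hbonds(
    frame: Frame,
    topology: Topology,
    helixdef: HelixDefinition,
    criterion: Optional[HBondCriterion] = None,
) -> List[Tuple[int, int]]:
    """Return the reference (acceptor, donor) pairs intact in this frame.

    A pair (i, i+4) is intact when the carbonyl O of residue i lies within
    ``max_ON_distance`` of the backbone N of residue i+4 (and, optionally,
    the N-H...O angle test passes).
    """
    criterion = criterion or HBondCriterion()
    o_map = _backbone_atom_map(topology, helixdef, "O")
    n_map = _backbone_atom_map(topology, helixdef, "N")
    needed_acc = {acc for acc, _ in helixdef.reference_bonds}
    needed_don = {don for _, don in helixdef.reference_bonds}
    for res in sorted(needed_acc - set(o_map)):
        raise ValueError(f"residue {res}: backbone O atom missing")
    for res in sorted(needed_don - set(n_map)):
        raise ValueError(f"residue {res}: backbone N atom missing")
    h_map = {}
    if criterion.require_hydrogen:
        for hname in ("H", "HN"):
            h_map.update(_backbone_atom_map(topology, helixdef, hname))
    intact = []
    X = frame.coords
    for acc, don in helixdef.reference_bonds:
        o, n = X[o_map[acc]], X[n_map[don]]
        if np.linalg.norm(o - n) > criterion.max_ON_distance:
            continue
        if criterion.require_hydrogen:
            if don not in h_map:
                raise ValueError(f"residue {don}: amide hydrogen missing but required")
            h = X[h_map[don]]
            v1, v2 = n - h, o - h
            cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
            if np.degrees(np.arccos(np.clip(cosang, -1, 1))) < criterion.min_NHO_angle:
                continue
        intact.append((acc, don))
    return intact


def _round_half_up(x: float, ndigits: int = 2) -> float:
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(x).quantize(q, rounding=decimal.ROUND_HALF_UP))


def helicity_percent(
    frame: Frame,
    topology: Topology,
    helixdef: HelixDefinition,
    criterion: Optional[HBondCriterion] = None,
) -> HelicityResult:
    """Percent of reference backbone H-bonds intact, to 2 decimals (half-up).

    With the default 7-bond reference the attainable values are exactly
    k/7 x 100: 0, 14.29, 28.57, 42.86, 57.14, 71.43, 85.71, 100.
    """
    intact = detect_backbone_hbonds(frame, topology, helixdef, criterion)
    ref = helixdef.reference_count
    # exact rational before rounding, so 5/7 -> 71.43 not 71.42
    pct = decimal.Decimal(100 * len(intact)) / decimal.Decimal(ref)
    return HelicityResult(_round_half_up(float(pct)), tuple(intact), ref)


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    subset: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` where
    ``mobile @ rotation.T + translation`` best fits the reference over
    the given atom subset (all atoms if None). The rotation is proper
    (det = +1); the RMSD is the least-squares minimum over the subset.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if subset is None:
        P, Q = mobile, reference
    else:
        subset = np.asarray(subset, int)
        P, Q = mobile[subset], reference[subset]
    if len(P) < 3 or len(P) != len(Q):
        raise ValueError("superposition needs >= 3 paired atoms")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    scale = max(np.linalg.norm(P0), np.linalg.norm(Q0))
    if scale == 0 or S[1] <= 1e-10 * max(S[0], 1e-300):
        raise ValueError("degenerate atom subset (coincident or collinear)")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cq - R @ cp
    diff = (P0 @ R.T) - Q0
    rmsd = float(np.sqrt((diff**2).sum() / len(P)))
    return R, t, rmsd


def radius_of_gyration(
    frame: Frame,
    topology: Topology,
    subset: Union[str, np.ndarray],
    mass_weighted: bool = True,
) -> float:
    """Root-mean-square distance of the subset atoms from their centroid."""
    idx = select(topology, subset)
    if idx.size < 1:
        raise ValueError("empty selection for radius of gyration")
    X = frame.coords[idx]
    w = topology.masses()[idx] if mass_weighted else np.ones(len(idx))
    centroid = (w[:, None] * X).sum(axis=0) / w.sum()
    return float(np.sqrt((w * ((X - centroid) ** 2).sum(axis=1)).sum() / w.sum()))


def helix_backbone_indices(topology: Topology, helixdef: HelixDefinition) -> np.ndarray:
    lo, hi = helixdef.res_id_range
    return select(topology, f"name=N,CA,C,O & res_id in [{lo},{hi}]")


def helix_heavy_indices(topology: Topology, helixdef: HelixDefinition) -> np.ndarray:
    lo, hi = helixdef.res_id_range
    idx = select(topology, f"res_id in [{lo},{hi}]")
    heavy = [i for i in idx if topology.atoms[i].element.upper() != "H"]
    return np.asarray(heavy, dtype=int)


def compute_features(
    trajectory: Trajectory,
    helixdef: HelixDefinition,
    reference_frame: Optional[Frame] = None,
    mass_weighted_rg: bool = True,
    superpose_subset: Optional[np.ndarray] = None,
) -> FeatureSeries:
    """Per-frame (RMSD, Rg) features.

    Each frame is rigidly superposed on the reference over the helix
    backbone (N, CA, C, O of the helical segment, or an explicit subset),
    and the RMSD is taken over that same atom set; Rg is computed over
    the helix heavy atoms of the same frame.
    """
    topo = trajectory.topology
    ref = reference_frame or trajectory.frames[0]
    bb = superpose_subset if superpose_subset is not None else helix_backbone_indices(topo, helixdef)
    if len(bb) < 3:
        raise ValueError("helix backbone subset has fewer than 3 atoms")
    heavy = helix_heavy_indices(topo, helixdef)
    rmsds, rgs, idxs = [], [], []
    for f in trajectory.frames:
        _, _, rmsd = kabsch_superpose(f.coords, ref.coords, bb)
        rmsds.append(rmsd)
        rgs.append(radius_of_gyration(f, topo, heavy, mass_weighted=mass_weighted_rg))
        idxs.append(f.frame_index)
    return FeatureSeries(np.array(idxs), np.array(rmsds), np.array(rgs))
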