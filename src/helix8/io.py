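"""Trajectory and topology file I/O.

Trajectories travel as multi-model PDB (MODEL/ENDMDL delimited, angstrom
coordinates); topologies as delimited tables with one row per atom. The
two are kept separate because the density stage needs atomic numbers and
partial charges, which the PDB format cannot carry.
"""
from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import AtomRecord, Frame, Topology, Trajectory

__all__ = [
    "read_multi_model_pdb",
    "write_multi_model_pdb",
    "read_topology_table",
    "write_topology_table",
]

TOPOLOGY_COLUMNS = [
    "index",
    "name",
    "res_name",
    "res_id",
    "chain",
    "element",
    "z_number",
    "partial_charge",
    "mass",
]

# default masses/Z for element fallback when a PDB is read without a sidecar
_ELEMENT_Z = {"H": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16}
_ELEMENT_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974, "S": 32.06}


def _scan_model_atom_counts(path: Path) -> list:
    """Count ATOM/HETATM lines per MODEL block (whole file = 1 block if none)."""
    counts = []
    current = 0
    seen_model = False
    n_lines = 0
    with open(path) as fh:
        for line in fh:
            n_lines += 1
            rec = line[:6].strip()
            if rec == "MODEL":
                seen_model = True
                current = 0
            elif rec == "ENDMDL":
                counts.append(current)
            elif rec in ("ATOM", "HETATM"):
                current += 1
    if n_lines == 0:
        raise ValueError(f"{path}: empty file")
    if not seen_model:
        counts = [current]
    elif current and not counts:
        counts = [current]
    if not counts or all(c == 0 for c in counts):
        raise ValueError(f"{path}: no ATOM/HETATM records found")
    return counts


def read_multi_model_pdb(
    path: Union[str, Path], topology: Optional[Topology] = None
) -> Trajectory:
    """Read a (multi-model) PDB file into a :class:`Trajectory`.

    Each MODEL/ENDMDL block becomes one frame; a single-model file yields
    one frame. If ``topology`` is given it overrides the per-atom metadata
    parsed from the PDB (which lacks charges and exact masses); atom counts
    must then agree.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    counts = _scan_model_atom_counts(path)
    ref = counts[0]
    for i, c in enumerate(counts, start=1):
        if c != ref:
            raise ValueError(
                f"{path}: model {i} has {c} atoms, expected {ref} (models must match)"
            )

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path), in_memory=True)

    if topology is None:
        names = [str(n) for n in u.atoms.names]
        try:
            elements = [str(e) if str(e).strip() else "" for e in u.atoms.elements]
        except Exception:
            elements = ["" for _ in names]
        resnames = [str(r) for r in u.atoms.resnames]
        resids = [int(r) for r in u.atoms.resids]
        try:
            chains = [str(c) if str(c).strip() else "A" for c in u.atoms.chainIDs]
        except Exception:
            chains = ["A"] * len(names)
        atoms = []
        for i, name in enumerate(names):
            el = elements[i].strip().capitalize()
            if not el:
                # fall back to the first alphabetic character of the atom name
                el = next((ch for ch in name if ch.isalpha()), "C").upper()
            z = _ELEMENT_Z.get(el, 6)
            mass = _ELEMENT_MASS.get(el, 12.011)
            atoms.append(
                AtomRecord(i, name, resnames[i], resids[i], chains[i], el, z, 0.0, mass)
            )
        box = None
        if u.dimensions is not None and np.all(u.dimensions[:3] > 0):
            box = tuple(float(x) for x in u.dimensions[:3])
        topology = Topology(atoms, box=box)
    elif topology.n_atoms != ref:
        raise ValueError(
            f"{path}: file has {ref} atoms per model, topology has {topology.n_atoms}"
        )

    frames = [
        Frame(u.atoms.positions.astype(float).copy(), frame_index=i)
        for i, _ts in enumerate(u.trajectory)
    ]
    return Trajectory(topology, frames)


def write_multi_model_pdb(traj: Trajectory, path: Union[str, Path]) -> None:
    """Write a trajectory as a multi-model PDB (coordinates to 0.001 A).

    Occupancy/B-factor are written as 1.00/0.00; residue ids wrap at 9999
    and atom serials at 99999 as the fixed columns require.
    """
    path = Path(path)
    atoms = traj.topology.atoms
    with open(path, "w") as fh:
        if traj.topology.box is not None:
            lx, ly, lz = traj.topology.box
            fh.write(
                f"CRYST1{lx:9.3f}{ly:9.3f}{lz:9.3f}{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
            )
        for m, frame in enumerate(traj.frames, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            for a, (x, y, z) in zip(atoms, frame.coords):
                serial = a.index % 99999 + 1
                resid = (a.res_id - 1) % 9999 + 1 if a.res_id > 0 else a.res_id
                name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                fh.write(
                    f"ATOM  {serial:5d} {name:4.4s} {a.res_name:<4.4s}"
                    f"{a.chain[:1]}{resid:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                    f"{a.element:>2.2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_topology_table(path: Union[str, Path]) -> Topology:
    """Read a CSV/TSV atom table (header: index,name,...,mass) into a Topology."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, comment="#")
    missing = [c for c in TOPOLOGY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing topology columns: {', '.join(missing)}")
    if len(df) == 0:
        raise ValueError(f"{path}: empty topology (no atom rows)")
    atoms = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        rec = dict(zip(df.columns, row))
        try:
            atoms.append(
                AtomRecord(
                    index=int(rec["index"]),
                    name=str(rec["name"]),
                    res_name=str(rec["res_name"]),
                    res_id=int(rec["res_id"]),
                    chain=str(rec["chain"]),
                    element=str(rec["element"]),
                    z_number=int(rec["z_number"]),
                    partial_charge=float(rec["partial_charge"]),
                    mass=float(rec["mass"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: bad numeric value on row {row_no}: {exc}") from exc
    box = None
    return Topology(atoms, box=box)


def write_topology_table(topology: Topology, path: Union[str, Path]) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    rows = [
        {
            "index": a.index,
            "name": a.name,
            "res_name": a.res_name,
            "res_id": a.res_id,
            "chain": a.chain,
            "element": a.element,
            "z_number": a.z_number,
            "partial_charge": a.partial_charge,
            "mass": a.mass,
        }
        for a in topology.atoms
    ]
    pd.DataFrame(rows, columns=TOPOLOGY_COLUMNS).to_csv(path, sep=sep, index=False)
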