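"""Conformational-state analysis in the (RMSD, Rg) plane.

The probability density over the 2-D feature space is estimated with a
Gaussian-product-kernel KDE on a regular grid; strict local maxima of
the grid density are the conformational states; frames are assigned to
states by steepest-ascent hill climbing on the grid. Per-state
probabilities are assigned-frame fractions, and per-state average
structures are coordinate means after backbone superposition.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage

from .core import Frame, Topology, Trajectory
from .metrics import (
    FeatureSeries,
    HBondCriterion,
    HelicityResult,
    HelixDefinition,
    helicity_percent,
    helix_backbone_indices,
    kabsch_superpose,
)

logger = logging.getLogger(__name__)

__all__ = ["KDEResult", "Mode", "StateModel", "kde2d", "find_modes", "assign_frames",
           "state_average_structure"]


@dataclass
class KDEResult:
    """Gaussian-product KDE evaluated on a regular (rmsd, rg) lattice."""

    x: np.ndarray  # rmsd grid centers
    y: np.ndarray  # rg grid centers
    density: np.ndarray  # shape (len(x), len(y)), >= 0
    bandwidths: Tuple[float, float]

    @property
    def cell_area(self) -> float:
        return float((self.x[1] - self.x[0]) * (self.y[1] - self.y[0]))

    def mass(self) -> float:
        """Riemann sum of the density over the grid (should be ~1)."""
        return float(self.density.sum() * self.cell_area)

    def cell_of(self, rmsd: float, rg: float) -> Tuple[int, int]:
        """Grid cell containing a point, clipped to the grid."""
        i = int(np.clip(np.round((rmsd - self.x[0]) / (self.x[1] - self.x[0])), 0, len(self.x) - 1))
        j = int(np.clip(np.round((rg - self.y[0]) / (self.y[1] - self.y[0])), 0, len(self.y) - 1))
        return i, j

    def to_tsv(self, path: Union[str, Path]) -> None:
        """Density grid as TSV matrix (rows = rmsd cells, cols = rg cells)."""
        header = "\t".join(f"{v:.6f}" for v in self.y)
        np.savetxt(path, self.density, delimiter="\t", header="rg:\t" + header, fmt="%.8e")


def _bandwidths(points: np.ndarray, rule) -> Tuple[float, float]:
    n, d = points.shape
    sd = points.std(axis=0, ddof=1)
    if isinstance(rule, (tuple, list, np.ndarray)):
        return float(rule[0]), float(rule[1])
    if isinstance(rule, (int, float)):
        return float(rule), float(rule)
    if rule == "scott":
        factor = n ** (-1.0 / (d + 4))
    elif rule == "silverman":
        factor = (n * (d + 2) / 4.0) ** (-1.0 / (d + 4))
    else:
        raise ValueError(f"unknown bandwidth rule: {rule!r}")
    return float(sd[0] * factor), float(sd[1] * factor)


def kde2d(
    features: FeatureSeries,
    bandwidth_rule: Union[str, float, Tuple[float, float]] = "scott",
    grid_size: int = 128,
    margin_bandwidths: float = 3.0,
) -> KDEResult:
    """Gaussian-product-kernel density of the features on a regular grid.

    The grid spans the data range plus ``margin_bandwidths`` bandwidths on
    each side. Per-dimension bandwidths come from Scott's rule by default
    (``n**(-1/6) * sd``; Silverman's rule and fixed values are accepted).
    The evaluation is algebraically identical to the naive double loop
    ``sum_i K(x - x_i) K(y - y_i) / n`` but vectorized as a matrix
    product over the separable kernel.
    """
    pts = features.points
    if len(pts) < 2:
        raise ValueError("KDE needs at least 2 frames")
    if np.any(pts.std(axis=0) == 0):
        raise ValueError(
            "zero variance in a feature dimension; pass a fixed bandwidth instead"
        )
    hx, hy = _bandwidths(pts, bandwidth_rule)
    if hx <= 0 or hy <= 0:
        raise ValueError("bandwidths must be positive")
    gx = np.linspace(pts[:, 0].min() - margin_bandwidths * hx,
                     pts[:, 0].max() + margin_bandwidths * hx, grid_size)
    gy = np.linspace(pts[:, 1].min() - margin_bandwidths * hy,
                     pts[:, 1].max() + margin_bandwidths * hy, grid_size)
    norm = 1.0 / (2 * np.pi * hx * hy * len(pts))
    Ax = np.exp(-0.5 * ((gx[:, None] - pts[None, :, 0]) / hx) ** 2)
    Ay = np.exp(-0.5 * ((gy[:, None] - pts[None, :, 1]) / hy) ** 2)
    density = norm * (Ax @ Ay.T)
    return KDEResult(gx, gy, density, (hx, hy))


def kde2d_brute(points: np.ndarray, probes: np.ndarray, hx: float, hy: float) -> np.ndarray:
    """Direct double-loop KDE at probe points (independent check path)."""
    out = np.zeros(len(probes))
    for j, (px, py) in enumerate(probes):
        s = 0.0
        for x, y in points:
            s += np.exp(-0.5 * ((px - x) / hx) ** 2) * np.exp(-0.5 * ((py - y) / hy) ** 2)
        out[j] = s / (2 * np.pi * hx * hy * len(points))
    return out


@dataclass(frozen=True)
class Mode:
    label: int
    rmsd: float
    rg: float
    density: float
    cell: Tuple[int, int]


def find_modes(
    kde: KDEResult,
    min_rel_density: float = 0.05,
    min_separation_bandwidths: float = 1.0,
) -> List[Mode]:
    """Strict 8-neighborhood local maxima of the grid density.

    Maxima below ``min_rel_density`` of the global maximum are dropped as
    sampling ripples, as are maxima closer than
    ``min_separation_bandwidths`` (in bandwidth-scaled distance) to a
    denser one: the KDE cannot resolve structure below its own bandwidth,
    so sub-bandwidth maxima are noise on a single mode. Modes are
    labeled 1..k in order of decreasing density.
    """
    D = kde.density
    hx, hy = kde.bandwidths
    footprint = np.ones((3, 3), bool)
    footprint[1, 1] = False
    neigh_max = ndimage.maximum_filter(D, footprint=footprint, mode="constant", cval=-np.inf)
    mask = (D > neigh_max) & (D >= min_rel_density * D.max())
    cells = np.argwhere(mask)
    order = np.argsort(-D[mask])
    kept: List[Mode] = []
    for k in order:
        i, j = cells[k]
        x, y = float(kde.x[i]), float(kde.y[j])
        sep = min(
            (np.hypot((x - m.rmsd) / hx, (y - m.rg) / hy) for m in kept),
            default=np.inf,
        )
        if sep < min_separation_bandwidths:
            continue
        kept.append(Mode(len(kept) + 1, x, y, float(D[i, j]), (int(i), int(j))))
    return kept


@dataclass
class StateModel:
    """Detected modes plus the per-frame state assignment."""

    modes: List[Mode]
    assignment: np.ndarray  # per-frame state label, 1..k
    counts: np.ndarray  # frames per state
    n_outside_grid: int = 0

    @property
    def n_states(self) -> int:
        return len(self.modes)

    @property
    def probabilities(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    def to_json(self, path: Union[str, Path], extra: Optional[dict] = None) -> None:
        payload = {
            "n_states": self.n_states,
            "modes": [
                {"state": m.label, "rmsd_A": m.rmsd, "rg_A": m.rg, "density": m.density}
                for m in self.modes
            ],
            "probabilities": {str(m.label): float(p) for m, p in zip(self.modes, self.probabilities)},
            "n_frames": int(self.counts.sum()),
            "n_outside_grid": self.n_outside_grid,
        }
        if extra:
            payload.update(extra)
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _hill_climb(D: np.ndarray, start: Tuple[int, int], cache: Dict) -> Tuple[int, int]:
    """Steepest ascent to a local maximum; ties -> lowest flat cell index."""
    path = []
    cell = start
    nx, ny = D.shape
    while cell not in cache:
        path.append(cell)
        i, j = cell
        i0, i1 = max(i - 1, 0), min(i + 2, nx)
        j0, j1 = max(j - 1, 0), min(j + 2, ny)
        block = D[i0:i1, j0:j1]
        best = np.flatnonzero(block == block.max())
        bi, bj = np.unravel_index(best[0], block.shape)  # lowest flat index on ties
        nxt = (i0 + int(bi), j0 + int(bj))
        if nxt == cell:
            cache[cell] = cell
            break
        cell = nxt
    top = cache[cell]
    for c in path:
        cache[c] = top
    return top


def assign_frames(
    features: FeatureSeries,
    kde: KDEResult,
    modes: Sequence[Mode],
) -> StateModel:
    """Assign every frame to a state by hill climbing on the density grid.

    Each frame starts from its containing grid cell (frames outside the
    grid are snapped to the nearest cell and counted, never dropped) and
    climbs to a local maximum; the reached maximum's mode gives the
    state. Climbs that end on a sub-threshold ripple maximum are
    attributed to the nearest mode in feature units.
    """
    if not modes:
        raise ValueError("no modes to assign frames to")
    D = kde.density
    mode_by_cell = {m.cell: m.label for m in modes}
    mode_xy = np.array([[m.rmsd, m.rg] for m in modes])
    cache: Dict = {}
    labels = np.empty(len(features), dtype=int)
    n_outside = 0
    for k, (x, yv) in enumerate(features.points):
        if not (kde.x[0] <= x <= kde.x[-1] and kde.y[0] <= yv <= kde.y[-1]):
            n_outside += 1
        cell = kde.cell_of(x, yv)
        top = _hill_climb(D, cell, cache)
        if top in mode_by_cell:
            labels[k] = mode_by_cell[top]
        else:
            tx, ty = kde.x[top[0]], kde.y[top[1]]
            labels[k] = modes[int(np.argmin(((mode_xy - [tx, ty]) ** 2).sum(axis=1)))].label
    if n_outside:
        logger.info("assign_frames: %d frame(s) outside the KDE grid were snapped", n_outside)
    counts = np.array([(labels == m.label).sum() for m in modes])
    return StateModel(list(modes), labels, counts, n_outside)


def state_average_structure(
    trajectory: Trajectory,
    model: StateModel,
    state_label: int,
    helixdef: HelixDefinition,
    criterion: Optional[HBondCriterion] = None,
) -> Tuple[Frame, HelicityResult]:
    """Coordinate-wise mean structure of a state's member frames.

    Members are superposed on the first member over the helix backbone
    before averaging (so rigid-body motion does not smear the mean), and
    the helicity of the mean structure is reported alongside it.
    """
    members = [f for f, lab in zip(trajectory.frames, model.assignment) if lab == state_label]
    if not members:
        raise ValueError(f"state {state_label} has no member frames")
    topo = trajectory.topology
    bb = helix_backbone_indices(topo, helixdef)
    ref = members[0]
    acc = np.zeros_like(ref.coords)
    for f in members:
        R, t, _ = kabsch_superpose(f.coords, ref.coords, bb)
        acc += f.coords @ R.T + t
    mean = Frame(acc / len(members), frame_index=-1)
    return mean, helicity_percent(mean, topo, helixdef, criterion)
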