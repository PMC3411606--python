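"""End-to-end orchestration: synthesize -> features -> states -> densities.

A single :class:`RunConfig` (YAML-loadable) drives every stage and every
output is a pure function of (config, seed): rerunning a config produces
byte-identical summaries. Each stage writes its files under the output
directory so any stage can be re-run from its predecessor's outputs.

For a synthetic preset the run covers both axes of the analysis:

* the conformational landscape — feature-space mixture -> KDE -> modes
  -> state probabilities, plus a structural helix trajectory (fraying
  schedule) -> per-state average structures and their helicities;
* the membrane geometry — bilayer point clouds -> electron density
  profiles -> PO4 and carbonyl peak-to-peak thickness, plus the
  deterministic helix-vs-PO4 offset system.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import yaml

from . import __version__
from .core import Trajectory
from .density import electron_density_profile, helix_offset, peak_to_peak
from .io import read_multi_model_pdb, read_topology_table, write_multi_model_pdb
from .metrics import FeatureSeries, HBondCriterion, HelixDefinition, compute_features, helicity_percent
from .presets import BILAYER_PRESETS, bilayer_preset, build_offset_system, mixture_preset
from .states import assign_frames, find_modes, kde2d, state_average_structure
from .synthetic import (
    HelixBuildSpec,
    generate_bilayer,
    generate_feature_cloud,
    generate_helix_trajectory,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "concat_runs"]

#: fraying schedules emulating each membrane condition: with cholesterol
#: the helix stays fully folded; without it the landscape spans fully
#: folded down to strongly disturbed states
HELIX_SCHEDULES: Dict[str, List[Tuple[int, int]]] = {
    "chol_rich": [(0, 400)],
    "chol_depleted": [(0, 150), (2, 100), (4, 100), (5, 50)],
}
#: helix hydrophobic-face C-alpha plane per condition: buried 1.6 A below
#: the PO4 plane with cholesterol, expelled 1.73 A above it without
OFFSET_GEOMETRY: Dict[str, Tuple[float, float]] = {
    "chol_rich": (21.9, 21.9 - 1.60),
    "chol_depleted": (20.68, 20.68 + 1.73),
}


@dataclass
class RunConfig:
    """Everything one pipeline run needs; exactly one of preset/input."""

    output_dir: Union[str, Path] = "run_output"
    preset: Optional[str] = None  # chol_rich | chol_depleted
    trajectory: Optional[str] = None  # multi-model PDB path
    topology: Optional[str] = None  # sidecar atom table path
    seed: int = 0
    helix_range: Tuple[int, int] = (817, 827)
    hbond_max_ON: float = 3.5
    kde_bandwidth: Union[str, float] = "scott"
    # structural clusters from the fraying generator are jitter-tight
    # (~0.05 A wide); Scott's rule oversmooths them, so the structural
    # KDE uses a fixed bandwidth on the jitter scale
    structural_bandwidth: float = 0.1
    kde_grid_size: int = 128
    min_rel_density: float = 0.05
    po4_selection: str = "name=P"
    carbonyl_selection: str = "name=C & res_name=CBL"
    helix_ca_selection: str = "name=CA"
    atoms_per_leaflet: int = 5000
    bilayer_frames: int = 20
    mixture_samples: int = 6000
    slab_width: float = 1.0

    def __post_init__(self) -> None:
        if (self.preset is None) == (self.trajectory is None):
            raise ValueError("exactly one of 'preset' or 'trajectory' must be set")
        if self.trajectory is not None and self.topology is None:
            raise ValueError("an input trajectory needs a topology table")
        if self.preset is not None and self.preset not in BILAYER_PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "helix_range" in data:
            data["helix_range"] = tuple(data["helix_range"])
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the scientific settings (output location excluded)."""
        payload = {k: (list(v) if isinstance(v, tuple) else str(v) if isinstance(v, Path) else v)
                   for k, v in dataclasses.asdict(self).items() if k != "output_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class RunReport:
    config: RunConfig
    summary: Dict
    files: Dict[str, Path] = field(default_factory=dict)
    features: Optional[FeatureSeries] = None
    helixdef: Optional[HelixDefinition] = None

    @property
    def summary_path(self) -> Path:
        return self.files["summary"]


def _write_summary(outdir: Path, summary: Dict) -> Path:
    path = outdir / "summary.json"
    path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return path


def run_pipeline(config: RunConfig) -> RunReport:
    """Run every stage for one config; see the module docstring.

    Any stage failure aborts with the stage name and cause; outputs of
    completed stages are retained next to a FAILED marker file.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    criterion = HBondCriterion(max_ON_distance=config.hbond_max_ON)
    logger.info(
        "run %s: H-bond cutoff %.2f A (heavy-atom, no hydrogens); KDE bandwidth %s, "
        "grid %d, mode threshold %.2f; EDP electrons Z - q, slab %.2f A",
        config.preset or config.trajectory, config.hbond_max_ON, config.kde_bandwidth,
        config.kde_grid_size, config.min_rel_density, config.slab_width,
    )
    summary: Dict = {
        "preset": config.preset,
        "seed": config.seed,
        "provenance": {"version": __version__, "config_hash": config.config_hash()},
    }
    files: Dict[str, Path] = {}
    stage = "setup"
    try:
        if config.preset is not None:
            stage = "simulate"
            helix_traj = generate_helix_trajectory(
                HELIX_SCHEDULES[config.preset], seed=config.seed
            )
            write_multi_model_pdb(helix_traj, outdir / "helix_trajectory.pdb")
            files["helix_trajectory"] = outdir / "helix_trajectory.pdb"
            bilayer = generate_bilayer(
                bilayer_preset(config.preset, config.atoms_per_leaflet, seed=config.seed),
                n_frames=config.bilayer_frames,
            )
            landscape = generate_feature_cloud(
                mixture_preset(config.preset, config.mixture_samples, seed=config.seed)
            )
            helixdef = HelixDefinition(res_id_range=config.helix_range)
        else:
            stage = "read_input"
            topo = read_topology_table(config.topology)
            helix_traj = read_multi_model_pdb(config.trajectory, topology=topo)
            bilayer = None
            landscape = None
            helixdef = HelixDefinition(res_id_range=config.helix_range)

        stage = "features"
        feats = compute_features(helix_traj, helixdef)
        feats.to_tsv(outdir / "features.tsv")
        files["features"] = outdir / "features.tsv"
        trace = [
            helicity_percent(f, helix_traj.topology, helixdef, criterion).percent_folded
            for f in helix_traj.frames
        ]
        summary["helicity_trace_mean"] = float(np.mean(trace))

        stage = "states"
        landscape_feats = landscape if landscape is not None else feats
        kde = kde2d(landscape_feats, config.kde_bandwidth, config.kde_grid_size)
        modes = find_modes(kde, config.min_rel_density)
        model = assign_frames(landscape_feats, kde, modes)
        kde.to_tsv(outdir / "density_grid.tsv")
        summary["n_states"] = model.n_states
        summary["state_probabilities"] = [float(p) for p in model.probabilities]

        # structural states from the helix trajectory itself
        kde_s = kde2d(feats, config.structural_bandwidth, config.kde_grid_size)
        modes_s = find_modes(kde_s, config.min_rel_density)
        model_s = assign_frames(feats, kde_s, modes_s)
        per_state = []
        for m in modes_s:
            mean_frame, hel = state_average_structure(
                helix_traj, model_s, m.label, helixdef, criterion
            )
            pdb = outdir / f"state_{m.label}_avg.pdb"
            write_multi_model_pdb(Trajectory(helix_traj.topology, [mean_frame]), pdb)
            files[f"state_{m.label}_avg"] = pdb
            per_state.append(
                {"state": m.label, "percent_folded": hel.percent_folded,
                 "probability": float(model_s.probabilities[m.label - 1])}
            )
        summary["structural_states"] = per_state
        model.to_json(outdir / "states.json", extra={"seed": config.seed})
        files["states"] = outdir / "states.json"

        if bilayer is not None:
            stage = "edp"
            prof_po4 = electron_density_profile(bilayer, config.po4_selection, config.slab_width)
            prof_cbl = electron_density_profile(bilayer, config.carbonyl_selection, config.slab_width)
            prof_po4.to_tsv(outdir / "edp_po4.tsv")
            prof_cbl.to_tsv(outdir / "edp_carbonyl.tsv")
            files["edp_po4"] = outdir / "edp_po4.tsv"

            stage = "thickness"
            th = peak_to_peak(prof_po4)
            th_c = peak_to_peak(prof_cbl)
            summary["thickness_po4_A"] = round(th.distance, 3)
            summary["thickness_po4_sd_A"] = round(th.sd, 3)
            summary["thickness_carbonyl_A"] = round(th_c.distance, 3)
            summary["thickness_carbonyl_sd_A"] = round(th_c.sd, 3)

            stage = "offset"
            po4_z, helix_z = OFFSET_GEOMETRY[config.preset]
            osys = build_offset_system(po4_center=po4_z, helix_center=helix_z)
            zr = (-30.0, 30.0)
            p_po4 = electron_density_profile(osys, "name=P", config.slab_width, z_range=zr)
            p_ca = electron_density_profile(osys, config.helix_ca_selection, config.slab_width, z_range=zr)
            off = helix_offset(p_ca, p_po4, "upper")
            summary["helix_offset_A"] = round(off.offset, 3)
            summary["helix_offset_direction"] = off.direction

        stage = "report"
        files["summary"] = _write_summary(outdir, summary)
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return RunReport(config, summary, files, features=feats, helixdef=helixdef)


def concat_runs(reports: Sequence[RunReport]) -> FeatureSeries:
    """Merge per-run feature series (run labels preserved) for a joint PDF."""
    if not reports:
        raise ValueError("no runs to concatenate")
    first = reports[0].helixdef
    for r in reports[1:]:
        if r.helixdef is None or first is None or r.helixdef.res_id_range != first.res_id_range:
            raise ValueError("runs have mismatched helix definitions")
    parts = []
    for label, r in enumerate(reports):
        f = r.features
        if f is None:
            f = FeatureSeries.from_tsv(r.files["features"])
        parts.append(FeatureSeries(f.frame_index, f.rmsd, f.rg, np.full(len(f), label)))
    return FeatureSeries.concatenate(parts)
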