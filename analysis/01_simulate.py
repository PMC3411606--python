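#!/usr/bin/env python
"""Generate the synthetic inputs for the two membrane conditions.

Writes the small persistent artifacts: frayed-helix trajectories
(multi-model PDB + topology table) and feature-space clouds (TSV) for
the cholesterol-rich and cholesterol-depleted landscapes. Bilayer point
clouds are pure functions of their preset spec and are regenerated where
needed (03) instead of being stored as multi-megabyte PDBs.

Run from the repository root: python analysis/01_simulate.py [--seed N]
"""
import argparse
from pathlib import Path

from helix8.io import write_multi_model_pdb, write_topology_table
from helix8.pipeline import HELIX_SCHEDULES
from helix8.presets import mixture_preset
from helix8.synthetic import generate_feature_cloud, generate_helix_trajectory

OUT = Path("results/inputs")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    OUT.mkdir(parents=True, exist_ok=True)

    for condition, schedule in HELIX_SCHEDULES.items():
        traj = generate_helix_trajectory(schedule, seed=args.seed)
        write_multi_model_pdb(traj, OUT / f"helix_{condition}.pdb")
        write_topology_table(traj.topology, OUT / f"helix_{condition}_topology.csv")
        cloud = generate_feature_cloud(mixture_preset(condition, seed=args.seed))
        cloud.to_tsv(OUT / f"landscape_{condition}.tsv")
        print(
            f"{condition}: helix trajectory {traj.n_frames} frames "
            f"(fraying schedule {schedule}), landscape cloud {len(cloud)} samples"
        )
    print(f"wrote inputs -> {OUT}/")


if __name__ == "__main__":
    main()
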