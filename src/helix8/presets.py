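"""Named study conditions for the synthetic generators.

Two membrane conditions are shipped, one per cholesterol level, each
with its measured leaflet geometry and conformational landscape:

* ``chol_rich``     — phosphate leaflets at +/-21.9 A (thickness 43.8 A),
  carbonyl at +/-17.5 A (35.0 A), plus a sterol-like species deeper in
  the membrane; feature-space landscape with 2 states.
* ``chol_depleted`` — phosphate at +/-20.68 A (41.36 A), carbonyl at
  +/-15.0 A (30.0 A); feature-space landscape with 6 states (three
  high-probability, one medium, two low).

The leaflet separations, state counts and state-probability ordering
are the measured study conditions being emulated; the (RMSD, Rg)
coordinates of the mixture components are synthetic, chosen
well-separated on the scale the helix generator produces (folded
Rg ~5.3 A, frayed up to ~7.6 A).
"""
from __future__ import annotations

from typing import Dict, Tuple

import numpy as np

from .core import AtomRecord, Frame, Topology, Trajectory
from .synthetic import BilayerSpec, BilayerSpecies, MixtureComponent, MixtureSpec

__all__ = [
    "bilayer_preset",
    "mixture_preset",
    "build_offset_system",
    "BILAYER_PRESETS",
    "MIXTURE_PRESETS",
]

_PO4 = dict(label="PO4", atom_name="P", z_number=15, partial_charge=1.5, mass=30.974)
_CARBONYL = dict(label="CBL", atom_name="C", z_number=6, partial_charge=0.55, mass=12.011)
_STEROL = dict(label="CHL", atom_name="O", z_number=8, partial_charge=-0.65, mass=15.999)

BILAYER_PRESETS: Dict[str, dict] = {
    # leaflet means set the target peak-to-peak distances:
    # 2 x 21.9 = 43.8 A (PO4, with cholesterol), 2 x 17.5 = 35.0 A (carbonyl)
    "chol_rich": dict(
        po4=dict(mean=21.9, sd=2.0),
        carbonyl=dict(mean=17.5, sd=2.0),
        sterol=dict(mean=13.0, sd=3.0),
    ),
    # 2 x 20.68 = 41.36 A and 2 x 15.0 = 30.0 A (without cholesterol)
    "chol_depleted": dict(
        po4=dict(mean=20.68, sd=2.5),
        carbonyl=dict(mean=15.0, sd=2.5),
        sterol=None,
    ),
}


def bilayer_preset(
    name: str,
    atoms_per_leaflet: int = 5000,
    seed: int = 42,
    box: Tuple[float, float] = (94.0, 94.0),
) -> BilayerSpec:
    """Bilayer spec for a named membrane condition."""
    if name not in BILAYER_PRESETS:
        raise KeyError(f"unknown bilayer preset {name!r}; have {sorted(BILAYER_PRESETS)}")
    cfg = BILAYER_PRESETS[name]
    species = [
        BilayerSpecies(
            atoms_per_leaflet=atoms_per_leaflet,
            leaflet_mean_z=cfg["po4"]["mean"],
            leaflet_sd_z=cfg["po4"]["sd"],
            **_PO4,
        ),
        BilayerSpecies(
            atoms_per_leaflet=atoms_per_leaflet,
            leaflet_mean_z=cfg["carbonyl"]["mean"],
            leaflet_sd_z=cfg["carbonyl"]["sd"],
            **_CARBONYL,
        ),
    ]
    if cfg["sterol"] is not None:
        species.append(
            BilayerSpecies(
                atoms_per_leaflet=atoms_per_leaflet // 2,
                leaflet_mean_z=cfg["sterol"]["mean"],
                leaflet_sd_z=cfg["sterol"]["sd"],
                **_STEROL,
            )
        )
    return BilayerSpec(tuple(species), box=box, seed=seed)


# (weight, mean_rmsd, mean_rg, sd_rmsd, sd_rg) per component; coordinates
# are synthetic (see module docstring), separations >= ~4 smoothed sds
_MIXTURES = {
    "chol_rich": [
        (0.65, 0.60, 5.25, 0.12, 0.12),
        (0.35, 1.50, 5.55, 0.12, 0.12),
    ],
    "chol_depleted": [
        (0.22, 0.60, 5.25, 0.15, 0.15),
        (0.22, 1.80, 5.80, 0.15, 0.15),
        (0.22, 3.00, 6.40, 0.15, 0.15),
        (0.15, 4.20, 7.10, 0.15, 0.15),
        (0.095, 1.50, 7.00, 0.15, 0.15),
        (0.095, 4.60, 5.40, 0.15, 0.15),
    ],
}
MIXTURE_PRESETS = {k: tuple(MixtureComponent(*c) for c in v) for k, v in _MIXTURES.items()}


def mixture_preset(name: str, n_samples: int = 6000, seed: int = 7) -> MixtureSpec:
    """Feature-space Gaussian-mixture spec for a named membrane condition."""
    if name not in MIXTURE_PRESETS:
        raise KeyError(f"unknown mixture preset {name!r}; have {sorted(MIXTURE_PRESETS)}")
    return MixtureSpec(MIXTURE_PRESETS[name], n_samples=n_samples, seed=seed)


def build_offset_system(
    po4_center: float = 21.9,
    helix_center: float = 20.3,
    half_width: float = 3.5,
    atoms_per_slab_scale: int = 2000,
    z_extent: float = 30.0,
    box: Tuple[float, float] = (94.0, 94.0),
) -> Trajectory:
    """Deterministic system for the helix-vs-phosphate offset measurement.

    Phosphate atoms (name P, mirrored lower leaflet) and helix C-alpha
    atoms (name CA, upper leaflet only) are stacked at 1 A slab centers
    with per-slab counts following an exact parabolic cap of the given
    half-width, so 3-point parabolic peak interpolation recovers the
    stated centers to rounding precision. Use a profile ``z_range`` of
    ``(-z_extent, z_extent)`` so both species share the slab grid.
    """
    centers = np.arange(-z_extent + 0.5, z_extent, 1.0)

    def cap_counts(c: float) -> np.ndarray:
        u = (centers - c) / half_width
        return np.round(atoms_per_slab_scale * np.clip(1 - u**2, 0, None)).astype(int)

    atoms = []
    coords = []
    idx = 0

    def add_species(name: str, res_name: str, z_number: int, counts_list) -> None:
        nonlocal idx
        for counts in counts_list:
            for z, n in zip(centers, counts):
                for _ in range(n):
                    atoms.append(
                        AtomRecord(idx, name, res_name, idx % 9999 + 1, "M", name[:1],
                                   z_number, 0.0, 30.0)
                    )
                    coords.append((box[0] / 2, box[1] / 2, z))
                    idx += 1

    add_species("P", "PO4", 15, [cap_counts(po4_center), cap_counts(-po4_center)])
    add_species("CA", "HCA", 6, [cap_counts(helix_center)])
    topo = Topology(atoms, box=(box[0], box[1], 2 * z_extent))
    return Trajectory(topo, [Frame(np.array(coords), frame_index=0)])
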