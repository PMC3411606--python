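# Methods

This note documents the models and procedures implemented in `helix8`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic generators do and do not emulate.

## The scientific setting

Class A G-protein-coupled receptors carry a short amphipathic helix
(helix 8, H8) at the cytoplasmic membrane interface, lying parallel to
the membrane plane with a hydrophobic face buried among the lipid tails
and a polar face toward the phosphate headgroups and solvent. For the
class C receptor mGluR2 the analogous segment is residues 817–834
(ILFQPQKNVVSHRAPTS), with a helical core of 817–827. Whether this
segment folds stably depends on its membrane environment: cholesterol
thickens the bilayer and keeps the hydrophobic face embedded, while
cholesterol depletion thins the membrane, expels the helix toward the
solvent, and destabilizes it into a ladder of partially unfolded
states. The package quantifies this picture with three observable
families: per-frame helicity, a 2-D conformational-state density, and
electron-density profiles of the bilayer.

## Helicity by backbone hydrogen-bond fraction

An α-helical segment of L residues has L−4 canonical i→i+4 backbone
hydrogen bonds, O(i)···H–N(i+4). Helicity is reported as the percentage
of a frozen *reference* bond set still intact in a frame:

    percent_folded = 100 × |intact| / |reference|

For the default 11-residue core the reference set has 7 bonds, so the
metric lives on the lattice k/7 × 100: 0, 14.29, 28.57, 42.86, 57.14,
71.43, 85.71, 100 (values reported to 2 decimals, rounded half-up from
the exact rational).

A bond is *intact* when the heavy-atom O···N distance is ≤ 3.5 Å. The
criterion is hydrogen-free by default because the synthetic topologies
carry no hydrogens; 3.5 Å is the conventional heavy-atom donor–acceptor
cutoff. An optional mode additionally requires an N–H···O angle ≥ 120°
when amide hydrogens are present. The reference set can be frozen from
any starting frame (`HelixDefinition.from_reference_frame`); for the
ideal starting helix this yields all 7 pairs.

Two hydrophobic-face residue sets are shipped: {821, 822, 824, 825,
826, 828, 829} (the default) and an alternative {821, 823, 824, 825,
826, 829, 830}. Published descriptions of this helix disagree between
these two labelings; both are selectable, and nothing downstream depends
on the choice except which Cα atoms enter the helix density profile.

## Feature space: RMSD and radius of gyration

Each frame is reduced to a 2-D point:

* **RMSD** from the starting structure after optimal rigid
  superposition (Kabsch, SVD-based, proper rotation enforced) of the
  helix backbone N/CA/C/O atoms, measured over that same atom set. This
  measures *internal* deformation of the helix, not its rigid-body
  motion; an external anchor selection can be passed instead.
* **Radius of gyration** Rg = √(Σᵢ wᵢ|rᵢ−r̄|² / Σᵢ wᵢ) over the helix
  heavy atoms, mass-weighted by default (unweighted optional).

Degenerate superposition subsets (fewer than 3 atoms, collinear or
coincident points — second singular value ≤ 1e-10 of the first) are
rejected rather than silently resolved.

## Conformational states by 2-D kernel density estimation

The probability density over (RMSD, Rg) is estimated with a Gaussian
product kernel,

    f(x, y) = 1/(2π hx hy n) Σᵢ exp(−(x−xᵢ)²/2hx²) exp(−(y−yᵢ)²/2hy²),

evaluated on a regular grid (default 128×128) spanning the data range
plus 3 bandwidths per side. Per-dimension bandwidths default to Scott's
rule, hⱼ = σⱼ n^(−1/6); Silverman's rule and fixed bandwidths are
accepted. The grid evaluation is vectorized as a separable matrix
product that is algebraically identical to the naive double sum (the
test suite checks this against a literal double loop at 1e-10).

**States** are strict local maxima of the grid density over their
8-neighborhood, subject to two filters:

* density ≥ 5% of the global maximum (`min_rel_density = 0.05`, kept
  low because genuinely shallow states must survive);
* distance ≥ 1 bandwidth (scaled per-dimension) from any denser mode.
  A KDE cannot resolve structure below its own bandwidth, so
  sub-bandwidth maxima are sampling ripples on a single mode, not
  states. Without this filter a single-Gaussian cloud of n = 2000
  points grows a spurious second mode in roughly 8 of 100 seeds at the
  defaults. Even with it, mode *counting* needs adequate sampling —
  peak-level KDE fluctuations shrink like n^(−1/3) — which is why the
  unimodal recovery test uses n = 20 000.

**Assignment**: every frame starts at its containing grid cell (frames
outside the grid are snapped to the nearest cell and counted, never
dropped) and climbs by steepest ascent over the 8-neighborhood until a
local maximum; ties break to the lowest flat cell index, making
assignment fully deterministic. Climbs ending on a filtered ripple
maximum are attributed to the nearest surviving mode in feature units.
State probabilities are assigned-frame fractions. Per-state **average
structures** are coordinate-wise means after superposing all members on
the first member over the helix backbone (a medoid option was
considered and rejected as the default because the mean is what the
average-structure insets of this kind of analysis show); the helicity
of the mean structure is reported with it.

The landscape KDE uses Scott's rule. The *structural* KDE inside the
pipeline — run on features of the fraying-schedule trajectories, whose
clusters are jitter-tight (≈0.05 Å) — uses a fixed 0.1 Å bandwidth
instead (`RunConfig.structural_bandwidth`): reference rules assume the
data's spread reflects smooth density, and on near-degenerate clusters
Scott oversmooths by an order of magnitude and merges adjacent states.

## Electron density profiles, thickness, and helix position

Each selected atom contributes an electron count to the 1 Å slab
(default; configurable) containing its z coordinate:

    e = Z − q   (atomic number minus partial charge, default)

A positive partial charge depletes an atom's electron cloud, so Z − q
is the physically standard convention; the literal sum Z + q is
available behind `charge_sign=+1` for comparison. Slab sums are
normalized by slab volume (box cross-section × slab width — the full
box area, as no local-area estimate is attempted), giving e/Å³. The
profile is the per-slab mean over frames with the per-slab sd across
frames; per-frame profiles are retained so derived quantities can carry
frame-to-frame spreads. Total electron count is conserved exactly per
frame (a test asserts this to 1e-12 relative).

**Leaflet peaks**: the profile is split at its grid midpoint; each half
must contain an interior maximum (a flat, monotone, or one-sided
profile is an error), which is refined to sub-slab precision by
3-point parabolic interpolation — needed because the measured distances
carry 0.01 Å precision against a 1 Å slab. **Bilayer thickness** is the
upper-minus-lower peak distance (D_PO4–PO4 when the selection is the
phosphate species); its sd is the sd of per-frame peak-to-peak
distances. The default phosphate selection is by atom name (`name=P`);
whether "PO4 group" means P alone or P plus its four oxygens is a
selection choice left to the caller — for symmetric species
distributions it moves the peak by construction not at all, and the
selection string is recorded in the profile.

**Helix offset**: with both profiles on a shared grid, the offset is

    offset = |z_helix_peak| − |z_PO4_peak|

on the chosen leaflet — negative when the helix Cα peak sits closer to
the bilayer center than the phosphate plane ("buried"), positive when
displaced toward the solvent ("expelled"). This sign convention is
leaflet-independent. The helix profile must have its global maximum on
the chosen leaflet side.

## Synthetic generators: what they emulate, what they do not

All generators are pure functions of (spec, seed); reruns are
bit-identical.

**Ideal helix.** Backbone N/CA/C/O atoms are placed on cylinders around
the z axis: CA at radius 2.3 Å with 1.5 Å rise and 100° twist per
residue (the canonical α-helix), N/C/O at fixed cylindrical offsets
from each CA. The offsets were calibrated once against a helix built
from standard internal coordinates (φ = −57°, ψ = −47°;
`scripts/calibrate_helix_geometry.py` re-derives them) and give every
O(i)···N(i+4) pair a distance of ≈2.85 Å — comfortably hydrogen-bonded.
No side chains or hydrogens are built: the helicity metric needs only
the heavy backbone atoms.

**Fraying.** `perturb_unfold(n_break)` displaces the outermost
`n_break` residues along the helix axis with a progressively growing
shift (2 Å per displaced residue, extending the chain), which breaks
exactly the `n_break` most terminal reference bonds and no others —
giving exact control of the helicity lattice value. Unfolding proceeds
from the C-terminus by default (terminal fraying; the N-terminal mode
is available). Trajectory generation adds per-frame Gaussian jitter
(0.05 Å sd, far below the 0.65 Å cutoff margin, so jitter never flips a
bond state) and an optional random rigid-body motion per frame to
exercise the superposition step.

**Bilayers.** Each species (phosphate-like, carbonyl-like,
sterol-like) is an independent point cloud: z ~ Normal(±leaflet mean,
leaflet sd) per leaflet, x/y uniform in the box. There are no packed
lipids, no bonds, no excluded volume — the electron density profile
depends only on z positions, Z, q and slab volume, so nothing more is
needed. Preset geometries: `chol_rich` PO4 at ±21.9 Å (sd 2.0),
carbonyl ±17.5 Å (sd 2.0), sterol ±13.0 Å; `chol_depleted` PO4 at
±20.68 Å (sd 2.5), carbonyl ±15.0 Å (sd 2.5), no sterol. The leaflet
positions are the measured study conditions; the sds are chosen as
realistic headgroup spreads that keep the two leaflets well separated.

**Feature-space mixtures.** Bivariate Gaussian mixtures emulate the
conformational landscapes: 2 components (65/35) for the
cholesterol-rich system, 6 components (three high-probability at 22%
each, one medium at 15%, two low at 9.5%) for the depleted system. The
(RMSD, Rg) coordinates of the components are synthetic — chosen on the
scale the helix generator produces (folded Rg ≈ 5.3 Å) with pairwise
separations ≥ ~4 smoothed sds so that the stated state counts are
actually resolvable — because no per-state coordinates are published.
RMSD draws are reflected at zero (component means sit ≥4 sds above 0,
so the truncation is negligible).

**The deterministic offset system** stacks atoms at 1 Å slab centers
with per-slab counts following an exact parabolic cap (half-width
3.5 Å, scale 2000/slab). Because the slab values around the maximum lie
exactly on a parabola, 3-point parabolic interpolation recovers the
stated peak centers to count-rounding precision (~1e-3 Å), isolating
the offset sign convention from sampling noise.

What passing tests on these generators shows: that the *measurement
chain* — H-bond counting, superposition, KDE state detection, density
profiling, peak interpolation — recovers known ground truth at the
precision the measurements are reported with. What it does not show:
anything about force fields, lipid packing, sampling convergence, or
whether a real membrane produces these geometries; the generators take
the leaflet positions and state structure as given conditions rather
than re-deriving them from physics.

## Numerical choices and degenerate inputs

* Helicity percentages: exact rational k/R, rounded half-up to 2
  decimals via decimal arithmetic (so 5/7 → 71.43, never 71.42).
* Kabsch: proper rotation enforced via the sign of det(V Uᵀ);
  reflection-requiring inputs get the best proper rotation. Degenerate
  subsets raise.
* KDE grid mass: the Riemann sum over the grid matches the analytic
  kernel mass inside the grid box to ~1e-3 (midpoint-rule error at
  128×128; the normalization itself is exact).
* Hill-climb ties: lowest flattened cell index, for deterministic
  assignment.
* Parabolic peak refinement: requires an interior maximum and negative
  curvature; otherwise the slab center is returned unrefined (and
  boundary maxima are rejected upstream as monotone/truncated
  profiles).
* Slab grids align to multiples of the slab width when built from data,
  or to an explicit `z_range` when two profiles must share a grid
  (grid mismatch is an error, not a resample).
* PDB round-trips preserve coordinates to the format's 0.001 Å; residue
  ids wrap at 9999 and serials at 99999 per the fixed columns.

## Problem sizes

Defaults used throughout the analyses and tests: bilayers with 5000
atoms/leaflet/species × 20 frames (thickness estimates stable to
≈0.1–0.3 Å, well inside the reference spreads of 0.42–1.15 Å); landscape
clouds of 6000 samples; helix trajectories of 400 frames; 100-seed
replication for state-count recovery. These sizes were chosen so each
quantity's sampling error sits comfortably below the tolerance it is
compared against while the full analysis runs in well under a minute.

## Known limitations

* The selection language is deliberately small (five clause kinds,
  conjunctions only); no disjunction, negation, or distance-based
  selections.
* No periodic-boundary imaging: coordinates are used as given.
* The H-bond criterion is geometric only; no DSSP-style energy model,
  and no per-residue secondary-structure strings.
* Mode counting inherits KDE's bandwidth sensitivity: states closer
  than one bandwidth are unresolvable by construction, and reference
  bandwidth rules are inappropriate for near-degenerate clusters (use a
  fixed bandwidth there, as the pipeline does for structural states).
* Thickness sd is a frame-to-frame spread, not an error estimate of
  the mean; with multiple runs, the spread across run means is the
  appropriate figure (the pipeline records per-run summaries for this).
* No free-energy conversion, Markov-state modeling, or kinetics: states
  are density modes with occupation fractions, nothing more.
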