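import numpy as np
import pytest

from helix8.core import AtomRecord, Frame, Topology, Trajectory
from helix8.density import (
    DensityProfile,
    electron_density_profile,
    helix_offset,
    leaflet_peaks,
    peak_to_peak,
)
from helix8.presets import bilayer_preset, build_offset_system
from helix8.synthetic import BilayerSpec, BilayerSpecies, generate_bilayer

AREA = 94.0 * 94.0


def _point_atoms(zs, z_number=8, charge=0.0):
    atoms = [
        AtomRecord(i, "X", "PTS", i + 1, "M", "O", z_number, charge, 16.0)
        for i in range(len(zs))
    ]
    coords = np.column_stack([np.full(len(zs), 47.0), np.full(len(zs), 47.0), zs])
    return Trajectory(Topology(atoms, box=(94.0, 94.0, 60.0)), [Frame(coords)])


class TestElectronDensityProfile:
    def test_single_oxygen_fills_one_slab(self):
        traj = _point_atoms([10.5])
        prof = electron_density_profile(traj, "name=X", z_range=(0.0, 20.0))
        k = np.argmax(prof.values)
        assert prof.centers[k] == pytest.approx(10.5)
        assert prof.values[k] == pytest.approx(8.0 / (AREA * 1.0))
        assert np.count_nonzero(prof.values) == 1

    def test_partial_charge_depletes_electrons(self):
        traj = _point_atoms([5.5], z_number=15, charge=1.5)
        prof = electron_density_profile(traj, "name=X", z_range=(0.0, 10.0))
        assert prof.values.max() == pytest.approx(13.5 / AREA)  # Z - q
        literal = electron_density_profile(traj, "name=X", z_range=(0.0, 10.0), charge_sign=+1.0)
        assert literal.values.max() == pytest.approx(16.5 / AREA)  # Z + q reading

    def test_electron_count_conserved_per_frame(self):
        spec = bilayer_preset("chol_rich", atoms_per_leaflet=400, seed=5)
        traj = generate_bilayer(spec, n_frames=3)
        prof = electron_density_profile(traj, "name=P")
        idx = [a.index for a in traj.topology.atoms if a.name == "P"]
        total = sum(traj.topology.atoms[i].z_number - traj.topology.atoms[i].partial_charge for i in idx)
        for row in prof.per_frame:
            assert row.sum() * AREA * 1.0 == pytest.approx(total, rel=1e-12)

    def test_profile_symmetric_for_mirror_bilayer(self):
        spec = BilayerSpec((BilayerSpecies("PO4", "P", 4000, 20.0, 2.0, 15),), seed=8)
        traj = generate_bilayer(spec, n_frames=10)
        prof = electron_density_profile(traj, "name=P", z_range=(-30.0, 30.0))
        v, sd = prof.values, prof.per_slab_sd
        se = sd / np.sqrt(len(prof.per_frame))
        diff = np.abs(v - v[::-1])
        tol = 5 * (se + se[::-1]) + 1e-8
        assert np.all(diff <= tol)

    def test_z_translation_shifts_peaks_equally(self):
        traj = _point_atoms([-20.5, 20.5])
        prof = electron_density_profile(traj, "name=X", z_range=(-30.0, 30.0))
        lo, hi = leaflet_peaks(prof)
        shifted = _point_atoms([-17.5, 23.5])  # +3 A shift of both atoms
        prof2 = electron_density_profile(shifted, "name=X", z_range=(-27.0, 33.0))
        lo2, hi2 = leaflet_peaks(prof2)
        assert (lo2 - lo, hi2 - hi) == pytest.approx((3.0, 3.0))

    def test_empty_selection_rejected(self):
        traj = _point_atoms([1.0])
        with pytest.raises(ValueError, match="selection"):
            electron_density_profile(traj, "name=ZZ")

    def test_missing_area_rejected(self):
        traj = _point_atoms([1.0])
        traj.topology.box = None
        with pytest.raises(ValueError, match="area"):
            electron_density_profile(traj, "name=X")


class TestLeafletPeaks:
    def test_delta_leaflets_recovered_exactly(self):
        traj = _point_atoms([-20.5, 20.5])
        prof = electron_density_profile(traj, "name=X", z_range=(-30.0, 30.0))
        lo, hi = leaflet_peaks(prof)
        assert (lo, hi) == pytest.approx((-20.5, 20.5), abs=0.1)

    def test_gaussian_leaflet_peak_bias_below_0_2(self):
        spec = BilayerSpec((BilayerSpecies("PO4", "P", 5000, 21.9, 2.0, 15),), seed=17)
        traj = generate_bilayer(spec, n_frames=20)
        prof = electron_density_profile(traj, "name=P", z_range=(-30.0, 30.0))
        lo, hi = leaflet_peaks(prof)
        assert abs(hi - 21.9) < 0.2 and abs(lo + 21.9) < 0.2

    def test_monotone_profile_rejected(self):
        edges = np.arange(0.0, 11.0)
        vals = np.linspace(0.1, 1.0, 10)
        prof = DensityProfile(edges, vals, np.zeros(10))
        with pytest.raises(ValueError):
            leaflet_peaks(prof)

    def test_flat_profile_rejected(self):
        edges = np.arange(0.0, 11.0)
        prof = DensityProfile(edges, np.ones(10), np.zeros(10))
        with pytest.raises(ValueError, match="flat"):
            leaflet_peaks(prof)


class TestPeakToPeak:
    @pytest.mark.parametrize(
        "mean,sd,expected,tol",
        [(21.9, 2.0, 43.8, 0.42), (20.68, 2.5, 41.36, 0.92), (17.5, 2.0, 35.0, 0.63)],
    )
    def test_thickness_recovery(self, mean, sd, expected, tol):
        spec = BilayerSpec((BilayerSpecies("PO4", "P", 5000, mean, sd, 15),), seed=42)
        traj = generate_bilayer(spec, n_frames=20)
        th = peak_to_peak(electron_density_profile(traj, "name=P"))
        assert abs(th.distance - expected) < tol
        assert th.sd > 0

    def test_halving_slab_width_moves_peaks_below_0_1(self):
        spec = bilayer_preset("chol_rich", atoms_per_leaflet=5000, seed=42)
        traj = generate_bilayer(spec, n_frames=20)
        th1 = peak_to_peak(electron_density_profile(traj, "name=P", slab_width=1.0))
        th2 = peak_to_peak(electron_density_profile(traj, "name=P", slab_width=0.5))
        assert abs(th1.peak_z_upper - th2.peak_z_upper) < 0.1
        assert abs(th1.peak_z_lower - th2.peak_z_lower) < 0.1


class TestHelixOffset:
    def test_coincident_peaks_give_zero(self):
        traj = build_offset_system(po4_center=21.9, helix_center=21.9)
        zr = (-30.0, 30.0)
        po4 = electron_density_profile(traj, "name=P", z_range=zr)
        ca = electron_density_profile(traj, "name=CA", z_range=zr)
        off = helix_offset(ca, po4, "upper")
        assert off.offset == pytest.approx(0.0, abs=0.01)

    def test_buried_helix_reads_minus_1_60(self):
        traj = build_offset_system(po4_center=21.9, helix_center=21.9 - 1.60)
        zr = (-30.0, 30.0)
        po4 = electron_density_profile(traj, "name=P", z_range=zr)
        ca = electron_density_profile(traj, "name=CA", z_range=zr)
        off = helix_offset(ca, po4, "upper")
        assert off.offset == pytest.approx(-1.60, abs=0.01)
        assert off.direction == "toward-center"

    def test_cross_system_difference_is_3_33(self):
        zr = (-30.0, 30.0)

        def offset_for(po4_c, helix_c):
            traj = build_offset_system(po4_center=po4_c, helix_center=helix_c)
            po4 = electron_density_profile(traj, "name=P", z_range=zr)
            ca = electron_density_profile(traj, "name=CA", z_range=zr)
            return helix_offset(ca, po4, "upper").offset

        buried = offset_for(21.9, 21.9 - 1.60)
        expelled = offset_for(20.68, 20.68 + 1.73)
        assert expelled - buried == pytest.approx(3.33, abs=0.01)

    def test_grid_mismatch_rejected(self):
        traj = build_offset_system()
        po4 = electron_density_profile(traj, "name=P", z_range=(-30.0, 30.0))
        ca = electron_density_profile(traj, "name=CA", z_range=(-29.0, 31.0))
        with pytest.raises(ValueError, match="grid"):
            helix_offset(ca, po4, "upper")

    def test_wrong_leaflet_rejected(self):
        traj = build_offset_system()
        zr = (-30.0, 30.0)
        po4 = electron_density_profile(traj, "name=P", z_range=zr)
        ca = electron_density_profile(traj, "name=CA", z_range=zr)
        with pytest.raises(ValueError, match="leaflet"):
            helix_offset(ca, po4, "lower")
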