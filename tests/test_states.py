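import numpy as np
import pytest
from scipy import stats

from helix8.metrics import FeatureSeries, HelixDefinition, compute_features, kabsch_superpose
from helix8.presets import mixture_preset
from helix8.states import (
    assign_frames,
    find_modes,
    kde2d,
    kde2d_brute,
    state_average_structure,
)
from helix8.synthetic import (
    MixtureComponent,
    MixtureSpec,
    generate_feature_cloud,
    generate_helix_trajectory,
)


def _cloud(seed=0, n=300, mean=(1.0, 6.0), sd=(0.3, 0.2)):
    spec = MixtureSpec((MixtureComponent(1.0, mean[0], mean[1], sd[0], sd[1]),), n, seed)
    return generate_feature_cloud(spec)


class TestKDE2D:
    def test_matches_brute_force_at_probe_points(self):
        fs = _cloud(seed=5, n=200)
        kde = kde2d(fs)
        rng = np.random.default_rng(1)
        probes = np.column_stack(
            [rng.uniform(kde.x[0], kde.x[-1], 25), rng.uniform(kde.y[0], kde.y[-1], 25)]
        )
        brute = kde2d_brute(fs.points, probes, *kde.bandwidths)
        # evaluate the grid-free density the same way the grid is built
        hx, hy = kde.bandwidths
        Ax = np.exp(-0.5 * ((probes[:, 0, None] - fs.points[None, :, 0]) / hx) ** 2)
        Ay = np.exp(-0.5 * ((probes[:, 1, None] - fs.points[None, :, 1]) / hy) ** 2)
        ours = (Ax * Ay).sum(axis=1) / (2 * np.pi * hx * hy * len(fs))
        np.testing.assert_allclose(ours, brute, atol=1e-10)

    def test_grid_density_equals_brute_force_on_grid_cells(self):
        fs = _cloud(seed=6, n=150)
        kde = kde2d(fs, grid_size=32)
        ii = [3, 10, 17, 25, 31]
        probes = np.array([(kde.x[i], kde.y[j]) for i in ii for j in ii])
        brute = kde2d_brute(fs.points, probes, *kde.bandwidths)
        ours = np.array([kde.density[i, j] for i in ii for j in ii])
        np.testing.assert_allclose(ours, brute, atol=1e-10)

    def test_normalizes_to_unit_mass(self):
        fs = _cloud(seed=7, n=2000)
        kde = kde2d(fs)
        hx, hy = kde.bandwidths
        # exact mass of the KDE inside the grid box, kernel by kernel
        px = stats.norm.cdf(kde.x[-1], fs.points[:, 0], hx) - stats.norm.cdf(
            kde.x[0], fs.points[:, 0], hx
        )
        py = stats.norm.cdf(kde.y[-1], fs.points[:, 1], hy) - stats.norm.cdf(
            kde.y[0], fs.points[:, 1], hy
        )
        exact = float((px * py).mean())
        assert kde.mass() == pytest.approx(exact, abs=1e-3)
        assert kde.mass() == pytest.approx(1.0, abs=5e-3)
        assert np.all(kde.density >= 0)

    def test_peak_near_true_mean_for_gaussian_cloud(self):
        fs = _cloud(seed=8, n=10000, mean=(2.0, 6.0))
        kde = kde2d(fs)
        i, j = np.unravel_index(np.argmax(kde.density), kde.density.shape)
        assert kde.x[i] == pytest.approx(2.0, abs=0.05)
        assert kde.y[j] == pytest.approx(6.0, abs=0.05)

    def test_zero_variance_dimension_rejected(self):
        fs = FeatureSeries(np.arange(10), np.full(10, 1.0), np.linspace(5, 6, 10))
        with pytest.raises(ValueError, match="bandwidth"):
            kde2d(fs)

    def test_too_few_frames_rejected(self):
        fs = FeatureSeries([0], [1.0], [5.0])
        with pytest.raises(ValueError):
            kde2d(fs)


class TestFindModes:
    def test_unimodal_cloud_gives_one_mode(self):
        # n chosen large enough that KDE wiggles stay below mode scale
        fs = _cloud(seed=9, n=20000, sd=(0.2, 0.2))
        modes = find_modes(kde2d(fs))
        assert len(modes) == 1

    def test_rich_preset_gives_two_modes(self):
        fs = generate_feature_cloud(mixture_preset("chol_rich", seed=7))
        modes = find_modes(kde2d(fs))
        assert len(modes) == 2
        assert modes[0].density >= modes[1].density

    def test_depleted_preset_gives_six_modes(self):
        fs = generate_feature_cloud(mixture_preset("chol_depleted", seed=7))
        assert len(find_modes(kde2d(fs))) == 6


class TestAssignFrames:
    def test_unimodal_assignment(self):
        fs = _cloud(seed=10, n=2000)
        kde = kde2d(fs, bandwidth_rule=0.2)
        model = assign_frames(fs, kde, find_modes(kde))
        assert model.n_states == 1
        assert np.all(model.assignment == 1)
        assert model.probabilities[0] == 1.0

    def test_equal_clusters_split_half_half(self):
        spec = MixtureSpec(
            (
                MixtureComponent(0.5, 0.8, 5.3, 0.12, 0.12),
                MixtureComponent(0.5, 2.4, 6.4, 0.12, 0.12),
            ),
            2000,
            seed=11,
        )
        fs = generate_feature_cloud(spec)
        kde = kde2d(fs)
        model = assign_frames(fs, kde, find_modes(kde))
        assert model.n_states == 2
        # binomial 3-sigma band around 0.5 at n=2000
        tol = 3 * 0.5 / np.sqrt(2000)
        assert abs(model.probabilities[0] - 0.5) < tol

    def test_assignment_deterministic_and_probabilities_sum_to_one(self):
        fs = generate_feature_cloud(mixture_preset("chol_depleted", seed=3))
        kde = kde2d(fs)
        modes = find_modes(kde)
        m1 = assign_frames(fs, kde, modes)
        m2 = assign_frames(fs, kde, modes)
        np.testing.assert_array_equal(m1.assignment, m2.assignment)
        assert m1.counts.sum() == len(fs)
        assert m1.probabilities.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.isin(m1.assignment, [m.label for m in modes]))


class TestStateAverageStructure:
    def test_identical_frames_average_to_that_frame(self, ideal_helix, helixdef):
        traj = generate_helix_trajectory([(0, 6)], seed=0, jitter_sd=1e-9, rigid_motion=False)
        fs = compute_features(traj, helixdef)
        # degenerate variance: assign everything to a single synthetic mode
        fs = FeatureSeries(fs.frame_index, fs.rmsd + 1e-6 * np.arange(6), fs.rg)
        kde = kde2d(fs, bandwidth_rule=0.1)
        model = assign_frames(fs, kde, find_modes(kde))
        mean, hel = state_average_structure(traj, model, 1, helixdef)
        np.testing.assert_allclose(mean.coords, traj.frames[0].coords, atol=1e-6)
        assert hel.percent_folded == 100.0

    def test_frames_at_five_broken_average_to_28_57(self, helixdef):
        traj = generate_helix_trajectory([(5, 40)], seed=13)
        fs = compute_features(traj, helixdef)
        kde = kde2d(fs, bandwidth_rule=0.1)
        model = assign_frames(fs, kde, find_modes(kde))
        assert model.n_states == 1
        _, hel = state_average_structure(traj, model, 1, helixdef)
        assert hel.percent_folded == 28.57

    def test_average_permutation_invariant(self, helixdef):
        traj = generate_helix_trajectory([(0, 10)], seed=14)
        fs = compute_features(traj, helixdef)
        kde = kde2d(fs, bandwidth_rule=0.1)
        model = assign_frames(fs, kde, find_modes(kde))
        mean1, _ = state_average_structure(traj, model, 1, helixdef)
        perm = np.arange(10)[::-1]
        traj2 = type(traj)(traj.topology, [traj.frames[i] for i in perm])
        model.assignment = model.assignment[perm]
        mean2, _ = state_average_structure(traj2, model, 1, helixdef)
        # invariant up to the (jitter-scale) error of re-superposing on a
        # different first member
        _, _, rmsd = kabsch_superpose(mean2.coords, mean1.coords)
        assert rmsd < 1e-4

    def test_empty_state_rejected(self, ideal_helix, helixdef):
        fs = _cloud(seed=15, n=1)
        with pytest.raises(ValueError):
            fs_full = _cloud(seed=15, n=50)
            kde = kde2d(fs_full)
            model = assign_frames(fs_full, kde, find_modes(kde))
            state_average_structure(ideal_helix, model, 99, helixdef)
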