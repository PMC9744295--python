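"""PCA variants, free-energy surfaces, k-means separation, hierarchy."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from confrec import conformer_sampling as cs
from confrec import synthetic_data as syn
from tests.conftest import make_trajectory


class TestComputeDihedrals:
    def test_matches_per_frame_geometry(self, planted_trajectory):
        traj, _ = planted_trajectory
        dih = cs.compute_dihedrals(traj, kinds=("psi",), segment="receptor")
        from confrec._geom import dihedral

        t = traj.system.torsion_by_name(dih.labels[0])
        for f in (0, 100, 599):
            want = float(dihedral(*[traj.coords[f, i] for i in t.atoms]))
            assert dih.angles[f, 0] == pytest.approx(want, abs=1e-9)

    def test_empty_selection_is_configuration_error(self, planted_trajectory):
        traj, _ = planted_trajectory
        with pytest.raises(cs.ConfigurationError):
            cs.compute_dihedrals(traj, segment="ligand")

    def test_colinear_quadruple_flagged(self, trajectory_factory):
        coords = np.array([[[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0.0]]])
        traj = trajectory_factory(coords)
        from confrec.structure_io import Torsion

        traj.system.torsions = [Torsion("t", "phi", "receptor", (0, 1, 2, 3))]
        with pytest.warns(UserWarning, match="undefined dihedral"):
            dih = cs.compute_dihedrals(traj)
        assert dih.flagged is not None and len(dih.flagged) == 1


class TestEncodeCircular:
    @pytest.mark.parametrize("theta,sin_cos", [
        (0.0, (0.0, 1.0)),
        (90.0, (1.0, 0.0)),
        (-180.0, (0.0, -1.0)),
    ])
    def test_unit_circle_points(self, theta, sin_cos):
        series = cs.DihedralSeries(labels=["t"], kinds=["phi"], segments=["receptor"],
                                   angles=np.array([[theta]]))
        feats = cs.encode_circular(series)
        assert feats.values[0, 0] == pytest.approx(sin_cos[0], abs=1e-12)
        assert feats.values[0, 1] == pytest.approx(sin_cos[1], abs=1e-12)

    def test_sin2_cos2_identity(self, planted_trajectory):
        traj, _ = planted_trajectory
        feats = cs.encode_circular(cs.compute_dihedrals(traj))
        s2c2 = feats.values[:, 0::2] ** 2 + feats.values[:, 1::2] ** 2
        assert np.abs(s2c2 - 1).max() < 1e-9


class TestCartesianFeatures:
    def test_rigid_body_motion_removed(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(7, 3))
        frames = []
        for _ in range(5):
            th = rng.uniform(0, 2 * np.pi)
            R = np.array([[np.cos(th), -np.sin(th), 0],
                          [np.sin(th), np.cos(th), 0], [0, 0, 1]])
            frames.append(base @ R.T + rng.normal(size=3) * 5)
        traj = make_trajectory(np.array(frames))
        feats = cs.cartesian_features(traj)
        assert feats.values.var(axis=0).max() < 1e-10

    def test_repeated_frame_gives_constant_features(self):
        base = np.random.default_rng(1).normal(size=(5, 3))
        traj = make_trajectory(np.repeat(base[None], 4, axis=0))
        feats = cs.cartesian_features(traj)
        assert np.ptp(feats.values, axis=0).max() < 1e-12

    def test_two_frame_mean_matches_direct_fit(self):
        """Closed two-frame case: iterating the mean must agree with a single
        direct superposition of frame 2 onto frame 1 (same fitted rmsd)."""
        from confrec._geom import kabsch

        rng = np.random.default_rng(2)
        f0 = rng.normal(size=(6, 3))
        f1 = f0 + rng.normal(size=(6, 3)) * 0.1
        traj = make_trajectory(np.array([f0, f1]))
        feats = cs.cartesian_features(traj)
        a = feats.values[0].reshape(-1, 3)
        b = feats.values[1].reshape(-1, 3)
        iter_rmsd = np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))
        _, _, direct = kabsch(f0, f1)
        assert iter_rmsd == pytest.approx(direct, abs=1e-9)

    def test_colinear_reference_rejected(self):
        line = np.column_stack([np.arange(4.0), np.zeros(4), np.zeros(4)])
        traj = make_trajectory(np.repeat(line[None], 3, axis=0))
        with pytest.raises(ValueError, match="degenerate"):
            cs.cartesian_features(traj)


class TestRunPCA:
    def test_rank_one_cloud(self):
        t = np.random.default_rng(0).normal(size=200)
        X = np.column_stack([t, t])
        proj = cs.run_pca(cs.FeatureMatrix(X, ["x", "y"]), 2)
        assert proj.variance_fraction[0] == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_gaussian_eigenvalues_balanced(self):
        X = np.random.default_rng(1).normal(size=(10_000, 2))
        proj = cs.run_pca(cs.FeatureMatrix(X, ["x", "y"]), 2)
        ratio = proj.eigenvalues[0] / proj.eigenvalues[1]
        assert ratio == pytest.approx(1.0, rel=0.05)

    def test_full_reconstruction_identity(self):
        X = np.random.default_rng(2).normal(size=(50, 4))
        proj = cs.run_pca(cs.FeatureMatrix(X, list("abcd")), 4)
        rec = proj.projections @ proj.components + X.mean(axis=0)
        assert np.abs(rec - X).max() < 1e-9

    def test_constant_features_give_zero_spectrum(self):
        X = np.ones((10, 3))
        proj = cs.run_pca(cs.FeatureMatrix(X, list("abc")), 2)
        assert np.abs(proj.eigenvalues).max() < 1e-12
        assert np.abs(proj.projections).max() < 1e-9

    def test_components_orthonormal(self, planted_trajectory):
        traj, _ = planted_trajectory
        feats = cs.encode_circular(cs.compute_dihedrals(traj))
        proj = cs.run_pca(feats, 4)
        gram = proj.components @ proj.components.T
        assert np.abs(gram - np.eye(4)).max() < 1e-6


class TestFreeEnergySurface:
    def _surface_from_occupancy(self, occupancy, kT=1.0):
        """Place point masses with the requested bin occupancies."""
        xs = []
        for i, n in enumerate(occupancy):
            xs += [[i + 0.5, 0.5]] * n
        X = np.array(xs, float)
        proj = cs.PCProjection(
            eigenvalues=np.array([1.0, 0.5]), components=np.eye(2),
            projections=X, variance_fraction=np.array([0.7, 0.3]))
        return cs.free_energy_surface(proj, n_bins=len(occupancy), kT=kT)

    def test_two_bin_occupancy_gives_ln4(self):
        fel = self._surface_from_occupancy([80, 20], kT=1.0)
        occupied = np.sort(fel.delta_g[fel.probability > 0])
        assert occupied[0] == pytest.approx(0.0, abs=1e-12)
        assert occupied[1] == pytest.approx(np.log(4.0), abs=1e-12)

    def test_uniform_occupancy_is_flat_zero(self):
        fel = self._surface_from_occupancy([25, 25, 25, 25])
        assert np.allclose(fel.delta_g[fel.probability > 0], 0.0, atol=1e-12)

    def test_kT_scales_linearly(self):
        a = self._surface_from_occupancy([80, 20], kT=1.0)
        b = self._surface_from_occupancy([80, 20], kT=2.0)
        occ = a.probability > 0
        assert np.allclose(b.delta_g[occ], 2 * a.delta_g[occ], atol=1e-12)

    def test_random_histograms_normalised_with_zero_minimum(self):
        """Probabilities sum to 1 and min ΔG = 0 across random histograms."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            X = rng.normal(size=(rng.integers(10, 200), 2))
            proj = cs.PCProjection(
                eigenvalues=np.array([1.0, 0.5]), components=np.eye(2),
                projections=X, variance_fraction=np.array([0.7, 0.3]))
            fel = cs.free_energy_surface(proj, n_bins=int(rng.integers(2, 12)))
            assert fel.probability.sum() == pytest.approx(1.0, abs=1e-9)
            occ = fel.probability > 0
            assert np.nanmin(fel.delta_g[occ]) == pytest.approx(0.0, abs=1e-12)
            assert not np.any(np.isfinite(fel.delta_g[~occ]))


class TestKMeans:
    def _proj(self, X):
        X = np.asarray(X, float)
        return cs.PCProjection(eigenvalues=np.array([1.0, 0.5]),
                               components=np.eye(2), projections=X,
                               variance_fraction=np.array([0.7, 0.3]))

    def test_two_point_masses(self):
        X = np.array([[0, 0]] * 30 + [[10, 0]] * 20, float)
        model = cs.kmeans_cluster(self._proj(X), k=2, seed=0)
        assert sorted(model.populations.tolist()) == [20, 30]

    def test_k_equal_one(self):
        X = np.random.default_rng(0).normal(size=(40, 2))
        model = cs.kmeans_cluster(self._proj(X), k=1)
        assert model.k == 1 and np.all(model.labels == 0)

    def test_k_larger_than_frames_rejected(self):
        X = np.zeros((3, 2))
        with pytest.raises(ValueError, match="exceeds"):
            cs.kmeans_cluster(self._proj(X), k=5)

    def test_auto_k_with_flat_variance_falls_back_to_one(self):
        X = np.random.default_rng(1).normal(size=(100, 2)) * 0.01
        model = cs.kmeans_cluster(self._proj(X), k="auto", variance_floor=0.05)
        assert model.k == 1

    def test_deterministic_under_fixed_seed(self):
        X = np.random.default_rng(2).normal(size=(200, 2))
        X[100:] += 4.0
        a = cs.kmeans_cluster(self._proj(X), k=2, seed=5, n_restarts=10)
        b = cs.kmeans_cluster(self._proj(X), k=2, seed=5, n_restarts=10)
        assert np.array_equal(a.labels, b.labels)


class TestDPCACircularity:
    def test_uniform_torsion_shift_preserves_spectrum(self, planted_trajectory):
        """Rotating every torsion by a constant is an orthogonal map of the
        sin/cos features: the eigenvalue spectrum must not change."""
        traj, _ = planted_trajectory
        dih = cs.compute_dihedrals(traj)
        shifted = cs.DihedralSeries(
            labels=dih.labels, kinds=dih.kinds, segments=dih.segments,
            angles=cs.wrap_degrees(dih.angles + 77.0))
        ncomp = 5
        a = cs.run_pca(cs.encode_circular(dih), ncomp)
        b = cs.run_pca(cs.encode_circular(shifted), ncomp)
        assert np.abs(a.eigenvalues - b.eigenvalues).max() < 1e-6


class TestHierarchy:
    def test_single_level_k1_is_whole_trajectory(self, planted_trajectory):
        traj, _ = planted_trajectory
        ens = cs.hierarchical_sample(traj, [cs.LevelSpec("dihedral", 1)])
        assert len(ens.members) == 1
        assert len(ens.members[0]) == traj.n_frames

    def test_two_by_two_planted_product_states(self, complex_system):
        """2 receptor states × 2 ligand states: two refinement levels recover
        4 leaves with populations within 3 binomial SE of the planted 2×2
        weights."""
        system = complex_system
        base = {z.torsion_name: z.torsion for z in system.zmatrix if z.torsion_name}
        names = system.mobile_torsions
        ref = np.array([base[n] for n in names])
        rec_i = [i for i, n in enumerate(names) if not n.startswith("g")]
        lig_i = [i for i, n in enumerate(names) if n.startswith("g")]
        specs, weights = [], []
        for a, wa in ((0, 0.6), (1, 0.4)):
            for b, wb in ((0, 0.7), (1, 0.3)):
                m = ref.copy()
                m[rec_i[-2:]] += a * 90.0
                m[lig_i[-2:]] += b * 90.0
                specs.append(syn.StateSpec(tuple(syn.wrap_degrees(m)), 400.0, wa * wb))
                weights.append(wa * wb)
        traj, truth = syn.sample_metastable_trajectory(system, specs, 800, 0.02,
                                                       seed=17)
        levels = [cs.LevelSpec("dihedral", 2, segment="receptor"),
                  cs.LevelSpec("dihedral", 2, segment="ligand")]
        ens = cs.hierarchical_sample(traj, levels, seed=0)
        assert len(ens.members) == 4
        ari = adjusted_rand_score(truth.frame_labels, ens.labels(800))
        assert ari >= 0.95
        pops = sorted(ens.populations.values(), reverse=True)
        for p, w in zip(pops, sorted(weights, reverse=True)):
            assert abs(p / 800 - w) <= 3 * np.sqrt(w * (1 - w) / 800)

    def test_min_population_merges_small_leaves(self, planted_trajectory):
        traj, _ = planted_trajectory
        # min_population larger than any planted subcluster: collapse to parent
        ens = cs.hierarchical_sample(traj, [cs.LevelSpec("dihedral", 3)],
                                     min_population=500)
        assert len(ens.members) == 1

    def test_unavailable_torsions_named_in_error(self, planted_trajectory):
        traj, _ = planted_trajectory
        with pytest.raises(cs.ConfigurationError, match="level 1"):
            cs.hierarchical_sample(traj, [cs.LevelSpec("dihedral", 2,
                                                       segment="ligand")])


class TestSubtrajectories:
    def test_partition_round_trip(self, planted_trajectory):
        traj, _ = planted_trajectory
        ens = cs.ConformerEnsemble(members={0: np.array([0, 2, 4]),
                                            1: np.array([1, 3])})
        subs = cs.extract_subtrajectories(traj, ens)
        assert subs[0].n_frames == 3 and subs[1].n_frames == 2
        merged = np.concatenate([subs[0].frame_times, subs[1].frame_times])
        assert sorted(merged.tolist()) == [0.0, 1.0, 2.0, 3.0, 4.0]

    def test_empty_cluster_skipped_with_warning(self, planted_trajectory):
        traj, _ = planted_trajectory
        ens = cs.ConformerEnsemble(members={0: np.arange(5), 1: np.array([], int)})
        with pytest.warns(UserWarning, match="empty"):
            subs = cs.extract_subtrajectories(traj, ens)
        assert set(subs) == {0}

    def test_subtrajectory_rmsd_sd_not_larger(self, receptor, planted_trajectory):
        """Binning metastable states reduces the RMSD spread: each planted
        state's subtrajectory has sd(RMSD) below the full trajectory's."""
        from confrec.ensemble_descriptors import rmsd_series

        traj, truth = planted_trajectory
        full = rmsd_series(traj)
        for state in range(3):
            idx = np.where(truth.frame_labels == state)[0]
            sub = traj.subset(idx)
            sd = rmsd_series(sub).sd
            assert sd <= full.sd
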