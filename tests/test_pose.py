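"""Pose-clustering pipeline: subsampling, bound filter, featurization, PCA
projection, mixture fitting, centroids, RMSD stability."""

import numpy as np
import pandas as pd
import pytest

from posepop.pose import (
    FeatureMatrix,
    centroid_frames,
    cluster_poses,
    compare_pose_stability,
    featurize,
    fit_mixture,
    ligand_rmsd,
    name_clusters,
    project_2d,
    select_bound,
    subsample,
)
from posepop.topology import FEATURE_COLUMNS, AtomRecord, Topology
from posepop.trajectory import Trajectory


def _single_pose_traj(topo, coords_list, times=None, reps=None):
    n = len(coords_list)
    return Trajectory(
        coords=np.array(coords_list),
        times=np.asarray(times if times is not None else np.arange(1, n + 1), dtype=float),
        replicate_ids=np.asarray(reps if reps is not None else np.zeros(n), dtype=int),
        topology=topo,
    )


class TestSubsample:
    def _uniform(self, topo, n, dt=1.0):
        ref = topo.reference_coords
        return _single_pose_traj(topo, [ref] * n, times=(np.arange(n) + 1) * dt)

    def test_second_half_window_at_1ns(self, topo):
        traj = self._uniform(topo, 200)
        sub = subsample(traj, t_start=100.0, t_end=200.0, interval=1.0)
        # both window ends inclusive
        assert sub.n_frames == 101
        assert sub.times[0] == 100.0 and sub.times[-1] == 200.0

    def test_full_window_native_spacing_is_identity(self, topo):
        traj = self._uniform(topo, 50)
        sub = subsample(traj, t_start=1.0, t_end=50.0, interval=1.0)
        np.testing.assert_array_equal(sub.times, traj.times)

    def test_double_interval_keeps_every_second_frame(self, topo):
        traj = self._uniform(topo, 50)
        sub = subsample(traj, t_start=1.0, t_end=50.0, interval=2.0)
        np.testing.assert_array_equal(sub.times, traj.times[::2])

    def test_default_window_is_second_half(self, topo):
        traj = self._uniform(topo, 200)
        sub = subsample(traj)
        assert sub.times[0] == 100.0 and sub.n_frames == 101

    def test_empty_selection_raises(self, topo):
        traj = self._uniform(topo, 10)
        with pytest.raises(ValueError, match="selects no frames"):
            subsample(traj, t_start=3.25, t_end=3.75, interval=1.0)

    def test_bad_window_raises(self, topo):
        traj = self._uniform(topo, 10)
        with pytest.raises(ValueError):
            subsample(traj, t_start=5.0, t_end=5.0)


class TestSelectBound:
    def test_retained_fraction_tracks_ground_truth(self, make_traj):
        traj, truth = make_traj(
            n_replicates=4, n_frames_per_replicate=150, unbound_fraction=0.2, seed=8
        )
        bound, mask = select_bound(traj)
        assert mask.mean() == pytest.approx(0.8, abs=0.05)
        assert bound.n_frames == mask.sum()

    def test_boundary_distance_excluded_strictly(self, topo):
        # place the ligand so S1 sits exactly 5 A from C433 N
        ref = topo.reference_coords.copy()
        s1, c433_n = topo.ligand_index("S1"), topo.index(433, "N")
        u = ref[s1] - ref[c433_n]
        u /= np.linalg.norm(u)
        frame = ref.copy()
        frame[topo.ligand_indices] += (ref[c433_n] + 5.0 * u) - ref[s1]
        traj = _single_pose_traj(topo, [frame])
        d = np.linalg.norm(traj.coords[0, s1] - traj.coords[0, c433_n])
        assert d == pytest.approx(5.0, abs=1e-9)
        _, mask = select_bound(traj, threshold=5.0)
        assert not mask[0]

    def test_all_bound_is_identity(self, make_traj):
        traj, _ = make_traj(n_replicates=1, n_frames_per_replicate=30,
                            unbound_fraction=0.0, seed=1)
        bound, mask = select_bound(traj)
        assert mask.all()
        np.testing.assert_array_equal(bound.coords, traj.coords)

    def test_missing_anchor_named_in_error(self, topo):
        atoms = [a for a in topo.atoms if not (a.res_id == 433 and a.name == "N")]
        keep = [i for i, a in enumerate(topo.atoms)
                if not (a.res_id == 433 and a.name == "N")]
        small = Topology(atoms=atoms, reference_coords=topo.reference_coords[keep])
        traj = _single_pose_traj(small, [small.reference_coords])
        with pytest.raises(KeyError, match="433"):
            select_bound(traj)


class TestFeaturize:
    def test_hand_computed_distances(self, topo):
        f = featurize(_single_pose_traj(topo, [topo.reference_coords]))
        ref = topo.reference_coords
        expected = np.linalg.norm(
            ref[topo.ligand_index("S1")] - ref[topo.index(433, "N")]
        )
        assert f.data["C433_1"].iloc[0] == pytest.approx(expected)
        # every column equals its defining pair distance
        for col, li, pi in topo.feature_pair_indices():
            assert f.data[col].iloc[0] == pytest.approx(np.linalg.norm(ref[li] - ref[pi]))

    def test_atom_order_permutation_invariant(self, topo):
        rng = np.random.default_rng(0)
        perm = rng.permutation(topo.n_atoms)
        permuted = Topology(
            atoms=[topo.atoms[i] for i in perm],
            reference_coords=topo.reference_coords[perm],
        )
        f1 = featurize(_single_pose_traj(topo, [topo.reference_coords]))
        f2 = featurize(_single_pose_traj(permuted, [permuted.reference_coords]))
        pd.testing.assert_frame_equal(f1.data, f2.data)

    def test_column_contract_enforced(self, topo):
        f = featurize(_single_pose_traj(topo, [topo.reference_coords] * 3))
        assert tuple(f.data.columns) == FEATURE_COLUMNS
        with pytest.raises(ValueError, match="positive"):
            FeatureMatrix(f.data - 100.0)


class TestProject2d:
    def test_two_templates_collapse_to_two_points(self, two_template_traj):
        traj, labels = two_template_traj
        proj = project_2d(featurize(traj))
        pts = np.round(proj.coords, 9)
        assert len(np.unique(pts, axis=0)) == 2

    def test_isotropic_cloud_has_near_equal_explained_variance(self, topo):
        rng = np.random.default_rng(42)
        x = 10.0 + rng.normal(0, 0.5, size=(3000, 10))
        idx = pd.MultiIndex.from_product([[0], range(3000)],
                                         names=["replicate_id", "frame_index"])
        f = FeatureMatrix(pd.DataFrame(x, columns=list(FEATURE_COLUMNS), index=idx))
        proj = project_2d(f)
        ev1, ev2 = proj.explained_variance
        assert ev2 / ev1 > 0.8  # eigenvalue symmetry up to sampling error

    def test_invariant_to_constant_column_shift(self, make_traj):
        traj, _ = make_traj(n_replicates=1, n_frames_per_replicate=50, seed=2)
        f = featurize(traj)
        shifted = FeatureMatrix(f.data + 7.0)
        p1, p2 = project_2d(f), project_2d(shifted)
        np.testing.assert_allclose(p1.coords, p2.coords, atol=1e-8)

    def test_rank_zero_input_raises(self, topo):
        traj = _single_pose_traj(topo, [topo.reference_coords] * 5)
        with pytest.raises(ValueError, match="rank"):
            project_2d(featurize(traj))

    def test_too_few_frames_raises(self, topo):
        traj = _single_pose_traj(topo, [topo.reference_coords] * 2)
        with pytest.raises(ValueError, match="3 frames"):
            project_2d(featurize(traj))


class TestFitMixture:
    def test_recovers_mixture_populations(self, make_traj):
        traj, truth = make_traj(
            n_replicates=8, n_frames_per_replicate=100,
            pose_weight_A=0.55, unbound_fraction=0.0, seed=6,
        )
        proj = project_2d(featurize(traj))
        result = fit_mixture(proj, k=2, seed=0)
        realized = (truth.pose_labels == "A").mean()
        assert result.converged
        # populations match the realized label fractions almost exactly
        assert min(abs(result.populations - realized)) < 0.01
        assert result.populations.sum() == pytest.approx(1.0)

    def test_single_component(self, make_traj):
        traj, _ = make_traj(n_replicates=1, n_frames_per_replicate=50,
                            pose_weight_A=1.0, seed=0)
        proj = project_2d(featurize(traj))
        result = fit_mixture(proj, k=1, seed=0)
        assert result.populations.tolist() == [1.0]

    def test_cluster_identity_from_geometry_not_fit_order(self, make_traj):
        # pose A is the *minor* cluster here; naming must still call it A
        traj, truth = make_traj(
            n_replicates=8, n_frames_per_replicate=100,
            pose_weight_A=0.3, unbound_fraction=0.0, seed=13,
        )
        report = cluster_poses(traj, t_start=1.0, seed=0)
        realized = (truth.pose_labels == "A").mean()
        assert report.populations["A"] == pytest.approx(realized, abs=0.01)
        assert report.populations["A"] < report.populations["B"]

    def test_bic_scan_prefers_two_components(self, make_traj):
        from posepop.pose import scan_components

        traj, _ = make_traj(n_replicates=4, n_frames_per_replicate=100,
                            pose_weight_A=0.5, unbound_fraction=0.0, seed=3)
        proj = project_2d(featurize(traj))
        scan = scan_components(proj, k_max=3, seed=0)
        assert scan.loc[scan["bic"].idxmin(), "k"] == 2

    def test_too_few_frames_rejected(self, make_traj):
        traj, _ = make_traj(n_replicates=1, n_frames_per_replicate=15, seed=0)
        proj = project_2d(featurize(traj))
        with pytest.raises(ValueError, match="frames"):
            fit_mixture(proj, k=2)


class TestCentroidFrames:
    def test_agrees_with_exhaustive_search(self, make_traj):
        traj, _ = make_traj(n_replicates=4, n_frames_per_replicate=100,
                            pose_weight_A=0.5, seed=21)
        proj = project_2d(featurize(traj))
        result = fit_mixture(proj, k=2, seed=0)
        cents = centroid_frames(result, proj)
        keys = list(proj.frame_index)
        for c, cent in enumerate(cents):
            members = np.flatnonzero(result.assignments == c)
            d = np.linalg.norm(proj.coords[members] - result.means[c], axis=1)
            brute = sorted(
                (float(di), keys[int(i)]) for di, i in zip(d, members)
            )[0][1]
            assert cent == brute

    def test_noise_free_templates_tie_break_earliest(self, two_template_traj):
        traj, labels = two_template_traj
        proj = project_2d(featurize(traj))
        result = fit_mixture(proj, k=2, seed=0)
        cents = centroid_frames(result, proj)
        names = name_clusters(result, traj, proj)
        # all frames of a template are equidistant (distance 0) from their
        # cluster mean; the earliest frame of each template must be returned
        by_name = {names[c]: cent for c, cent in enumerate(cents)}
        assert by_name["A"] == (0, 0)
        assert by_name["B"] == (0, 1)

    def test_single_point_at_mean(self, make_traj):
        traj, _ = make_traj(n_replicates=2, n_frames_per_replicate=30,
                            pose_weight_A=0.5, seed=5)
        proj = project_2d(featurize(traj))
        result = fit_mixture(proj, k=2, seed=0)
        # move one cluster mean exactly onto a member point
        c = 0
        member = int(np.flatnonzero(result.assignments == c)[3])
        result.means[c] = proj.coords[member]
        cents = centroid_frames(result, proj)
        assert cents[c] == list(proj.frame_index)[member]


class TestPipelineInvariants:
    def test_deterministic_given_seed(self, make_traj):
        traj, _ = make_traj(seed=4)
        r1 = cluster_poses(traj, seed=3)
        r2 = cluster_poses(traj, seed=3)
        assert r1.to_dict() == r2.to_dict()

    def test_populations_invariant_to_replicate_order(self, make_traj):
        traj, _ = make_traj(n_replicates=4, n_frames_per_replicate=100, seed=17)
        r1 = cluster_poses(traj, seed=0)
        order = np.concatenate([
            np.flatnonzero(traj.replicate_ids == r) for r in [3, 1, 0, 2]
        ])
        shuffled = traj.select_frames(order)
        r2 = cluster_poses(shuffled, seed=0)
        assert r1.populations["A"] == pytest.approx(r2.populations["A"], abs=1e-9)

    @pytest.mark.parametrize("weight", [0.5, 0.55, 0.61, 0.75])
    def test_population_recovery_across_weights(self, make_traj, weight):
        """Across mixture weights, the recovered major-cluster population
        matches the realized bound-frame label fraction within 3 pp in at
        least 95% of seeded repetitions (here: all of 10)."""
        for seed in range(10):
            traj, truth = make_traj(
                n_replicates=8, n_frames_per_replicate=100,
                pose_weight_A=weight, unbound_fraction=0.1,
                seed=1000 + seed,
            )
            bound, mask = select_bound(traj)
            realized = (truth.pose_labels[mask] == "A").mean()
            report = cluster_poses(traj, t_start=1.0, seed=seed)
            assert report.populations["A"] == pytest.approx(realized, abs=0.03)


class TestLigandRmsd:
    def test_reference_vs_itself_is_zero(self, topo):
        traj = _single_pose_traj(topo, [topo.reference_coords])
        rs = ligand_rmsd(traj, topo.reference_coords)
        assert rs.median[0] == pytest.approx(0.0, abs=1e-9)

    def test_pure_ligand_translation_gives_exact_rmsd(self, topo):
        frame = topo.reference_coords.copy()
        frame[topo.ligand_indices] += np.array([0.0, 0.0, 2.0])
        traj = _single_pose_traj(topo, [frame])
        rs = ligand_rmsd(traj, topo.reference_coords)
        assert rs.median[0] == pytest.approx(2.0, abs=1e-9)

    def test_median_and_mad_across_replicates(self, topo):
        # replicates with ligand shifted by 1, 1, 1, 5 A at one time point
        frames, reps = [], []
        for r, shift in enumerate([1.0, 1.0, 1.0, 5.0]):
            f = topo.reference_coords.copy()
            f[topo.ligand_indices] += np.array([shift, 0.0, 0.0])
            frames.append(f)
            reps.append(r)
        traj = _single_pose_traj(topo, frames, times=[1.0] * 4, reps=reps)
        rs = ligand_rmsd(traj, topo.reference_coords)
        assert rs.median[0] == pytest.approx(1.0, abs=1e-9)
        assert rs.mad[0] == pytest.approx(0.0, abs=1e-9)

    def test_invariant_under_global_rigid_transform(self, make_traj, topo):
        from scipy.spatial.transform import Rotation

        traj, _ = make_traj(n_replicates=2, n_frames_per_replicate=20, seed=2)
        rs1 = ligand_rmsd(traj, topo.reference_coords)
        rot = Rotation.from_euler("xyz", [30, -45, 60], degrees=True)
        moved = traj.select_frames(np.arange(traj.n_frames))
        moved.coords = rot.apply(
            traj.coords.reshape(-1, 3)
        ).reshape(traj.coords.shape) + np.array([10.0, -4.0, 2.0])
        rs2 = ligand_rmsd(moved, topo.reference_coords)
        np.testing.assert_allclose(rs1.median, rs2.median, atol=1e-8)

    def test_shape_mismatch_rejected(self, topo):
        traj = _single_pose_traj(topo, [topo.reference_coords])
        with pytest.raises(ValueError, match="shape"):
            ligand_rmsd(traj, topo.reference_coords[:-1])


class TestPoseStability:
    def _series(self, topo, shifts, reps=2):
        frames, rep_ids, times = [], [], []
        for r in range(reps):
            for t, s in enumerate(shifts):
                f = topo.reference_coords.copy()
                f[topo.ligand_indices] += np.array([s, 0.0, 0.0])
                frames.append(f)
                rep_ids.append(r)
                times.append(float(t + 1))
        traj = _single_pose_traj(topo, frames, times=times, reps=rep_ids)
        return ligand_rmsd(traj, topo.reference_coords)

    def test_identical_series_tie(self, topo):
        a = self._series(topo, [1.0, 1.5])
        b = self._series(topo, [1.0, 1.5])
        rep = compare_pose_stability(a, b)
        assert rep.more_stable == "tie" and rep.difference == pytest.approx(0.0)

    def test_offset_series_declares_lower_one_stable(self, topo):
        a = self._series(topo, [1.0, 1.5])
        b = self._series(topo, [2.0, 2.5])
        rep = compare_pose_stability(a, b)
        assert rep.more_stable == "A"
        assert rep.difference == pytest.approx(-1.0, abs=1e-9)

    def test_noisier_ensemble_less_stable(self, topo, make_traj):
        quiet, _ = make_traj(n_replicates=4, n_frames_per_replicate=50,
                             pose_weight_A=1.0, positional_noise_sd=0.2, seed=1)
        loud, _ = make_traj(n_replicates=4, n_frames_per_replicate=50,
                            pose_weight_A=1.0, positional_noise_sd=0.4, seed=1)
        rep = compare_pose_stability(
            ligand_rmsd(quiet, topo.reference_coords),
            ligand_rmsd(loud, topo.reference_coords),
        )
        assert rep.more_stable == "A"

    def test_grid_mismatch_rejected(self, topo):
        a = self._series(topo, [1.0, 1.5])
        b = self._series(topo, [1.0, 1.5, 2.0])
        with pytest.raises(ValueError, match="time grid"):
            compare_pose_stability(a, b)
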