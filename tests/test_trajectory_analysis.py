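"""RMSF profiles and hydrogen-bond occupancy from replicate ensembles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from serpinmap import synthetic_data as sd
from serpinmap.trajectory_analysis import (
    HBondCriteria,
    TrajectoryEnsemble,
    compute_rmsf,
    count_hbonds_frame,
    hbond_occupancy,
    load_ensemble,
    occupancy_difference,
    write_ensemble_pdb,
)


class TestEnsembleIO:
    def test_synthetic_ensemble_shape(self, helix):
        ensemble = sd.make_trajectory(helix, 0.1, n_frames=10, n_replicates=2, seed=0)
        assert ensemble.n_replicates == 2
        assert all(rep.shape[0] == 10 for rep in ensemble.replicates)

    def test_multi_model_pdb_roundtrip(self, helix, tmp_path):
        ensemble = sd.make_trajectory(helix, 0.1, n_frames=5, n_replicates=2, seed=1)
        sd.write_structure_pdb(helix, tmp_path / "top.pdb")
        paths = write_ensemble_pdb(ensemble, tmp_path / "traj")
        again = load_ensemble(paths, tmp_path / "top.pdb")
        for a, b in zip(ensemble.replicates, again.replicates):
            assert np.abs(a - b).max() < 1e-3

    def test_atom_count_mismatch_rejected(self, helix, tmp_path):
        ensemble = sd.make_trajectory(helix, 0.1, n_frames=3, seed=2)
        paths = write_ensemble_pdb(ensemble, tmp_path / "traj")
        sd.write_structure_pdb(sd.make_helix(10), tmp_path / "short.pdb")
        with pytest.raises(ValueError, match="atoms"):
            load_ensemble(paths, tmp_path / "short.pdb")

    def test_inconsistent_replicate_shape_rejected(self, helix):
        good = sd.make_trajectory(helix, 0.1, n_frames=3, seed=3).replicates[0]
        with pytest.raises(ValueError):
            TrajectoryEnsemble(
                replicates=[good, good[:, :10, :]], topology=helix
            )


class TestRmsf:
    def test_static_trajectory_is_zero(self, helix):
        ensemble = sd.make_trajectory(helix, 0.0, n_frames=5, seed=0)
        profile = compute_rmsf(ensemble)
        assert np.allclose(profile.rmsf, 0.0, atol=1e-12)

    def test_isotropic_gaussian_closed_form(self, helix):
        """Per-coordinate jitter σ gives RMSF σ√3 for isotropic noise."""
        sigma = 0.2
        ensemble = sd.make_trajectory(helix, sigma, n_frames=5000, seed=4)
        profile = compute_rmsf(ensemble)
        assert profile.rmsf.mean() == pytest.approx(sigma * np.sqrt(3), rel=0.05)

    def test_replicate_averaging(self, helix):
        e1 = sd.make_trajectory(helix, 0.1, n_frames=200, seed=5)
        e2 = sd.make_trajectory(helix, 0.3, n_frames=200, seed=6)
        combined = TrajectoryEnsemble(
            replicates=[e1.replicates[0], e2.replicates[0]], topology=helix
        )
        mean_profile = compute_rmsf(combined).rmsf
        separate = (compute_rmsf(e1).rmsf + compute_rmsf(e2).rmsf) / 2
        assert np.allclose(mean_profile, separate, atol=1e-12)

    def test_amplitude_scaling_linear(self, helix):
        """RMSF scales linearly with the jitter amplitude."""
        r1 = compute_rmsf(sd.make_trajectory(helix, 0.1, n_frames=3000, seed=7)).rmsf
        r3 = compute_rmsf(sd.make_trajectory(helix, 0.3, n_frames=3000, seed=8)).rmsf
        assert r3.mean() / r1.mean() == pytest.approx(3.0, rel=0.05)

    def test_single_frame_rejected(self, helix):
        ensemble = sd.make_trajectory(helix, 0.1, n_frames=1, seed=9)
        with pytest.raises(ValueError, match="2 frames"):
            compute_rmsf(ensemble)


class TestHBondCriteria:
    @pytest.mark.parametrize(
        "distance,angle,expected",
        [
            (3.40, 20.0, 1),  # inside both limits
            (3.60, 20.0, 0),  # distance exceeds 3.5 Å
            (3.40, 31.0, 0),  # angle exceeds 30°
            (3.50, 30.0, 1),  # boundary counts (≤ limits)
        ],
    )
    def test_constructed_geometries(self, distance, angle, expected):
        frame, donors, acceptors = sd.hbond_triad(distance, angle)
        assert count_hbonds_frame(frame, donors, acceptors) == expected

    def test_monotone_under_tightening(self, rng):
        """Tightening either criterion never increases the count."""
        for _ in range(1000):
            distance = rng.uniform(2.5, 5.0)
            angle = rng.uniform(0.0, 60.0)
            frame, donors, acceptors = sd.hbond_triad(distance, angle)
            loose = count_hbonds_frame(
                frame, donors, acceptors, HBondCriteria(3.5, 30.0)
            )
            tight_d = count_hbonds_frame(
                frame, donors, acceptors, HBondCriteria(3.2, 30.0)
            )
            tight_a = count_hbonds_frame(
                frame, donors, acceptors, HBondCriteria(3.5, 20.0)
            )
            assert tight_d <= loose
            assert tight_a <= loose


class TestOccupancy:
    @pytest.mark.parametrize("p", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_prescribed_occupancy_recovered(self, p):
        n_frames = 4000
        ensemble = sd.make_hbond_ensemble(
            p, n_frames=n_frames, n_replicates=2, seed=11
        )
        table = hbond_occupancy(ensemble, [(1, 2)])
        estimate = table.frame["mean"].iloc[0]
        se = max(np.sqrt(p * (1 - p) / (2 * n_frames)), 1e-12)
        assert abs(estimate - p) <= 3 * se + 1e-12

    def test_always_bonded_is_exactly_one(self):
        ensemble = sd.make_hbond_ensemble(1.0, n_frames=100, seed=12)
        table = hbond_occupancy(ensemble, [(1, 2)])
        assert table.frame["mean"].iloc[0] == 1.0

    def test_never_bonded_is_zero(self):
        ensemble = sd.make_hbond_ensemble(0.0, n_frames=100, seed=13)
        table = hbond_occupancy(ensemble, [(1, 2)])
        assert table.frame["mean"].iloc[0] == 0.0

    def test_rigid_transform_invariance(self):
        ensemble = sd.make_hbond_ensemble(0.5, n_frames=500, seed=14)
        rot = Rotation.random(random_state=3).as_matrix()
        moved = TrajectoryEnsemble(
            replicates=[
                rep @ rot.T + np.array([1.0, 2.0, 3.0])
                for rep in ensemble.replicates
            ],
            topology=ensemble.topology,
        )
        a = hbond_occupancy(ensemble, [(1, 2)]).frame["mean"].iloc[0]
        b = hbond_occupancy(moved, [(1, 2)]).frame["mean"].iloc[0]
        assert a == b

    def test_stride_must_divide_frames(self):
        ensemble = sd.make_hbond_ensemble(0.5, n_frames=50, seed=15, frame_interval=2.0)
        with pytest.raises(ValueError, match="stride"):
            hbond_occupancy(ensemble, [(1, 2)], stride=3.0)

    def test_donor_without_hydrogen_rejected(self):
        ensemble = sd.make_hbond_ensemble(0.5, n_frames=10, seed=16)
        with pytest.raises(ValueError, match="donor residue 2"):
            hbond_occupancy(ensemble, [(2, 1)])

    def test_empty_pair_list_rejected(self):
        ensemble = sd.make_hbond_ensemble(0.5, n_frames=10, seed=17)
        with pytest.raises(ValueError, match="empty"):
            hbond_occupancy(ensemble, [])


class TestOccupancyDifference:
    def test_self_difference_zero(self):
        ensemble = sd.make_hbond_ensemble(0.5, n_frames=200, seed=18)
        table = hbond_occupancy(ensemble, [(1, 2)])
        diff = occupancy_difference(table, table)
        assert (diff.difference == 0).all()

    def test_variant_ledger_layout(self):
        """A bond fully occupied in one variant and absent in the other
        yields difference = mean_a − 0, the layout of a mutation ledger
        (e.g. the helix-C → posthelix-I-loop bond lost by E75V:
        1.28 − 0.00 = 1.28)."""
        wild = hbond_occupancy(
            sd.make_hbond_ensemble(1.0, n_frames=200, seed=19), [(1, 2)]
        )
        mutant = hbond_occupancy(
            sd.make_hbond_ensemble(0.0, n_frames=200, seed=20), [(1, 2)]
        )
        diff = occupancy_difference(wild, mutant)
        assert diff.difference.iloc[0] == pytest.approx(1.0)
        # frozen arithmetic of the ledger: 1.28 present vs 0.00 absent
        assert 1.28 - 0.00 == pytest.approx(1.28)

    def test_sorted_descending_and_hand_computed(self):
        e_hi = sd.make_hbond_ensemble(0.9, n_frames=2000, seed=21)
        e_lo = sd.make_hbond_ensemble(0.3, n_frames=2000, seed=22)
        a = hbond_occupancy(e_hi, [(1, 2)])
        b = hbond_occupancy(e_lo, [(1, 2)])
        diff = occupancy_difference(a, b)
        expected = a.frame["mean"].iloc[0] - b.frame["mean"].iloc[0]
        assert diff.difference.iloc[0] == pytest.approx(expected, abs=1e-12)
        assert list(diff.difference) == sorted(diff.difference, reverse=True)

    def test_pair_set_mismatch_rejected(self):
        ensemble = sd.make_hbond_ensemble(0.5, n_frames=20, seed=23)
        t1 = hbond_occupancy(ensemble, [(1, 2)])
        # fabricate a table over a different pair set
        t2 = hbond_occupancy(ensemble, [(1, 2)])
        t2.frame.loc[0, "acceptor"] = 9
        with pytest.raises(ValueError, match="pair set"):
            occupancy_difference(t1, t2)
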