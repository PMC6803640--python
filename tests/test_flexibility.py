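"""Kabsch superposition and per-residue RMSF."""

import numpy as np
import pytest

from biophyskit.errors import PreconditionError
from biophyskit.flexibility import (
    Trajectory,
    apply_transform,
    kabsch_superpose,
    rmsf_per_residue,
)
from biophyskit.synthetic_data import fluctuation_trajectory


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def brute_force_rmsd(mobile, reference, seed=0, n_per_stage=4000, stages=6):
    """Quaternion-grid oracle: staged random search over rotations (with
    centroid-matching translation), refining around the incumbent."""
    rng = np.random.default_rng(seed)
    m0 = mobile - mobile.mean(axis=0)
    r0 = reference - reference.mean(axis=0)

    def rmsd_of(rot):
        return np.sqrt(np.mean(np.sum((m0 @ rot.T - r0) ** 2, axis=1)))

    best_q = np.array([1.0, 0.0, 0.0, 0.0])
    best = rmsd_of(np.eye(3))
    sigma = 1.0
    for _ in range(stages):
        for _ in range(n_per_stage):
            q = best_q + rng.normal(0, sigma, 4)
            q /= np.linalg.norm(q)
            w, x, y, z = q
            rot = np.array([
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ])
            r = rmsd_of(rot)
            if r < best:
                best, best_q = r, q
        sigma /= 8.0
    return best


class TestKabsch:
    def test_identical_sets_give_zero_rmsd_and_identity(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 2, 0], [0, 0, 3.0]])
        rot, trans, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(rot, np.eye(3), atol=1e-9)
        assert np.allclose(trans, 0.0, atol=1e-9)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_rigidly_moved_copy_is_recovered_exactly(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(scale=5.0, size=(12, 3))
        rot_true = random_rotation(rng)
        moved = pts @ rot_true.T + rng.uniform(-30, 30, 3)
        rot, trans, rmsd = kabsch_superpose(moved, pts)
        assert rmsd < 1e-9
        assert np.allclose(apply_transform(moved, rot, trans), pts, atol=1e-8)

    def test_agrees_with_quaternion_grid_brute_force(self):
        mobile = np.array([[0.0, 0, 0], [3, 0, 0], [0, 2, 0], [1, 1, 2]])
        reference = np.array([[0.2, -0.1, 0], [2.7, 0.4, 0.3],
                              [-0.2, 2.2, -0.1], [1.4, 0.8, 1.9]])
        _, _, rmsd = kabsch_superpose(mobile, reference)
        oracle = brute_force_rmsd(mobile, reference)
        assert rmsd <= oracle + 1e-9  # closed form can only be better
        assert rmsd == pytest.approx(oracle, abs=1e-6)

    def test_rotation_is_proper(self):
        # mirror-image configurations must not produce a reflection
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        mirrored = pts * np.array([1, 1, -1.0])
        rot, _, _ = kabsch_superpose(mirrored, pts)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_collinear_selection_is_degenerate(self):
        line = np.column_stack([np.arange(4.0), np.zeros(4), np.zeros(4)])
        with pytest.raises(PreconditionError):
            kabsch_superpose(line, line + 1.0)


class TestRmsf:
    def test_static_trajectory_has_zero_rmsf(self):
        traj, _ = fluctuation_trajectory(n_residues=10, n_frames=5, sigma_nm=0.0)
        prof = rmsf_per_residue(traj)
        assert np.allclose(prof.rmsf_nm, 0.0, atol=1e-12)

    def test_rigid_translation_is_removed_by_fitting(self):
        traj, _ = fluctuation_trajectory(n_residues=10, n_frames=5, sigma_nm=0.0)
        coords = traj.coords.copy()
        for f in range(coords.shape[0]):
            coords[f] += np.array([3.0 * f, -2.0 * f, f])
        shifted = Trajectory(coords, traj.atom_names, traj.residue_indices)
        prof = rmsf_per_residue(shifted, fit=True)
        assert np.allclose(prof.rmsf_nm, 0.0, atol=1e-9)
        # without fitting, the drift shows up as apparent fluctuation
        prof_nofit = rmsf_per_residue(shifted, fit=False)
        assert prof_nofit.rmsf_nm.max() > 0.1

    def test_isotropic_gaussian_displacement_follows_sqrt3_law(self):
        """sigma per coordinate => RMSF = sigma*sqrt(3) (second moment of
        the chi-3 distribution), measured against the generator's own
        noise-free reference curve."""
        sigma = 0.1
        n_res, n_frames = 16, 10_000
        traj, truth = fluctuation_trajectory(
            n_residues=n_res, n_frames=n_frames, sigma_nm=sigma, seed=6)
        ref = np.array(truth["reference_coords"])
        prof = rmsf_per_residue(traj, reference=ref, fit=False)
        assert np.allclose(prof.rmsf_nm, sigma * np.sqrt(3.0), rtol=0.02)
        assert np.allclose(truth["expected_rmsf_nm"], sigma * np.sqrt(3.0))

    def test_rigid_motion_contamination_is_removed_by_fitting(self):
        common = dict(n_residues=16, n_frames=400, sigma_nm=0.05, seed=9)
        clean, _ = fluctuation_trajectory(rigid_motion=False, **common)
        dirty, _ = fluctuation_trajectory(rigid_motion=True, **common)
        p_clean = rmsf_per_residue(clean, reference="first", fit=True)
        p_dirty = rmsf_per_residue(dirty, reference="first", fit=True)
        assert np.allclose(p_dirty.rmsf_nm, p_clean.rmsf_nm, rtol=0.01)

    def test_global_rigid_transform_invariance(self):
        traj, _ = fluctuation_trajectory(n_residues=12, n_frames=50,
                                         sigma_nm=0.08, seed=4)
        rng = np.random.default_rng(1)
        rot = random_rotation(rng)
        moved = Trajectory(traj.coords @ rot.T + np.array([10.0, -5.0, 2.0]),
                           traj.atom_names, traj.residue_indices)
        a = rmsf_per_residue(traj, fit=True).rmsf_nm
        b = rmsf_per_residue(moved, fit=True).rmsf_nm
        assert np.allclose(a, b, rtol=1e-6)

    def test_mean_reference_minimises_rmsf(self):
        traj, _ = fluctuation_trajectory(n_residues=12, n_frames=200,
                                         sigma_nm=0.1, seed=7)
        r_mean = rmsf_per_residue(traj, reference="mean", fit=True).rmsf_nm
        r_first = rmsf_per_residue(traj, reference="first", fit=True).rmsf_nm
        assert np.all(r_mean <= r_first + 1e-9)

    def test_mismatched_reference_shape_rejected(self):
        traj, _ = fluctuation_trajectory(n_residues=8, n_frames=5)
        with pytest.raises(PreconditionError):
            rmsf_per_residue(traj, reference=np.zeros((3, 3)))
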