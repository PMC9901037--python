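"""Trajectory model, frame superposition, and RMSF."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mhcgroove.structure_io import AtomSelector
from mhcgroove.synthetic import make_harmonic_trajectory
from mhcgroove.trajectory import (
    AtomRecord,
    Trajectory,
    TrajectoryError,
    read_trajectory,
    rmsf,
    superpose_frames,
    write_trajectory,
)

CA_SEL = AtomSelector(atom_names=("CA",))


def _static_traj(n_frames=5, n_res=10):
    top = [AtomRecord("A", i + 1, "ALA", "CA") for i in range(n_res)]
    base = np.column_stack([np.arange(n_res) * 3.8, np.sin(np.arange(n_res)), np.zeros(n_res)])
    coords = np.repeat(base[None], n_frames, axis=0)
    return Trajectory(coords, np.arange(n_frames) * 20.0, top)


def test_multi_model_round_trip(tmp_path):
    traj, _ = make_harmonic_trajectory({r: 0.2 for r in range(1, 8)}, 5, seed=1)
    path = tmp_path / "traj.pdb"
    write_trajectory(traj, path)
    back = read_trajectory(path)
    assert back.n_frames == 5
    assert back.n_atoms == traj.n_atoms
    assert [(r.chain, r.resnum, r.name) for r in back.topology] == [
        (r.chain, r.resnum, r.name) for r in traj.topology
    ]
    assert np.allclose(back.coordinates, traj.coordinates, atol=5e-4)  # printed precision
    assert np.allclose(back.times, traj.times)


def test_single_structure_is_one_frame_trajectory(tmp_path):
    traj = _static_traj(n_frames=1)
    path = tmp_path / "single.pdb"
    write_trajectory(traj, path)
    assert read_trajectory(path).n_frames == 1


def test_frame_atom_mismatch_raises(tmp_path):
    good = (
        "MODEL        1\n"
        "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
        "ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C\n"
        "ENDMDL\nMODEL        2\n"
        "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
        "ENDMDL\nEND\n"
    )
    path = tmp_path / "bad.pdb"
    path.write_text(good)
    with pytest.raises(TrajectoryError, match="frame 1"):
        read_trajectory(path)


def test_invariants_enforced():
    top = [AtomRecord("A", 1, "ALA", "CA")]
    with pytest.raises(TrajectoryError):
        Trajectory(np.zeros((2, 1, 3)), np.array([10.0, 10.0]), top)  # times not increasing
    with pytest.raises(TrajectoryError):
        Trajectory(np.zeros((2, 2, 3)), np.array([0.0, 1.0]), top)  # topology mismatch


class TestSuperposeFrames:
    def test_identical_frames_unchanged(self):
        traj = _static_traj()
        out = superpose_frames(traj, CA_SEL)
        assert np.allclose(out.coordinates, traj.coordinates, atol=1e-9)

    def test_rigid_motions_removed(self, rng):
        traj = _static_traj(n_frames=8)
        coords = traj.coordinates.copy()
        for f in range(1, 8):
            R = Rotation.random(random_state=f).as_matrix()
            coords[f] = coords[f] @ R.T + rng.normal(size=3) * 5
        moved = Trajectory(coords, traj.times, traj.topology)
        out = superpose_frames(moved, CA_SEL)
        spread = out.coordinates.std(axis=0).max()
        assert spread < 1e-6

    def test_mean_reference_not_worse_than_first_frame(self):
        traj, _ = make_harmonic_trajectory({r: 0.3 for r in range(1, 12)}, 50, seed=4)
        out_mean = superpose_frames(traj, CA_SEL, reference="mean")
        out_first = superpose_frames(traj, CA_SEL, reference="first")
        def fit_rmsd(t):
            mean = t.coordinates.mean(axis=0)
            return np.sqrt(((t.coordinates - mean) ** 2).sum(axis=2).mean())
        assert fit_rmsd(out_mean) <= fit_rmsd(out_first) + 1e-9

    def test_degenerate_fit_rejected(self):
        traj = _static_traj()
        with pytest.raises(TrajectoryError):
            superpose_frames(traj, AtomSelector(residues=(1, 2)))


class TestRmsf:
    def test_static_trajectory_zero(self):
        prof = rmsf(_static_traj(), fit=CA_SEL)
        assert np.allclose(prof.values, 0.0, atol=1e-9)

    def test_single_frame_undefined(self):
        with pytest.raises(TrajectoryError, match="undefined"):
            rmsf(_static_traj(n_frames=1))

    def test_two_state_atom_closed_form(self):
        # one atom alternating between positions 2d apart among a static scaffold:
        # deviations are +/-d about the midpoint, so rmsf = d exactly
        d = 1.3
        traj = _static_traj(n_frames=40, n_res=30)
        coords = traj.coordinates.copy()
        coords[1::2, 0, 2] += 2 * d
        moving = Trajectory(coords, traj.times, traj.topology)
        fit = AtomSelector(residues=range(2, 31), atom_names=("CA",))
        prof = rmsf(moving, fit=fit).as_dict()
        assert np.isclose(prof[("A", 1)], d, rtol=1e-6)
        assert all(v < 1e-9 for (c, r), v in prof.items() if r != 1)

    def test_gaussian_fluctuation_matches_sigma_sqrt3(self):
        sigma = 0.4
        traj, truth = make_harmonic_trajectory({r: sigma for r in range(1, 31)}, 2000, seed=9)
        prof = rmsf(superpose_frames(traj, CA_SEL))
        mean_rmsf = float(np.mean(prof.values))
        assert abs(mean_rmsf - sigma * np.sqrt(3)) / (sigma * np.sqrt(3)) < 0.05

    def test_rmsf_invariant_under_global_rigid_motion(self):
        traj, _ = make_harmonic_trajectory({r: 0.25 for r in range(1, 16)}, 200, seed=2)
        base = rmsf(superpose_frames(traj, CA_SEL)).values
        R = Rotation.from_euler("xyz", [11, 23, 35], degrees=True).as_matrix()
        moved = Trajectory(traj.coordinates @ R.T + 100.0, traj.times, traj.topology)
        assert np.allclose(rmsf(superpose_frames(moved, CA_SEL)).values, base, atol=1e-9)

    def test_monotone_in_amplitude(self):
        profiles = []
        for amp in (0.1, 0.3, 0.6):
            traj, _ = make_harmonic_trajectory({r: amp for r in range(1, 21)}, 400, seed=7)
            profiles.append(float(np.mean(rmsf(superpose_frames(traj, CA_SEL)).values)))
        assert profiles[0] < profiles[1] < profiles[2]

    def test_region_contrast_top_k_in_flexible_region(self):
        # amplitudes elevated only for residues 41-62: the profile's top-k
        # residues must all fall inside that window
        amps = {r: (0.5 if 41 <= r <= 62 else 0.1) for r in range(1, 181)}
        traj, _ = make_harmonic_trajectory(amps, 300, seed=13)
        fit = AtomSelector(residues=[r for r in range(1, 181) if not 41 <= r <= 62],
                           atom_names=("CA",))
        prof = rmsf(superpose_frames(traj, fit))
        order = np.argsort(prof.values)[::-1]
        top_residues = {prof.residues[i][1] for i in order[:22]}
        assert top_residues == set(range(41, 63))
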