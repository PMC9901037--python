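"""Ring geometry, CH-π criterion, π-π classification, distributions."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mhcgroove.geometry import (
    CHPiCriteria,
    GeometryError,
    RingSpec,
    ch_pi_angle,
    ch_pi_satisfied,
    classify_pi_pi,
    estimate_distribution,
    p1_interaction_series,
    peak_location,
    ring_center,
    ring_normal,
)
from mhcgroove.synthetic import make_ring_pair

RING = RingSpec("P", 1, "PHE")
NAMES = RING.atom_names


def _hexagon_atoms(center=(0.0, 0.0, 0.0), order=+1, radius=1.39):
    """Regular hexagon in the xy-plane, counterclockwise from +z if order=+1."""
    center = np.asarray(center, dtype=float)
    out = {}
    for i, name in enumerate(NAMES):
        t = order * np.radians(60 * i)
        out[name] = center + radius * np.array([np.cos(t), np.sin(t), 0.0])
    return out


class TestRingCenterNormal:
    def test_center_of_unit_hexagon_is_origin(self):
        assert np.allclose(ring_center(_hexagon_atoms(), RING), 0.0, atol=1e-12)

    def test_center_translates_with_ring(self):
        assert np.allclose(ring_center(_hexagon_atoms((3, 4, 0)), RING), (3, 4, 0))

    def test_center_equals_brute_force_mean(self, rng):
        atoms = {n: rng.normal(size=3) * 2 for n in NAMES}
        expected = sum(atoms.values()) / 6.0
        assert np.allclose(ring_center(atoms, RING), expected, atol=1e-12)

    def test_center_needs_five_atoms(self):
        atoms = _hexagon_atoms()
        for n in NAMES[:2]:
            del atoms[n]
        with pytest.raises(GeometryError):
            ring_center(atoms, RING)

    def test_normal_sign_follows_atom_order(self):
        assert np.allclose(ring_normal(_hexagon_atoms(order=+1), RING), (0, 0, 1), atol=1e-9)
        assert np.allclose(ring_normal(_hexagon_atoms(order=-1), RING), (0, 0, -1), atol=1e-9)

    def test_normal_robust_to_out_of_plane_noise(self, rng):
        atoms = _hexagon_atoms()
        noisy = {n: p + np.array([0, 0, rng.normal(0, 0.1)]) for n, p in atoms.items()}
        n_hat = ring_normal(noisy, RING)
        angle = np.degrees(np.arccos(abs(np.dot(n_hat, [0, 0, 1]))))
        assert angle < 5.0

    def test_normal_reproducible_under_rotation(self, rng):
        atoms = _hexagon_atoms()
        R = Rotation.random(random_state=1).as_matrix()
        rotated = {n: R @ p for n, p in atoms.items()}
        expected = R @ ring_normal(atoms, RING)
        assert np.allclose(ring_normal(rotated, RING), expected, atol=1e-9)

    def test_collinear_atoms_rejected(self):
        atoms = {n: np.array([i, 0.0, 0.0]) for i, n in enumerate(NAMES)}
        with pytest.raises(GeometryError):
            ring_normal(atoms, RING)


class TestInteractionSeries:
    def test_parallel_coaxial_rings(self, ring_pair_positions):
        traj, _ = make_ring_pair(5.0, 0.0, 0.0, 1)
        s = p1_interaction_series(traj, ring_pair_positions, "Tyr59")
        assert np.isclose(s.distances[0], 5.0, atol=1e-9)
        assert np.isclose(s.angles[0], 0.0, atol=1e-9)

    def test_perpendicular_rings(self, ring_pair_positions):
        traj, _ = make_ring_pair(6.0, 90.0, 0.0, 1)
        s = p1_interaction_series(traj, ring_pair_positions, "Tyr59")
        assert np.isclose(s.distances[0], 6.0, atol=1e-9)
        assert np.isclose(s.angles[0], 90.0, atol=1e-9)

    def test_programmed_angle_recovered_from_jittered_ensemble(self, ring_pair_positions):
        traj, _ = make_ring_pair(6.0, 150.0, 0.1, 500, seed=8)
        s = p1_interaction_series(traj, ring_pair_positions, "Tyr59")
        dist = estimate_distribution(s.angles, 5.0)
        assert abs(dist.peak - 150.0) < 5.0

    def test_rigid_motion_invariance(self, ring_pair_positions):
        from mhcgroove.trajectory import Trajectory

        traj, _ = make_ring_pair(6.0, 117.0, 0.05, 20, seed=3)
        base = p1_interaction_series(traj, ring_pair_positions, "Tyr59")
        R = Rotation.random(random_state=9).as_matrix()
        moved = Trajectory(traj.coordinates @ R.T + 50.0, traj.times, traj.topology)
        same = p1_interaction_series(moved, ring_pair_positions, "Tyr59")
        assert np.allclose(same.distances, base.distances, atol=1e-9)
        assert np.allclose(same.angles, base.angles, atol=1e-6)

    def test_unsupported_p1_type_rejected(self, ring_pair_positions):
        from mhcgroove.trajectory import AtomRecord, Trajectory

        traj, _ = make_ring_pair(6.0, 90.0, 0.0, 1)
        top = [AtomRecord(r.chain, r.resnum, "TRP" if r.chain == "P" else r.resname, r.name)
               for r in traj.topology]
        bad = Trajectory(traj.coordinates, traj.times, top)
        with pytest.raises(GeometryError, match="PHE, ALA"):
            p1_interaction_series(bad, ring_pair_positions, "Tyr59")


class TestChPi:
    def test_collinear_gives_180(self):
        ring_atoms = _hexagon_atoms(center=(0, 0, 5))
        donor = {"CD1": np.array([0.0, 0.0, -1.09 - 1.0]), "HD11": np.array([0.0, 0.0, -1.0])}
        # H between Cδ and ring center along z: angle at H is 180
        ang = ch_pi_angle(donor, ring_atoms, RING)
        assert np.isclose(ang, 180.0, atol=1e-9)

    def test_right_angle_construction(self):
        ring_atoms = _hexagon_atoms(center=(0, 0, 4))
        donor = {"CD1": np.array([1.09, 0.0, 0.0]), "HD11": np.array([0.0, 0.0, 0.0])}
        assert np.isclose(ch_pi_angle(donor, ring_atoms, RING), 90.0, atol=1e-9)

    def test_constructed_hydrogens_when_absent(self):
        ring_atoms = _hexagon_atoms(center=(0, 0, 5))
        donor = {"CD1": np.array([0.0, 0.0, 0.0]), "CG1": np.array([0.0, 0.0, -1.53])}
        ang = ch_pi_angle(donor, ring_atoms, RING)
        # ideal methyl H at 109.47 degrees from the Cγ->Cδ axis: C-H-X angle is obtuse
        assert 90 < ang <= 180
        with pytest.raises(GeometryError):
            ch_pi_angle(donor, ring_atoms, RING, construct_h=False)

    @pytest.mark.parametrize(
        "dist,angle,expected",
        [(5.0, 135.0, True), (10.0, 140.0, False), (4.0, 90.0, False), (6.0, 120.0, True)],
    )
    def test_criterion_cases(self, dist, angle, expected):
        assert ch_pi_satisfied(dist, angle) is expected

    def test_criterion_monotone_in_cutoffs(self, rng):
        # loosening either cutoff never flips a satisfied verdict to false
        for _ in range(200):
            d, a = rng.uniform(2, 12), rng.uniform(60, 180)
            base = CHPiCriteria()
            if ch_pi_satisfied(d, a, base):
                looser = CHPiCriteria(base.max_distance + 1.0, base.min_angle - 10.0)
                assert ch_pi_satisfied(d, a, looser)


class TestPiPiClassification:
    @pytest.mark.parametrize(
        "center,expected",
        [(90.0, "T-shaped"), (150.0, "parallel-like"), (0.0, "parallel-like"),
         (110.0, "T-shaped"), (135.0, "intermediate"), (30.0, "parallel-like")],
    )
    def test_tight_ensembles(self, center, expected, rng):
        samples = np.clip(center + rng.normal(0, 2.0, 400), 0, 180)
        assert classify_pi_pi(samples).label == expected

    def test_fold_symmetry(self, rng):
        samples = rng.uniform(0, 180, 300)
        a = classify_pi_pi(samples)
        b = classify_pi_pi(180.0 - samples)
        assert a.label == b.label
        assert np.isclose(a.peak_deviation, b.peak_deviation, atol=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(GeometryError):
            classify_pi_pi(np.array([]))


class TestDistribution:
    def test_constant_samples_peak_within_half_bin(self):
        d = estimate_distribution(np.full(50, 5.0), 0.25)
        assert abs(d.peak - 5.0) <= 0.125 + 1e-12

    def test_gaussian_peak_recovered(self, rng):
        samples = rng.normal(6.0, 0.8, 10_000)
        d = estimate_distribution(samples, 0.25)
        assert abs(d.peak - 6.0) < 0.25
        # FWHM of a Gaussian is 2.355 sigma
        assert abs(d.fwhm - 2.355 * 0.8) < 0.4

    def test_uniform_density_flat(self, rng):
        samples = rng.uniform(0, 1, 100_000)
        d = estimate_distribution(samples, 0.05)
        assert np.max(np.abs(d.density - 1.0)) < 0.1

    def test_density_integrates_to_one(self, rng):
        samples = rng.normal(0, 2, 5000)
        d = estimate_distribution(samples, 0.5)
        widths = np.diff(d.bin_edges)
        assert np.isclose(float((d.density * widths).sum()), 1.0, atol=1e-9)

    def test_peak_tie_breaks_to_lowest(self):
        samples = np.array([1.0, 1.0, 3.0, 3.0])
        d = estimate_distribution(samples, 0.5)
        assert d.peak < 2.0
        assert peak_location(d) == d.peak

    def test_bad_bin_width_rejected(self):
        with pytest.raises(GeometryError):
            estimate_distribution(np.array([1.0, 2.0]), 0.0)
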