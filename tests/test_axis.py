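"""Axis determination: Kabsch fit, polar angles, two-step re-framing, DNA axis."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from ringchannel import (
    AxisLine,
    CorrespondenceError,
    DegenerateInputError,
    RingAssembly,
    SyntheticRingSpec,
    align_axis_to_z,
    align_line_to_z,
    apply_rigid_transform,
    fit_dna_helical_axis,
    generate_duplex,
    generate_ring,
    least_squares_rotation,
    permutation_fit,
    polar_axis,
    polar_to_rotation,
    rotation_to_polar,
)
from ringchannel.errors import EmptyStructureError

from oracles import axis_angle_between, brute_force_rotation, ring_pairs


def _centered_cloud(seed, n=5, scale=10.0):
    rng = np.random.default_rng(seed)
    pts = rng.normal(scale=scale, size=(n, 3))
    return pts - pts.mean(axis=0)


class TestLeastSquaresRotation:
    def test_identity_for_identical_clouds(self):
        P = _centered_cloud(1)
        desc = least_squares_rotation(P, P)
        np.testing.assert_allclose(desc.matrix, np.eye(3), atol=1e-12)
        assert desc.fit_rmsd == pytest.approx(0.0, abs=1e-12)

    def test_sixty_degrees_about_z(self):
        P = _centered_cloud(2)
        R = Rotation.from_euler("z", 60, degrees=True).as_matrix()
        desc = least_squares_rotation(P, P @ R.T)
        assert desc.chi_deg == pytest.approx(60.0, abs=1e-9)
        assert desc.omega_deg == pytest.approx(0.0, abs=1e-9)
        assert desc.fit_rmsd == pytest.approx(0.0, abs=1e-12)

    def test_recovers_random_rotation_and_matches_brute_force(self):
        P = _centered_cloud(3)
        R_true = Rotation.random(rng=np.random.default_rng(33)).as_matrix()
        Q = P @ R_true.T
        desc = least_squares_rotation(P, Q)
        np.testing.assert_allclose(desc.matrix, R_true, atol=1e-9)
        R_brute = brute_force_rotation(P, Q, seed=7)
        np.testing.assert_allclose(desc.matrix, R_brute, atol=1e-5)

    def test_matches_scipy_align_vectors_on_noisy_pairs(self):
        rng = np.random.default_rng(4)
        P = _centered_cloud(4, n=40)
        R_true = Rotation.random(rng=rng).as_matrix()
        Q = P @ R_true.T + rng.normal(scale=0.3, size=P.shape)
        Q -= Q.mean(axis=0)
        desc = least_squares_rotation(P, Q)
        rot, _ = Rotation.align_vectors(Q, P)
        np.testing.assert_allclose(desc.matrix, rot.as_matrix(), atol=1e-9)

    def test_collinear_points_raise(self):
        P = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        P = P - P.mean(axis=0)
        with pytest.raises(DegenerateInputError):
            least_squares_rotation(P, P)

    def test_too_few_points_raise(self):
        P = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        with pytest.raises(DegenerateInputError):
            least_squares_rotation(P, P)


class TestPolarAngles:
    def test_identity_is_all_zero(self):
        assert rotation_to_polar(np.eye(3)) == (0.0, 0.0, 0.0)

    def test_rotation_about_z(self):
        R = Rotation.from_euler("z", 60, degrees=True).as_matrix()
        om, ph, ch = rotation_to_polar(R)
        assert (om, ph) == (0.0, 0.0)
        assert ch == pytest.approx(60.0, abs=1e-9)

    def test_90_90_theta_rotates_about_y(self):
        R = polar_to_rotation(90.0, 90.0, 37.0)
        expected = Rotation.from_euler("y", 37, degrees=True).as_matrix()
        np.testing.assert_allclose(R, expected, atol=1e-12)

    def test_omega_zero_ignores_phi(self):
        for phi in (-120.0, 0.0, 45.0, 180.0):
            np.testing.assert_allclose(
                polar_to_rotation(0.0, phi, 25.0),
                Rotation.from_euler("z", 25, degrees=True).as_matrix(),
                atol=1e-12,
            )

    def test_roundtrip_on_100_random_rotations(self):
        rng = np.random.default_rng(99)
        for R in Rotation.random(100, rng=rng).as_matrix():
            om, ph, ch = rotation_to_polar(R)
            assert 0.0 <= om <= 180.0
            assert -180.0 < ph <= 180.0
            assert 0.0 <= ch <= 180.0
            np.testing.assert_allclose(polar_to_rotation(om, ph, ch), R, atol=1e-9)

    def test_half_turn_axis_canonicalized_to_upper_hemisphere(self):
        axis = np.array([0.3, -0.4, -0.866])
        axis /= np.linalg.norm(axis)
        R = Rotation.from_rotvec(axis * math.pi).as_matrix()
        om, ph, ch = rotation_to_polar(R)
        assert ch == pytest.approx(180.0, abs=1e-9)
        assert om <= 90.0
        np.testing.assert_allclose(polar_to_rotation(om, ph, ch), R, atol=1e-9)

    def test_reflection_rejected(self):
        with pytest.raises(ValueError):
            rotation_to_polar(np.diag([1.0, 1.0, -1.0]))

    @given(
        omega=st.floats(1.0, 179.0),
        phi=st.floats(-179.0, 180.0),
    )
    def test_two_step_recipe_maps_axis_to_z(self, omega, phi):
        """Rotating by (0,0,-Phi) then (90,90,-Omega) carries the axis to +Z.

        This algebraic identity is what makes the two-step re-framing
        procedure correct; it is checked over a dense sampled grid.
        """
        axis = polar_axis(omega, phi)
        R = polar_to_rotation(90.0, 90.0, -omega) @ polar_to_rotation(0.0, 0.0, -phi)
        np.testing.assert_allclose(R @ axis, [0.0, 0.0, 1.0], atol=1e-9)


class TestPermutationFit:
    @pytest.mark.parametrize("n", [3, 4, 5, 6, 7, 8])
    def test_clean_ring_chi_is_360_over_n(self, n):
        model, truth = generate_ring(SyntheticRingSpec(n_subunits=n))
        ring = RingAssembly(model, tuple("ABCDEFGHIJ"[:n]))
        desc = permutation_fit(ring)
        assert desc.chi_deg == pytest.approx(360.0 / n, abs=1e-6)
        assert axis_angle_between(desc.axis, truth.axis.direction) < math.degrees(1e-6)
        assert desc.fit_rmsd <= 1e-9

    def test_tilted_ring_recovers_axis_up_to_sign(self, tilted_c6_ring):
        ring, truth = tilted_c6_ring
        desc = permutation_fit(ring)
        assert axis_angle_between(desc.axis, truth.axis.direction) < math.degrees(1e-6)

    def test_chi_invariant_axis_equivariant_under_rigid_motion(self, c6_ring):
        ring, _ = c6_ring
        base = permutation_fit(ring)
        moved, t = apply_rigid_transform(ring.model, seed=17)
        desc = permutation_fit(RingAssembly(moved, ring.ring_chains))
        assert desc.chi_deg == pytest.approx(base.chi_deg, abs=1e-6)
        expected_axis = t.rotation @ base.axis
        assert axis_angle_between(desc.axis, expected_axis) < math.degrees(1e-6)

    def test_ca_only_option_agrees_on_ca_only_rings(self, c6_ring):
        ring, _ = c6_ring  # synthetic subunits are all-CA already
        all_fit = permutation_fit(ring, atoms="all")
        ca_fit = permutation_fit(ring, atoms="ca")
        assert ca_fit.n_pairs == all_fit.n_pairs
        np.testing.assert_allclose(ca_fit.matrix, all_fit.matrix, atol=1e-12)

    def test_disjoint_numbering_raises_correspondence_error(self, c6_ring):
        from dataclasses import replace

        ring, _ = c6_ring
        shifted = tuple(
            replace(a, residue_number=a.residue_number + 1000)
            if a.chain_id == "B"
            else a
            for a in ring.model.atoms
        )
        model = type(ring.model)(shifted, "broken")
        with pytest.raises(CorrespondenceError):
            RingAssembly(model, ring.ring_chains)

    def test_missing_chain_rejected(self, c6_ring):
        ring, _ = c6_ring
        with pytest.raises(ValueError):
            RingAssembly(ring.model, tuple("ABCDEZ"))


class TestAlignAxisToZ:
    def test_already_aligned_ring_keeps_radii(self, c6_ring):
        ring, _ = c6_ring
        before = np.hypot(*(ring.model.coords[:, :2].T))
        aligned, _, _ = align_axis_to_z(ring)
        after = np.hypot(*(aligned.coords[:, :2].T))
        np.testing.assert_allclose(after, before, atol=1e-9)

    def test_self_consistency_after_alignment(self, tilted_c6_ring):
        ring, _ = tilted_c6_ring
        aligned, frame, desc = align_axis_to_z(ring)
        # the composed transform maps the fitted axis onto +Z
        np.testing.assert_allclose(
            frame.composed.rotation @ desc.axis, [0, 0, 1], atol=1e-6
        )
        redo = permutation_fit(RingAssembly(aligned, ring.ring_chains))
        assert axis_angle_between(redo.axis, [0, 0, 1]) < math.degrees(1e-6)

    def test_two_step_equals_direct_alignment_radii(self, tilted_c6_ring):
        ring, _ = tilted_c6_ring
        aligned, frame, desc = align_axis_to_z(ring)
        two_step = np.hypot(*(aligned.coords[:, :2].T))
        from ringchannel import geometric_center

        center = geometric_center(ring.model, selection=ring.ring_chains)
        direct = align_line_to_z(ring.model, AxisLine(center, desc.axis))
        one_step = np.hypot(*(direct.coords[:, :2].T))
        np.testing.assert_allclose(two_step, one_step, atol=1e-9)


class TestNoiseRobustness:
    def test_axis_error_small_under_gaussian_noise(self):
        """sigma = 0.2 A on a C6 ring of 300 atoms/subunit: axis within 0.5 deg."""
        from ringchannel import default_template

        template = default_template(10.0, n_wall_atoms=299)
        axis = np.array([0.2, -0.3, 0.93])
        axis /= np.linalg.norm(axis)
        hits = 0
        for seed in range(20):
            model, truth = generate_ring(
                SyntheticRingSpec(
                    n_subunits=6,
                    template_atoms=template,
                    axis_direction=axis,
                    noise_sigma=0.2,
                    seed=seed,
                )
            )
            desc = permutation_fit(RingAssembly(model, tuple("ABCDEF")))
            if axis_angle_between(desc.axis, truth.axis.direction) < 0.5:
                hits += 1
        assert hits == 20  # expected error is ~0.02 deg at this atom count


class TestDnaHelicalAxis:
    def test_ideal_duplex_recovers_z(self):
        model, _ = generate_duplex(20, rise=3.4, twist_deg=34.3, radius=9.4)
        line = fit_dna_helical_axis(model, "A", "B")
        assert axis_angle_between(line.direction, [0, 0, 1]) < 0.5
        # canonical sign: along strand A 5'->3'
        assert line.direction[2] > 0

    def test_equivariance_under_rigid_motion(self):
        model, _ = generate_duplex(20)
        line0 = fit_dna_helical_axis(model, "A", "B")
        moved, t = apply_rigid_transform(model, seed=5)
        line1 = fit_dna_helical_axis(moved, "A", "B")
        expected_dir = t.rotation @ line0.direction
        expected_pt = t.apply(line0.point[None, :])[0]
        assert axis_angle_between(line1.direction, expected_dir) < 0.5
        # the recovered point is on the transformed line
        v = line1.point - expected_pt
        v -= np.dot(v, expected_dir) * expected_dir
        assert np.linalg.norm(v) < 0.1

    def test_two_basepair_duplex_rejected(self):
        with pytest.raises(ValueError):
            generate_duplex(2)

    def test_short_strands_rejected_by_fit(self):
        model, _ = generate_duplex(3)
        short = model.select(predicate=lambda a: a.residue_number <= 2)
        with pytest.raises((EmptyStructureError, CorrespondenceError)):
            fit_dna_helical_axis(short, "A", "B")
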