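"""Torus transforms: wrapping, unwrapping, displacement, embedding, torsions."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import biotite.structure as struc

from torsiondyn import (
    AngleTrajectory,
    build_backbone,
    dihedral_angle,
    displacement,
    embed_sincos,
    extract_backbone_dihedrals,
    integrate_displacement,
    phi_psi_angle_names,
    unwrap,
    wrap_to_interval,
)
from torsiondyn.torus import geodesic_step

finite_angles = st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False)


class TestWrap:
    @pytest.mark.parametrize(
        "value,expected",
        [(-356.0, 4.0), (0.0, 0.0), (540.0, -180.0), (180.0, -180.0), (-180.0, -180.0)],
    )
    def test_examples(self, value, expected):
        assert wrap_to_interval(value) == expected

    @given(finite_angles)
    def test_congruent_and_in_range(self, x):
        w = wrap_to_interval(x)
        assert -180.0 <= w < 180.0
        assert abs((x - w) % 360.0) < 1e-6 or abs((x - w) % 360.0 - 360.0) < 1e-6

    @given(finite_angles)
    def test_idempotent(self, x):
        w = wrap_to_interval(x)
        assert wrap_to_interval(w) == w

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            wrap_to_interval(np.nan)

    def test_geodesic_step_tie_maps_to_plus_180(self):
        assert geodesic_step(180.0) == 180.0
        assert geodesic_step(-180.0) == 180.0


class TestUnwrap:
    def test_hand_example(self):
        gamma = unwrap(np.array([[178.0], [-178.0], [-174.0]]))
        np.testing.assert_allclose(gamma.values.ravel(), [178.0, 182.0, 186.0])

    def test_constant_column(self):
        gamma = unwrap(np.full((3, 1), 10.0))
        np.testing.assert_array_equal(gamma.values.ravel(), [10.0, 10.0, 10.0])

    def test_round_trip_reversibility(self, random_wrapped):
        recovered = unwrap(random_wrapped).wrap()
        np.testing.assert_allclose(recovered, random_wrapped, atol=1e-9)

    def test_successive_steps_bounded(self, random_wrapped):
        gamma = unwrap(random_wrapped).values
        assert np.all(np.abs(np.diff(gamma, axis=0)) <= 180.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            unwrap(np.empty((0, 3)))


class TestDisplacement:
    def test_worked_jump_example(self):
        # a 178 -> -178 move is a true change of +4 degrees, not -356
        chi = displacement(np.array([[178.0], [-178.0]]))
        assert chi.values[0, 0] == 4.0

    def test_constant_is_zero(self):
        chi = displacement(np.full((5, 3), 42.0))
        np.testing.assert_array_equal(chi.values, 0.0)

    def test_equals_first_difference_of_unwrap(self, random_wrapped):
        chi = displacement(random_wrapped).values
        oracle = np.diff(unwrap(random_wrapped).values, axis=0)
        np.testing.assert_allclose(chi, oracle, atol=1e-12)

    def test_geodesic_shortest_arc_brute_force(self, rng):
        theta = rng.uniform(-180, 180, size=(50, 4))
        chi = displacement(theta).values
        raw = np.diff(theta, axis=0)
        candidates = np.stack([raw - 360.0, raw, raw + 360.0])
        shortest = np.take_along_axis(
            candidates, np.abs(candidates).argmin(axis=0)[None], axis=0
        )[0]
        np.testing.assert_allclose(chi, shortest, atol=1e-12)
        assert np.all(np.abs(chi) <= 180.0)

    def test_too_few_frames(self):
        with pytest.raises(ValueError):
            displacement(np.zeros((1, 3)))

    def test_commutes_with_column_permutation(self, random_wrapped, rng):
        perm = rng.permutation(random_wrapped.shape[1])
        np.testing.assert_array_equal(
            displacement(random_wrapped).values[:, perm],
            displacement(random_wrapped[:, perm]).values,
        )


class TestIntegrateDisplacement:
    def test_round_trip(self, random_wrapped):
        chi = displacement(random_wrapped)
        rebuilt = integrate_displacement(chi, random_wrapped[0])
        np.testing.assert_allclose(rebuilt.values, random_wrapped, atol=1e-9)

    def test_zero_steps_stay_at_anchor(self):
        anchor = np.array([10.0, -30.0])
        rebuilt = integrate_displacement(np.zeros((4, 2)), anchor)
        np.testing.assert_array_equal(rebuilt.values, np.tile(anchor, (5, 1)))

    def test_hand_cumulation_with_wrapping(self):
        rebuilt = integrate_displacement(np.full((2, 1), 4.0), np.array([178.0]))
        np.testing.assert_allclose(rebuilt.values.ravel(), [178.0, -178.0, -174.0])

    def test_anchor_mismatch(self):
        with pytest.raises(ValueError):
            integrate_displacement(np.zeros((3, 2)), np.zeros(3))


class TestEmbedSincos:
    @pytest.mark.parametrize("theta,pair", [(0.0, (0.0, 1.0)), (90.0, (1.0, 0.0))])
    def test_cardinal_angles(self, theta, pair):
        emb = embed_sincos(np.array([[theta]])).values
        np.testing.assert_allclose(emb[0], pair, atol=1e-15)

    def test_periodicity(self, random_wrapped):
        a = embed_sincos(random_wrapped).values
        b = embed_sincos(np.asarray(wrap_to_interval(random_wrapped + 360.0))).values
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_unit_circle_invariant(self, random_wrapped):
        emb = embed_sincos(random_wrapped).values
        assert emb.shape[1] == 2 * random_wrapped.shape[1]
        norms = emb[:, 0::2] ** 2 + emb[:, 1::2] ** 2
        np.testing.assert_allclose(norms, 1.0, atol=1e-12)


class TestDihedralAngle:
    P1, P2, P3 = [-0.5, 1.0, 0.0], [0.0, 0.0, 0.0], [1.0, 0.0, 0.0]

    def test_cis_is_zero(self):
        assert dihedral_angle(self.P1, self.P2, self.P3, [1.5, 1.0, 0.0]) == 0.0

    def test_trans_maps_to_minus_180(self):
        assert dihedral_angle(self.P1, self.P2, self.P3, [1.5, -1.0, 0.0]) == -180.0

    def test_explicit_rotation_oracle(self):
        # rotate the cis-position p4 by +90 degrees about the p2->p3 axis (+x)
        rot = np.array([[1, 0, 0], [0, 0, -1], [0, 1, 0]], dtype=float)
        p4 = np.array([1.5, 0, 0]) + rot @ np.array([0.0, 1.0, 0.0])
        assert dihedral_angle(self.P1, self.P2, self.P3, p4) == pytest.approx(90.0)

    def test_matches_biotite(self, rng):
        for _ in range(50):
            pts = rng.normal(size=(4, 3))
            try:
                mine = dihedral_angle(*pts)
            except ValueError:
                continue
            ref = np.rad2deg(struc.dihedral(*pts))
            # biotite computes in float32
            assert abs(wrap_to_interval(mine - ref)) < 1e-3

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            dihedral_angle([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])


class TestExtractBackboneDihedrals:
    def test_hexapeptide_has_ten_columns(self, rng):
        phi = rng.uniform(-170, 170, 5)
        psi = rng.uniform(-170, 170, 5)
        traj = extract_backbone_dihedrals([build_backbone(phi, psi)])
        assert traj.n_angles == 10
        assert traj.angle_names == phi_psi_angle_names(6)

    def test_round_trip_with_builder(self, rng):
        phi = rng.uniform(-170, 170, 5)
        psi = rng.uniform(-170, 170, 5)
        traj = extract_backbone_dihedrals([build_backbone(phi, psi)])
        expected = np.empty(10)
        expected[0::2] = psi
        expected[1::2] = phi
        np.testing.assert_allclose(traj.values[0], expected, atol=1e-6)

    def test_dipeptide_matches_dihedral_oracle(self, rng):
        s = build_backbone(rng.uniform(-170, 170, 1), rng.uniform(-170, 170, 1))
        traj = extract_backbone_dihedrals([s])
        assert traj.n_angles == 2
        a = s.coords
        psi1 = dihedral_angle(a[0, 0], a[0, 1], a[0, 2], a[1, 0])
        phi2 = dihedral_angle(a[0, 2], a[1, 0], a[1, 1], a[1, 2])
        np.testing.assert_allclose(traj.values[0], [psi1, phi2], atol=1e-10)


class TestAngleTrajectory:
    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            AngleTrajectory(values=np.array([[200.0]]))

    def test_lag_time_bookkeeping(self):
        traj = AngleTrajectory(values=np.zeros((3, 2)), frame_spacing=4.0)
        assert traj.lag_time(10) == 40.0
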