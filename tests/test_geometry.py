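"""Occlusal frame construction and signed angle measurement."""

import numpy as np
import pytest

from rootsetup import geometry as geo
from rootsetup.errors import GeometryError

from conftest import random_rotation, rigid_transform

SIN10, COS10 = np.sin(np.radians(10)), np.cos(np.radians(10))
SIN7, COS7 = np.sin(np.radians(7)), np.cos(np.radians(7))


def brute_force_angles(lm, frame, lingual):
    """Independent oracle: explicit projection matrices + arccos, signs
    from raw dot products with the distal / lingual directions."""
    mid = (lm.M + lm.D) / 2
    u = lm.A - mid
    s = frame.superior
    n_ang = np.cross(lm.D - lm.M, s)
    n_ang = n_ang / np.linalg.norm(n_ang)
    P_ang = np.eye(3) - np.outer(n_ang, n_ang)
    proj = P_ang @ u
    cosv = abs(proj @ s) / np.linalg.norm(proj)
    ang = np.degrees(np.arccos(np.clip(cosv, -1, 1)))
    md = (lm.D - lm.M) - ((lm.D - lm.M) @ s) * s
    if proj @ md < 0:
        ang = -ang
    # inclination plane: spanned by s and n_ang
    P_inc = np.outer(s, s) + np.outer(n_ang, n_ang)
    proj2 = P_inc @ u
    cosv2 = abs(proj2 @ s) / np.linalg.norm(proj2)
    inc = np.degrees(np.arccos(np.clip(cosv2, -1, 1)))
    if proj2 @ lingual < 0:
        inc = -inc
    return ang, inc


class TestOcclusalFrame:
    def test_axis_aligned_construction(self, canonical_frame):
        assert np.allclose(canonical_frame.superior, [0, 0, 1], atol=1e-12)
        assert abs(canonical_frame.plane.signed_distance((5.0, 5.0, 0.0))) < 1e-12

    def test_rotated_frame_superior_follows_rotation(self, rng):
        pts = [np.array(p, float) for p in
               [(10, 0, 0), (-10, 0, 0), (0, 30, 0), (0, 15, 8)]]
        for _ in range(20):
            R = random_rotation(rng)
            f = geo.build_occlusal_frame(*(R @ p for p in pts))
            assert np.allclose(f.superior, R @ [0, 0, 1], atol=1e-9)

    def test_collinear_points_rejected(self):
        with pytest.raises(GeometryError, match="collinear"):
            geo.build_occlusal_frame((0, 0, 0), (1, 0, 0), (2, 0, 0), (0, 0, 5))

    def test_centroid_on_plane_is_ambiguous(self):
        with pytest.raises(GeometryError, match="ambiguous"):
            geo.build_occlusal_frame(
                (10, 0, 0), (-10, 0, 0), (0, 30, 0), (0, 15, 0)
            )


class TestLongAxis:
    def test_symmetric_landmarks(self):
        lm = geo.LandmarkTriplet(11, (-3, 0, 0), (3, 0, 0), (0, 0, 12))
        mid, axis = geo.long_axis(lm)
        assert np.allclose(mid, [0, 0, 0])
        assert np.allclose(axis, [0, 0, 1])

    def test_offset_landmarks(self):
        lm = geo.LandmarkTriplet(11, (0, 0, 0), (4, 0, 0), (2, 1, -10))
        mid, axis = geo.long_axis(lm)
        assert np.allclose(mid, [2, 0, 0])
        assert np.allclose(axis, np.array([0, 1, -10]) / np.linalg.norm([0, 1, -10]))

    def test_apex_at_midpoint_rejected(self):
        with pytest.raises(GeometryError):
            geo.LandmarkTriplet(11, (-3, 0, 0), (3, 0, 0), (0, 0, 0))


class TestAngulation:
    def test_axis_parallel_to_superior_is_zero(self, canonical_frame):
        lm = geo.LandmarkTriplet(11, (-3, 0, 0), (3, 0, 0), (0, 0, 12))
        assert geo.angulation(lm, canonical_frame) == 0.0

    @pytest.mark.parametrize("sign", [1.0, -1.0])
    def test_ten_degree_rotation_about_y(self, canonical_frame, sign):
        lm = geo.LandmarkTriplet(
            11, (-3, 0, 0), (3, 0, 0), (sign * 12 * SIN10, 0, 12 * COS10)
        )
        assert geo.angulation(lm, canonical_frame) == pytest.approx(
            sign * 10.0, abs=1e-9
        )

    def test_off_plane_apex_matches_projection_oracle(self, canonical_frame):
        lm = geo.LandmarkTriplet(11, (-3, 0, 0), (3, 0, 0),
                                 (12 * SIN10, 2.0, 12 * COS10))
        expected, _ = brute_force_angles(lm, canonical_frame, np.array([0, 1.0, 0]))
        assert geo.angulation(lm, canonical_frame) == pytest.approx(expected,
                                                                    abs=1e-9)

    def test_md_parallel_to_superior_rejected(self, canonical_frame):
        lm = geo.LandmarkTriplet(11, (0, 0, -3), (0, 0, 3), (5, 0, 0))
        with pytest.raises(GeometryError, match="parallel"):
            geo.angulation(lm, canonical_frame)


class TestInclination:
    def test_axis_parallel_to_superior_is_zero(self, canonical_frame):
        lm = geo.LandmarkTriplet(11, (-3, 0, 0), (3, 0, 0), (0, 0, 12))
        assert geo.inclination(lm, canonical_frame, (0, 1, 0)) == 0.0

    @pytest.mark.parametrize("sign", [1.0, -1.0])
    def test_seven_degree_lingual_tip(self, canonical_frame, sign):
        lm = geo.LandmarkTriplet(
            11, (-3, 0, 0), (3, 0, 0), (0, sign * 12 * SIN7, 12 * COS7)
        )
        assert geo.inclination(lm, canonical_frame, (0, 1, 0)) == pytest.approx(
            sign * 7.0, abs=1e-9
        )

    def test_lingual_must_lie_in_occlusal_plane(self, canonical_frame):
        lm = geo.LandmarkTriplet(11, (-3, 0, 0), (3, 0, 0), (0, 1, 12))
        with pytest.raises(GeometryError, match="occlusal plane"):
            geo.inclination(lm, canonical_frame, (0, 0, 1.0))


class TestOracleEquivalence:
    def test_composed_rotations_match_brute_force(self, canonical_frame, rng):
        """1000 random (ang, inc) pairs: A built by composing the two
        rotations about the midpoint; implementation == projection oracle."""
        lingual = np.array([0.0, 1.0, 0.0])
        for _ in range(1000):
            a, i = rng.uniform(-45, 45, 2)
            Ry = _rot_y(np.radians(a))   # mesiodistal tip
            Rx = _rot_x(-np.radians(i))  # lingual (+y) tip
            A = Rx @ Ry @ np.array([0.0, 0.0, 12.0])
            lm = geo.LandmarkTriplet(11, (-3, 0, 0), (3, 0, 0), A)
            exp_a, exp_i = brute_force_angles(lm, canonical_frame, lingual)
            assert geo.angulation(lm, canonical_frame) == pytest.approx(
                exp_a, abs=1e-9
            )
            assert geo.inclination(lm, canonical_frame, lingual) == pytest.approx(
                exp_i, abs=1e-9
            )


def _rot_y(t):
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_x(t):
    c, s = np.cos(t), np.sin(t)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


class TestLingualReference:
    @staticmethod
    def _arch(mirror=False):
        from rootsetup import synthetic as syn

        scn = syn.SetupScenario("crown", 0.0, 0.0)
        arch = syn.build_arch("P", "maxilla", scn, np.random.default_rng(0))
        if not mirror:
            return arch
        M = np.diag([-1.0, 1.0, 1.0, 1.0])
        for fdi, lm in arch.landmarks.items():
            arch.landmarks[fdi] = lm.transformed(M)
        return arch

    def test_points_toward_arch_interior(self, canonical_frame):
        arch = self._arch()
        mids = [geo.long_axis(lm)[0] for lm in arch.landmarks.values()]
        centroid = np.mean(mids, axis=0)
        for lm in arch.landmarks.values():
            lg = geo.lingual_reference(mids, lm, canonical_frame)
            mid, _ = geo.long_axis(lm)
            assert lg @ (centroid - mid) > 0

    def test_mirrored_arch_mirrors_lingual(self, canonical_frame):
        arch, mirrored = self._arch(), self._arch(mirror=True)
        mids = [geo.long_axis(lm)[0] for lm in arch.landmarks.values()]
        mmids = [geo.long_axis(lm)[0] for lm in mirrored.landmarks.values()]
        for fdi in arch.landmarks:
            lg = geo.lingual_reference(mids, arch.landmarks[fdi], canonical_frame)
            lgm = geo.lingual_reference(mmids, mirrored.landmarks[fdi],
                                        canonical_frame)
            assert np.allclose(lgm, np.diag([-1.0, 1.0, 1.0]) @ lg, atol=1e-9)

    def test_coincident_midpoint_and_centroid_ambiguous(self, canonical_frame):
        lm = geo.LandmarkTriplet(11, (-3, 0, 0), (3, 0, 0), (0, 0, 12))
        mids = [np.zeros(3), np.array([1.0, 0, 0]), np.array([-1.0, 0, 0])]
        with pytest.raises(GeometryError, match="ambiguous"):
            geo.lingual_reference(mids, lm, canonical_frame)


class TestMeasureSetup:
    def test_all_measurements_share_the_frame(self, canonical_frame):
        from rootsetup import synthetic as syn

        scn = syn.SetupScenario("crown", 2.0, 2.0)
        arch = syn.build_arch("P", "maxilla", scn, np.random.default_rng(1))
        out = geo.measure_setup(arch.landmarks.values(), canonical_frame, "crown")
        assert len(out) == 14
        assert all(m.frame is canonical_frame for m in out)

    def test_empty_input_gives_empty_output(self, canonical_frame):
        assert geo.measure_setup([], canonical_frame, "crown") == []

    def test_failing_tooth_is_named(self, canonical_frame):
        lms = [
            geo.LandmarkTriplet(11, (-3, 0, 0), (3, 0, 0), (0, 1, 12)),
            geo.LandmarkTriplet(12, (-8, 0, -3), (-8, 0, 3), (-8, 1, 12)),
            geo.LandmarkTriplet(13, (-13, 2, 0), (-10, 4, 0), (-12, 3, 12)),
        ]
        with pytest.raises(GeometryError, match="tooth 12"):
            geo.measure_setup(lms, canonical_frame, "crown")


class TestInvariances:
    def test_rigid_motion_leaves_angles_unchanged(self, canonical_frame, rng):
        from rootsetup import synthetic as syn

        scn = syn.SetupScenario("crown", 3.0, 3.0)
        arch = syn.build_arch("P", "maxilla", scn, np.random.default_rng(3))
        lms = [arch.landmarks[f] for f in sorted(arch.landmarks)]
        base = geo.measure_setup(lms, canonical_frame, "crown")
        for _ in range(5):
            T = rigid_transform(rng)
            lms_t = [lm.transformed(T) for lm in lms]
            frame_t = canonical_frame.transformed(T)
            moved = geo.measure_setup(lms_t, frame_t, "crown")
            for m0, m1 in zip(base, moved):
                assert m1.angulation == pytest.approx(m0.angulation, abs=1e-9)
                assert m1.inclination == pytest.approx(m0.inclination, abs=1e-9)

    def test_mirror_symmetry_preserves_angulation(self, canonical_frame):
        """Reflection across the midsagittal plane swaps quadrants but
        keeps every angulation value (distal-positive is side-symmetric)."""
        from rootsetup import synthetic as syn

        scn = syn.SetupScenario("crown", 3.0, 3.0)
        arch = syn.build_arch("P", "maxilla", scn, np.random.default_rng(4))
        M = np.diag([-1.0, 1.0, 1.0, 1.0])
        for fdi, lm in arch.landmarks.items():
            mirror_fdi = {1: 2, 2: 1}[fdi // 10] * 10 + fdi % 10
            mirrored = geo.LandmarkTriplet(
                mirror_fdi,
                (M @ np.append(lm.M, 1))[:3],
                (M @ np.append(lm.D, 1))[:3],
                (M @ np.append(lm.A, 1))[:3],
            )
            assert geo.angulation(mirrored, canonical_frame) == pytest.approx(
                geo.angulation(lm, canonical_frame), abs=1e-9
            )
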