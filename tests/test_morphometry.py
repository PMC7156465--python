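"""Morphometric operators validated against the analytic phantom."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.spatial.transform import Rotation

from iomorph import (
    BoneAxis,
    LandmarkSet,
    PipelineConfig,
    attachment_percentage,
    attachment_width,
    average_thickness,
    estimate_bone_axis,
    fan_out_angle,
    fibre_vectors,
    measure_ligament,
    split_ligament,
    thickness_axial_trend,
    thickness_profile,
)
from iomorph.errors import DegeneracyError, EmptyResultError
from iomorph.morphometry import FibreVector, ThicknessProfile, mid_fibre
from iomorph.phantom import LigamentSpec, PhantomTruth, make_phantom


def parallel_fibre_truth(thickness=1.0, span=(40.0, 56.0), area_fraction=None):
    """Single-ligament phantom whose d and p fibres are parallel (a flat
    slab); optionally sized so the ligament occupies *area_fraction* of
    the sheet's mid-surface."""
    gap, dz = 16.4, -30.0
    theta = math.degrees(math.atan2(gap, -dz))  # positive: distally directed
    margin = 5.0
    if area_fraction is not None:
        z_span = (span[1] - span[0]) / 100.0 * 254.4
        margin_z = 0.5 * (z_span / area_fraction - z_span)
        margin = margin_z * gap / math.hypot(gap, dz)
    return PhantomTruth(
        gap=gap,
        ligaments=[LigamentSpec("CB", radius_span=span,
                                fan_out=(theta, theta), thickness=thickness)],
        edge_margin=margin,
    )


class TestBoneAxis:
    def test_z_cylinder(self, default_phantom):
        axis = estimate_bone_axis(default_phantom.radius, [0, 0, -1])
        assert abs(abs(axis.direction[2]) - 1.0) < 1e-9
        assert axis.direction[2] > 0  # oriented distal -> proximal
        assert axis.length == pytest.approx(254.4, abs=0.5)
        assert axis.distal_point[2] == pytest.approx(0.0, abs=1e-9)

    def test_recovers_known_rotation(self, default_phantom):
        rot = Rotation.from_euler("xyz", [20, -35, 50], degrees=True).as_matrix()
        rotated = default_phantom.radius.transformed(rot, np.array([5.0, -3.0, 8.0]))
        hint = rot @ np.array([0.0, 0.0, -1.0]) + np.array([5.0, -3.0, 8.0])
        axis = estimate_bone_axis(rotated, hint)
        expected = rot @ np.array([0.0, 0.0, 1.0])
        angle = math.degrees(math.acos(np.clip(np.dot(axis.direction, expected), -1, 1)))
        assert angle < 0.1

    def test_sphere_rejected(self):
        import trimesh

        from iomorph import SurfaceMesh

        sphere = SurfaceMesh.from_trimesh(trimesh.creation.icosphere(3), "sphere")
        with pytest.raises(DegeneracyError):
            estimate_bone_axis(sphere, [0, 0, -1])


class TestFibreVectors:
    def test_ulnar_minus_radial(self):
        lm = LandmarkSet("CB", {
            "R_p": [0, 0, 0], "U_p": [10, 0, 0],
            "R_d": [0, 0, -5], "U_d": [10, 0, -8],
        })
        vecs = {v.position: v for v in fibre_vectors(lm)}
        np.testing.assert_allclose(vecs["p"].vector, [10, 0, 0])
        np.testing.assert_allclose(vecs["p"].unit, [1, 0, 0])
        np.testing.assert_allclose(vecs["d"].vector, [10, 0, -3])

    def test_doac_three_four_five(self):
        lm = LandmarkSet("DOAC", {"R_m": [0, 0, 0], "U_m": [3, 4, 0]})
        (v,) = fibre_vectors(lm)
        assert v.position == "m"
        assert np.linalg.norm(v.vector) == pytest.approx(5.0)

    def test_phantom_landmarks_match_analytic_fibres(self, default_phantom):
        truth = default_phantom.truth
        for lm in default_phantom.landmarks:
            spec = next(s for s in truth.ligaments if s.ligament_id == lm.ligament_id)
            ends = truth.fibre_endpoints(spec)
            for fv in fibre_vectors(lm):
                r, u = ends[fv.position]
                np.testing.assert_allclose(fv.vector, u - r, atol=1e-6)


class TestFanOutAngle:
    AXIS = BoneAxis([0, 0, 0], [0, 0, 1], 250.0)

    def test_parallel_is_zero(self):
        assert fan_out_angle(np.array([0, 0, 3.0]), self.AXIS) == 0.0
        assert fan_out_angle(np.array([0, 0, -3.0]), self.AXIS) == 0.0

    def test_distally_directed_is_positive(self):
        assert fan_out_angle(np.array([1, 0, -1.0]), self.AXIS) == pytest.approx(45.0)

    def test_proximally_directed_is_negative(self):
        assert fan_out_angle(np.array([1, 0, 1.0]), self.AXIS) == pytest.approx(-45.0)

    def test_perpendicular_is_plus_ninety(self):
        assert fan_out_angle(np.array([1.0, 0, 0]), self.AXIS) == pytest.approx(90.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(DegeneracyError):
            fan_out_angle(np.zeros(3), self.AXIS)

    def test_rigid_invariance(self, rng):
        """A common rotation of fibre and axis leaves the angle unchanged."""
        for _ in range(50):
            v = rng.normal(size=3)
            a = rng.normal(size=3)
            a /= np.linalg.norm(a)
            axis = BoneAxis([0, 0, 0], a, 100.0)
            base = fan_out_angle(v, axis)
            rot = Rotation.random(random_state=rng).as_matrix()
            axis_r = BoneAxis(rng.normal(size=3), rot @ a, 100.0)
            assert fan_out_angle(rot @ v, axis_r) == pytest.approx(base, abs=1e-9)

    def test_matches_arccos_oracle(self, rng):
        """Brute-force oracle: arccos of the dot product with post-hoc
        acute-angle and sign correction."""
        a = np.array([0.0, 0.0, 1.0])
        axis = BoneAxis([0, 0, 0], a, 100.0)
        for _ in range(200):
            v = rng.normal(size=3)
            u = v / np.linalg.norm(v)
            theta = math.degrees(math.acos(np.clip(np.dot(u, a), -1.0, 1.0)))
            acute = min(theta, 180.0 - theta)
            sign = 1.0 if np.dot(u, a) < 0 else -1.0
            expected = sign * acute if acute > 0 else 0.0
            assert fan_out_angle(v, axis) == pytest.approx(expected, abs=1e-9)


class TestAttachmentMapping:
    AXIS = BoneAxis([0, 0, 0], [0, 0, 1], 254.4)

    def test_distal_point_is_zero(self):
        assert attachment_percentage([0, 0, 0], self.AXIS) == 0.0

    def test_proximal_end_is_hundred(self):
        assert attachment_percentage([0, 0, 254.4], self.AXIS) == pytest.approx(100.0)

    def test_out_of_range_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="outside"):
            assert attachment_percentage([0, 0, 280.0], self.AXIS) == 100.0

    def test_width_axial_projection(self):
        assert attachment_width([5, 2, 10.0], [7, -1, 10.0], self.AXIS) == 0.0
        assert attachment_width([0, 0, 43.9], [0, 0, 10.0], self.AXIS) == pytest.approx(33.9)

    def test_width_euclidean_switch(self):
        w = attachment_width([3, 4, 10.0], [0, 0, 10.0], self.AXIS, metric="euclidean")
        assert w == pytest.approx(5.0)

    def test_rigid_invariance(self, rng):
        rot = Rotation.random(random_state=rng).as_matrix()
        t = rng.normal(size=3)
        p = np.array([1.0, 2.0, 100.0])
        axis_r = BoneAxis(rot @ np.zeros(3) + t, rot @ np.array([0, 0, 1.0]), 254.4)
        assert attachment_percentage(rot @ p + t, axis_r) == pytest.approx(
            attachment_percentage(p, self.AXIS), abs=1e-9
        )


class TestSplitLigament:
    def test_no_clip_identity(self):
        """Planes at the sheet edges (no margin) keep the full area."""
        truth = parallel_fibre_truth()
        truth.edge_margin = 0.0
        res = make_phantom(truth)
        lig = split_ligament(res.membrane, res.landmarks[0], res.radius_axis)
        assert lig.area == pytest.approx(res.membrane.area, rel=1e-6)

    def test_area_fraction_matches_analytic(self):
        truth = parallel_fibre_truth(area_fraction=0.4)
        res = make_phantom(truth)
        lig = split_ligament(res.membrane, res.landmarks[0], res.radius_axis)
        assert lig.area / res.membrane.area == pytest.approx(0.40, abs=0.02)

    def test_clips_are_disjoint_and_bounded(self, default_phantom, default_axes):
        radius_axis, _ = default_axes
        res = default_phantom
        clips = {
            lm.ligament_id: split_ligament(res.membrane, lm, radius_axis)
            for lm in res.landmarks
        }
        total = sum(c.area for c in clips.values())
        assert total <= res.membrane.area * (1 + 1e-9)
        for c in clips.values():
            assert c.area <= res.membrane.area * (1 + 1e-9)
        # CB and AB separations share no interior: their triangle
        # centroids fall on opposite sides of the CB distal clip plane
        from iomorph.morphometry import _clip_plane_normal, fibre_vectors

        cb_lm = next(l for l in res.landmarks if l.ligament_id == "CB")
        fd = next(v for v in fibre_vectors(cb_lm) if v.position == "d")
        n = _clip_plane_normal(fd.unit, radius_axis)

        def centroids(mesh):
            v = mesh.vertices
            return v[mesh.faces].mean(axis=1)

        cb_side = (centroids(clips["CB"]) - fd.radial_point) @ n
        ab_side = (centroids(clips["AB"]) - fd.radial_point) @ n
        assert cb_side.min() >= -1e-6 and ab_side.max() <= 1e-6

    def test_empty_clip_rejected(self, default_phantom, default_axes):
        radius_axis, _ = default_axes
        lm = LandmarkSet("DOAC", {"R_m": [9.0, 0, -60.0], "U_m": [25.4, 0, -45.0]})
        with pytest.raises(EmptyResultError):
            split_ligament(default_phantom.membrane, lm, radius_axis)


class TestThicknessProfile:
    def test_flat_slab_constant_thickness(self, cfg):
        res = make_phantom(parallel_fibre_truth(thickness=1.0))
        lm = res.landmarks[0]
        lig = split_ligament(res.membrane, lm, res.radius_axis)
        for fv in fibre_vectors(lm):
            prof = thickness_profile(lig, fv, fv.radial_point, cfg)
            vals = prof.values()
            assert len(vals) > 100
            inner = prof.thickness[2:-2]
            inner = inner[np.isfinite(inner)]
            np.testing.assert_allclose(inner, 1.0, atol=0.02)

    def test_linear_ramp_recovered(self, cfg):
        res = make_phantom(parallel_fibre_truth(thickness=(1.0, 3.0)))
        lm = res.landmarks[0]
        lig = split_ligament(res.membrane, lm, res.radius_axis)
        fv = mid_fibre(lm)
        span = float(np.linalg.norm(fv.vector))
        prof = thickness_profile(lig, fv, fv.radial_point, cfg)
        ok = prof.valid
        st, th = prof.stations[ok][2:-2], prof.thickness[ok][2:-2]
        # per-station agreement with the analytic ramp
        predicted = 1.0 + 2.0 * np.clip(st / span, 0.0, 1.0)
        assert np.max(np.abs(th - predicted)) < 0.05
        fit = stats.linregress(st, th)
        assert fit.slope == pytest.approx(2.0 / span, abs=cfg.station_step)

    def test_empty_slab_rejected(self, cfg, default_phantom, default_axes):
        res = default_phantom
        lm = next(l for l in res.landmarks if l.ligament_id == "CB")
        lig = split_ligament(res.membrane, lm, res.radius_axis)
        fv = fibre_vectors(lm)[0]
        # move the slab plane far along the bone axis, past the membrane edge
        far = fv.radial_point + np.array([0.0, 0.0, 500.0])
        with pytest.raises(EmptyResultError):
            thickness_profile(lig, fv, far, cfg)

    def test_profile_station_grid_is_uniform(self):
        with pytest.raises(Exception):
            ThicknessProfile("CB", "p", [0.0, 0.05, 0.2], [1, 1, 1], 0.2)


class TestAggregation:
    def test_average_thickness_examples(self):
        p = ThicknessProfile("CB", "p", [0.0, 0.05, 0.1], [2.0, 2.0, 2.0], 0.2)
        assert average_thickness([p]) == (2.0, 0.0, (2.0, 2.0))
        q = ThicknessProfile("CB", "d", [0.0, 0.05], [1.0, 3.0], 0.2)
        mean, sd, rng_ = average_thickness([q])
        assert (mean, sd, rng_) == (2.0, 1.0, (1.0, 3.0))

    def test_average_thickness_skips_missing(self):
        p = ThicknessProfile("CB", "p", [0.0, 0.05, 0.1], [2.0, np.nan, 4.0], 0.2)
        mean, sd, rng_ = average_thickness([p])
        assert mean == 3.0 and rng_ == (2.0, 4.0)

    def test_average_thickness_empty_rejected(self):
        p = ThicknessProfile("CB", "p", [0.0, 0.05], [np.nan, np.nan], 0.2)
        with pytest.raises(EmptyResultError):
            average_thickness([p])

    def test_axial_trend_exact_line(self):
        slope, intercept = thickness_axial_trend([(0, 1.0), (50, 2.0), (100, 3.0)])
        assert slope == pytest.approx(0.02)
        assert intercept == pytest.approx(1.0)

    def test_axial_trend_constant(self):
        slope, _ = thickness_axial_trend([(0, 2.0), (50, 2.0), (100, 2.0)])
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_axial_trend_degenerate(self):
        with pytest.raises(DegeneracyError):
            thickness_axial_trend([(50, 1.0), (50, 2.0)])


class TestFullRecovery:
    """End-to-end parameter recovery on the default phantom."""

    def test_default_phantom_recovery(self, default_phantom, default_axes):
        res = default_phantom
        radius_axis, ulna_axis = default_axes
        for lm in res.landmarks:
            expected = res.expected[lm.ligament_id]
            rec = measure_ligament(res.membrane, lm, radius_axis, ulna_axis)
            for pos, val in expected["fan_out_deg"].items():
                assert rec.fan_out_deg[pos] == pytest.approx(val, abs=0.5)
                assert rec.radial_attachment_pct[pos] == pytest.approx(
                    expected["radial_pct"][pos], abs=0.5
                )
                assert rec.ulnar_attachment_pct[pos] == pytest.approx(
                    expected["ulnar_pct"][pos], abs=0.5
                )
            if expected["width_radial"] is not None:
                assert rec.width_radial == pytest.approx(
                    expected["width_radial"], abs=0.1
                )
                assert rec.width_ulnar == pytest.approx(
                    expected["width_ulnar"], abs=0.1
                )
            assert rec.mean_thickness == pytest.approx(
                expected["mean_thickness"], abs=0.05
            )

    def test_rotated_phantom_recovery(self):
        truth = PhantomTruth(random_orientation=True)
        res = make_phantom(truth, seed=42)
        radius_axis = estimate_bone_axis(res.radius, res.distal_hints["radius"])
        ulna_axis = estimate_bone_axis(res.ulna, res.distal_hints["ulna"])
        lm = next(l for l in res.landmarks if l.ligament_id == "CB")
        expected = res.expected["CB"]
        rec = measure_ligament(res.membrane, lm, radius_axis, ulna_axis)
        for pos in ("p", "d"):
            assert rec.fan_out_deg[pos] == pytest.approx(
                expected["fan_out_deg"][pos], abs=0.5
            )
        assert rec.mean_thickness == pytest.approx(
            expected["mean_thickness"], abs=0.05
        )

    def test_declining_thickness_gives_negative_axial_trend(self):
        """Ligaments generated thinner toward the proximal end must yield
        a negative thickness-vs-axial-position slope."""
        truth = PhantomTruth(ligaments=[
            LigamentSpec("DOB", radius_span=(10.0, 17.5), ulna_span=(11.0, 19.1),
                         thickness=6.0),
            LigamentSpec("CB", radius_span=(51.7, 65.1), ulna_span=(32.9, 46.4),
                         thickness=3.5),
            LigamentSpec("DOAC", radius_span=74.0, fan_out=-18.7, thickness=2.0),
        ])
        res = make_phantom(truth)
        radius_axis = estimate_bone_axis(res.radius, res.distal_hints["radius"])
        ulna_axis = estimate_bone_axis(res.ulna, res.distal_hints["ulna"])
        points = []
        for lm in res.landmarks:
            rec = measure_ligament(res.membrane, lm, radius_axis, ulna_axis)
            for pos, pct in rec.radial_attachment_pct.items():
                points.append((pct, rec.mean_thickness))
        slope, _ = thickness_axial_trend(points)
        assert slope < 0
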