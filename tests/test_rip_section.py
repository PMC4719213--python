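"""Section frames, RIP sampling, center correction, polar rules."""
import numpy as np
import pytest

from coroct3d import centerline as cl
from coroct3d import rip_section as rs
from coroct3d.hu_mixture import HuMixtureModel
from coroct3d.volume_io import ImageVolume


def _line_spline(length=20.0, axis=2):
    pts = np.zeros((101, 3))
    pts[:, axis] = np.linspace(0, length, 101)
    return cl.fit_and_sample(cl.CenterlinePolyline(pts), 0.2)


def _tube_volume(radius=2.0, n=81, spacing=0.25, hu_in=300.0, hu_out=0.0):
    half = (n - 1) / 2
    x, y, z = np.meshgrid(*(np.arange(n) - half,) * 3, indexing="ij")
    r = np.hypot(x, y) * spacing
    arr = np.where(r <= radius, hu_in, hu_out)
    origin = -half * spacing * np.ones(3)
    return ImageVolume(arr, np.full(3, spacing), origin)


@pytest.fixture(scope="module")
def wall_model():
    """Idealized tissue model with the default phantom parameters."""
    return HuMixtureModel([0.25] * 4, [350.0, 800.0, 60.0, -50.0],
                          [40.0, 80.0, 25.0, 60.0])


class TestBuildFrames:
    def test_straight_centerline_constant_axes(self):
        spline, stations = _line_spline()
        frames = rs.build_frames(spline, stations)
        for f in frames:
            np.testing.assert_allclose(f.tangent, [0, 0, 1], atol=1e-6)
            np.testing.assert_allclose(f.u_axis, frames[0].u_axis, atol=1e-6)
        assert len(frames) == 101

    def test_frame_orthonormality(self):
        t = np.linspace(0, 4 * np.pi, 200)
        pts = np.column_stack([3 * np.cos(t), 3 * np.sin(t), 2 * t])
        spline, stations = cl.fit_and_sample(cl.CenterlinePolyline(pts), 0.2)
        for f in rs.build_frames(spline, stations):
            M = np.stack([f.u_axis, f.v_axis, f.tangent])
            np.testing.assert_allclose(M @ M.T, np.eye(3), atol=1e-9)

    def test_helix_tangent_and_twist(self):
        R, P = 3.0, 30.0
        l_turn = np.hypot(2 * np.pi * R, P)
        k, h = 2 * np.pi / l_turn, P / l_turn
        s = np.linspace(0, 25, 200)
        pts = np.column_stack([R * np.cos(k * s), R * np.sin(k * s), h * s])
        spline, stations = cl.fit_and_sample(cl.CenterlinePolyline(pts), 0.2)
        frames = rs.build_frames(spline, stations)
        mid = frames[len(frames) // 2]
        sm = mid.station
        expected = np.array([-R * k * np.sin(k * sm), R * k * np.cos(k * sm), h])
        expected /= np.linalg.norm(expected)
        ang = np.degrees(np.arccos(np.clip(mid.tangent @ expected, -1, 1)))
        assert ang < 2.0
        # rotation-minimizing axes turn slowly between stations
        for a, b in zip(frames[:-1], frames[1:]):
            twist = np.degrees(np.arccos(np.clip(a.u_axis @ b.u_axis, -1, 1)))
            assert twist < 5.0


class TestSampleRip:
    def test_constant_volume_constant_image(self):
        vol = ImageVolume(np.full((20, 20, 20), 100.0), (0.5, 0.5, 0.5))
        spline, stations = _line_spline(5.0)
        frame = rs.build_frames(spline, stations)[10]
        frame.center = np.array([5.0, 5.0, 2.0])
        img = rs.sample_rip(vol, frame, half_width=2.0, pixel=0.1)
        np.testing.assert_allclose(img, 100.0)

    def test_perpendicular_section_shows_disk(self, wall_model):
        vol = _tube_volume(radius=2.0)
        spline, stations = _line_spline(8.0)
        frames = rs.build_frames(spline, stations)
        f = frames[20]
        f.center = np.array([0.0, 0.0, 0.0])
        img = rs.sample_rip(vol, f, half_width=4.0, pixel=0.1)
        nh = img.shape[0] // 2
        ax = (np.arange(img.shape[0]) - nh) * 0.1
        A, B = np.meshgrid(ax, ax, indexing="ij")
        rad = np.hypot(A, B)
        inside = img[rad < 1.7]
        outside = img[rad > 2.3]
        assert inside.mean() > 290
        assert outside.mean() < 10

    def test_tilted_plane_shows_ellipse(self):
        """Negative control: a 45-degree plane stretches the disk by sqrt 2."""
        vol = _tube_volume(radius=2.0)
        t = np.array([0.0, np.sqrt(0.5), np.sqrt(0.5)])
        u = np.array([1.0, 0.0, 0.0])
        v = np.cross(t, u)
        frame = rs.SectionFrame(0.0, np.zeros(3), t, u, v)
        img = rs.sample_rip(vol, frame, half_width=4.0, pixel=0.1)
        nh = img.shape[0] // 2
        row = img[nh, :]          # along v: stretched axis
        col = img[:, nh]          # along u: true radius
        width_v = (row > 150).sum() * 0.1
        width_u = (col > 150).sum() * 0.1
        assert width_u == pytest.approx(4.0, abs=0.3)
        # staircase voxel corners on the diagonal cut can add up to half a
        # voxel diagonal per side to the smooth-surface value 4 sqrt(2)
        assert 4.0 * np.sqrt(2) - 0.3 <= width_v <= 4.0 * np.sqrt(2) + 0.7
        assert width_v > width_u + 1.0

    def test_plane_outside_volume_rejected(self):
        vol = _tube_volume(radius=2.0, n=21)
        spline, stations = _line_spline(5.0)
        frame = rs.build_frames(spline, stations)[0]
        frame.center = np.array([500.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="outside"):
            rs.sample_rip(vol, frame, 2.0, 0.1)


class TestCorrectCenter:
    def _displaced_frame(self, offset_mm):
        spline, stations = _line_spline(5.0)
        frame = rs.build_frames(spline, stations)[10]
        frame.center = np.array([offset_mm[0], offset_mm[1], 0.0])
        return frame

    def test_first_iteration_recovers_disk_offset(self):
        """Disk displaced by (0.3, 0.4) mm: first shift ~ the displacement."""
        vol = _tube_volume(radius=2.0)
        frame = self._displaced_frame((0.3, 0.4))
        _, hist = rs.correct_center(vol, frame, iterations=1,
                                    threshold_hu=150.0, max_radius=4.0,
                                    half_width=4.0, pixel=0.1)
        shift = hist[1] - hist[0]
        world_shift = shift[0] * frame.u_axis + shift[1] * frame.v_axis
        np.testing.assert_allclose(world_shift[:2], [-0.3, -0.4], atol=0.08)

    def test_centered_disk_stays_put(self):
        vol = _tube_volume(radius=2.0)
        frame = self._displaced_frame((0.0, 0.0))
        out, _ = rs.correct_center(vol, frame, 5, 150.0, 4.0, 4.0, 0.1)
        assert np.linalg.norm(out.offset) < 0.05

    def test_large_offset_converges_below_one_pixel(self):
        """5 px = 0.5 mm displacement: residual < 1 px after 5 iterations,
        decreasing monotonically."""
        vol = _tube_volume(radius=2.0)
        frame = self._displaced_frame((0.5, 0.0))
        out, hist = rs.correct_center(vol, frame, 5, 150.0, 4.0, 4.0, 0.1)
        true_center = np.zeros(3)
        residuals = []
        for off in hist:
            origin = frame.center + off[0] * frame.u_axis + off[1] * frame.v_axis
            residuals.append(np.linalg.norm(origin - true_center))
        assert residuals[-1] < 0.1          # < 1 pixel (0.1 mm)
        assert all(b <= a + 1e-6 for a, b in zip(residuals, residuals[1:]))

    def test_empty_binarization_warns_and_keeps_offset(self):
        vol = ImageVolume(np.full((20, 20, 20), -500.0), (0.5, 0.5, 0.5))
        spline, stations = _line_spline(5.0)
        frame = rs.build_frames(spline, stations)[0]
        frame.center = np.array([5.0, 5.0, 2.0])
        with pytest.warns(UserWarning, match="empty binarization"):
            out, _ = rs.correct_center(vol, frame, 5, 150.0, 4.0, 4.0, 0.1)
        np.testing.assert_array_equal(out.offset, [0.0, 0.0])


class TestToPolar:
    def test_constant_image(self):
        img = np.full((81, 81), 42.0)
        polar = rs.to_polar(img, n_rays=32, radial_step=0.1, max_radius=3.0,
                            pixel=0.1)
        assert polar.shape == (32, 31)
        np.testing.assert_allclose(polar, 42.0)

    def test_centered_disk_drop_radius(self):
        nh = 40
        ax = (np.arange(81) - nh) * 0.1
        A, B = np.meshgrid(ax, ax, indexing="ij")
        img = np.where(np.hypot(A, B) <= 2.0, 300.0, 0.0)
        polar = rs.to_polar(img, 60, 0.1, 3.5, 0.1)
        for j in range(60):
            # the first sub-threshold bin lies just outside the disk edge
            drop = np.argmax(polar[j] < 150.0) * 0.1
            assert 2.0 <= drop <= 2.2

    def test_off_center_disk_sinusoidal_boundary(self):
        nh = 40
        ax = (np.arange(81) - nh) * 0.1
        A, B = np.meshgrid(ax, ax, indexing="ij")
        img = np.where(np.hypot(A - 0.5, B) <= 2.0, 300.0, 0.0)
        polar = rs.to_polar(img, 120, 0.05, 3.5, 0.1)
        drops = np.array([np.argmax(polar[j] < 150.0) * 0.05 for j in range(120)])
        th = np.deg2rad(np.arange(120) * 3.0)
        # circle offset d along u: r(theta) = d cos(theta) + sqrt(R^2 - d^2 sin^2)
        expected = 0.5 * np.cos(th) + np.sqrt(4.0 - 0.25 * np.sin(th) ** 2)
        np.testing.assert_allclose(drops, expected, atol=0.12)

    def test_too_few_rays_rejected(self):
        with pytest.raises(ValueError):
            rs.to_polar(np.zeros((21, 21)), n_rays=4, radial_step=0.1,
                        max_radius=1.0, pixel=0.1)


class TestExtractRoi:
    def test_stops_before_first_zero_cross(self):
        polar = np.array([[350.0, 60.0, -200.0, 40.0, 30.0]])
        roi = rs.extract_roi(polar)
        assert roi[0] == 1          # bins 0..1 kept

    def test_full_ray_without_crossing(self):
        polar = np.full((3, 8), 50.0)
        np.testing.assert_array_equal(rs.extract_roi(polar), [7, 7, 7])

    def test_first_bin_below_threshold_flags_empty(self):
        polar = np.array([[-500.0, 100.0, 100.0]])
        assert rs.extract_roi(polar)[0] == -1


class TestDetectWalls:
    def _ring_polar(self, n_rays=24, lumen_hu=350.0, wall_hu=60.0,
                    bg_hu=-50.0, r_lumen=1.5, r_outer=2.5, nk=41, h=0.1):
        r = np.arange(nk) * h
        prof = np.where(r < r_lumen, lumen_hu,
                        np.where(r < r_outer, wall_hu, bg_hu))
        return np.tile(prof, (n_rays, 1))

    def test_profile_rule_on_labeled_sequence(self, wall_model):
        """Classes L,L,L,NCP,CP,NCP,B,B -> lumen at bin 4, outer at bin 6
        (1-based bins, 0.1 mm steps, guard disabled)."""
        hu = np.array([350.0, 350, 350, 60, 800, 60, -50, -50])
        polar = np.tile(hu, (24, 1))
        roi = np.full(24, 7)
        walls = rs.detect_walls(polar, roi, wall_model, radial_step=0.1,
                                guard_mm=0.0, smooth_window=3,
                                clean_labels=False, refine=False)
        assert walls.valid
        np.testing.assert_allclose(walls.lumen_r, 0.3, atol=1e-9)
        np.testing.assert_allclose(walls.outer_r, 0.5, atol=1e-9)

    def test_ring_radii_recovered(self, wall_model):
        polar = self._ring_polar()
        roi = rs.extract_roi(polar)
        walls = rs.detect_walls(polar, roi, wall_model)
        assert walls.valid
        np.testing.assert_allclose(walls.lumen_r, 1.5, atol=0.1)
        np.testing.assert_allclose(walls.outer_r, 2.5, atol=0.1)

    def test_all_lumen_ray_interpolated_from_neighbors(self, wall_model):
        polar = self._ring_polar(n_rays=24)
        polar[5] = 350.0            # no wall on this ray: undefined
        roi = rs.extract_roi(polar)
        walls = rs.detect_walls(polar, roi, wall_model)
        assert walls.valid
        assert walls.lumen_r[5] == pytest.approx(1.5, abs=0.15)

    def test_mostly_undefined_section_invalid(self, wall_model):
        polar = np.full((24, 41), 350.0)   # lumen everywhere, no borders
        roi = rs.extract_roi(polar)
        walls = rs.detect_walls(polar, roi, wall_model)
        assert not walls.valid

    def test_lumen_never_exceeds_outer(self, wall_model, rng):
        polar = self._ring_polar() + rng.normal(0, 40, (24, 41))
        roi = rs.extract_roi(polar)
        walls = rs.detect_walls(polar, roi, wall_model)
        if walls.valid:
            assert np.all(walls.lumen_r <= walls.outer_r + 1e-9)


class TestPlaqueRegions:
    def _arc_polar(self, arc_rays, n_rays=60, nk=41, h=0.1):
        polar = TestDetectWalls()._ring_polar(n_rays=n_rays, nk=nk, h=h)
        for j in arc_rays:
            polar[j, 16:21] = 800.0   # CP at 1.6-2.0 mm
        return polar

    def test_no_high_posterior_no_regions(self, wall_model):
        polar = TestDetectWalls()._ring_polar(n_rays=60)
        roi = rs.extract_roi(polar)
        walls = rs.detect_walls(polar, roi, wall_model)
        assert rs.extract_plaque_regions(polar, walls, wall_model) == []

    def test_single_arc_detected_with_area(self, wall_model):
        arc = range(10, 30)         # 20 rays of 6 deg = 120 deg
        polar = self._arc_polar(arc)
        roi = rs.extract_roi(polar)
        walls = rs.detect_walls(polar, roi, wall_model)
        regions = rs.extract_plaque_regions(polar, walls, wall_model)
        assert len(regions) == 1
        reg = regions[0]
        np.testing.assert_array_equal(reg.rays, np.arange(10, 30))
        # annular sector: dtheta * integral r dr over [1.55, 2.05] per bin area
        r = np.arange(41) * 0.1
        expected = len(list(arc)) * (2 * np.pi / 60) * 0.1 * r[16:21].sum()
        assert reg.area == pytest.approx(expected, rel=1e-6)

    def test_seam_crossing_arc_is_one_region(self, wall_model):
        arc = [57, 58, 59, 0, 1, 2]
        polar = self._arc_polar(arc)
        roi = rs.extract_roi(polar)
        walls = rs.detect_walls(polar, roi, wall_model)
        regions = rs.extract_plaque_regions(polar, walls, wall_model)
        assert len(regions) == 1
        assert set(regions[0].rays.tolist()) == set(arc)

    def test_two_disjoint_arcs_two_regions(self, wall_model):
        polar = self._arc_polar(list(range(0, 10)) + list(range(30, 40)))
        roi = rs.extract_roi(polar)
        walls = rs.detect_walls(polar, roi, wall_model)
        regions = rs.extract_plaque_regions(polar, walls, wall_model)
        assert len(regions) == 2


class TestContoursToCartesian:
    def test_circle_on_straight_frame(self):
        spline, stations = _line_spline(10.0)
        frame = rs.build_frames(spline, stations)[25]
        pts = rs.contours_to_cartesian(frame, np.full(32, 2.0))
        assert pts.shape == (32, 3)
        np.testing.assert_allclose(pts[:, 2], frame.center[2], atol=1e-9)
        np.testing.assert_allclose(
            np.linalg.norm(pts - frame.center, axis=1), 2.0, atol=1e-9)

    def test_offset_shifts_curve_along_u(self):
        spline, stations = _line_spline(10.0)
        frame = rs.build_frames(spline, stations)[25]
        base = rs.contours_to_cartesian(frame, np.full(16, 2.0))
        frame.offset = np.array([1.0, 0.0])
        shifted = rs.contours_to_cartesian(frame, np.full(16, 2.0))
        np.testing.assert_allclose(shifted - base,
                                   np.tile(frame.u_axis, (16, 1)), atol=1e-9)


class TestRefineEdge:
    def test_half_height_crossing_on_ramp(self):
        r = np.arange(51) * 0.1
        prof = np.interp(r, [0, 1.45, 1.75, 5.0], [350, 350, 60, 60])
        got = rs.refine_edge(prof, 16, 0.1, lo=0, hi=50, inside_end=15,
                             window=8)
        assert got == pytest.approx(1.6, abs=0.02)

    def test_low_contrast_falls_back_to_bin_radius(self):
        prof = np.full(51, 100.0)
        assert rs.refine_edge(prof, 20, 0.1, 0, 50, 19) == pytest.approx(2.0)
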