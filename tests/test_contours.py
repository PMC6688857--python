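"""Contour extraction, orientation estimation, intensity sampling."""

import numpy as np
import pytest

from photogeo import contours, shading, terrain
from photogeo.shading import ShadedImage
from photogeo.terrain import LevelCutMask


def make_mask(mask: np.ndarray) -> LevelCutMask:
    return LevelCutMask(mask, cut_depth=0.0, polarity="convex")


def disc_mask(n: int, radius: float) -> LevelCutMask:
    yy, xx = np.mgrid[0:n, 0:n] - (n - 1) / 2
    return make_mask(xx**2 + yy**2 <= radius**2)


class TestExtractContourPixels:
    def test_single_dot_yields_eight_neighbours(self):
        mask = np.zeros((9, 9), bool)
        mask[4, 4] = True
        pos = contours.extract_contour_pixels(make_mask(mask))
        assert len(pos) == 8
        assert np.all(np.abs(pos - 4).max(axis=1) == 1)

    def test_half_plane_boundary_row(self):
        mask = np.zeros((16, 16), bool)
        mask[8:, :] = True
        pos = contours.extract_contour_pixels(make_mask(mask))
        assert np.all(pos[:, 0] == 7)
        assert len(pos) == 16

    def test_disc_ring_matches_brute_force_oracle(self):
        """The extracted disc ring equals a direct per-pixel neighbour
        check and scales with the circumference (between 2*pi*R and the
        Chebyshev perimeter 8*(R+1) of the rasterized disc)."""
        radius = 20.0
        m = disc_mask(64, radius)
        pos = contours.extract_contour_pixels(m)
        expected = set()
        mask = m.mask
        for r in range(64):
            for c in range(64):
                if mask[r, c]:
                    continue
                neigh = mask[max(0, r - 1) : r + 2, max(0, c - 1) : c + 2]
                if neigh.any():
                    expected.add((r, c))
        assert set(map(tuple, pos)) == expected
        assert 2 * np.pi * radius <= len(pos) <= 8 * (radius + 1)

    def test_contour_pixels_lie_outside_mask(self):
        m = disc_mask(64, 20.0)
        pos = contours.extract_contour_pixels(m)
        assert not m.mask[pos[:, 0], pos[:, 1]].any()

    def test_uniform_mask_rejected(self):
        with pytest.raises(ValueError):
            contours.extract_contour_pixels(make_mask(np.zeros((8, 8), bool)))


class TestEstimateOrientation180:
    def test_horizontal_contour(self):
        pos = np.column_stack([np.full(20, 5), np.arange(20)])
        tangents, valid = contours.estimate_orientation_180(pos)
        assert valid.all()
        assert np.allclose(tangents, 0.0)

    def test_diagonal_contour(self):
        pos = np.column_stack([np.arange(20), np.arange(20)])
        tangents, valid = contours.estimate_orientation_180(pos)
        # descending rows on screen: display angle 135 (equiv. -45) mod 180
        assert np.allclose(tangents[valid], 135.0)

    def test_circle_tangent_oracle(self):
        """Tangents of a radius-100 circle match phi + 90 (mod 180)
        with MAE < 5 degrees."""
        m = disc_mask(256, 100.0)
        pos = contours.extract_contour_pixels(m)
        tangents, valid = contours.estimate_orientation_180(pos, shape=m.mask.shape)
        c = (256 - 1) / 2
        phi = np.degrees(np.arctan2(-(pos[:, 0] - c), pos[:, 1] - c))
        expected = (phi + 90.0) % 180.0
        err = np.abs(tangents[valid] - expected[valid])
        err = np.minimum(err, 180.0 - err)
        assert err.mean() < 5.0

    def test_isolated_pixels_flagged_invalid(self):
        pos = np.array([[2, 2], [30, 30]])
        tangents, valid = contours.estimate_orientation_180(pos, shape=(40, 40))
        assert not valid.any()
        assert np.isnan(tangents).all()

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            contours.estimate_orientation_180(np.zeros((3, 2), int), window=8)


class TestDisambiguateOrientation360:
    def test_half_plane_normals_point_down(self):
        mask = np.zeros((16, 16), bool)
        mask[8:, :] = True
        m = make_mask(mask)
        pos = contours.extract_contour_pixels(m)
        tangents, _ = contours.estimate_orientation_180(pos, shape=mask.shape)
        theta = contours.disambiguate_orientation_360(m, pos, tangents)
        inner = np.isfinite(theta)
        assert np.allclose(theta[inner], 270.0)

    def test_disc_normals_point_to_center(self):
        m = disc_mask(256, 100.0)
        pos = contours.extract_contour_pixels(m)
        tangents, _ = contours.estimate_orientation_180(pos, shape=m.mask.shape)
        theta = contours.disambiguate_orientation_360(m, pos, tangents)
        c = (256 - 1) / 2
        phi = np.degrees(np.arctan2(-(pos[:, 0] - c), pos[:, 1] - c))
        expected = (phi + 180.0) % 360.0
        ok = np.isfinite(theta)
        err = np.abs(theta[ok] - expected[ok])
        err = np.minimum(err, 360.0 - err)
        assert err.mean() < 5.0

    def test_rotated_mask_flips_normals(self, smooth_terrain):
        d = terrain.level_cut_depth_for_visibility(smooth_terrain, 0.5)
        m = terrain.make_level_cut_mask(smooth_terrain, d)
        rot = terrain.rotate_mask(m)
        pos = contours.extract_contour_pixels(m)
        tangents, _ = contours.estimate_orientation_180(pos, shape=m.mask.shape)
        theta = contours.disambiguate_orientation_360(m, pos, tangents)
        # the same contour pixels in the rotated mask sit at (N-1-r, N-1-c)
        n = m.mask.shape[0]
        pos_rot = n - 1 - pos
        tan_rot, _ = contours.estimate_orientation_180(pos_rot, shape=m.mask.shape)
        theta_rot = contours.disambiguate_orientation_360(rot, pos_rot, tan_rot)
        ok = np.isfinite(theta) & np.isfinite(theta_rot)
        diff = np.abs((theta_rot - theta) % 360.0)[ok]
        diff = np.minimum(diff, 360.0 - diff)
        assert np.median(np.abs(diff - 180.0)) < 1e-6


class TestSampleAdjacentIntensity:
    def test_uniform_image(self):
        m = disc_mask(64, 20.0)
        img = ShadedImage(np.full((64, 64), 0.42))
        px = contours.measure_contour(img, m)
        assert np.allclose(px.intensity[px.valid], 0.42)

    def test_half_plane_over_ramp(self):
        """One-pixel inset from a lower-half mask reads the ramp value one
        row above the boundary row."""
        n = 16
        ramp = np.tile(np.linspace(0, 1, n)[:, None], (1, n))
        mask = np.zeros((n, n), bool)
        mask[8:, :] = True
        px = contours.measure_contour(ShadedImage(ramp), make_mask(mask))
        ok = px.valid
        assert np.allclose(px.intensity[ok], ramp[6, 0])

    def test_hemisphere_rim_matches_cosine(self, hemisphere):
        """Intensities sampled inside the rim of a rendered hemisphere
        reproduce the clipped rim cosine with r > 0.99."""
        from scipy import stats

        h, _ = hemisphere
        img = shading.render_height_field(h)
        rim = terrain.make_level_cut_mask(h, 1.0, "convex")
        px = contours.measure_contour(img, rim)
        ok = px.valid
        pred = shading.rim_luminance(
            px.orientation[ok],
            shading.CosineFalloff(amplitude=np.sin(np.radians(45.0)), phase=90.0),
        )
        r, _ = stats.pearsonr(pred, px.intensity[ok])
        assert r > 0.99


class TestGroundTruthTilt:
    def test_tilted_plane(self):
        n = 32
        h = terrain.HeightField(np.tile(np.arange(n, dtype=float)[:, None], (1, n)))
        tilt = contours.ground_truth_tilt(h)
        # heights increase with row = down-screen, so -grad points up (90 deg)
        assert np.allclose(tilt[1:-1, 1:-1], 90.0)

    def test_radial_bump_points_outward(self):
        n = 65
        yy, xx = np.mgrid[0:n, 0:n] - (n - 1) / 2
        h = terrain.HeightField(np.exp(-(xx**2 + yy**2) / 100.0))
        tilt = contours.ground_truth_tilt(h)
        phi = np.degrees(np.arctan2(-yy, xx)) % 360.0
        sel = (xx**2 + yy**2 > 25) & (xx**2 + yy**2 < 400)
        err = np.abs(tilt[sel] - phi[sel])
        err = np.minimum(err, 360.0 - err)
        assert err.max() < 1.0  # central differences of a radial field

    def test_estimator_agrees_with_gradient_oracle(self, smooth_terrain, rendered_terrain):
        """On a smooth terrain's level cut, the estimated into-mask
        normal tracks the true surface tilt: circular MAE < 10 deg and
        >= 95% of valid pixels within 15 deg; < 5% invalid."""
        d = terrain.level_cut_depth_for_visibility(smooth_terrain, 0.5)
        m = terrain.make_level_cut_mask(smooth_terrain, d)
        px = contours.measure_contour(rendered_terrain, m)
        assert px.valid_fraction > 0.95
        gt = contours.ground_truth_tilt(smooth_terrain)
        ok = px.valid
        pos = px.positions[ok]
        err = np.abs(px.orientation[ok] - gt[pos[:, 0], pos[:, 1]])
        err = np.minimum(err, 360.0 - err)
        assert err.mean() < 10.0
        assert (err < 15.0).mean() >= 0.95


class TestContourPixelSetRoundTrip:
    def test_csv_frame_round_trip(self, smooth_terrain, rendered_terrain):
        d = terrain.level_cut_depth_for_visibility(smooth_terrain, 0.5)
        m = terrain.make_level_cut_mask(smooth_terrain, d)
        px = contours.measure_contour(rendered_terrain, m)
        back = contours.ContourPixelSet.from_frame(px.to_frame())
        assert np.array_equal(back.positions, px.positions)
        assert np.allclose(back.orientation, px.orientation, equal_nan=True)
        assert np.array_equal(back.valid, px.valid)
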