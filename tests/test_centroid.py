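"""Centroid extraction: classical window CoG and whole-frame matched filter."""

import numpy as np
import pytest

import shwfs
from shwfs.centroid import (
    CentroidSet,
    CorrelatorTemplate,
    correlate,
    cog_subaperture,
    extract_centroids,
    gaussian_template,
    refine_subpixel,
)
from shwfs.forward_model import SpotFrame, _pixel_gaussian_1d, build_geometry
from shwfs.zernike import ZernikeCoefficients


def make_frame(geometry, centers, flux=1.0, sigma=1.0):
    """Frame with pixel-integrated Gaussian spots at arbitrary positions."""
    h, w = geometry.frame_shape
    img = np.zeros((h, w))
    for cx, cy in np.atleast_2d(centers):
        fx = _pixel_gaussian_1d(np.array([cx]), np.arange(w), sigma)[0]
        fy = _pixel_gaussian_1d(np.array([cy]), np.arange(h), sigma)[0]
        img += flux * np.outer(fy, fx)
    return SpotFrame(intensity=img, geometry=geometry)


@pytest.fixture(scope="module")
def geom8():
    return build_geometry(grid_shape=8)


class TestWindowCoG:
    def test_single_lit_pixel(self, geom8):
        rs, cs = geom8.window(0)
        y, x = rs.start + 3, cs.start + 7
        img = np.zeros(geom8.frame_shape)
        img[y, x] = 3.0
        frame = SpotFrame(intensity=img, geometry=geom8)
        assert cog_subaperture(frame, 0, geom8) == (float(x), float(y))

    def test_symmetric_spot_at_window_center(self, geom8):
        frame = make_frame(geom8, geom8.reference_centers)
        for i in (0, 5, geom8.k_effective - 1):
            x, y = cog_subaperture(frame, i, geom8)
            assert x == pytest.approx(geom8.reference_centers[i, 0], abs=1e-6)
            assert y == pytest.approx(geom8.reference_centers[i, 1], abs=1e-6)

    def test_equals_bruteforce_weighted_mean(self, geom8):
        rng = np.random.default_rng(0)
        img = rng.random(geom8.frame_shape)
        frame = SpotFrame(intensity=img, geometry=geom8)
        for i in (0, 17, 31):
            rs, cs = geom8.window(i)
            num_x = num_y = den = 0.0
            for yy in range(rs.start, rs.stop):
                for xx in range(cs.start, cs.stop):
                    num_x += xx * img[yy, xx]
                    num_y += yy * img[yy, xx]
                    den += img[yy, xx]
            x, y = cog_subaperture(frame, i, geom8)
            assert x == pytest.approx(num_x / den, rel=1e-12)
            assert y == pytest.approx(num_y / den, rel=1e-12)

    def test_empty_window_returns_window_center(self, geom8):
        """Classical failure mode: the spot left its window entirely, so the
        algorithm reports the reference position (zero displacement)."""
        # all spots at reference except lenslet 0's, moved 1.5 windows away
        centers = geom8.reference_centers.copy()
        centers[0] += 30.0
        frame = make_frame(geom8, centers)
        x, y = cog_subaperture(frame, 0, geom8)
        assert (x, y) == tuple(geom8.reference_centers[0])

    def test_two_spots_in_one_window_common_centroid(self, geom8):
        """Classical failure mode: an intruding neighbor corrupts the CoG
        toward the common centroid of both spots."""
        ref = geom8.reference_centers
        centers = [ref[0], ref[0] + np.array([6.0, 0.0])]
        frame = make_frame(geom8, centers)
        x, y = cog_subaperture(frame, 0, geom8)
        assert x == pytest.approx(ref[0, 0] + 3.0, abs=0.05)
        assert y == pytest.approx(ref[0, 1], abs=1e-6)


class TestCorrelate:
    def test_matches_direct_spatial_sum(self, geom8):
        rng = np.random.default_rng(1)
        img = rng.random((32, 32))
        tmpl = gaussian_template(1.0)  # 9x9
        resp = correlate(img, tmpl).values
        hprof = tmpl.profile
        r = hprof.shape[0] // 2
        direct = np.zeros_like(img)
        for y in range(32):
            for x in range(32):
                acc = 0.0
                for dy in range(-r, r + 1):
                    for dx in range(-r, r + 1):
                        yy, xx = y + dy, x + dx
                        if 0 <= yy < 32 and 0 <= xx < 32:
                            acc += img[yy, xx] * hprof[r + dy, r + dx]
                direct[y, x] = acc
        np.testing.assert_allclose(resp, direct, rtol=1e-9, atol=1e-12 * direct.max())

    def test_delta_template_reproduces_frame(self, geom8):
        img = np.random.default_rng(2).random((24, 24))
        delta = CorrelatorTemplate(profile=np.ones((1, 1)), center_offset=(0, 0))
        np.testing.assert_allclose(correlate(img, delta).values, img, rtol=1e-12)

    def test_matched_gaussian_peaks_at_spot_pixel(self, geom8):
        frame = make_frame(geom8, [(83.0, 47.0)])
        resp = correlate(frame, gaussian_template(1.0)).values
        iy, ix = np.unravel_index(np.argmax(resp), resp.shape)
        assert (ix, iy) == (83, 47)

    def test_template_larger_than_frame_rejected(self):
        with pytest.raises(ValueError):
            correlate(np.ones((4, 4)), gaussian_template(1.0))


class TestSubpixelRefinement:
    def test_symmetric_response_returns_integer_peak(self):
        y, x = np.mgrid[0:31, 0:31]
        resp = np.exp(-((x - 15.0) ** 2 + (y - 12.0) ** 2) / 4.0)
        rx, ry = refine_subpixel(resp, (15, 12))
        assert rx == pytest.approx(15.0, abs=1e-6)
        assert ry == pytest.approx(12.0, abs=1e-6)

    def test_recovers_offcenter_gaussian(self):
        cx, cy = 10.30, 20.75
        y, x = np.mgrid[0:41, 0:41]
        resp = np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * 2.0))
        rx, ry = refine_subpixel(resp, (10, 21))
        assert rx == pytest.approx(cx, abs=0.05)
        assert ry == pytest.approx(cy, abs=0.05)

    def test_subsample_convergence(self):
        cx, cy = 14.37, 9.81
        y, x = np.mgrid[0:31, 0:31]
        resp = np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * 2.0))
        a = refine_subpixel(resp, (14, 10), subsample=10)
        b = refine_subpixel(resp, (14, 10), subsample=20)
        assert abs(a[0] - b[0]) <= 0.01 and abs(a[1] - b[1]) <= 0.01

    def test_flat_response_returns_peak(self):
        rx, ry = refine_subpixel(np.zeros((16, 16)), (8, 8))
        assert (rx, ry) == (8.0, 8.0)


class TestExtraction:
    def test_known_spots_any_order(self, geom8):
        rng = np.random.default_rng(5)
        gx, gy = np.meshgrid([40.0, 70.0, 100.0], [40.0, 70.0, 100.0])
        true = np.column_stack([gx.ravel(), gy.ravel()])
        true += rng.uniform(-3, 3, size=true.shape)  # sub-pixel + jitter
        frame = make_frame(geom8, true)
        cset = extract_centroids(frame, gaussian_template(1.0), k=9)
        from scipy.spatial.distance import cdist

        d = cdist(cset.points, true)
        assert d.min(axis=1).max() <= 0.1
        assert sorted(d.argmin(axis=1)) == list(range(9))

    def test_beyond_window_spot_still_found(self, geom8):
        """Spots displaced 1.5 window widths stay recoverable to 0.1 px."""
        centers = geom8.reference_centers.copy()
        centers[0] += np.array([30.0, 0.0])
        frame = make_frame(geom8, centers)
        cset = extract_centroids(frame, gaussian_template(1.0), k=geom8.k_effective)
        from scipy.spatial.distance import cdist

        assert cdist(cset.points, centers).min(axis=1).max() <= 0.1

    def test_single_spot_k1(self, geom8):
        frame = make_frame(geom8, [(55.25, 77.5)])
        cset = extract_centroids(frame, gaussian_template(1.0), k=1)
        assert len(cset) == 1
        assert cset.points[0, 0] == pytest.approx(55.25, abs=0.05)
        assert cset.points[0, 1] == pytest.approx(77.5, abs=0.05)

    def test_row_major_tie_break(self, geom8):
        # exact equal maxima via a crafted response map: the earlier point
        # in row-major scan order must be taken first
        from shwfs.centroid import ResponseMap

        resp = np.zeros(geom8.frame_shape)
        resp[40, 60] = 1.0
        resp[100, 30] = 1.0
        frame = SpotFrame(intensity=resp, geometry=geom8)
        delta = CorrelatorTemplate(profile=np.ones((1, 1)), center_offset=(0, 0))
        cset = extract_centroids(
            frame, delta, k=2, suppression_radius=2, response=ResponseMap(resp)
        )
        np.testing.assert_allclose(cset.points[0], (60.0, 40.0), atol=1e-6)
        np.testing.assert_allclose(cset.points[1], (30.0, 100.0), atol=1e-6)

    def test_exhausted_response_raises(self, geom8):
        frame = make_frame(geom8, [(50.0, 50.0)])
        with pytest.raises(RuntimeError, match="1 of 4"):
            extract_centroids(frame, gaussian_template(1.0), k=4, suppression_radius=200)

    def test_translation_equivariance(self, geom8):
        rng = np.random.default_rng(8)
        gx, gy = np.meshgrid([40.0, 62.0, 84.0], [40.0, 62.0])
        true = np.column_stack([gx.ravel(), gy.ravel()])
        true += rng.uniform(-2, 2, size=true.shape)
        frame_a = make_frame(geom8, true)
        dx, dy = 7, 11
        frame_b = SpotFrame(
            intensity=np.roll(frame_a.intensity, (dy, dx), axis=(0, 1)),
            geometry=geom8,
        )
        tmpl = gaussian_template(1.0)
        a = extract_centroids(frame_a, tmpl, k=6).points
        b = extract_centroids(frame_b, tmpl, k=6).points
        a = a[np.lexsort(a.T)]
        b = b[np.lexsort(b.T)]
        np.testing.assert_allclose(b, a + np.array([dx, dy]), atol=5e-3)

    def test_autocorrelation_vs_cog_in_window_and_beyond(self, geom8):
        """On matched noiseless frames whole-frame extraction is as accurate
        as the window CoG in range, and stays accurate out of range."""
        centers = geom8.reference_centers.copy()
        centers[:, 0] += 3.0  # uniform in-window shift
        centers[5, 0] += 27.0  # this spot leaves its window
        frame = make_frame(geom8, centers)
        cset = extract_centroids(frame, gaussian_template(1.0))
        from scipy.spatial.distance import cdist

        d = cdist(cset.points, centers)
        assert d.min(axis=1).max() <= 0.1
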