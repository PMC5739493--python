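"""Yolk segmentation, boundary tracing and Fourier-descriptor algebra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage
from scipy.spatial.distance import cdist

from conftest import random_contour
from yolkvision.fixtures import analytic_contour, make_egg_image, make_truth_mask
from yolkvision.preprocess import preprocess, resize32
from yolkvision.shape import (Contour, NoYolkError, contour_features,
                              feature_vector, fourier_descriptors,
                              normalize_fds, reconstruct_boundary,
                              reconstruction_error, segment_yolk,
                              trace_boundary)


def dft_oracle(points):
    """O(N^2) brute-force discrete Fourier transform of x + iy."""
    s = points[:, 0] + 1j * points[:, 1]
    n = len(s)
    k = np.arange(n)
    return np.array([np.sum(s * np.exp(-2j * np.pi * u * k / n)) for u in range(n)])


def nearest_error_oracle(a, b):
    """All-pairs nearest-point mean distance."""
    return float(cdist(a.points, b.points).min(axis=1).mean())


class TestSegmentYolk:
    def test_sy_single_component_matches_truth(self, sy_scene, sy_roipair):
        yolk = segment_yolk(sy_roipair)
        _, n = ndimage.label(yolk, structure=np.ones((3, 3)))
        assert n == 1
        top, left, side = sy_roipair.crop_rectangle
        truth = make_truth_mask(sy_scene)[top:top + side, left:left + side]
        truth32 = resize32(truth, is_mask=True).astype(bool)
        inter = (yolk.astype(bool) & truth32).sum()
        union = (yolk.astype(bool) | truth32).sum()
        assert inter / union >= 0.6

    def test_dy_overlapping_one_component(self, dy_roipair):
        _, n = ndimage.label(segment_yolk(dy_roipair), structure=np.ones((3, 3)))
        assert n == 1

    def test_dy_separated_two_components(self, separated_roipair):
        """The separated-yolk failure mode is preserved, not hidden."""
        _, n = ndimage.label(segment_yolk(separated_roipair),
                             structure=np.ones((3, 3)))
        assert n == 2

    def test_empty_yolk_raises(self):
        # bright egg with only isolated dark specks: the median filter
        # removes them all, leaving no yolk region
        from yolkvision.preprocess import RoiPair
        roi = np.full((32, 32), 200.0)
        roi[4::8, 4::8] = 50.0
        rp = RoiPair(roi=roi, mask=np.ones((32, 32), dtype=np.uint8),
                     crop_rectangle=(0, 0, 32))
        with pytest.raises(NoYolkError):
            segment_yolk(rp)


class TestTraceBoundary:
    def test_solid_3x3_square_eight_points(self):
        grid = np.zeros((5, 5), dtype=np.uint8)
        grid[1:4, 1:4] = 1
        c = trace_boundary(grid)
        assert len(c) == 8
        expected = {(x, y) for x in (1, 2, 3) for y in (1, 2, 3)} - {(2, 2)}
        assert {tuple(map(int, p)) for p in c.points} == expected
        assert c.signed_area > 0

    def test_largest_component_wins(self):
        grid = np.zeros((20, 40), dtype=np.uint8)
        grid[2:12, 2:7] = 1     # area 50
        grid[5:10, 30:32] = 1   # area 10
        c = trace_boundary(grid)
        assert c.points[:, 0].max() < 10

    def test_boundary_length_geometric_bound(self, dy_roipair):
        """A closed trace spanning a w x h bounding box must travel at
        least 2(w-1) in x and 2(h-1) in y; 8-connected steps cover at most
        L1-distance 2 each, so the trace needs >= w + h - 2 points."""
        yolk = segment_yolk(dy_roipair)
        c = trace_boundary(yolk)
        w = np.ptp(c.points[:, 0]) + 1
        h = np.ptp(c.points[:, 1]) + 1
        assert len(c) >= w + h - 2
        closed = np.vstack([c.points, c.points[:1]])
        l1_length = np.abs(np.diff(closed, axis=0)).sum()
        assert l1_length >= 2 * (w - 1) + 2 * (h - 1)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            trace_boundary(np.zeros((8, 8), dtype=np.uint8))


class TestFourierDescriptors:
    def test_circle_energy_only_on_fundamental(self):
        c = analytic_contour("circle", 64, radius=5.0, center=(3.0, -2.0))
        a = fourier_descriptors(c).coeffs
        mags = np.abs(a)
        off = np.delete(mags, [0, 1])
        assert off.max() <= 1e-9 * mags[1]

    def test_dc_term_is_centroid(self):
        rng = np.random.default_rng(3)
        c = random_contour(rng)
        a = fourier_descriptors(c).coeffs
        centroid = c.points.mean(axis=0)
        np.testing.assert_allclose([a[0].real / len(c), a[0].imag / len(c)],
                                   centroid, atol=1e-9)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        c = random_contour(rng, n=32)
        a = fourier_descriptors(c).coeffs
        np.testing.assert_allclose(a, dft_oracle(c.points),
                                   atol=1e-9 * np.abs(a).max())

    def test_inverse_recovers_contour(self):
        rng = np.random.default_rng(9)
        c = random_contour(rng)
        ds = fourier_descriptors(c)
        recon = reconstruct_boundary(ds, len(c))
        np.testing.assert_allclose(recon.points, c.points, atol=1e-9)


class TestNormalizedDescriptors:
    def test_circle_nfd_vector(self):
        c = analytic_contour("circle", 64)
        ds = normalize_fds(fourier_descriptors(c))
        assert ds.nfd[0] == 0.0
        assert ds.nfd[1] == 1.0
        np.testing.assert_allclose(ds.nfd[2:], 0.0, atol=1e-9)

    def test_figure_eight_has_higher_harmonics(self):
        c = analytic_contour("figure_eight", 256)
        a = dft_oracle(c.points)          # independent of the fft path
        d = np.abs(a[:16]) / np.abs(a[1])
        assert d[2:16].max() > 0.05
        ds = normalize_fds(fourier_descriptors(c))
        np.testing.assert_allclose(ds.nfd[2:], d[2:16], atol=1e-9)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_similarity_invariance(self, seed):
        rng = np.random.default_rng(seed)
        c = random_contour(rng, n=40)
        angle = rng.uniform(0, 2 * np.pi)
        scale = rng.uniform(0.2, 5.0)
        shift = rng.uniform(-20, 20, size=2)
        start = rng.integers(0, 40)
        rot = np.array([[np.cos(angle), -np.sin(angle)],
                        [np.sin(angle), np.cos(angle)]])
        pts = (c.points @ rot.T) * scale + shift
        pts = np.roll(pts, start, axis=0)
        base = normalize_fds(fourier_descriptors(c)).nfd
        moved = normalize_fds(fourier_descriptors(Contour(pts))).nfd
        np.testing.assert_allclose(base, moved, atol=1e-6)

    def test_explicit_transform_example(self):
        c = random_contour(np.random.default_rng(12), n=48)
        th = np.deg2rad(37.0)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        pts = np.roll((c.points @ rot.T) * 2.5 + [11.0, -7.0], 13, axis=0)
        np.testing.assert_allclose(
            normalize_fds(fourier_descriptors(c)).nfd,
            normalize_fds(fourier_descriptors(Contour(pts))).nfd, atol=1e-6)

    def test_degenerate_contour_rejected(self):
        # s(k) constant up to a pure u=2 harmonic: a(1) = 0
        t = 2 * np.pi * np.arange(16) / 16
        pts = np.column_stack([np.cos(2 * t), np.sin(2 * t)])
        with pytest.raises(ValueError, match="degenerate|fundamental"):
            normalize_fds(fourier_descriptors(Contour(pts)))


class TestFeatureVector:
    def test_circle_gives_zeros(self):
        c = analytic_contour("circle", 64)
        fv = feature_vector(normalize_fds(fourier_descriptors(c)))
        assert fv.shape == (14,)
        np.testing.assert_allclose(fv, 0.0, atol=1e-9)

    def test_excludes_constant_descriptors(self):
        c = random_contour(np.random.default_rng(5))
        ds = normalize_fds(fourier_descriptors(c))
        fv = feature_vector(ds)
        np.testing.assert_allclose(fv, ds.nfd[2:16])

    def test_figure_eight_far_from_circle(self):
        f8 = feature_vector(normalize_fds(fourier_descriptors(
            analytic_contour("figure_eight", 256))))
        circ = feature_vector(normalize_fds(fourier_descriptors(
            analytic_contour("circle", 256))))
        assert np.linalg.norm(f8 - circ) > 0.05

    def test_short_nfd_rejected(self):
        c = analytic_contour("circle", 64)
        ds = normalize_fds(fourier_descriptors(c), m=8)
        with pytest.raises(ValueError):
            feature_vector(ds)


class TestReconstruction:
    def test_circle_recovered_from_two_harmonics(self):
        c = analytic_contour("circle", 64, radius=4.0, center=(1.0, 2.0))
        recon = reconstruct_boundary(fourier_descriptors(c), 2)
        np.testing.assert_allclose(recon.points, c.points, atol=1e-9)

    def test_out_of_range_n(self):
        ds = fourier_descriptors(analytic_contour("circle", 32))
        for n in (1, 33):
            with pytest.raises(ValueError):
                reconstruct_boundary(ds, n)

    def test_identical_contours_zero_error(self):
        c = random_contour(np.random.default_rng(2))
        assert reconstruction_error(c, c) == 0.0

    def test_pure_translation_345(self):
        # widely spaced points translated by (3, 4): every nearest match is
        # the point's own translate, distance exactly 5
        pts = np.array([[0.0, 0.0], [100.0, 0.0], [100.0, 100.0], [0.0, 100.0]])
        a = Contour(pts)
        b = Contour(pts + [3.0, 4.0])
        assert reconstruction_error(a, b) == pytest.approx(5.0, abs=1e-12)

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(8)
        a, b = random_contour(rng), random_contour(rng, n=37)
        assert reconstruction_error(a, b) == pytest.approx(
            nearest_error_oracle(a, b), abs=1e-12)

    def test_error_curve_decreases_for_yolk_contour(self, dy_roipair):
        c = trace_boundary(segment_yolk(dy_roipair))
        ds = fourier_descriptors(c)
        errs = [reconstruction_error(c, reconstruct_boundary(ds, n))
                for n in range(4, 20, 2)]
        for lo, hi in zip(errs[1:], errs[:-1]):
            assert lo <= hi + 0.1
        assert errs[range(4, 20, 2).index(16)] < 0.5

    def test_round_trip_error_negligible(self):
        c = random_contour(np.random.default_rng(4))
        recon = reconstruct_boundary(fourier_descriptors(c), len(c))
        assert reconstruction_error(c, recon) < 1e-6


class TestEndToEndFeatures:
    def test_sy_vs_dy_separable(self, sy_roipair, dy_roipair):
        fv_sy = contour_features(sy_roipair)
        fv_dy = contour_features(dy_roipair)
        assert np.linalg.norm(fv_dy - fv_sy) > 0.05
        # the two-lobed outline concentrates energy in d(3)
        assert fv_dy[1] > 5 * fv_sy[1]
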