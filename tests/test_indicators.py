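"""Intensity maps, DOS symmetry statistic, barycenters, confidence ellipses."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.interpolate import RBFInterpolator

from swemg.indicators import (BiharmonicSpline, DegenerateRatioError,
                              barycenter, barycenter_series, chi2_quantile,
                              confidence_ellipse, dos, intensity_map)
from swemg.recording import Recording

FS = 1000.0


def window_recording(n_samples, seed=0, transform=None):
    rng = np.random.default_rng(seed)
    sig = rng.standard_normal((n_samples, 64))
    if transform is not None:
        sig = transform(sig)
    return Recording(signal=sig, fs=FS)


def mirrored_signal(grid, n_samples, seed=0, left_scale=1.0):
    """Noise where each left channel is left_scale x its right mirror."""
    rng = np.random.default_rng(seed)
    sig = rng.standard_normal((n_samples, 64))
    for region in ("submental", "infrahyoid"):
        for left, right in grid.pairs(region):
            sig[:, left - 1] = left_scale * sig[:, right - 1]
    return Recording(signal=sig, fs=FS)


class TestIntensityMap:
    def test_3000ms_window_yields_6_frames(self, grid):
        imap = intensity_map(window_recording(3000), grid)
        assert len(imap.frames) == 6
        assert imap.frame_duration_ms == 500.0

    def test_wrong_window_length_rejected(self, grid):
        with pytest.raises(ValueError):
            intensity_map(window_recording(2999), grid)

    def test_minmax_normalization_hits_0_and_1(self, grid):
        imap = intensity_map(window_recording(3000, seed=4), grid)
        vals = np.stack([f.channel_values for f in imap.frames])
        assert vals.max() == pytest.approx(1.0)
        assert vals.min() == pytest.approx(0.0)
        assert vals.shape == (6, 64)

    def test_constant_window_maps_to_zero(self, grid):
        rec = Recording(signal=np.ones((3000, 64)), fs=FS)
        imap = intensity_map(rec, grid)
        assert all(np.all(f.channel_values == 0) for f in imap.frames)


class TestBiharmonicSpline:
    def test_exact_at_electrode_positions(self, grid):
        rng = np.random.default_rng(1)
        for region in ("submental", "infrahyoid"):
            pts = grid.positions(grid.channels_in_region(region))
            vals = rng.uniform(0, 1, len(pts))
            spline = BiharmonicSpline(pts, vals)
            assert np.abs(spline(pts) - vals).max() < 1e-6

    def test_agrees_with_thin_plate_rbf_at_data_sites(self, grid):
        # independent route: scipy's thin-plate RBF also interpolates exactly
        pts = grid.positions(grid.channels_in_region("submental"))
        vals = np.random.default_rng(2).uniform(0, 1, len(pts))
        ours = BiharmonicSpline(pts, vals)(pts)
        theirs = RBFInterpolator(pts, vals, kernel="thin_plate_spline")(pts)
        assert np.allclose(ours, theirs, atol=1e-8)


class TestDOS:
    def test_identical_left_right_gives_exactly_1(self, grid):
        rec = mirrored_signal(grid, 1500, seed=0, left_scale=1.0)
        for region in ("submental", "infrahyoid"):
            res = dos(rec, grid, region)
            assert res.dos == 1.0
            assert np.all(res.ratios == 1.0)

    def test_left_double_right_gives_2(self, grid):
        rec = mirrored_signal(grid, 1500, seed=1, left_scale=2.0)
        assert dos(rec, grid, "submental").dos == pytest.approx(2.0)
        assert dos(rec, grid, "infrahyoid").dos == pytest.approx(2.0)

    def test_segment_and_pair_counts(self, grid):
        rec = window_recording(1500, seed=2)
        sub = dos(rec, grid, "submental")
        inf = dos(rec, grid, "infrahyoid")
        assert sub.ratios.shape == (15, 8)
        assert inf.ratios.shape == (15, 24)
        assert (sub.n_segments, sub.n_pairs) == (15, 8)
        assert (inf.n_segments, inf.n_pairs) == (15, 24)

    def test_wrong_window_length_rejected(self, grid):
        with pytest.raises(ValueError):
            dos(window_recording(1000), grid, "submental")

    @settings(max_examples=15, deadline=None)
    @given(st.floats(0.1, 10.0), st.integers(0, 10 ** 6))
    def test_invariant_to_common_scaling(self, grid, scale, seed):
        rec = window_recording(1500, seed=seed)
        scaled = rec.with_signal(scale * rec.signal)
        assert dos(scaled, grid, "infrahyoid").dos == pytest.approx(
            dos(rec, grid, "infrahyoid").dos)

    def test_left_right_swap_gives_reciprocal_for_constant_ratio(self, grid):
        r = 2.0
        rec = mirrored_signal(grid, 1500, seed=3, left_scale=r)
        swapped = rec.with_signal(rec.signal.copy())
        for region in ("submental", "infrahyoid"):
            for left, right in grid.pairs(region):
                swapped.signal[:, [left - 1, right - 1]] = \
                    rec.signal[:, [right - 1, left - 1]]
        assert dos(swapped, grid, "submental").dos == pytest.approx(1.0 / r)

    def test_zero_right_side_signaled(self, grid):
        rec = mirrored_signal(grid, 1500, seed=4)
        for _, right in grid.pairs("submental"):
            rec.signal[:, right - 1] = 0.0
        with pytest.raises(DegenerateRatioError):
            dos(rec, grid, "submental")


class TestBarycenter:
    def test_uniform_rms_gives_centroid(self, grid):
        rec = Recording(signal=np.ones((100, 64)), fs=FS)
        for region, n in (("submental", 16), ("infrahyoid", 48)):
            pts = grid.positions(grid.channels_in_region(region))
            assert len(pts) == n
            b = barycenter(rec, grid, region)
            assert (b.b_x_mm, b.b_y_mm) == pytest.approx(
                tuple(pts.mean(axis=0)))

    def test_weighted_mean_two_active_channels(self, grid):
        # two submental channels at x = 0-ish: use actual coordinates
        chans = grid.channels_in_region("submental")
        c1, c2 = chans[0], chans[5]
        sig = np.zeros((100, 64))
        sig[:, c1 - 1] = 1.0
        sig[:, c2 - 1] = 3.0
        b = barycenter(Recording(signal=sig, fs=FS), grid, "submental")
        p1 = grid.positions([c1])[0]
        p2 = grid.positions([c2])[0]
        expected = (1.0 * p1 + 3.0 * p2) / 4.0
        assert (b.b_x_mm, b.b_y_mm) == pytest.approx(tuple(expected))

    def test_lies_in_convex_hull_and_scale_invariant(self, grid):
        rec = window_recording(500, seed=6)
        for region in ("submental", "infrahyoid"):
            pts = grid.positions(grid.channels_in_region(region))
            b = barycenter(rec, grid, region)
            assert pts[:, 0].min() <= b.b_x_mm <= pts[:, 0].max()
            assert pts[:, 1].min() <= b.b_y_mm <= pts[:, 1].max()
            b2 = barycenter(rec.with_signal(7.5 * rec.signal), grid, region)
            assert (b2.b_x_mm, b2.b_y_mm) == pytest.approx(
                (b.b_x_mm, b.b_y_mm))

    def test_all_zero_rms_signaled(self, grid):
        rec = Recording(signal=np.zeros((100, 64)), fs=FS)
        with pytest.raises(ValueError):
            barycenter(rec, grid, "submental")

    def test_series_yields_15_segments(self, grid):
        pts = barycenter_series(window_recording(1500, seed=7), grid,
                                "infrahyoid")
        assert len(pts) == 15
        assert [p.segment for p in pts] == list(range(15))


class TestConfidenceEllipse:
    def test_chi2_quantile_matches_closed_form(self):
        # chi^2 CDF with 2 dof is 1 - exp(-q/2); invert at 0.95
        assert chi2_quantile(0.95, 2) == pytest.approx(-2 * np.log(0.05),
                                                       abs=1e-9)

    def test_gaussian_containment_is_95pct(self):
        rng = np.random.default_rng(0)
        pts = rng.multivariate_normal([1.0, -2.0], [[2.0, 0.8], [0.8, 1.0]],
                                      size=10_000)
        ell = confidence_ellipse(pts, level=0.95)
        assert ell.contains(pts).mean() == pytest.approx(0.95, abs=0.01)

    @settings(max_examples=10, deadline=None)
    @given(st.integers(0, 10 ** 6))
    def test_containment_over_random_covariances(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((2, 2))
        cov = A @ A.T + 0.1 * np.eye(2)
        pts = rng.multivariate_normal(rng.standard_normal(2), cov, size=4000)
        ell = confidence_ellipse(pts, level=0.95)
        assert ell.contains(pts).mean() == pytest.approx(0.95, abs=0.02)

    def test_isotropic_cloud_near_circular(self):
        rng = np.random.default_rng(3)
        pts = rng.standard_normal((20_000, 2))
        ell = confidence_ellipse(pts)
        major, minor = ell.semi_axes
        assert major / minor == pytest.approx(1.0, abs=0.05)
        # orientation tie broken toward +x: angle in [-pi/2, pi/2]
        assert -np.pi / 2 <= ell.orientation_rad <= np.pi / 2

    def test_center_is_sample_mean(self):
        pts = np.array([[0.0, 0.0], [2.0, 0.0], [1.0, 3.0], [1.0, 1.0]])
        ell = confidence_ellipse(pts)
        assert ell.center == pytest.approx((1.0, 1.0))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            confidence_ellipse(np.array([[0, 0], [1, 1]]))
        collinear = np.column_stack([np.arange(5.0), 2 * np.arange(5.0)])
        with pytest.raises(ValueError):
            confidence_ellipse(collinear)
        with pytest.raises(ValueError):
            confidence_ellipse(np.random.default_rng(0).standard_normal(
                (10, 2)), level=1.5)
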