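"""Kymographs, regional traces, Otsu nuclear masks, peaks and correlations."""

import numpy as np
import pytest

from wormlapse import (
    DevelopmentalTimeline,
    ExpressionTrace,
    PixelGrid,
    build_kymograph,
    detect_stage_peak,
    fit_body_axis,
    nuclear_mean_intensity,
    peak_relative_to_event,
    regional_trace,
    total_intensity,
    trace_correlation,
)
from wormlapse.expression import smooth_trace

TL = DevelopmentalTimeline(0.0, (11.0, 18.0, 25.0, 35.0))


@pytest.fixture(scope="module")
def flat_axis():
    pts = np.column_stack([np.linspace(5, 205, 10), np.full(10, 64.0)])
    return fit_body_axis(pts, (100.0, 30.0))


def stripe_image(axis, s_frac, t_um=0.0, sigma_s=6.0, amp=100.0, shape=(128, 216)):
    """Gaussian stripe across the body at a fractional A-P position."""
    from wormlapse import BodyPoint, from_body_coords

    cam = from_body_coords(BodyPoint(s_frac * axis.length, t_um), axis)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    return amp * np.exp(-((xx - cam[0]) ** 2) / (2 * sigma_s**2)) * np.exp(
        -((yy - cam[1]) ** 2) / (2 * 15.0**2)
    )


class TestKymograph:
    def test_uniform_image_gives_constant_row(self, flat_axis, grid):
        k = build_kymograph(
            [np.full((128, 216), 4.0)], [flat_axis], [0.0], grid, dv_window=30
        )
        np.testing.assert_allclose(k.values[0], 4.0, atol=1e-9)

    def test_stripe_localized_to_its_bin(self, flat_axis, grid):
        img = stripe_image(flat_axis, 0.5)
        k = build_kymograph([img], [flat_axis], [0.0], grid, dv_window=30)
        assert abs(k.position_pct[np.argmax(k.values[0])] - 50.0) <= 1.0

    def test_stripe_outside_dv_window_excluded(self, flat_axis, grid):
        """Signal at |t| = 45 um does not enter a 40 um window."""
        yy, xx = np.mgrid[0:128, 0:216].astype(float)
        img = 100.0 * np.exp(-((yy - (64.0 + 45.0)) ** 2) / (2 * 2.0**2))
        k = build_kymograph([img], [flat_axis], [0.0], grid, dv_window=40)
        assert np.nanmax(k.values[0]) < 1.0

    def test_travelling_pulse_tracked_within_one_bin(self, flat_axis, grid):
        fracs = [0.2, 0.35, 0.5, 0.65, 0.8]
        frames = [stripe_image(flat_axis, f) for f in fracs]
        k = build_kymograph(
            frames, [flat_axis] * 5, np.arange(5.0), grid, dv_window=30
        )
        for row, f in zip(k.values, fracs):
            assert abs(k.position_pct[np.argmax(row)] - 100 * f) <= 1.0

    def test_rejects_empty_window(self, flat_axis, grid):
        with pytest.raises(ValueError, match="window"):
            build_kymograph([np.zeros((8, 8))], [flat_axis], [0.0], grid, dv_window=0)


class TestRegionalTrace:
    def test_uniform_region_sums_bins(self, flat_axis, grid):
        k = build_kymograph(
            [np.full((128, 216), 2.0)], [flat_axis], [0.0], grid, dv_window=30
        )
        tr = regional_trace(k, 50.0, width_pct=5.0)
        assert tr.intensity[0] == pytest.approx(5 * 2.0)  # 5 one-percent bins

    def test_pulse_confined_to_centre_region(self, flat_axis, grid):
        img = stripe_image(flat_axis, 0.5, sigma_s=3.0)
        k = build_kymograph([img], [flat_axis], [0.0], grid, dv_window=30)
        centre = regional_trace(k, 50.0).intensity[0]
        flank = regional_trace(k, 25.0).intensity[0]
        assert centre > 50 * max(flank, 1e-9)

    def test_invalid_regions_rejected(self, flat_axis, grid):
        k = build_kymograph(
            [np.zeros((128, 216))], [flat_axis], [0.0], grid, dv_window=30
        )
        with pytest.raises(ValueError, match="width"):
            regional_trace(k, 50.0, width_pct=0.0)
        with pytest.raises(ValueError, match="outside the body"):
            regional_trace(k, 99.0, width_pct=5.0)


class TestTotalIntensity:
    def test_zero_image(self, flat_axis, grid):
        assert total_intensity(np.zeros((128, 216)), flat_axis, grid) == 0.0

    def test_two_spots_sum(self, flat_axis, grid):
        img = stripe_image(flat_axis, 0.3, sigma_s=2.0) * (2 / 3) + stripe_image(
            flat_axis, 0.7, sigma_s=2.0
        ) / 3
        reference = img.sum()
        got = total_intensity(img, flat_axis, grid, half_width=40.0)
        assert got == pytest.approx(reference, rel=0.02)

    def test_constant_background_invariance(self, flat_axis, grid):
        img = stripe_image(flat_axis, 0.5, sigma_s=2.0)
        base = total_intensity(img, flat_axis, grid, half_width=40.0)
        offset = total_intensity(img + 11.0, flat_axis, grid, half_width=40.0)
        assert offset == pytest.approx(base, rel=0.02, abs=1.0)


def exhaustive_otsu(roi):
    """Oracle: maximize between-class variance over all candidate thresholds."""
    values = np.sort(np.unique(roi.ravel()))
    best_thr, best_var = values[0], -1.0
    x = roi.ravel().astype(float)
    for thr in values[:-1]:
        lo, hi = x[x <= thr], x[x > thr]
        w0, w1 = len(lo) / len(x), len(hi) / len(x)
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_thr = var, thr
    return best_thr


class TestNuclearIntensity:
    def test_disk_nucleus_recovered(self, grid):
        yy, xx = np.mgrid[0:32, 0:32].astype(float)
        disk = (xx - 16) ** 2 + (yy - 16) ** 2 <= 1.5**2
        img = np.where(disk, 200, 10).astype(np.uint16)
        mean, roi = nuclear_mean_intensity(img, (16.0, 16.0), grid)
        jaccard = (roi.mask & disk[14:19, 14:19]).sum() / (
            roi.mask | disk[14:19, 14:19]
        ).sum()
        assert jaccard >= 0.9
        assert mean == pytest.approx(200, abs=2)

    def test_threshold_matches_exhaustive_search(self, grid):
        rng = np.random.default_rng(21)
        for _ in range(20):
            roi_img = rng.integers(0, 255, size=(9, 9)).astype(np.uint8)
            img = np.zeros((32, 32), dtype=np.uint8)
            img[10:19, 10:19] = roi_img
            if np.ptp(roi_img) == 0:
                continue
            _, roi = nuclear_mean_intensity(img, (14.0, 14.0), grid, roi_side_um=8.0)
            oracle_thr = exhaustive_otsu(roi.roi)
            np.testing.assert_array_equal(roi.mask, roi.roi > oracle_thr)

    def test_perfectly_separable_two_level_roi(self, grid):
        rng = np.random.default_rng(4)
        roi = np.full((9, 9), 10, dtype=np.uint8)
        bright = rng.choice(81, size=8, replace=False)
        roi.ravel()[bright] = 200
        img = np.zeros((32, 32), dtype=np.uint8)
        img[10:19, 10:19] = roi
        mean, res = nuclear_mean_intensity(img, (14.0, 14.0), grid, roi_side_um=8.0)
        assert mean == 200.0
        assert res.mask.sum() == 8

    def test_uniform_roi_rejected(self, grid):
        img = np.full((32, 32), 77, dtype=np.uint8)
        with pytest.raises(ValueError, match="no contrast"):
            nuclear_mean_intensity(img, (16.0, 16.0), grid)

    def test_roi_outside_image_rejected(self, grid):
        with pytest.raises(ValueError, match="outside"):
            nuclear_mean_intensity(np.zeros((32, 32)), (1.0, 16.0), grid)


class TestStagePeaks:
    def test_symmetric_pulse_peak_exact(self):
        t = np.arange(0.0, 36.0, 1 / 3)
        trace = ExpressionTrace("x", t, np.exp(-0.5 * ((t - 16.0) / 1.0) ** 2))
        peaks = detect_stage_peak(trace, TL)
        assert peaks.loc["L2", "peak_time_h"] == pytest.approx(16.0, abs=1e-9)
        assert not peaks.loc["L2", "boundary"]

    def test_monotone_trace_flagged_boundary(self):
        t = np.arange(0.0, 36.0, 1 / 3)
        peaks = detect_stage_peak(ExpressionTrace("x", t, t.copy()), TL)
        assert peaks.loc["L2", "boundary"]

    def test_uncovered_stage_missing(self):
        t = np.arange(0.0, 10.0, 1 / 3)
        peaks = detect_stage_peak(ExpressionTrace("x", t, np.ones_like(t)), TL)
        assert np.isnan(peaks.loc["L3", "peak_time_h"])

    def test_affine_intensity_rescaling_invariance(self):
        rng = np.random.default_rng(2)
        t = np.arange(0.0, 36.0, 1 / 3)
        x = np.exp(-0.5 * ((t - 16.0) / 1.5) ** 2) + rng.normal(0, 0.05, len(t))
        p1 = detect_stage_peak(ExpressionTrace("x", t, x), TL)
        p2 = detect_stage_peak(ExpressionTrace("x", t, 7.3 * x + 41.0), TL)
        assert p1["peak_time_h"].equals(p2["peak_time_h"])

    def test_gaussian_filter_is_renormalized_at_edges(self):
        t = np.arange(0.0, 10.0, 1 / 3)
        sm = smooth_trace(ExpressionTrace("x", t, np.full_like(t, 3.0)))
        np.testing.assert_allclose(sm.intensity, 3.0, atol=1e-12)


class TestPeakTiming:
    def test_peak_before_event_positive(self):
        import pandas as pd

        peaks = pd.DataFrame(
            {"peak_time_h": [26.9], "boundary": [False]}, index=["L3"]
        )
        lead = peak_relative_to_event(peaks, TL)
        assert lead["L3"] == pytest.approx(25.0 - 26.9)

    def test_relative_timing_less_variable_than_absolute(self, cohort):
        """Ecdysis jitter with a fixed physiological lag: peak times relative
        to each animal's own ecdysis vary far less than absolute peak times."""
        absolute, relative = [], []
        for m in cohort:
            e = m.truth.expression[m.truth.expression.cell == "V1"]
            trace = ExpressionTrace("V1", e.time_h.to_numpy(), e.intensity.to_numpy())
            peaks = detect_stage_peak(trace, m.truth.timeline)
            absolute.append(peaks.loc["L3", "peak_time_h"])
            relative.append(
                peak_relative_to_event(peaks, m.truth.timeline, "L3")["L3"]
            )
        assert np.std(relative, ddof=1) < np.std(absolute, ddof=1)

    def test_planted_lag_recovered(self, cohort):
        leads = []
        for m in cohort[:8]:
            e = m.truth.expression[m.truth.expression.cell == "V2"]
            trace = ExpressionTrace("V2", e.time_h.to_numpy(), e.intensity.to_numpy())
            peaks = detect_stage_peak(trace, m.truth.timeline)
            leads.extend(peak_relative_to_event(peaks, m.truth.timeline).values)
        assert np.nanmean(leads) == pytest.approx(
            cohort[0].config.pulse_lag_h, abs=0.25
        )


class TestTraceCorrelation:
    def test_identical_traces(self):
        t = np.arange(10.0)
        x = np.sin(t)
        tr = ExpressionTrace("a", t, x)
        assert trace_correlation(tr, ExpressionTrace("b", t, x)) == pytest.approx(1.0)

    def test_negated_trace(self):
        t = np.arange(10.0)
        x = np.sin(t)
        assert trace_correlation(
            ExpressionTrace("a", t, x), ExpressionTrace("b", t, -x)
        ) == pytest.approx(-1.0)

    def test_zero_variance_undefined(self):
        t = np.arange(10.0)
        r = trace_correlation(
            ExpressionTrace("a", t, np.ones_like(t)),
            ExpressionTrace("b", t, np.sin(t)),
        )
        assert np.isnan(r)

    def test_requires_shared_time_points(self):
        with pytest.raises(ValueError, match="fewer than 3"):
            trace_correlation(
                ExpressionTrace("a", [0.0, 1.0], [1.0, 2.0]),
                ExpressionTrace("b", [5.0, 6.0], [1.0, 2.0]),
            )

    def test_attenuation_matches_analytic_value(self):
        """Shared oscillation with independent noise: R approaches
        var_signal / (var_signal + var_noise)."""
        rng = np.random.default_rng(17)
        t = np.arange(150) / 3.0
        sig = np.sin(2 * np.pi * t / 8.0)
        sd = np.std(sig) / np.sqrt(5.0)  # SNR 5 in variance
        a = ExpressionTrace("a", t, sig + rng.normal(0, sd, len(t)))
        b = ExpressionTrace("b", t, sig + rng.normal(0, sd, len(t)))
        analytic = np.var(sig) / (np.var(sig) + sd**2)
        assert trace_correlation(a, b) == pytest.approx(analytic, abs=0.05)
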