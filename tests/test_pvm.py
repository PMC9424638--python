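"""PVM trace analysis: primitives, transition detection, study designs."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import ndtr

from sspt.errors import DegenerateTraceError, NoTransitionError
from sspt.pvm import (
    IntensityTrace,
    RegionOfInterest,
    analyze_positions,
    boxcar_smooth,
    cluster_t1,
    crop_roi,
    detect_transition,
    first_derivative,
    hwhm_report,
    mean_trace,
    normalize_trace,
    roi_size_sweep,
    superpixel_traces,
)
from sspt.stack import FrameStack
from sspt.synthetic import render_video

from conftest import small_spec

SQRT_2LN2 = np.sqrt(2 * np.log(2))


def make_stack(frames, dt=0.5):
    return FrameStack(np.asarray(frames, dtype=np.uint8), frame_interval_s=dt)


def gaussian_pulse_trace(center, sigma, height=1.0, t_end=120.0, dt=0.5):
    t = np.arange(0.0, t_end + dt / 2, dt)
    return IntensityTrace(t, height * np.exp(-0.5 * ((t - center) / sigma) ** 2))


class TestCropAndSuperpixels:
    def test_full_frame_crop_is_identity(self, clean_stack_and_field):
        stack, _ = clean_stack_and_field
        roi = RegionOfInterest(0, 0, stack.shape[1])
        np.testing.assert_array_equal(crop_roi(stack, roi).frames, stack.frames)

    def test_crop_shape_and_out_of_bounds(self, clean_stack_and_field):
        stack, _ = clean_stack_and_field
        sub = crop_roi(stack, RegionOfInterest(0, 0, 10))
        assert sub.shape == (stack.n_frames, 10, 10)
        with pytest.raises(ValueError, match="height"):
            crop_roi(stack, RegionOfInterest(60, 0, 10))
        with pytest.raises(ValueError, match="width"):
            crop_roi(stack, RegionOfInterest(0, 60, 10))

    def test_cropped_mean_equals_covering_superpixel(self, clean_stack_and_field):
        """Two code paths agree: the mean trace of a 2x2 ROI equals the
        bin-2 superpixel trace covering it."""
        stack, _ = clean_stack_and_field
        roi = RegionOfInterest(20, 30, 2)
        by_crop = mean_trace(crop_roi(stack, roi))
        traces = superpixel_traces(stack, bin_px=2)
        w2 = stack.shape[2] // 2
        by_bin = traces[(20 // 2) * w2 + (30 // 2)]
        np.testing.assert_allclose(by_crop.values, by_bin.values)

    def test_bin1_count_and_constant_bin2(self):
        stack = make_stack(np.full((3, 4, 6), 7))
        assert len(superpixel_traces(stack, 1)) == 24
        for tr in superpixel_traces(stack, 2):
            assert np.all(tr.values == 7.0)

    def test_checkerboard_bin2_mean(self):
        board = np.indices((4, 4)).sum(axis=0) % 2 * 255
        stack = make_stack(np.broadcast_to(board, (3, 4, 4)))
        for tr in superpixel_traces(stack, 2):
            assert np.all(tr.values == 127.5)


class TestBoxcar:
    def test_identity_and_constant(self):
        tr = IntensityTrace(np.arange(10.0), np.arange(10.0) ** 2)
        np.testing.assert_array_equal(boxcar_smooth(tr, 1).values, tr.values)
        const = IntensityTrace(np.arange(10.0), np.full(10, 3.3))
        np.testing.assert_allclose(boxcar_smooth(const, 5).values, 3.3)

    def test_preserves_linear_ramp_in_interior(self):
        tr = IntensityTrace(np.arange(50.0), 2.0 * np.arange(50.0) + 1.0)
        sm = boxcar_smooth(tr, 9)
        interior = slice(4, -4)
        np.testing.assert_allclose(sm.values[interior], tr.values[interior])

    def test_window_errors(self):
        tr = IntensityTrace(np.arange(10.0), np.arange(10.0))
        with pytest.raises(ValueError, match="9"):
            boxcar_smooth(tr, 11)
        with pytest.raises(ValueError, match="odd"):
            boxcar_smooth(tr, 4)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        a=st.floats(-5, 5), b=st.floats(-100, 100),
        window=st.sampled_from([3, 5, 9]),
    )
    def test_commutes_with_affine_maps(self, a, b, window):
        rng = np.random.default_rng(0)
        v = rng.normal(50, 10, 60)
        tr = IntensityTrace(np.arange(60.0), v)
        lhs = boxcar_smooth(tr.replace(a * v + b), window).values
        rhs = a * boxcar_smooth(tr, window).values + b
        np.testing.assert_allclose(lhs, rhs, atol=1e-8)


class TestNormalizeAndDerivative:
    def test_normalize_examples_and_idempotence(self):
        tr = IntensityTrace([0.0, 1.0, 2.0], [0.0, 5.0, 10.0])
        out = normalize_trace(tr)
        np.testing.assert_allclose(out.values, [0.0, 0.5, 1.0])
        assert out.normalized
        np.testing.assert_allclose(normalize_trace(out).values, out.values)
        with pytest.raises(DegenerateTraceError):
            normalize_trace(IntensityTrace([0.0, 1.0, 2.0], [4.0, 4.0, 4.0]))

    def test_derivative_constant_and_ramp(self):
        t = np.arange(20.0) * 0.5
        np.testing.assert_allclose(
            first_derivative(IntensityTrace(t, np.full(20, 2.0))).values, 0.0
        )
        d = first_derivative(IntensityTrace(t, 3.0 * t + 1.0))
        np.testing.assert_allclose(d.values, 3.0)

    def test_derivative_peak_of_normal_cdf(self):
        t = np.arange(0.0, 120.0, 0.5)
        tr = IntensityTrace(t, ndtr((t - 60.0) / 10.0))
        d = first_derivative(tr)
        assert t[np.argmax(d.values)] == pytest.approx(60.0, abs=0.5)


class TestDetectTransition:
    def test_gaussian_pulse_t1_and_hwhm(self):
        """An exact Gaussian derivative peak at 55.7 s with sigma 10 s has
        HWHM 11.774 s."""
        ev = detect_transition(gaussian_pulse_trace(55.7, 10.0))
        assert ev.t1_s == pytest.approx(55.7, abs=0.05)
        assert ev.hwhm_s == pytest.approx(10.0 * SQRT_2LN2, abs=0.05)
        assert ev.direction == 1
        assert not ev.flags

    def test_shoulder_before_primary(self):
        a = gaussian_pulse_trace(40.0, 4.0, height=0.3)
        b = gaussian_pulse_trace(60.0, 4.0, height=1.0)
        ev = detect_transition(a.replace(a.values + b.values))
        assert ev.t1_s == pytest.approx(60.0, abs=0.1)
        assert len(ev.shoulder_times_s) == 1
        assert ev.shoulder_times_s[0] == pytest.approx(40.0, abs=0.5)

    def test_falling_transition_detected(self):
        tr = gaussian_pulse_trace(50.0, 8.0)
        ev = detect_transition(tr.replace(-tr.values))
        assert ev.direction == -1
        assert ev.t1_s == pytest.approx(50.0, abs=0.1)

    def test_all_zero_derivative_raises(self):
        t = np.arange(0.0, 60.0, 0.5)
        with pytest.raises(NoTransitionError):
            detect_transition(IntensityTrace(t, np.zeros_like(t)))

    def test_pure_noise_raises(self):
        rng = np.random.default_rng(0)
        t = np.arange(0.0, 60.0, 0.5)
        with pytest.raises(NoTransitionError):
            detect_transition(IntensityTrace(t, rng.normal(0, 1, len(t))))

    def test_flank_missing_is_flagged(self):
        # trace ends partway down the right flank, above half height
        t = np.arange(0.0, 55.5, 0.5)
        v = np.exp(-0.5 * ((t - 50.0) / 10.0) ** 2)
        ev = detect_transition(IntensityTrace(t, v), noise_floor_factor=0.0)
        assert "right_flank_missing" in ev.flags
        assert ev.hwhm_s == pytest.approx(10.0 * SQRT_2LN2, rel=0.05)

    def test_agrees_with_brute_force_oracle(self):
        """On random clean Gaussian pulses the detector matches a brute-force
        oracle (raw argmax; half-crossings by linear scan)."""
        rng = np.random.default_rng(7)
        dt = 0.5
        for _ in range(300):
            center = rng.uniform(25, 95)
            sigma = rng.uniform(3, 15)
            height = rng.uniform(0.5, 50)
            tr = gaussian_pulse_trace(center, sigma, height, dt=dt)
            ev = detect_transition(tr)
            # oracle: discrete argmax and scanned half-crossings
            t, v = tr.times_s, tr.values
            i = int(np.argmax(v))
            half = v[i] / 2
            left = t[:i][v[:i] >= half]
            right = t[i:][v[i:] >= half]
            oracle_hwhm = (right[-1] - left[0]) / 2
            assert abs(ev.t1_s - t[i]) <= dt
            assert abs(ev.hwhm_s - oracle_hwhm) <= dt


class TestPipelineInvariances:
    def test_time_translation_equivariance(self):
        """Delaying the transition by D seconds shifts T1 by exactly D."""
        base = small_spec(t1_mean_s=50.0)
        shifted = small_spec(t1_mean_s=65.0)
        ev0 = self._event(render_video(base)[0])
        ev1 = self._event(render_video(shifted)[0])
        assert ev1.t1_s - ev0.t1_s == pytest.approx(15.0, abs=0.2)
        assert ev1.hwhm_s == pytest.approx(ev0.hwhm_s, abs=0.2)

    @staticmethod
    def _event(stack, window=39):
        tr = mean_trace(crop_roi(stack, RegionOfInterest(24, 24, 16)))
        return detect_transition(first_derivative(boxcar_smooth(tr, window)))

    def test_affine_intensity_invariance(self, clean_stack_and_field):
        """T1 and HWHM are unchanged by an affine intensity rescaling."""
        stack, _ = clean_stack_and_field
        ev0 = self._event(stack)
        scaled = stack.with_frames(
            (stack.frames.astype(np.int32) // 2 + 40).astype(np.uint8)
        )
        ev1 = self._event(scaled)
        assert ev1.t1_s == pytest.approx(ev0.t1_s, abs=0.3)
        assert ev1.hwhm_s == pytest.approx(ev0.hwhm_s, rel=0.02)


class TestStudyDesigns:
    def test_positions_constant_field(self, clean_stack_and_field):
        stack, _ = clean_stack_and_field
        rois = [RegionOfInterest(r, c, 10, f"{r},{c}")
                for r, c in [(12, 12), (12, 42), (42, 12), (42, 42)]]
        df, summary = analyze_positions(stack, rois)
        assert summary["n"] == 4
        assert summary["mean_t1_s"] == pytest.approx(58.0, abs=0.5)
        assert summary["sd_t1_s"] < 0.1

    def test_positions_gradient_ordering(self):
        spec = small_spec(t1_gradient_s_per_um=4.0)  # later to the right
        stack, _ = render_video(spec)
        rois = [RegionOfInterest(28, c, 8, str(c)) for c in (10, 25, 40)]
        df, _ = analyze_positions(stack, rois)
        assert df["t1_s"].is_monotonic_increasing

    def test_single_roi_sd_zero_flagged(self, clean_stack_and_field):
        stack, _ = clean_stack_and_field
        _, summary = analyze_positions(stack, [RegionOfInterest(20, 20, 10)])
        assert summary["sd_t1_s"] == 0.0
        assert summary.get("n1_flag") is True

    def test_failing_roi_reported_not_raised(self):
        spec = small_spec(final_intensity=30.0)  # no transition anywhere
        stack, _ = render_video(spec)
        df, summary = analyze_positions(stack, [RegionOfInterest(20, 20, 10)])
        assert df["error"].notna().all()
        assert summary["n"] == 0

    def test_sweep_constant_noiseless_sd_zero(self, clean_stack_and_field):
        stack, _ = clean_stack_and_field
        summary, _ = roi_size_sweep(stack, (32, 32), sizes_px=(2, 4, 8, 14),
                                    bin_px=2)
        assert np.all(summary["sd_t1_s"].to_numpy() < 1e-6)

    def test_sweep_size2_bin2_single_superpixel(self, clean_stack_and_field):
        stack, _ = clean_stack_and_field
        summary, events = roi_size_sweep(stack, (32, 32), sizes_px=(2,), bin_px=2)
        assert len(events) == 1
        assert summary.iloc[0]["n"] == 1
        assert summary.iloc[0].get("n1_flag", False)

    def test_sweep_oversized_roi_clipped_with_warning(self, clean_stack_and_field):
        stack, _ = clean_stack_and_field
        with pytest.warns(UserWarning, match="clipped"):
            summary, _ = roi_size_sweep(stack, (32, 32), sizes_px=(80,), bin_px=2)
        assert summary.iloc[0]["n"] > 0


class TestClustering:
    def test_k1_centroid_is_mean(self):
        res = cluster_t1([50.0, 60.0, 70.0], k=1, seed=0)
        assert res.centroids[0] == pytest.approx(60.0)

    def test_k2_matches_exhaustive_partition(self):
        values = [50.0, 51.0, 52.0, 90.0, 91.0, 92.0]
        res = cluster_t1(values, k=2, seed=0)
        # oracle: best SSE over every 2-partition
        best, best_sse = None, np.inf
        idx = range(len(values))
        for r in range(1, len(values)):
            for left in itertools.combinations(idx, r):
                right = tuple(i for i in idx if i not in left)
                sse = sum(
                    np.var([values[i] for i in grp]) * len(grp)
                    for grp in (left, right)
                )
                if sse < best_sse:
                    best, best_sse = (set(left), set(right)), sse
        got = (
            {i for i in idx if res.labels[i] == res.labels[0]},
            {i for i in idx if res.labels[i] != res.labels[0]},
        )
        assert {frozenset(g) for g in got} == {frozenset(g) for g in best}
        assert sorted(res.centroids) == pytest.approx([51.0, 91.0])

    def test_permutation_invariance(self):
        values = [50.0, 51.0, 52.0, 90.0, 91.0, 92.0]
        a = cluster_t1(values, k=2, seed=3)
        b = cluster_t1(values[::-1], k=2, seed=3)
        assert sorted(a.centroids) == pytest.approx(sorted(b.centroids))

    def test_n_less_than_k_rejected(self):
        with pytest.raises(ValueError):
            cluster_t1([1.0, 2.0], k=3, seed=0)


class TestHwhmReport:
    def test_single_event_and_empty(self):
        import pandas as pd

        df = pd.DataFrame(
            {"crystal": ["S2"], "roi_size_px": [14], "hwhm_s": [17.2]}
        )
        out = hwhm_report(df)
        assert len(out) == 1
        assert out.iloc[0]["mean_hwhm_s"] == 17.2
        assert out.iloc[0]["sd_hwhm_s"] == 0.0
        assert hwhm_report(pd.DataFrame()).empty

    def test_synthetic_width_recovered(self, clean_stack_and_field):
        """Mean HWHM over superpixels matches the generator's primary width
        after accounting for boxcar broadening."""
        import pandas as pd

        stack, _ = clean_stack_and_field
        _, events = roi_size_sweep(stack, (32, 32), sizes_px=(14,), bin_px=2,
                                   window=39)
        events["crystal"] = "synthetic"
        out = hwhm_report(events)
        sigma = 8.0
        broadened = np.sqrt(sigma**2 + (39**2 - 1) * 0.5**2 / 12)
        assert out.iloc[0]["mean_hwhm_s"] == pytest.approx(
            broadened * SQRT_2LN2, rel=0.15
        )
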