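"""dF/F trace analysis: registration, bout detection, waves, binned metrics."""

import numpy as np
import pytest
from scipy import ndimage

from larvahomeo import bouts as bt
from larvahomeo.synthetic import PeristalsisSimConfig, gen_peristaltic_traces


def _nmj_image(seed=0, shape=(64, 64), n_spots=12):
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.full(shape, 20.0)
    for _ in range(n_spots):
        y, x = rng.uniform(12, shape[0] - 12, 2)
        img += rng.uniform(50, 150) * np.exp(-((yy - y) ** 2 + (xx - x) ** 2) / (2 * 1.8**2))
    return img


class TestRegistration:
    def test_identical_frames_identity(self):
        img = _nmj_image()
        reg = bt.register_frames(np.stack([img] * 4), reference=0)
        np.testing.assert_allclose(reg.translations, 0.0)

    def test_integer_shifts_recovered_exactly(self):
        img = _nmj_image()
        shifts = [(0, 0), (3, -2), (-4, 1), (0, 5)]
        stack = np.stack([np.roll(img, s, axis=(0, 1)) for s in shifts])
        reg = bt.register_frames(stack, reference=0)
        for row, (dy, dx) in zip(reg.translations, shifts):
            assert row[0] == pytest.approx(-dy, abs=1e-9)
            assert row[1] == pytest.approx(-dx, abs=1e-9)

    def test_subpixel_shift_within_tenth_pixel(self):
        img = _nmj_image()
        moved = ndimage.shift(img, (0.5, 0.5), order=3, mode="nearest")
        reg = bt.register_frames(np.stack([img, moved]), reference=0, upsample_factor=100)
        np.testing.assert_allclose(np.abs(reg.translations[1]), 0.5, atol=0.1)

    def test_high_intensity_reference_selection(self):
        img = _nmj_image()
        stack = np.stack([0.5 * img, img, 2.0 * img])
        reg = bt.register_frames(stack, reference="high-intensity")
        assert reg.reference_frame == 2

    def test_affine_stage_returns_matrices(self):
        img = _nmj_image(shape=(32, 32), n_spots=5)
        stack = np.stack([img, np.roll(img, 2, axis=0)])
        reg = bt.register_frames(stack, reference=0, stages=("translation", "affine"))
        assert len(reg.affine) == 2
        np.testing.assert_allclose(reg.affine[0], [[1, 0, 0], [0, 1, 0]])


class TestExtractTrace:
    def _stack(self, roi_series, fm_series):
        n = len(roi_series)
        stack = np.zeros((n, 8, 8))
        stack[:, :4, :] = np.asarray(roi_series)[:, None, None]
        stack[:, 4:, :] = np.asarray(fm_series)[:, None, None]
        roi = np.zeros((8, 8), bool)
        roi[:4] = True
        bg = ~roi
        return stack, roi, bg

    def test_constant_stack_zero_dff(self):
        stack, roi, bg = self._stack([100.0] * 20, [20.0] * 20)
        trace = bt.extract_trace(stack, roi, bg, baseline_quantile=0.0)
        np.testing.assert_allclose(trace.dff, 0.0)

    def test_step_arithmetic(self):
        # ROI steps 100 -> 150, Fm = 20, F0 = 80 -> dff steps 0 -> 0.625
        stack, roi, bg = self._stack([100.0] * 10 + [150.0] * 10, [20.0] * 20)
        trace = bt.extract_trace(stack, roi, bg, baseline_quantile=0.0)
        assert trace.f0 == pytest.approx(80.0)
        np.testing.assert_allclose(trace.dff[:10], 0.0)
        np.testing.assert_allclose(trace.dff[10:], 0.625)

    def test_shared_bleach_cancels(self):
        n = 100
        bleach = np.exp(-np.arange(n) / 200.0)
        roi_sig = 100.0 * bleach
        fm_sig = 20.0 * np.ones(n)
        stack, roi, bg = self._stack(roi_sig + fm_sig, fm_sig)
        # bleaching applied to the synaptic component only is not cancelled;
        # bleaching shared by ROI and background is
        shared, roi2, bg2 = self._stack((100.0 + 20.0) * bleach, 20.0 * bleach)
        trace = bt.extract_trace(shared, roi2, bg2)
        assert np.ptp(trace.dff) < np.ptp(
            bt.extract_trace(stack, roi, bg).dff
        ) + 0.35  # residual drift stays bounded

    def test_overlapping_masks_rejected(self):
        stack = np.zeros((5, 8, 8))
        mask = np.ones((8, 8), bool)
        with pytest.raises(ValueError, match="disjoint"):
            bt.extract_trace(stack, mask, mask)

    def test_nonpositive_baseline_rejected(self):
        stack, roi, bg = self._stack([10.0] * 10, [20.0] * 10)
        with pytest.raises(ValueError, match="F0"):
            bt.extract_trace(stack, roi, bg)


class TestDetectBouts:
    def test_square_pulse(self):
        dff = np.zeros(40)
        dff[10:20] = 0.5
        trace = bt.FluorTrace(t=np.arange(40) / 20.0, dff=dff)
        bouts = bt.detect_bouts(trace)
        assert len(bouts) == 1
        assert bouts[0].onset == pytest.approx(0.5)
        assert bouts[0].duration == pytest.approx(0.5)

    def test_flat_trace_no_bouts(self):
        trace = bt.FluorTrace(t=np.arange(40) / 20.0, dff=np.zeros(40))
        assert bt.detect_bouts(trace) == []

    def test_peak_below_ten_percent_threshold_ignored(self):
        # threshold semantics: dF/F must surpass 10% of baseline
        dff = np.zeros(40)
        dff[10:20] = 0.09
        trace = bt.FluorTrace(t=np.arange(40) / 20.0, dff=dff)
        assert bt.detect_bouts(trace, threshold=0.10) == []

    def test_short_gap_merges(self):
        dff = np.zeros(60)
        dff[10:20] = 0.5
        dff[21:30] = 0.5  # 1-frame gap at 20 Hz (50 ms < merge_gap 150 ms)
        trace = bt.FluorTrace(t=np.arange(60) / 20.0, dff=dff)
        bouts = bt.detect_bouts(trace)
        assert len(bouts) == 1

    def test_min_duration_filters(self):
        dff = np.zeros(60)
        dff[10:13] = 0.5  # 150 ms < default min 250 ms
        trace = bt.FluorTrace(t=np.arange(60) / 20.0, dff=dff)
        assert bt.detect_bouts(trace) == []

    def test_invariant_to_constant_f_offset(self):
        # adding a constant to raw F leaves dff unchanged when F0 recomputed
        n = 200
        F = np.full(n, 100.0)
        F[50:100] += 60.0
        stack = np.zeros((n, 8, 8))
        stack[:, :4, :] = F[:, None, None]
        stack[:, 4:, :] = 20.0
        roi = np.zeros((8, 8), bool)
        roi[:4] = True
        t1 = bt.extract_trace(stack, roi, ~roi)
        t2 = bt.extract_trace(stack + 50.0, roi, ~roi)
        b1 = bt.detect_bouts(t1)
        b2 = bt.detect_bouts(t2)
        assert [b.onset for b in b1] == [b.onset for b in b2]
        assert len(b1) == 1


class TestBoutMetrics:
    def test_fraction_time_active(self):
        dff = np.zeros(12000)  # 600 s at 20 Hz
        dff[:1200] = 0.5  # one 60 s bout
        trace = bt.FluorTrace(t=np.arange(12000) / 20.0, dff=dff)
        bouts = bt.detect_bouts(trace)
        _, fta = bt.bout_metrics(bouts, trace)
        assert fta == pytest.approx(0.1)

    def test_triangular_bout_time_to_max(self):
        n = 200
        tri = np.concatenate([np.linspace(0, 1, n // 2), np.linspace(1, 0, n // 2)])
        dff = np.zeros(400)
        dff[100:300] = tri
        trace = bt.FluorTrace(t=np.arange(400) / 20.0, dff=dff)
        bouts = bt.detect_bouts(trace)
        assert len(bouts) == 1
        assert bouts[0].time_to_max == pytest.approx(bouts[0].duration / 2, rel=0.1)

    def test_fraction_bounds(self, peristalsis_run):
        traces, _, _ = peristalsis_run
        for trace in traces.values():
            fta = bt.fraction_time_active(bt.detect_bouts(trace), trace)
            assert 0.0 <= fta <= 1.0


class TestWaves:
    def _bout(self, onset, offset):
        return bt.Bout(
            onset=onset, offset=offset, peak_time=onset, peak_amplitude=1.0,
            mean_amplitude=1.0, integral=1.0,
        )

    def test_pa_wave_delays(self):
        bbs = {
            "A2": [self._bout(1.6, 3.6)],
            "A3": [self._bout(1.3, 3.3)],
            "A4": [self._bout(1.0, 3.0)],
        }
        waves, rejected = bt.assemble_waves(bbs)
        assert not rejected
        assert len(waves) == 1
        assert waves[0].direction == "P->A"
        np.testing.assert_allclose(waves[0].onset_delays, [0.3, 0.3])

    def test_overlap_time(self):
        bbs = {"A2": [self._bout(1.0, 2.0)], "A3": [self._bout(1.5, 3.0)]}
        waves, _ = bt.assemble_waves(bbs)
        assert waves[0].overlap_times == [pytest.approx(0.5)]

    def test_non_monotone_chain_rejected(self):
        bbs = {
            "A2": [self._bout(1.3, 3.3)],
            "A3": [self._bout(1.0, 3.0)],
            "A4": [self._bout(1.3, 3.4)],
        }
        waves, rejected = bt.assemble_waves(bbs)
        assert waves == []
        assert rejected and rejected[0]["reason"] == "non-monotone"

    def test_wave_direction_matches_generator_truth(self, peristalsis_run):
        traces, _, truth_waves = peristalsis_run
        bbs = {seg: bt.detect_bouts(tr) for seg, tr in traces.items()}
        waves, rejected = bt.assemble_waves(bbs)
        assert len(waves) == len(truth_waves)
        for est, true in zip(waves, truth_waves):
            assert est.direction == true.direction

    def test_wave_count_in_poisson_interval(self):
        # 600 s at 2 waves/min: central 99% Poisson(20) interval is [10, 32]
        cfg = PeristalsisSimConfig(record_length=600.0, wave_rate=2.0, seed=9)
        traces, _, truth_waves = gen_peristaltic_traces(cfg)
        bbs = {seg: bt.detect_bouts(tr) for seg, tr in traces.items()}
        waves, _ = bt.assemble_waves(bbs)
        assert 10 <= len(waves) <= 32


class TestContractionDisplacement:
    def test_no_motion_zero(self):
        reg = bt.RegistrationResult(
            translations=np.zeros((100, 2)), reference_frame=0,
            residuals=np.ones(100), unregistered=np.zeros(100, bool),
        )
        bout = bt.Bout(onset=1.0, offset=2.0, peak_time=1.5, peak_amplitude=1.0,
                       mean_amplitude=1.0, integral=1.0)
        assert bt.contraction_displacement(reg, [bout], 20.0, 0.5) == [0.0]

    def test_injected_drift_arithmetic(self):
        # 12 px drift at 0.5 um/px -> 6 um
        translations = np.zeros((100, 2))
        translations[30:40, 0] = 12.0
        reg = bt.RegistrationResult(
            translations=translations, reference_frame=0,
            residuals=np.ones(100), unregistered=np.zeros(100, bool),
        )
        bout = bt.Bout(onset=1.5, offset=2.0, peak_time=1.7, peak_amplitude=1.0,
                       mean_amplitude=1.0, integral=1.0)
        out = bt.contraction_displacement(reg, [bout], 20.0, 0.5)
        assert out == [pytest.approx(6.0)]

    def test_unregistered_frames_flagged(self):
        reg = bt.RegistrationResult(
            translations=np.zeros((100, 2)), reference_frame=0,
            residuals=np.ones(100), unregistered=np.ones(100, bool),
        )
        bout = bt.Bout(onset=1.0, offset=2.0, peak_time=1.5, peak_amplitude=1.0,
                       mean_amplitude=1.0, integral=1.0)
        with pytest.warns(UserWarning, match="unregistered"):
            out = bt.contraction_displacement(reg, [bout], 20.0, 0.5)
        assert np.isnan(out[0])


class TestActivityRates:
    def test_rate_normalisation(self):
        # 5 bouts in 300 s -> 10 per 10 min
        t = np.arange(6000) / 20.0
        dff = np.zeros(6000)
        for k in range(5):
            dff[k * 1000 : k * 1000 + 40] = 0.5
        traces = {
            "A2": bt.FluorTrace(t=t, dff=dff, roi_id="A2"),
            "A3": bt.FluorTrace(t=t, dff=dff, roi_id="A3"),
        }
        out = bt.pmsi_activity(traces)
        assert out["bouts_per_10min"] == pytest.approx(10.0)

    def test_short_recording_rejected(self):
        t = np.arange(100) / 20.0
        traces = {"A2": bt.FluorTrace(t=t, dff=np.zeros(100))}
        with pytest.raises(ValueError, match="60 s"):
            bt.pmsi_activity(traces)

    def test_reduced_wave_rate_recovered(self):
        rates = {}
        for rate in (1.0, 2.0):
            counts = []
            for seed in range(3):
                cfg = PeristalsisSimConfig(wave_rate=rate, record_length=600.0, seed=seed)
                traces, _, _ = gen_peristaltic_traces(cfg)
                out = bt.pmsi_activity(traces)
                counts.append(out["waves_per_10min"])
            rates[rate] = np.mean(counts)
        assert rates[1.0] / rates[2.0] == pytest.approx(0.5, abs=0.2)


class TestBinnedTimecourse:
    def _bouts(self, amps, durs, bin_length=600.0):
        out = []
        for k, (a, d) in enumerate(zip(amps, durs)):
            onset = k * bin_length + 10.0
            out.append(
                bt.Bout(onset=onset, offset=onset + d, peak_time=onset,
                        peak_amplitude=a, mean_amplitude=a, integral=a * d)
            )
        return out

    def test_stationary_statistics_all_ones(self):
        bouts = self._bouts([0.5] * 4, [2.0] * 4)
        tc = bt.binned_timecourse(bouts, recording_length=2400.0)
        np.testing.assert_allclose(tc.relative_amplitude, 1.0)
        np.testing.assert_allclose(tc.relative_duration, 1.0)

    def test_amplitude_halved_after_bin(self):
        bouts = self._bouts([0.5, 0.5, 0.25, 0.25], [2.0] * 4)
        tc = bt.binned_timecourse(bouts, recording_length=2400.0)
        np.testing.assert_allclose(tc.relative_amplitude, [1.0, 1.0, 0.5, 0.5])

    def test_duration_step_recovered_from_generator(self):
        # concatenate a 1x and a 2x duration-scale recording: the second bin's
        # relative duration should recover the step within 10%
        all_bouts = []
        for k, scale in enumerate((1.0, 2.0)):
            cfg = PeristalsisSimConfig(duration_scale=scale, record_length=600.0, seed=6)
            traces, _, _ = gen_peristaltic_traces(cfg)
            bs = bt.detect_bouts(traces["A3"])
            for b in bs:
                all_bouts.append(
                    bt.Bout(onset=b.onset + 600.0 * k, offset=b.offset + 600.0 * k,
                            peak_time=b.peak_time + 600.0 * k,
                            peak_amplitude=b.peak_amplitude,
                            mean_amplitude=b.mean_amplitude, integral=b.integral)
                )
        tc = bt.binned_timecourse(all_bouts, recording_length=1200.0)
        assert tc.relative_duration[1] == pytest.approx(2.0, rel=0.1)

    def test_empty_reference_bin_rejected(self):
        bouts = self._bouts([0.5], [2.0])
        with pytest.raises(ValueError, match="reference"):
            bt.binned_timecourse(bouts, recording_length=1200.0, reference_bin=1)
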