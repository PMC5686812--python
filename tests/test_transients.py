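"""ΔF/F0 baseline, transient detection and per-ROI metrics."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, strategies as st

import dendrocalc as dc
from dendrocalc import transients as tr
from dendrocalc.imageio_roi import RawTraceSet

from conftest import naive_event_scan


def _trace_set(F, fs=2.0, trial_index=None, states=None):
    F = np.asarray(F, dtype=float)[:, None]
    n = F.shape[0]
    trial_index = np.zeros(n, int) if trial_index is None else np.asarray(trial_index)
    states = states or {int(t): "running" for t in np.unique(trial_index)}
    return RawTraceSet(F, ["roi"], fs, trial_index, states)


def _dff_trace(dff, threshold, fs=2.0, trial_index=None, cfg=None):
    dff = np.asarray(dff, dtype=float)
    n = dff.size
    trial_index = np.zeros(n, int) if trial_index is None else np.asarray(trial_index)
    thr = np.atleast_1d(np.asarray(threshold, dtype=float))
    if thr.size == 1:
        bounds = np.array([[0, n - 1]])
    else:
        edges = np.linspace(0, n, thr.size + 1, dtype=int)
        bounds = np.column_stack([edges[:-1], edges[1:] - 1])
    return tr.DffTrace(
        roi_id="roi", dff=dff, f0=np.ones(thr.size), baseline_sd=thr / 3.0,
        threshold=thr, window_bounds=bounds, sampling_rate_hz=fs,
        trial_index=trial_index, config=cfg or tr.DetectionConfig(),
    )


class TestComputeDff:
    def test_constant_trace(self):
        dffs = dc.compute_dff(_trace_set(np.full(120, 100.0)))
        d = dffs["roi"]
        assert d.f0[0] == pytest.approx(100.0)
        np.testing.assert_allclose(d.dff, 0.0)
        assert d.baseline_sd[0] == 0.0
        assert d.threshold[0] == d.config.threshold_floor

    def test_lowest_ten_percent_define_f0(self):
        # 110 frames at 100, 10 at 200 in one 120-frame window: the lowest
        # 12 samples are all 100, so F0 = 100 and elevated frames read 1.0
        F = np.full(120, 100.0)
        F[50:60] = 200.0
        d = dc.compute_dff(_trace_set(F))["roi"]
        assert d.f0[0] == pytest.approx(100.0)
        np.testing.assert_allclose(d.dff[50:60], 1.0)
        np.testing.assert_allclose(d.dff[:50], 0.0)

    def test_generator_peak_recovered_exactly(self, quiet_trace_cfg):
        cfg = replace(quiet_trace_cfg, fixed_events_per_trial=1,
                      n_running_trials=1, n_resting_trials=0)
        ts, gt = dc.generate_trace_set(cfg, 0, 1, 0)
        d = dc.compute_dff(dc.subtract_background(ts))["den000"]
        (ev,) = gt.events["den000"]
        assert d.dff.max() == pytest.approx(ev.amplitude, abs=1e-9)

    def test_background_must_be_subtracted_first(self, small_trace_set):
        ts, _ = small_trace_set
        with pytest.raises(ValueError, match="background"):
            dc.compute_dff(ts)

    def test_nonpositive_f0_rejected(self):
        F = np.full(120, 100.0)
        ts = _trace_set(F)
        over = RawTraceSet(ts.F - 200.0, ts.roi_ids, ts.sampling_rate_hz,
                           ts.trial_index, ts.trial_states)
        with pytest.raises(ValueError, match="F0"):
            dc.compute_dff(over)

    def test_short_window_rejected(self):
        with pytest.raises(ValueError, match="10 samples"):
            dc.compute_dff(_trace_set(np.full(5, 100.0)))

    def test_threshold_is_three_baseline_sd_when_above_floor(self):
        rng = np.random.default_rng(0)
        F = 100.0 + rng.normal(0, 5.0, 240)
        for d in dc.compute_dff(_trace_set(F)).values():
            for sd, thr in zip(d.baseline_sd, d.threshold):
                if 3 * sd >= d.config.threshold_floor:
                    assert thr == pytest.approx(3 * sd)
                else:
                    assert thr == d.config.threshold_floor


class TestDetect:
    def test_flat_trace_detects_nothing(self):
        assert dc.detect_transients(_dff_trace(np.zeros(100), 0.15)) == []

    def test_six_supra_samples_at_2hz_last_three_seconds(self):
        dff = np.zeros(40)
        dff[10:16] = 0.2
        (ev,) = dc.detect_transients(_dff_trace(dff, 0.15))
        assert (ev.onset_frame, ev.offset_frame) == (10, 15)
        assert ev.duration_s == pytest.approx(3.0)
        assert ev.peak_dff == pytest.approx(0.2)
        assert not ev.prolonged and not ev.large_amplitude

    def test_event_split_at_trial_boundary(self):
        dff = np.zeros(40)
        dff[18:24] = 0.5
        trial = np.repeat([0, 1], 20)
        evs = dc.detect_transients(_dff_trace(dff, 0.15, trial_index=trial))
        assert [(e.onset_frame, e.offset_frame, e.trial) for e in evs] == [
            (18, 19, 0), (20, 23, 1)
        ]

    def test_strict_prolonged_and_large_cutoffs(self):
        fs = 2.0
        dff = np.zeros(60)
        dff[0:16] = 0.2   # 8.0 s: not prolonged (strict >)
        dff[20:37] = 4.0  # 8.5 s: prolonged; peak 4.0 not large (strict >)
        dff[40:42] = 4.01
        evs = dc.detect_transients(_dff_trace(dff, 0.15, fs=fs))
        assert [e.prolonged for e in evs] == [False, True, False]
        assert [e.large_amplitude for e in evs] == [False, False, True]

    def test_matches_naive_scan_on_random_traces(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(30, 300))
            dff = rng.normal(0, 0.1, n) + (rng.random(n) < 0.1) * rng.uniform(0.2, 3.0, n)
            n_trials = int(rng.integers(1, 4))
            trial = np.sort(rng.integers(0, n_trials, n))
            thr = rng.uniform(0.05, 0.4, int(rng.integers(1, 4)))
            d = _dff_trace(dff, thr, trial_index=trial)
            got = [(e.onset_frame, e.offset_frame) for e in dc.detect_transients(d)]
            assert got == naive_event_scan(dff, d.threshold_per_sample(), trial)

    def test_zero_noise_ground_truth_recovery(self, quiet_trace_cfg):
        ts, gt = dc.generate_trace_set(quiet_trace_cfg, 0, 10, 0)
        dffs = dc.compute_dff(dc.subtract_background(ts))
        for rid, d in dffs.items():
            evs = dc.detect_transients(d)
            expected = gt.expected_detections(rid, d.threshold_per_sample())
            assert [(e.onset_frame, e.offset_frame) for e in evs] == [
                (a, b) for a, b, _ in expected
            ]
            for e, (_, _, peak) in zip(evs, expected):
                assert e.peak_dff == pytest.approx(peak, abs=1e-9)

    @given(scale=st.floats(min_value=0.1, max_value=50.0))
    def test_detection_invariant_under_raw_gain(self, scale):
        """ΔF/F0 is scale-free: multiplying raw F by a gain leaves events put."""
        rng = np.random.default_rng(5)
        F = 100.0 + rng.normal(0, 2.0, 120)
        F[40:50] += 60.0
        ev1 = dc.detect_transients(dc.compute_dff(_trace_set(F))["roi"])
        ev2 = dc.detect_transients(dc.compute_dff(_trace_set(F * scale))["roi"])
        assert [(e.onset_frame, e.offset_frame) for e in ev1] == [
            (e.onset_frame, e.offset_frame) for e in ev2
        ]


class TestSummaries:
    def test_empty_and_simple_frequencies(self):
        s = dc.summarize_roi([], 5.0, roi_id="d")
        assert s.frequency_per_min == 0 and s.total_duration_s == 0
        evs = [
            tr.CalciumTransient("d", 0, 2 * i, 2 * i + 1, 1.0, 0.5, 0.5, False, False)
            for i in range(10)
        ]
        assert dc.summarize_roi(evs, 5.0).frequency_per_min == pytest.approx(2.0)

    def test_summary_matches_brute_force(self):
        rng = np.random.default_rng(9)
        evs = [
            tr.CalciumTransient(
                "d", 0, i, i + 1, float(rng.uniform(0.5, 12)),
                float(rng.uniform(0.1, 5)), float(rng.uniform(0.1, 3)), False, False,
            )
            for i in range(0, 200, 2)
        ]
        s = dc.summarize_roi(evs, 7.5)
        assert s.n_events == len(evs)
        assert s.total_duration_s == pytest.approx(sum(e.duration_s for e in evs))
        assert s.mean_peak == pytest.approx(sum(e.peak_dff for e in evs) / len(evs))
        assert s.total_integrated_activity_per_min == pytest.approx(
            sum(e.integrated_activity for e in evs) / 7.5
        )

    def test_integrated_activity_conserved(self):
        """Sum of per-event integrals equals the summary's per-minute total
        times minutes (conservation through aggregation)."""
        rng = np.random.default_rng(3)
        F = 100.0 + rng.normal(0, 2.0, 240)
        F[30:40] += 80
        F[150:170] += 50
        d = dc.compute_dff(_trace_set(F))["roi"]
        evs = dc.detect_transients(d)
        s = dc.summarize_roi(evs, 2.0)
        assert s.total_integrated_activity_per_min * 2.0 == pytest.approx(
            sum(e.integrated_activity for e in evs)
        )

    def test_mixed_rois_rejected(self):
        evs = [
            tr.CalciumTransient("a", 0, 0, 1, 1.0, 0.5, 0.5, False, False),
            tr.CalciumTransient("b", 0, 4, 5, 1.0, 0.5, 0.5, False, False),
        ]
        with pytest.raises(ValueError):
            dc.summarize_roi(evs, 1.0)


class TestFractionsAndCorrelation:
    @staticmethod
    def _ev(duration, peak=1.0, rid="d"):
        return tr.CalciumTransient(rid, 0, 0, 1, duration, peak, 0.1,
                                   duration > 8.0, peak > 4.0)

    def test_all_or_none_prolonged(self):
        groups = {f"d{i}": [self._ev(10.0, rid=f"d{i}")] for i in range(5)}
        assert dc.dendrite_fraction_with(groups, "prolonged") == 1.0
        groups = {f"d{i}": [self._ev(3.0, rid=f"d{i}")] for i in range(5)}
        assert dc.dendrite_fraction_with(groups, "prolonged") == 0.0

    def test_denominator_excludes_eventless_dendrites(self):
        groups = {"a": [self._ev(10.0)], "b": [self._ev(2.0)], "c": []}
        assert dc.dendrite_fraction_with(groups, "prolonged") == pytest.approx(0.5)
        with pytest.raises(ValueError):
            dc.dendrite_fraction_with({"a": []}, "prolonged")

    def test_proportional_amplitudes_give_unit_correlation(self):
        evs = [self._ev(d, peak=0.3 * d) for d in np.linspace(1, 20, 30)]
        r, p = dc.duration_amplitude_correlation(evs)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_independent_amplitudes_give_null_correlation(self):
        rng = np.random.default_rng(17)
        n = 2000
        evs = [self._ev(float(rng.uniform(1, 20)), peak=float(rng.uniform(0.2, 5)))
               for _ in range(n)]
        r, _ = dc.duration_amplitude_correlation(evs)
        assert abs(r) < 3 / np.sqrt(n)

    def test_generated_coupling_detected(self):
        cfg = dc.TraceGenConfig(noise_sd=0.0, f_rest_jitter=0.0, seed=21)
        ts, _ = dc.generate_trace_set(cfg, 0, 120, 0)
        dffs = dc.compute_dff(dc.subtract_background(ts))
        evs = [e for d in dffs.values() for e in dc.detect_transients(d)]
        assert len(evs) >= 500
        r, p = dc.duration_amplitude_correlation(evs)
        assert r > 0 and p < 0.05

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            dc.duration_amplitude_correlation([self._ev(1.0)] * 2)
        with pytest.raises(ValueError):
            dc.duration_amplitude_correlation([self._ev(2.0, 1.0)] * 5)
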