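"""Spine-specific unmixing, activity calls and first-vs-third comparison."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, strategies as st
from hypothesis.extra.numpy import arrays

import dendrocalc as dc
from dendrocalc import spines as sp
from dendrocalc import transients as tr


def _dff(series, roi_id="x", fs=2.0):
    series = np.asarray(series, dtype=float)
    n = series.size
    return tr.DffTrace(
        roi_id=roi_id, dff=series, f0=np.array([1.0]),
        baseline_sd=np.array([0.0]), threshold=np.array([0.05]),
        window_bounds=np.array([[0, n - 1]]), sampling_rate_hz=fs,
        trial_index=np.zeros(n, int),
    )


class TestSpineSpecific:
    @given(
        d=arrays(np.float64, 40, elements=st.floats(-2, 5, allow_nan=False, width=32))
    )
    def test_scaled_dendrite_cancels_exactly(self, d):
        out = sp.spine_specific(_dff(0.7 * d, "s"), _dff(d, "den"), 0.7)
        np.testing.assert_allclose(out.dff_specific, 0.0, atol=1e-12)

    def test_silent_dendrite_passthrough(self):
        rng = np.random.default_rng(0)
        s = rng.uniform(0, 2, 50)
        out = sp.spine_specific(_dff(s, "s"), _dff(np.zeros(50), "den"))
        np.testing.assert_array_equal(out.dff_specific, s)
        assert out.scale == 0.7

    def test_generator_intrinsic_signal_recovered(self, quiet_trace_cfg):
        cfg = replace(quiet_trace_cfg, spine_response_prob=0.7, f_rest_jitter=0.1)
        ts, gt = dc.generate_trace_set(cfg, 0, 2, 4)
        dffs = dc.compute_dff(dc.subtract_background(ts))
        for spine, den in ts.roi_parents.items():
            out = sp.spine_specific(dffs[spine], dffs[den], cfg.bap_scale, ts.roi_parents)
            np.testing.assert_allclose(
                out.dff_specific, gt.spine_intrinsic_clean[spine], atol=1e-9
            )

    def test_linearity_in_both_traces(self):
        rng = np.random.default_rng(1)
        x, y = rng.uniform(0, 3, 30), rng.uniform(0, 3, 30)
        base = sp.spine_specific(_dff(x, "s"), _dff(y, "den")).dff_specific
        scaled = sp.spine_specific(_dff(4 * x, "s"), _dff(4 * y, "den")).dff_specific
        np.testing.assert_allclose(scaled, 4 * base, rtol=1e-12)

    def test_scale_zero_reduces_to_raw_spine(self):
        rng = np.random.default_rng(2)
        s, d = rng.uniform(0, 2, 40), rng.uniform(0, 2, 40)
        out = sp.spine_specific(_dff(s, "s"), _dff(d, "den"), scale=0.0)
        np.testing.assert_array_equal(out.dff_specific, s)

    def test_length_and_parentage_checks(self):
        with pytest.raises(ValueError, match="length"):
            sp.spine_specific(_dff(np.zeros(10), "s"), _dff(np.zeros(12), "den"))
        with pytest.raises(ValueError, match="spine of"):
            sp.spine_specific(
                _dff(np.zeros(10), "s"), _dff(np.zeros(10), "den"),
                parent_map={"s": "other_dendrite"},
            )


class TestClassifyActive:
    def _sst(self, series):
        return sp.spine_specific(_dff(series, "s"), _dff(np.zeros(len(series)), "den"))

    def test_flat_window_inactive(self):
        call = sp.classify_active(self._sst(np.zeros(60)), (10, 20))
        assert not call.active

    def test_large_event_active(self):
        x = np.zeros(60)
        x[12:15] = 0.5  # 10x the floor threshold
        call = sp.classify_active(self._sst(x), (10, 20))
        assert call.active and call.peak_specific == pytest.approx(0.5)

    def test_monotone_in_amplitude(self):
        x = np.zeros(60)
        x[12:15] = 0.08
        sst = self._sst(x)
        thr = sst.threshold.copy()
        assert sp.classify_active(sst, (10, 20)).active
        sst.dff_specific = 5 * sst.dff_specific  # scale up, threshold held fixed
        sst.threshold = thr
        assert sp.classify_active(sst, (10, 20)).active

    def test_ratio_rule_cutoff(self):
        sst = self._sst(np.zeros(30))
        active = sp.classify_active(sst, (0, 29), rule="ratio", head_shaft_ratio=1.56)
        inactive = sp.classify_active(sst, (0, 29), rule="ratio", head_shaft_ratio=0.46)
        assert active.active and not inactive.active
        with pytest.raises(ValueError):
            sp.classify_active(sst, (0, 29), rule="ratio")

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            sp.classify_active(self._sst(np.zeros(30)), (20, 10))

    def test_calls_match_generator_schedule(self, quiet_trace_cfg):
        """At zero noise, a spine is active at a dendritic event iff one of
        its injected synaptic responses is supra-threshold inside the event
        window (100 spines; expected calls derived from the event records,
        not from the rendered trace)."""
        cfg = replace(
            quiet_trace_cfg, spine_response_prob=0.5, spine_event_rate_per_min=0.0, seed=31
        )
        ts, gt = dc.generate_trace_set(cfg, 0, 4, 25)
        dffs = dc.compute_dff(dc.subtract_background(ts))
        fs, tau = cfg.sampling_rate_hz, cfg.tau_decay_s
        checked = 0
        for spine, den in ts.roi_parents.items():
            sst = sp.spine_specific(dffs[spine], dffs[den], cfg.bap_scale)
            den_events = dc.detect_transients(dffs[den])
            assert len(den_events) == len(gt.events[den])
            for i, de in enumerate(den_events):
                thr = float(sst.threshold_per_sample()[de.onset_frame])
                expected = False
                for r in gt.spine_events[spine]:
                    n_supra = r.n_plateau + max(
                        0, int(np.floor(tau * fs * np.log(max(r.amplitude, 1e-12) / thr)))
                    )
                    a, b = r.onset_frame, r.onset_frame + n_supra - 1
                    if r.amplitude >= thr and a <= de.offset_frame and b >= de.onset_frame:
                        expected = True
                call = sp.classify_active(sst, (de.onset_frame, de.offset_frame), i)
                assert call.active == expected
                checked += 1
        assert checked > 100


class TestFirstThird:
    @staticmethod
    def _event(onset, dur_s, trial=0, rid="den"):
        fs = 2.0
        off = onset + int(dur_s * fs) - 1
        return tr.CalciumTransient(rid, trial, onset, off, dur_s, 1.0, 1.0,
                                   dur_s > 8.0, False)

    def test_strict_duration_class_cutoff(self):
        evs = [self._event(0, 2.0), self._event(20, 8.5), self._event(60, 2.0)]
        sst = sp.spine_specific(_dff(np.zeros(100), "s"), _dff(np.zeros(100), "den"))
        recs = sp.first_third_comparison(evs, {"s": sst})
        assert len(recs) == 1 and recs[0].middle_duration_class == ">8 s"
        evs[1] = self._event(20, 8.0)
        recs = sp.first_third_comparison(evs, {"s": sst})
        assert recs[0].middle_duration_class == "0-8 s"

    def test_fewer_than_three_transients_skipped(self):
        evs = [self._event(0, 2.0), self._event(20, 2.0)]
        sst = sp.spine_specific(_dff(np.zeros(60), "s"), _dff(np.zeros(60), "den"))
        assert sp.first_third_comparison(evs, {"s": sst}) == []

    def test_sliding_triplets_flagged_non_primary(self):
        evs = [self._event(i * 20, 2.0) for i in range(4)]
        sst = sp.spine_specific(_dff(np.zeros(100), "s"), _dff(np.zeros(100), "den"))
        recs = sp.first_third_comparison(evs, {"s": sst}, all_triplets=True)
        assert [r.primary for r in recs] == [True, False]
        primary_only = sp.first_third_comparison(evs, {"s": sst})
        assert len(primary_only) == 1 and primary_only[0].primary

    def test_equal_peaks_give_null_paired_test(self):
        from dendrocalc import route_and_test

        x = np.zeros(100)
        x[5:8] = 0.5
        x[45:48] = 0.5
        x[85:88] = 0.5
        sst = sp.spine_specific(_dff(x, "s"), _dff(np.zeros(100), "den"))
        evs = [self._event(4, 2.0), self._event(44, 2.0), self._event(84, 2.0)]
        recs = sp.first_third_comparison(evs, {f"s{i}": sst for i in range(5)})
        pre = [r.peak_pre for r in recs]
        post = [r.peak_post for r in recs]
        assert pre == post
        res = route_and_test(pre, post, paired=True)
        assert res.p_value == 1.0 and res.effect_direction == "none"
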