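"""Event detector: bracketing rule, thresholds, fast variant, merging."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from olcam.events import (
    CaEvent,
    DetectionParams,
    detect_events,
    detect_events_fast,
    event_bounds,
    merge_events,
)
from conftest import make_ztrace, pulse_trace


def bounds_oracle(z, peak, bound=1.0, frac=0.10):
    """Literal restatement of the onset/offset rule, scanned frame by frame."""
    onset = 0
    for t in range(peak - 1, -1, -1):
        if z[t] < bound:
            onset = t
            break
    fall = z[onset] + frac * (z[peak] - z[onset])
    offset = len(z) - 1
    for t in range(peak + 1, len(z)):
        if z[t] <= bound and t + 1 < len(z) and z[t + 1] <= bound:
            offset = t
            break
        if z[t] <= fall:
            offset = t
            break
    return onset, offset


class TestEventBounds:
    def test_hand_traced_bracket(self):
        z = np.array([0, 0, 0.5, 3, 8, 3, 0.4, 0.3, 0], dtype=float)
        assert event_bounds(z, 4) == (2, 6)

    def test_monotone_rise_falls_back_to_last_frame(self):
        z = np.linspace(0, 9, 10)
        onset, offset = event_bounds(z, 9)
        assert offset == 9

    def test_impulse_at_frame_zero_falls_back_to_frame_zero(self):
        z = np.zeros(10)
        z[0] = 8.0
        onset, _ = event_bounds(z, 0)
        assert onset == 0

    def test_brute_force_oracle_agreement_on_random_traces(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            z = rng.normal(0, 2, size=rng.integers(10, 60))
            peak = int(np.argmax(z))
            if z[peak] <= 1.0:
                continue
            assert event_bounds(z, peak) == bounds_oracle(z, peak)


class TestDetectEvents:
    def test_minimum_retained_pulse_length_is_four_frames(self):
        detected = {L: len(detect_events(pulse_trace(L))) for L in range(1, 11)}
        assert min(L for L, n in detected.items() if n) == 4
        assert all(n == 0 for L, n in detected.items() if L < 4)

    def test_amplitude_threshold_is_strictly_above_five_z(self):
        n_by_amp = {
            a: len(detect_events(pulse_trace(10, amplitude=float(a))))
            for a in range(1, 11)
        }
        assert max(a for a, n in n_by_amp.items() if n == 0) == 5

    def test_event_invariants_on_noisy_traces(self):
        rng = np.random.default_rng(3)
        params = DetectionParams()
        for _ in range(50):
            z = rng.normal(0, 2.5, size=400)
            events = detect_events(make_ztrace(z), params)
            last_offset = -1
            for ev in events:
                assert ev.onset_frame <= ev.peak_frame <= ev.offset_frame
                assert ev.amplitude_z > params.amp_thresh_z
                assert ev.duration_frames >= params.min_dur_frames
                assert ev.onset_frame > last_offset  # non-overlapping, sorted
                last_offset = ev.offset_frame

    def test_quiet_trace_yields_no_events(self):
        assert detect_events(make_ztrace(np.zeros(100))) == []

    def test_noiseless_session_recall_and_precision(self):
        """Well-separated generator events are all recovered exactly once."""
        from olcam.micromap import load_manual_rois
        from olcam.synthgen import SimConfig, simulate_session
        from conftest import run_detection

        config = SimConfig(
            duration_s=300,
            n_bouts=0,
            n_microdomains=4,
            field_um=12,
            rate_resting_per_min=8.0,
            noise_sd=0.0,
            motion_amp_px=0,
            drift_slope=0.0,
            seed=9,
        )
        movie, _, truth = simulate_session(config)
        cam_map = load_manual_rois(truth.true_footprints, config.pixel_size_um)
        events = run_detection(movie, cam_map)
        true_by_roi = {}
        for roi, onset, _, _ in truth.true_events:
            true_by_roi.setdefault(roi, []).append(onset)
        # precision = 1: every detection corresponds to a true event
        for ev in events:
            onsets = np.array(true_by_roi.get(ev.roi_id, []))
            assert onsets.size and np.min(np.abs(onsets - ev.onset_frame)) <= 2
        # recall = 1 on well-separated events (Poisson draws can collide;
        # same-CaM events overlapping in time merge by construction)
        det_by_roi = {}
        for ev in events:
            det_by_roi.setdefault(ev.roi_id, []).append(ev.onset_frame)
        fs = config.frame_rate_hz
        n_isolated = 0
        for roi, onsets in true_by_roi.items():
            onsets = np.sort(onsets)
            gaps = np.diff(onsets) / fs
            for i, onset in enumerate(onsets):
                before = gaps[i - 1] if i > 0 else np.inf
                after = gaps[i] if i < gaps.size else np.inf
                if min(before, after) < 4.0:
                    continue
                n_isolated += 1
                det = np.array(det_by_roi.get(roi, []))
                assert det.size and np.min(np.abs(det - onset)) <= 2
        assert n_isolated > 10  # the check is not vacuous


class TestMonotonicity:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_raising_thresholds_never_increases_event_count(self, seed):
        z = np.random.default_rng(seed).normal(0, 3, size=300)
        base = DetectionParams()
        n0 = len(detect_events(make_ztrace(z), base))
        higher_amp = DetectionParams(amp_thresh_z=6.5)
        longer_dur = DetectionParams(min_dur_frames=6)
        assert len(detect_events(make_ztrace(z), higher_amp)) <= n0
        assert len(detect_events(make_ztrace(z), longer_dur)) <= n0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_wider_merge_gap_never_increases_event_count(self, seed):
        rng = np.random.default_rng(seed)
        events = []
        cursor = 0
        for _ in range(rng.integers(1, 10)):
            cursor += int(rng.integers(1, 20))
            onset = cursor
            cursor += int(rng.integers(4, 15))
            events.append(CaEvent(1, onset, onset, cursor, 9.0, 15.0))
            cursor += 1
        n_narrow = len(merge_events(events, 0.1))
        n_wide = len(merge_events(events, 0.4))
        assert n_wide <= n_narrow


class TestMergeEvents:
    @staticmethod
    def _pair(gap_frames, fs=15.0):
        first = CaEvent(1, 10, 12, 20, 9.0, fs)
        second = CaEvent(1, 20 + gap_frames, 22 + gap_frames, 30 + gap_frames, 8.0, fs)
        return [first, second]

    def test_events_below_point_two_seconds_apart_fuse(self):
        merged = merge_events(self._pair(gap_frames=2))  # 0.133 s
        assert len(merged) == 1
        assert merged[0].onset_frame == 10 and merged[0].offset_frame == 32
        assert merged[0].amplitude_z == 9.0

    def test_gap_of_exactly_point_two_seconds_stays_split(self):
        assert len(merge_events(self._pair(gap_frames=3))) == 2  # 0.2 s, strict <

    def test_chain_merging_is_transitive(self):
        fs = 15.0
        events = []
        start = 0
        for _ in range(5):
            events.append(CaEvent(1, start, start + 1, start + 8, 9.0, fs))
            start += 8 + 2  # 0.133 s gaps between consecutive events
        assert len(merge_events(events)) == 1


class TestFastDetector:
    def test_prefilter_excludes_traces_below_seven_z(self):
        outcomes = {}
        for amp in range(1, 13):
            z = np.zeros(300)
            z[100:130] = amp
            outcomes[amp] = len(detect_events_fast(make_ztrace(z, fs=15.0)))
        assert min(a for a, n in outcomes.items() if n) == 7
        assert all(n == 0 for a, n in outcomes.items() if a < 7)

    def test_fast_event_duration_is_preserved(self):
        """A 5-frame (0.33 s) transient at 15 Hz keeps its raw duration."""
        z = np.zeros(450)
        z[200:205] = 9.0
        events = detect_events_fast(make_ztrace(z, fs=15.0))
        assert len(events) == 1
        assert 0.27 <= events[0].duration_s <= 0.40

    def test_hypersegmented_slow_event_is_rejoined(self):
        z = np.zeros(600)
        z[100:115] = 8.0
        z[116:130] = 8.0  # one-frame notch, ~0.13 s apart
        events = detect_events_fast(make_ztrace(z, fs=15.0))
        assert len(events) == 1
        assert events[0].duration_s == pytest.approx(2.0, abs=0.1)

    def test_low_frame_rate_rejects_lowpass(self):
        with pytest.raises(ValueError):
            detect_events_fast(make_ztrace(np.zeros(100), fs=1.5))

    def test_slow_events_agree_between_rates(self):
        """Counts of >= 1 s events match between 15 Hz and 5 Hz detection."""
        rng = np.random.default_rng(11)
        fs_fast = 15.0
        z = rng.normal(0, 0.3, size=3000)
        onsets = np.arange(100, 2800, 300)
        for onset in onsets:
            dur = int(1.4 * fs_fast)
            z[onset : onset + dur] += 9.0 * np.exp(-np.arange(dur) / (dur / 2))
        fast = [
            e for e in detect_events_fast(make_ztrace(z, fs=fs_fast)) if e.duration_s >= 1
        ]
        z5 = z[::3]  # downsample to 5 Hz
        slow = [
            e for e in detect_events(make_ztrace(z5, fs=5.0)) if e.duration_s >= 1
        ]
        assert abs(len(fast) - len(slow)) <= 0.1 * max(len(fast), len(slow))
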