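"""Phase alignment, session summaries, responsiveness, latency."""

import numpy as np
import pytest

from olcam.behavior import LocomotionBout, RestingPeriod
from olcam.events import CaEvent
from olcam.metrics import (
    assign_phase,
    bout_triggered_response,
    classify_responsiveness,
    latency_to_max,
    neuron_responsive,
    summarize_session,
    _half_rise_lag,
)

FS = 5.1


def ev(onset_s, roi=1, dur_s=1.0, amp=9.0):
    onset = int(round(onset_s * FS))
    offset = onset + max(int(round(dur_s * FS)) - 1, 0)
    return CaEvent(roi, onset, onset, offset, amp, FS)


BOUT = LocomotionBout(start_s=100.0, end_raw_s=120.0, end_extended_s=122.5,
                      peak_speed_mm_s=60.0)
REST = RestingPeriod(start_s=160.0, end_s=220.0)


class TestAssignPhase:
    def test_onset_inside_extension_is_active(self):
        events = assign_phase([ev(121.0)], [BOUT], [REST])
        assert events[0].phase == "active"

    def test_onset_in_long_quiet_gap_is_resting(self):
        events = assign_phase([ev(200.0)], [BOUT], [REST])
        assert events[0].phase == "resting"

    def test_onset_in_short_gap_is_unclassified(self):
        events = assign_phase([ev(140.0)], [BOUT], [REST])
        assert events[0].phase == "unclassified"

    def test_every_event_gets_exactly_one_label(self):
        rng = np.random.default_rng(0)
        events = assign_phase(
            [ev(t) for t in rng.uniform(0, 300, 100)], [BOUT], [REST]
        )
        labels = {e.phase for e in events}
        assert labels <= {"active", "resting", "unclassified"}
        n_by = {p: sum(e.phase == p for e in events) for p in labels}
        assert sum(n_by.values()) == 100


class TestSummarize:
    def test_rate_arithmetic(self):
        """10 events in 2 resting minutes over 5 CaMs, every CaM active."""
        resting = [RestingPeriod(0.0, 120.0)]
        events = [ev(3 + 2 * i, roi=(i % 5) + 1) for i in range(10)]
        assign_phase(events, [], resting)
        s = summarize_session(events, [], resting, n_cams=5)
        assert s.resting.events_per_min == pytest.approx(5.0)
        assert s.resting.active_cams_per_min == pytest.approx(2.5)
        assert s.resting.events_per_min_per_cam == pytest.approx(1.0)
        assert s.resting.events_per_min >= s.resting.events_per_min_per_cam

    def test_no_events_gives_zero_rates_and_empty_distributions(self):
        resting = [RestingPeriod(0.0, 120.0)]
        s = summarize_session([], [], resting, n_cams=5)
        assert s.resting.events_per_min == 0
        assert s.resting.durations_s.size == 0
        assert s.resting.isis_s.size == 0

    def test_zero_resting_minutes_leaves_ratio_undefined(self):
        events = assign_phase([ev(101.0)], [BOUT], [])
        s = summarize_session(events, [BOUT], [], n_cams=3)
        assert s.ar_ratio is None
        assert s.responder_class == "undefined"

    def test_ar_ratio_equals_direct_recomputation(self):
        rng = np.random.default_rng(1)
        events = [ev(t, roi=rng.integers(1, 4)) for t in rng.uniform(95, 230, 60)]
        assign_phase(events, [BOUT], [REST])
        s = summarize_session(events, [BOUT], [REST], n_cams=3)
        assert s.ar_ratio == pytest.approx(
            s.active.events_per_min / s.resting.events_per_min
        )

    def test_isis_are_pooled_across_cams_within_phase(self):
        resting = [RestingPeriod(0.0, 60.0)]
        events = [ev(10.0, roi=1), ev(10.5, roi=2), ev(12.0, roi=1)]
        assign_phase(events, [], resting)
        s = summarize_session(events, [], resting, n_cams=2)
        # onsets quantized to frames 51, 54, 61 at 5.1 Hz
        expected = np.diff(np.array([51, 54, 61]) / FS)
        assert s.resting.isis_s == pytest.approx(expected)


class TestResponsiveness:
    def test_reported_class_means(self):
        assert classify_responsiveness(2.71) == "LR"
        assert classify_responsiveness(1.13) == "LNR"

    def test_boundary_is_strict(self):
        assert classify_responsiveness(1.5) == "LNR"
        grid = [k / 100 for k in range(100, 301)]
        largest_lnr = max(a for a in grid if classify_responsiveness(a) == "LNR")
        assert largest_lnr == pytest.approx(1.5)

    def test_undefined_ratio(self):
        assert classify_responsiveness(None) == "undefined"

    def test_more_active_events_never_flips_lr_to_lnr(self):
        events = [ev(t, roi=1) for t in (165, 170, 175)]  # resting
        active_times = [101, 104, 107, 110, 113]
        for n_active in range(2, len(active_times) + 1):
            evs = events + [ev(t, roi=1) for t in active_times[:n_active]]
            assign_phase(evs, [BOUT], [REST])
            s = summarize_session(evs, [BOUT], [REST], n_cams=1)
            if n_active == 2:
                previous = s.responder_class
            if previous == "LR":
                assert s.responder_class == "LR"
            previous = s.responder_class


class TestNeuronResponsive:
    BOUTS = [
        LocomotionBout(start_s=s, end_raw_s=s + 10, end_extended_s=s + 12.5,
                       peak_speed_mm_s=50.0)
        for s in np.arange(10, 510, 50.0)
    ]

    def _onsets(self, k):
        return np.array([b.start_s + 2.0 for b in self.BOUTS[:k]])

    def test_five_of_ten_is_responsive(self):
        assert neuron_responsive(self._onsets(5), self.BOUTS)

    def test_four_of_ten_is_not(self):
        assert not neuron_responsive(self._onsets(4), self.BOUTS)

    def test_window_boundary_is_closed(self):
        onsets = np.array([b.start_s + 4.0 for b in self.BOUTS[:5]])
        assert neuron_responsive(onsets, self.BOUTS)
        late = np.array([b.start_s + 4.01 for b in self.BOUTS[:5]])
        assert not neuron_responsive(late, self.BOUTS)

    def test_no_bouts_is_an_error(self):
        with pytest.raises(ValueError):
            neuron_responsive(np.array([1.0]), [])


class TestLatency:
    def test_single_event_at_bout_start_gives_near_zero_lag(self):
        n_frames = int(300 * FS)
        bout = LocomotionBout(100.0, 120.0, 122.5, 60.0)
        events = [ev(100.1, roi=1)]
        lags, hist = latency_to_max(events, [bout], n_frames, FS)
        assert len(lags) == 1
        assert lags[0] == pytest.approx(0.0, abs=0.7)
        assert hist.sum() == 1

    def test_truncated_bout_is_skipped_with_warning(self):
        n_frames = int(110 * FS)
        bout = LocomotionBout(105.0, 108.0, 110.0, 60.0)
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                bout_triggered_response([ev(106.0)], [bout], n_frames, FS)

    def test_configured_onset_lag_recovered_from_generator_sessions(self):
        """The rate switch lag (~3.6 s for OPCs after locomotion onset)
        is recovered from the bout-averaged onset-rate response."""
        import olcam.synthgen as sg

        lags = [self._session_lag(seed, 3.6, 5.1, 0.5) for seed in range(8)]
        assert np.mean(lags) == pytest.approx(3.6, abs=0.5)

    def test_short_fiber_lag_recovered_at_fifteen_hertz(self):
        lags = [self._session_lag(seed, 0.3, 15.0, 0.2) for seed in range(12)]
        assert np.mean(lags) <= 0.5

    @staticmethod
    def _session_lag(seed, lag_s, frame_rate, smooth_s):
        import olcam.synthgen as sg

        config = sg.SimConfig(seed=seed, onset_lag_s=lag_s, frame_rate_hz=frame_rate)
        rngs = sg._rngs(config.seed)
        _, true_bouts = sg.simulate_speed(config, rngs[0])
        segments = sg._piecewise_rate_windows(config, true_bouts)
        fs, n_frames = config.frame_rate_hz, config.n_frames
        events = []
        for roi in range(1, config.n_microdomains + 1):
            for t_ev in sg._sample_event_times(
                segments, 1 / config.n_microdomains, rngs[2]
            ):
                onset = int(round(t_ev * fs))
                if onset >= n_frames:
                    continue
                events.append(
                    CaEvent(roi, onset, onset, min(onset + 5, n_frames - 1), 9.0, fs)
                )
        bouts = [
            LocomotionBout(b0, b1, b1 + 2.5, 60.0) for b0, b1 in true_bouts
        ]
        lag_axis, response = bout_triggered_response(
            events, bouts, n_frames, fs, smooth_s=smooth_s
        )
        return _half_rise_lag(lag_axis, response)
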