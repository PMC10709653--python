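"""Shared fixtures: small synthetic sessions reused across test modules."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from olcam.events import detect_events
from olcam.micromap import segment_microdomains
from olcam.preprocess import (
    ZTrace,
    detrend_zscore,
    extract_traces,
    ratiometric_correct,
    register_rigid,
)
from olcam.synthgen import SimConfig, simulate_session

SMALL = dict(
    duration_s=120.0,
    n_bouts=1,
    bout_dur_s=30.0,
    n_microdomains=8,
    field_um=14.0,
)


def make_ztrace(values, fs=5.1, roi_id=0):
    return ZTrace(values=np.asarray(values, dtype=float), frame_rate_hz=fs, roi_id=roi_id)


def pulse_trace(length, amplitude=10.0, n=80, start=30, fs=5.1):
    """Flat z-trace with one square pulse."""
    z = np.zeros(n)
    z[start : start + length] = amplitude
    return make_ztrace(z, fs)


def run_detection(movie, cam_map):
    """Corrected-trace event detection for every ROI of a map."""
    fs = movie.frame_rate_hz
    green = extract_traces(movie.green, cam_map.labels)
    red = extract_traces(movie.red, cam_map.labels)
    events = []
    for k in green:
        corrected = ratiometric_correct(
            detrend_zscore(green[k], fs, roi_id=k),
            detrend_zscore(red[k], fs, roi_id=k),
        )
        events.extend(detect_events(corrected, roi_id=k))
    return events


@pytest.fixture(scope="session")
def small_session():
    """One registered small synthetic session with its map and events."""
    config = SimConfig(seed=42, **SMALL)
    movie, speed, truth = simulate_session(config)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        registered, shifts = register_rigid(movie)
        cam_map = segment_microdomains(
            registered.green, config.frame_rate_hz, config.pixel_size_um
        )
    events = run_detection(registered, cam_map)
    return {
        "config": config,
        "movie": registered,
        "speed": speed,
        "truth": truth,
        "shifts": shifts,
        "cam_map": cam_map,
        "events": events,
    }
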