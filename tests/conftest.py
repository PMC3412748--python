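"""Shared fixtures: hand-built epochs with known structure.

Fixture epochs are constructed directly (not via the signal generator) so
that scoring tests have ground truth independent of the generator code.
"""

import numpy as np
import pytest

from ptssrisk.epochs import SignalEpoch

FS = 100.0


def make_sampled_epoch(
    samples,
    channel="sc",
    onset=2.0,
    trial=1,
    paradigm="loud_tones",
    stimulus="tone",
    phase=None,
    fs=FS,
    **kw,
):
    return SignalEpoch(
        subject_id="T01",
        paradigm=paradigm,
        trial_index=trial,
        channel=channel,
        stimulus=stimulus,
        phase=phase,
        onset_time=onset,
        offset_time=onset + 0.5,
        sampling_rate=fs,
        samples=np.asarray(samples, dtype=float),
        **kw,
    )


def make_ibi_epoch(beat_times_ms, onset=2.0, trial=1, paradigm="loud_tones",
                   stimulus="tone", phase=None, **kw):
    return SignalEpoch(
        subject_id="T01",
        paradigm=paradigm,
        trial_index=trial,
        channel="ibi",
        stimulus=stimulus,
        phase=phase,
        onset_time=onset,
        offset_time=onset + 0.5,
        beat_times=np.asarray(beat_times_ms, dtype=float),
        **kw,
    )


def pulse_trace(n, fs, onset, pulse_t, amp, width=0.1, baseline=0.0):
    """Flat baseline plus a half-sine pulse of height ``amp`` at ``pulse_t``
    (s relative to onset)."""
    t = np.arange(n) / fs - onset
    s = (t - pulse_t) / width
    k = np.where((s >= 0) & (s < 1), np.sin(np.pi * np.clip(s, 0, 1)), 0.0)
    m = k.max()
    if m > 0:
        k = k / m
    return baseline + amp * k


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
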