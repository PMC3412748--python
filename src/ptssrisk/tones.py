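"""Loud-tone session scoring: startle reactivity and habituation features.

A session is 15 presentations of a 95-dB, 500-ms, 1000-Hz tone.  Per trial,
baseline-to-peak responses are scored for eyeblink EMG (peak within
40-200 ms of tone onset), skin conductance (peak within 1-4 s) and heart
rate (peak HR within 1-4 s against the two pre-onset beats).  Session
features are the mean square-root-transformed responses, mean pre-stimulus
levels, relative habituation (regression slope of transformed response on
log trial number, trials 2-15) and absolute habituation (trials to a
criterion of two successive non-response trials).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .epochs import SignalEpoch, TrialResponse, WindowSpec, peak_response
from .exceptions import DegenerateFitError, InvalidInputError, SessionShapeError

N_TONE_TRIALS = 15

#: Default scoring windows (s relative to tone onset, half-open).
TONE_WINDOWS: Dict[str, WindowSpec] = {
    "eyeblink_emg": WindowSpec(-1.0, 0.0, 0.04, 0.2, "max"),
    "sc": WindowSpec(-1.0, 0.0, 1.0, 4.0, "max"),
    "ibi": WindowSpec(-1.0, 0.0, 1.0, 4.0, "min_ibi", hr_baseline_beats=2),
}

#: Non-response criteria on raw responses (physical units).
SC_CRITERION_US = 0.05
EMG_CRITERION_UV = 0.30


@dataclass(frozen=True)
class ToneFeatures:
    pre_tone_hr_level: float  # bpm
    pre_tone_sc_level: float  # uS
    mean_hr_response: float  # sqrt(bpm)
    mean_sc_response: float  # sqrt(uS)
    mean_eyeblink_response: float  # sqrt(uV)
    hr_slope: float
    sc_slope: float
    eyeblink_slope: float
    sc_trials_to_criterion: int
    eyeblink_trials_to_criterion: int

    def to_feature_dict(self) -> Dict[str, float]:
        return {
            "hr_pre_tone_level": self.pre_tone_hr_level,
            "sc_pre_tone_level": self.pre_tone_sc_level,
            "hr_mean_response": self.mean_hr_response,
            "sc_mean_response": self.mean_sc_response,
            "emg_mean_response": self.mean_eyeblink_response,
            "hr_slope": self.hr_slope,
            "sc_slope": self.sc_slope,
            "emg_slope": self.eyeblink_slope,
            "sc_trials_to_criterion": self.sc_trials_to_criterion,
            "emg_trials_to_criterion": self.eyeblink_trials_to_criterion,
        }


def trials_to_criterion(raw_responses: Sequence[float], threshold: float) -> int:
    """Number of trials before two successive non-response trials.

    Returns ``k - 1`` for the first 1-based trial ``k`` such that trials
    ``k`` and ``k+1`` are both below ``threshold``; sessions that never
    reach the criterion are assigned the number of trials (15).
    """
    if threshold <= 0:
        raise InvalidInputError("criterion threshold must be positive")
    vals = list(raw_responses)
    for k in range(len(vals) - 1):
        if vals[k] < threshold and vals[k + 1] < threshold:
            return k
    return len(vals)


def habituation_slope(transformed_responses: Sequence[float]) -> float:
    """OLS slope of transformed response on log trial number, trials 2-15.

    Trial 1 is excluded by definition (the initial orienting-like response
    does not belong to the habituation course).  Natural log is used; the
    base only rescales the slope.
    """
    y_all = np.asarray(transformed_responses, dtype=float)
    trials = np.arange(1, len(y_all) + 1)
    mask = (trials >= 2) & np.isfinite(y_all)
    y = y_all[mask]
    x = np.log(trials[mask])
    if len(y) < 2 or np.ptp(x) == 0:
        raise DegenerateFitError("habituation slope needs >= 2 usable trials after trial 1")
    slope = np.polyfit(x, y, 1)[0]
    return float(slope)


def _group_session(epochs: Iterable[SignalEpoch]) -> Dict[str, List[SignalEpoch]]:
    by_channel: Dict[str, List[SignalEpoch]] = {}
    for ep in epochs:
        if ep.paradigm != "loud_tones":
            raise SessionShapeError(f"epoch for trial {ep.trial_index} is not loud_tones")
        by_channel.setdefault(ep.channel, []).append(ep)
    for ch, eps in by_channel.items():
        eps.sort(key=lambda e: e.trial_index)
        idx = [e.trial_index for e in eps]
        if idx != list(range(1, N_TONE_TRIALS + 1)):
            raise SessionShapeError(
                f"channel {ch!r}: expected trials 1..{N_TONE_TRIALS}, got {idx}"
            )
    return by_channel


def score_tone_session(
    epochs: Iterable[SignalEpoch],
    windows: Dict[str, WindowSpec] | None = None,
    sc_criterion: float = SC_CRITERION_US,
    emg_criterion: float = EMG_CRITERION_UV,
) -> Tuple[Dict[str, List[TrialResponse]], ToneFeatures]:
    """Score a 15-tone session into per-trial responses and session features."""
    windows = windows or TONE_WINDOWS
    by_channel = _group_session(epochs)
    for ch in ("eyeblink_emg", "sc", "ibi"):
        if ch not in by_channel:
            raise SessionShapeError(f"loud-tone session missing channel {ch!r}")

    responses = {
        ch: [peak_response(ep, windows[ch]) for ep in eps]
        for ch, eps in by_channel.items()
        if ch in windows
    }

    def mean_transformed(ch):
        return float(np.mean([r.transformed_response for r in responses[ch]]))

    def mean_baseline(ch):
        return float(np.mean([r.baseline_level for r in responses[ch]]))

    def slope(ch):
        return habituation_slope([r.transformed_response for r in responses[ch]])

    features = ToneFeatures(
        pre_tone_hr_level=mean_baseline("ibi"),
        pre_tone_sc_level=mean_baseline("sc"),
        mean_hr_response=mean_transformed("ibi"),
        mean_sc_response=mean_transformed("sc"),
        mean_eyeblink_response=mean_transformed("eyeblink_emg"),
        hr_slope=slope("ibi"),
        sc_slope=slope("sc"),
        eyeblink_slope=slope("eyeblink_emg"),
        sc_trials_to_criterion=trials_to_criterion(
            [r.raw_response for r in responses["sc"]], sc_criterion
        ),
        eyeblink_trials_to_criterion=trials_to_criterion(
            [r.raw_response for r in responses["eyeblink_emg"]], emg_criterion
        ),
    )
    return responses, features
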