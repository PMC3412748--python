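"""Channel-agnostic epoch arithmetic shared by every scoring stage.

An epoch is one channel's recording for one trial, time-locked to stimulus
onset.  Uniformly sampled channels (skin conductance, integrated EMG) carry a
``samples`` array; the cardiac channel carries R-wave event times
(``beat_times``, ms) from which heart rate is derived per interbeat interval
(IBI).  All scoring windows are expressed in seconds relative to stimulus
onset and are half-open ``[start, end)`` so the onset sample is counted once.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .exceptions import EmptyWindowError, InvalidInputError, ValidationError

PARADIGMS = ("loud_tones", "conditioning", "imagery")
PHASES = ("baseline", "habituation", "acquisition", "extinction", "imagery")
STIMULI = ("tone", "cs_plus", "cs_minus", "ucs", "script_trauma", "script_other")
SAMPLED_CHANNELS = ("eyeblink_emg", "corrugator_emg", "frontalis_emg", "sc")
BEAT_CHANNELS = ("ibi",)
CHANNELS = SAMPLED_CHANNELS + BEAT_CHANNELS

#: Channel units (EMG integrated microvolts, skin conductance microsiemens,
#: heart rate in beats/min derived from IBI ms).
CHANNEL_UNITS = {
    "eyeblink_emg": "uV",
    "corrugator_emg": "uV",
    "frontalis_emg": "uV",
    "sc": "uS",
    "ibi": "ms",
}


def ibi_to_hr(ibi_ms: float) -> float:
    """Convert an interbeat interval (ms) to heart rate (beats/min)."""
    if ibi_ms <= 0:
        raise InvalidInputError(f"interbeat interval must be positive, got {ibi_ms}")
    return 60000.0 / ibi_ms


def signed_sqrt(x):
    """Odd extension of the square root: ``sign(x) * sqrt(|x|)``.

    The square-root transform reduces skewness of response magnitudes; the
    odd extension keeps it defined (and order preserving) for the negative
    raw responses that HR/SC decelerations can produce.
    """
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.sqrt(np.abs(x))
    return out if out.ndim else float(out)


@dataclass
class SignalEpoch:
    """One channel's data for one trial, time-locked to stimulus onset.

    Sample ``k`` of a uniformly sampled channel lies at ``k / sampling_rate``
    seconds from epoch start; ``onset_time`` locates the stimulus within the
    epoch.  ``beat_times`` are in ms from epoch start (ibi channel only).
    """

    subject_id: str
    paradigm: str
    trial_index: int
    channel: str
    stimulus: str
    onset_time: float
    offset_time: float
    phase: Optional[str] = None
    sampling_rate: Optional[float] = None
    samples: Optional[np.ndarray] = None
    beat_times: Optional[np.ndarray] = None
    ucs_onset_time: Optional[float] = None
    ucs_offset_time: Optional[float] = None

    def __post_init__(self):
        if self.paradigm not in PARADIGMS:
            raise ValidationError(f"unknown paradigm {self.paradigm!r}")
        if self.channel not in CHANNELS:
            raise ValidationError(f"unknown channel {self.channel!r}")
        if self.stimulus not in STIMULI:
            raise ValidationError(f"unknown stimulus {self.stimulus!r}")
        if self.phase is not None and self.phase not in PHASES:
            raise ValidationError(f"unknown phase {self.phase!r}")
        if self.trial_index < 1:
            raise ValidationError("trial_index must be a positive integer")
        if self.channel in SAMPLED_CHANNELS:
            if self.samples is None or self.beat_times is not None:
                raise ValidationError(
                    f"channel {self.channel!r} requires samples and no beat_times"
                )
            if not self.sampling_rate or self.sampling_rate <= 0:
                raise ValidationError("sampling_rate must be > 0 for sampled channels")
            self.samples = np.asarray(self.samples, dtype=float)
        else:
            if self.beat_times is None or self.samples is not None:
                raise ValidationError("ibi channel requires beat_times and no samples")
            self.beat_times = np.asarray(self.beat_times, dtype=float)
            if np.any(np.diff(self.beat_times) <= 0):
                raise ValidationError("beat_times must be strictly increasing")
        if self.offset_time < self.onset_time:
            raise ValidationError("offset_time must be >= onset_time")

    @property
    def duration(self) -> float:
        if self.samples is not None:
            return len(self.samples) / self.sampling_rate
        return float(self.beat_times[-1]) / 1000.0 if len(self.beat_times) else 0.0

    @property
    def sample_times(self) -> np.ndarray:
        """Times (s, from epoch start) of the uniformly sampled values."""
        if self.samples is None:
            raise ValidationError("sample_times undefined for beat-event channel")
        return np.arange(len(self.samples)) / self.sampling_rate

    def copy(self, **changes) -> "SignalEpoch":
        return replace(self, **changes)


@dataclass(frozen=True)
class WindowSpec:
    """Baseline and search windows (s, relative to onset), half-open.

    ``statistic`` selects the search-window reduction: ``max`` for sampled
    channels, ``min_ibi`` for peak heart rate (HR of the shortest interbeat
    interval terminating inside the window), ``mean`` for averages.
    ``hr_baseline_beats`` switches the cardiac baseline to the mean HR of
    that many beats immediately preceding onset instead of a time window.
    """

    baseline_start: float
    baseline_end: float
    search_start: float
    search_end: float
    statistic: str = "max"
    hr_baseline_beats: Optional[int] = None

    def __post_init__(self):
        if self.baseline_end > 0:
            raise ValidationError("baseline must end at or before stimulus onset")
        if not self.baseline_start < self.baseline_end:
            raise ValidationError("baseline_start must precede baseline_end")
        if not self.search_start < self.search_end:
            raise ValidationError("search_start must precede search_end")
        if self.statistic not in ("max", "min_ibi", "mean"):
            raise ValidationError(f"unknown statistic {self.statistic!r}")


@dataclass(frozen=True)
class TrialResponse:
    """Per-trial baseline level plus raw and square-root-transformed response."""

    channel: str
    trial_index: int
    baseline_level: float
    raw_response: float
    transformed_response: float


def _ibi_in_window(epoch: SignalEpoch, lo_s: float, hi_s: float) -> np.ndarray:
    """Interbeat intervals (ms) whose terminating beat falls in [lo, hi) s."""
    bt = epoch.beat_times
    ibis = np.diff(bt)
    term = bt[1:]
    mask = (term >= lo_s * 1000.0) & (term < hi_s * 1000.0)
    return ibis[mask]


def window_statistic(epoch: SignalEpoch, start: float, end: float, statistic: str) -> float:
    """Reduce the samples (or beats) in the window [start, end) s after onset.

    For sampled channels returns the mean or max of in-window samples.  For
    the ibi channel, ``min_ibi`` returns the HR of the shortest interbeat
    interval terminating in the window; ``mean`` returns the mean HR of the
    in-window intervals.
    """
    lo = epoch.onset_time + start
    hi = epoch.onset_time + end
    if epoch.channel in BEAT_CHANNELS:
        ibis = _ibi_in_window(epoch, lo, hi)
        if len(ibis) == 0:
            raise EmptyWindowError(
                f"no beat terminates in window [{start}, {end}) s for trial "
                f"{epoch.trial_index}"
            )
        if statistic == "min_ibi":
            return ibi_to_hr(float(np.min(ibis)))
        if statistic == "mean":
            return float(np.mean(60000.0 / ibis))
        raise InvalidInputError(f"statistic {statistic!r} undefined for ibi channel")
    t = epoch.sample_times
    mask = (t >= lo) & (t < hi)
    if not np.any(mask):
        raise EmptyWindowError(
            f"window [{start}, {end}) s holds no samples for trial {epoch.trial_index}"
        )
    vals = epoch.samples[mask]
    if statistic == "mean":
        return float(np.mean(vals))
    if statistic == "max":
        return float(np.max(vals))
    raise InvalidInputError(f"statistic {statistic!r} undefined for sampled channel")


def hr_pre_stimulus(epoch: SignalEpoch, n_beats: int = 2) -> float:
    """Mean HR of the ``n_beats`` beats immediately preceding stimulus onset.

    Each pre-onset beat contributes the HR of the interbeat interval that
    terminates at it.
    """
    if epoch.channel not in BEAT_CHANNELS:
        raise InvalidInputError("hr_pre_stimulus requires the ibi channel")
    bt = epoch.beat_times
    ibis = np.diff(bt)
    term = bt[1:]
    pre = ibis[term < epoch.onset_time * 1000.0]
    if len(pre) < n_beats:
        raise EmptyWindowError(
            f"need {n_beats} pre-onset beats, found {len(pre)} (trial {epoch.trial_index})"
        )
    return float(np.mean(60000.0 / pre[-n_beats:]))


def peak_response(epoch: SignalEpoch, spec: WindowSpec) -> TrialResponse:
    """Baseline-to-peak response score for one trial.

    raw = search-window statistic minus baseline mean; the transformed score
    is the signed square root of raw.  For the cardiac channel the baseline
    is either the mean HR over the baseline window or, when
    ``spec.hr_baseline_beats`` is set, the mean HR of the beats immediately
    preceding onset.
    """
    if epoch.channel in BEAT_CHANNELS:
        if spec.hr_baseline_beats is not None:
            baseline = hr_pre_stimulus(epoch, spec.hr_baseline_beats)
        else:
            baseline = window_statistic(
                epoch, spec.baseline_start, spec.baseline_end, "mean"
            )
        stat = spec.statistic if spec.statistic != "max" else "min_ibi"
        peak = window_statistic(epoch, spec.search_start, spec.search_end, stat)
    else:
        baseline = window_statistic(epoch, spec.baseline_start, spec.baseline_end, "mean")
        peak = window_statistic(epoch, spec.search_start, spec.search_end, spec.statistic)
    raw = peak - baseline
    return TrialResponse(
        channel=epoch.channel,
        trial_index=epoch.trial_index,
        baseline_level=baseline,
        raw_response=raw,
        transformed_response=signed_sqrt(raw),
    )


def replace_aberrant(responses: Sequence[float], index: int) -> list:
    """Replace the response at 1-based ``index`` by its neighbours' average.

    Interior trials take the mean of the immediately preceding and following
    responses; an aberrant first or last trial takes its single neighbour's
    value, the two-neighbour rule being undefined at the edges.
    """
    vals = list(responses)
    n = len(vals)
    if n < 2:
        raise InvalidInputError("need at least two trials to repair an aberrant one")
    if not 1 <= index <= n:
        raise InvalidInputError(f"index {index} outside 1..{n}")
    i = index - 1
    if i == 0:
        vals[i] = vals[1]
    elif i == n - 1:
        vals[i] = vals[n - 2]
    else:
        vals[i] = 0.5 * (vals[i - 1] + vals[i + 1])
    return vals
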