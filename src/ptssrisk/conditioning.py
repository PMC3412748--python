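"""Differential fear-conditioning session scoring.

The paradigm has three phases: habituation (5 presentations each of the
to-be CS+ and CS-), acquisition (5 + 5, shock following each CS+ offset) and
extinction (10 + 10, unreinforced).  Per-trial responses are baseline-to-peak
scores: mean level over the 2 s preceding CS onset subtracted from the
channel's highest value during the 8-s CS interval.  "Conditionability"
(differential) scores subtract mean CS- responses from mean CS+ responses
within a phase; CS+-only means capture reactivity to the fear cue itself;
the unconditioned response (UCR) is scored against the 2 s preceding shock
onset with the peak searched through 6 s past shock offset.

Conditioning features are reported in raw channel units (uS / uV / bpm); only
the skin-conductance orienting response (first habituation trial) is
square-root transformed, matching the loud-tone response scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np

from .epochs import (
    SignalEpoch,
    TrialResponse,
    WindowSpec,
    hr_pre_stimulus,
    peak_response,
    signed_sqrt,
    window_statistic,
)
from .exceptions import InvalidInputError, SessionShapeError, ValidationError

PHASE_TRIALS = {"habituation": 5, "acquisition": 5, "extinction": 10}
CONDITIONING_CHANNELS = ("sc", "corrugator_emg", "ibi")

#: 2-s pre-CS baseline, peak within the 8-s CS interval.
CS_WINDOW = WindowSpec(-2.0, 0.0, 0.0, 8.0, "max")
#: Seconds past UCS offset through which the UCR peak is searched.
UCR_POST_OFFSET_S = 6.0


def score_cs_trial(epoch: SignalEpoch, window: WindowSpec = CS_WINDOW) -> TrialResponse:
    """Baseline-to-peak response for one CS trial (raw units are primary)."""
    return peak_response(epoch, window)


def differential_score(
    cs_plus_responses: Sequence[float], cs_minus_responses: Sequence[float]
) -> float:
    """mean(CS+) - mean(CS-) within one phase and channel."""
    if len(cs_plus_responses) == 0 or len(cs_minus_responses) == 0:
        raise InvalidInputError("differential score needs >= 1 trial of each type")
    return float(np.mean(cs_plus_responses) - np.mean(cs_minus_responses))


def ucr_score(epoch: SignalEpoch, post_offset_s: float = UCR_POST_OFFSET_S) -> float:
    """Unconditioned response: peak in [UCS onset, UCS offset + 6 s) minus
    the mean level over the 2 s preceding UCS onset."""
    if epoch.ucs_onset_time is None or epoch.ucs_offset_time is None:
        raise ValidationError(
            f"trial {epoch.trial_index}: UCS markers missing, cannot score UCR"
        )
    # Windows are relative to stimulus onset; shift to UCS timing.
    u0 = epoch.ucs_onset_time - epoch.onset_time
    u1 = epoch.ucs_offset_time - epoch.onset_time
    if epoch.channel == "ibi":
        baseline = window_statistic(epoch, u0 - 2.0, u0, "mean")
        peak = window_statistic(epoch, u0, u1 + post_offset_s, "min_ibi")
    else:
        baseline = window_statistic(epoch, u0 - 2.0, u0, "mean")
        peak = window_statistic(epoch, u0, u1 + post_offset_s, "max")
    return float(peak - baseline)


def orienting_response(
    habituation_sc_epochs: Sequence[SignalEpoch],
    method: str = "first",
    window: WindowSpec = CS_WINDOW,
) -> float:
    """Skin-conductance orienting response (sqrt uS).

    Defaults to the response to the first habituation-phase presentation;
    ``method='mean'`` averages over all habituation trials instead.
    """
    eps = sorted(habituation_sc_epochs, key=lambda e: e.trial_index)
    if not eps:
        raise SessionShapeError("no habituation-phase SC epochs")
    if method == "first":
        raw = score_cs_trial(eps[0], window).raw_response
    elif method == "mean":
        raw = float(np.mean([score_cs_trial(e, window).raw_response for e in eps]))
    else:
        raise InvalidInputError(f"unknown orienting method {method!r}")
    return float(signed_sqrt(raw))


@dataclass(frozen=True)
class ConditioningFeatures:
    """Table-style conditioning feature block (raw channel units).

    HR extinction scores are computed and kept on the object but excluded
    from :meth:`to_feature_dict`, which mirrors the predictor set used in
    the risk analysis (extinction rows list SC and EMG only).
    """

    sc_orienting: float  # sqrt(uS)
    sc_diff_acq: float
    emg_diff_acq: float
    hr_diff_acq: float
    sc_diff_ext: float
    emg_diff_ext: float
    hr_diff_ext: float  # internal
    sc_csplus_acq: float
    emg_csplus_acq: float
    hr_csplus_acq: float
    sc_csplus_ext: float
    emg_csplus_ext: float
    hr_csplus_ext: float  # internal
    ucr_sc: float
    ucr_emg: float
    ucr_hr: float

    def to_feature_dict(self) -> Dict[str, float]:
        return {
            "sc_orienting": self.sc_orienting,
            "sc_diff_acq": self.sc_diff_acq,
            "emg_diff_acq": self.emg_diff_acq,
            "hr_diff_acq": self.hr_diff_acq,
            "sc_diff_ext": self.sc_diff_ext,
            "emg_diff_ext": self.emg_diff_ext,
            "sc_csplus_acq": self.sc_csplus_acq,
            "emg_csplus_acq": self.emg_csplus_acq,
            "hr_csplus_acq": self.hr_csplus_acq,
            "sc_csplus_ext": self.sc_csplus_ext,
            "emg_csplus_ext": self.emg_csplus_ext,
        }


def _group(epochs: Iterable[SignalEpoch]):
    by_key: Dict[tuple, List[SignalEpoch]] = {}
    for ep in epochs:
        if ep.paradigm != "conditioning":
            raise SessionShapeError(f"epoch for trial {ep.trial_index} is not conditioning")
        by_key.setdefault((ep.channel, ep.phase, ep.stimulus), []).append(ep)
    for eps in by_key.values():
        eps.sort(key=lambda e: e.trial_index)
    return by_key


def score_conditioning_session(
    epochs: Iterable[SignalEpoch],
    window: WindowSpec = CS_WINDOW,
    orienting_method: str = "first",
) -> ConditioningFeatures:
    """Reduce a 5+5 / 5+5 / 10+10 conditioning session to its feature block."""
    by_key = _group(epochs)
    for ch in CONDITIONING_CHANNELS:
        for phase, n in PHASE_TRIALS.items():
            for stim in ("cs_plus", "cs_minus"):
                eps = by_key.get((ch, phase, stim), [])
                if len(eps) != n:
                    raise SessionShapeError(
                        f"channel {ch!r} phase {phase!r} {stim}: "
                        f"expected {n} trials, got {len(eps)}"
                    )

    def raw_scores(ch, phase, stim):
        return [score_cs_trial(e, window).raw_response for e in by_key[(ch, phase, stim)]]

    def diff(ch, phase):
        return differential_score(raw_scores(ch, phase, "cs_plus"), raw_scores(ch, phase, "cs_minus"))

    def csplus_mean(ch, phase):
        return float(np.mean(raw_scores(ch, phase, "cs_plus")))

    def ucr(ch):
        eps = by_key[(ch, "acquisition", "cs_plus")]
        return float(np.mean([ucr_score(e) for e in eps]))

    return ConditioningFeatures(
        sc_orienting=orienting_response(
            by_key[("sc", "habituation", "cs_plus")]
            + by_key[("sc", "habituation", "cs_minus")],
            method=orienting_method,
            window=window,
        ),
        sc_diff_acq=diff("sc", "acquisition"),
        emg_diff_acq=diff("corrugator_emg", "acquisition"),
        hr_diff_acq=diff("ibi", "acquisition"),
        sc_diff_ext=diff("sc", "extinction"),
        emg_diff_ext=diff("corrugator_emg", "extinction"),
        hr_diff_ext=diff("ibi", "extinction"),
        sc_csplus_acq=csplus_mean("sc", "acquisition"),
        emg_csplus_acq=csplus_mean("corrugator_emg", "acquisition"),
        hr_csplus_acq=csplus_mean("ibi", "acquisition"),
        sc_csplus_ext=csplus_mean("sc", "extinction"),
        emg_csplus_ext=csplus_mean("corrugator_emg", "extinction"),
        hr_csplus_ext=csplus_mean("ibi", "extinction"),
        ucr_sc=ucr("sc"),
        ucr_emg=ucr("corrugator_emg"),
        ucr_hr=ucr("ibi"),
    )
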