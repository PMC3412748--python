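"""Synthetic raw physiological sessions with known ground-truth traits.

The generator exists so every scoring stage can be exercised end to end:
each subject's latent traits (tonic levels, phasic response amplitudes,
habituation decay, CS+/CS- conditioning amplitudes, UCR and imagery
reactivity) are injected into plausible signal shapes whose peaks fall
inside the corresponding scoring windows, so that baseline-to-peak scoring
recovers the planted amplitudes as noise goes to zero.

Signal shapes: skin-conductance phasic responses are bi-exponential kernels
(~1 s rise, ~3 s decay) on a slowly drifting tonic level; integrated-EMG
responses are short half-sine bursts inside the scoring windows; heart-rate
responses are plateau-shaped accelerations encoded as transient interbeat-
interval shortening.  Measurement noise is an additive Gaussian AR(1)
(Ornstein-Uhlenbeck) process: slow tonic wander rather than sample-level
white noise, since white noise would bias max-based scores upward while the
recorded channels (integrated EMG, SC level) are band-limited.

All randomness flows from the supplied seed or generator; the same seed
yields bitwise-identical sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Union

import numpy as np

from .epochs import SignalEpoch
from .exceptions import InvalidInputError

DEFAULT_FS = 100.0  # Hz; desk-scale default, any rate is supported


def _kernel_biexp(t: np.ndarray, t0: float, rise: float = 0.4, decay: float = 1.2) -> np.ndarray:
    """Difference-of-exponentials kernel, zero before t0, grid-normalized to 1."""
    s = np.clip(t - t0, 0.0, None)
    k = np.exp(-s / decay) - np.exp(-s / rise)
    k[t < t0] = 0.0
    m = k.max()
    return k / m if m > 0 else k


def _kernel_burst(t: np.ndarray, t0: float, width: float) -> np.ndarray:
    """Half-sine burst on [t0, t0 + width), grid-normalized to 1."""
    s = (t - t0) / width
    k = np.where((s >= 0) & (s < 1), np.sin(np.pi * np.clip(s, 0, 1)), 0.0)
    m = k.max()
    return k / m if m > 0 else k


def _plateau(t: np.ndarray, up0: float, up1: float, down0: float, down1: float) -> np.ndarray:
    """Trapezoid: ramps up over [up0, up1], holds 1, ramps down over [down0, down1]."""
    k = np.zeros_like(t)
    k[(t >= up1) & (t <= down0)] = 1.0
    ramp = (t > up0) & (t < up1)
    k[ramp] = (t[ramp] - up0) / (up1 - up0)
    fall = (t > down0) & (t < down1)
    k[fall] = 1.0 - (t[fall] - down0) / (down1 - down0)
    return k


def _ou_noise(rng, n: int, dt: float, sd: float, tau: float = 30.0) -> np.ndarray:
    """Stationary Gaussian AR(1) (OU) noise with sd ``sd`` and time scale ``tau``."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    rho = np.exp(-dt / tau)
    x = np.empty(n)
    x[0] = rng.standard_normal()
    innov = rng.standard_normal(n - 1) * np.sqrt(1 - rho**2)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + innov[i - 1]
    return sd * x


@dataclass
class SubjectTraits:
    """Latent per-subject parameters realized by the generated sessions.

    Amplitudes are in channel units (uS, uV, bpm); ``habituation_decay`` is
    the per-trial geometric factor applied to loud-tone startle amplitudes;
    ``conditioning_amp[channel][phase][stimulus]`` are CS-response
    amplitudes; ``noise`` maps channel name to the additive noise SD.
    """

    sc_tonic: float = 7.2  # uS
    hr_tonic: float = 71.6  # bpm
    emg_tonic: float = 0.5  # uV, integrated-EMG resting level
    startle_amp: Dict[str, float] = field(
        default_factory=lambda: {"sc": 0.6, "eyeblink_emg": 8.0, "hr": 5.0}
    )
    # 0.78/trial puts SC trials-to-criterion near 10 and the log-trial
    # habituation slope in the -0.3..-0.4 range typical of healthy cohorts
    habituation_decay: float = 0.78
    conditioning_amp: Dict[str, Dict[str, Dict[str, float]]] = field(
        default_factory=lambda: {
            "sc": {
                "habituation": {"cs_plus": 0.36, "cs_minus": 0.36},
                "acquisition": {"cs_plus": 0.6, "cs_minus": 0.4},
                "extinction": {"cs_plus": 0.2, "cs_minus": 0.3},
            },
            "corrugator_emg": {
                "habituation": {"cs_plus": 2.0, "cs_minus": 2.0},
                "acquisition": {"cs_plus": 2.5, "cs_minus": 2.3},
                "extinction": {"cs_plus": 3.1, "cs_minus": 3.8},
            },
            "hr": {
                "habituation": {"cs_plus": 3.0, "cs_minus": 3.0},
                "acquisition": {"cs_plus": 5.8, "cs_minus": 4.8},
                "extinction": {"cs_plus": 2.0, "cs_minus": 1.5},
            },
        }
    )
    ucr_amp: Dict[str, float] = field(
        default_factory=lambda: {"sc": 1.2, "corrugator_emg": 8.0, "hr": 15.0}
    )
    imagery_delta: Dict[str, float] = field(
        default_factory=lambda: {
            "hr": 2.0,
            "sc": 0.3,
            "frontalis_emg": 1.5,
            "corrugator_emg": 1.0,
        }
    )
    noise: Dict[str, float] = field(
        default_factory=lambda: {
            "sc": 0.03,
            "eyeblink_emg": 0.3,
            "corrugator_emg": 0.15,
            "frontalis_emg": 0.1,
            "hr": 0.5,
        }
    )
    # correlation time of the tonic wander (s); long relative to the scoring
    # windows, so baseline-to-peak scores stay unbiased (short correlation
    # times reintroduce the positive max-selection bias of peak scoring)
    noise_tau: float = 60.0

    def __post_init__(self):
        for ch, sd in self.noise.items():
            if sd < 0:
                raise InvalidInputError(f"noise SD for {ch!r} must be >= 0")
        if not 0 < self.habituation_decay <= 1:
            raise InvalidInputError("habituation_decay must lie in (0, 1]")

    def scaled_noise(self, factor: float) -> "SubjectTraits":
        return replace(self, noise={k: v * factor for k, v in self.noise.items()})


def _ibi_epoch_from_hr(rng, hr_of_t, span: float, noise_sd: float, tau: float = 30.0):
    """Beat times (ms) over [0, span] s for an instantaneous HR profile.

    Beats are laid down sequentially: the next interval is 60000 / HR at the
    current beat, jittered by the (slow) HR noise process sampled per beat.
    """
    beats = [0.0]
    t = 0.0
    # slow HR wander, one value per prospective beat (AR(1) across beats)
    rho = np.exp(-0.85 / tau)
    z = rng.standard_normal()
    while True:
        hr = hr_of_t(t) + noise_sd * z
        hr = max(hr, 20.0)
        ibi_s = 60.0 / hr
        t = t + ibi_s
        if t > span:
            break
        beats.append(t)
        z = rho * z + np.sqrt(1 - rho**2) * rng.standard_normal()
    return np.array(beats) * 1000.0


def _sampled_epoch(values, fs, **meta) -> SignalEpoch:
    return SignalEpoch(samples=np.asarray(values), sampling_rate=fs, **meta)


def generate_loud_tone_session(
    traits: SubjectTraits,
    rng: np.random.Generator,
    subject_id: str = "SYN",
    fs: float = DEFAULT_FS,
) -> List[SignalEpoch]:
    """15-tone startle session: eyeblink EMG, SC and IBI epochs per trial.

    Epochs span [-2, +5] s around tone onset.  Startle amplitudes decay
    geometrically across trials (trait ``habituation_decay``); peaks fall
    inside the scoring windows (eyeblink 40-200 ms, SC/HR 1-4 s).
    """
    pre, post = 2.0, 5.0
    n_samp = int(round((pre + post) * fs))
    t = np.arange(n_samp) / fs - pre  # s relative to onset
    epochs: List[SignalEpoch] = []
    for trial in range(1, 16):
        amp = traits.habituation_decay ** (trial - 1)
        meta = dict(
            subject_id=subject_id,
            paradigm="loud_tones",
            trial_index=trial,
            stimulus="tone",
            phase=None,
            onset_time=pre,
            offset_time=pre + 0.5,
        )
        sc = (
            traits.sc_tonic
            + traits.startle_amp["sc"] * amp * _kernel_biexp(t, 1.0)
            + _ou_noise(rng, n_samp, 1 / fs, traits.noise["sc"], traits.noise_tau)
        )
        epochs.append(_sampled_epoch(sc, fs, **{**meta, "channel": "sc"}))
        emg = (
            traits.emg_tonic
            + traits.startle_amp["eyeblink_emg"] * amp * _kernel_burst(t, 0.05, 0.1)
            + _ou_noise(rng, n_samp, 1 / fs, traits.noise["eyeblink_emg"], traits.noise_tau)
        )
        epochs.append(_sampled_epoch(emg, fs, **{**meta, "channel": "eyeblink_emg"}))
        hr_kernel = _plateau(t, 1.0, 1.5, 3.0, 4.0)
        hr_amp = traits.startle_amp["hr"] * amp

        def hr_of_t(tt, _k=hr_kernel, _a=hr_amp):
            # tt is time from epoch start; the kernel grid is onset-relative
            idx = min(int(tt * fs), n_samp - 1)
            return traits.hr_tonic + _a * _k[idx]

        beats = _ibi_epoch_from_hr(rng, hr_of_t, pre + post, traits.noise["hr"], traits.noise_tau)
        epochs.append(
            SignalEpoch(beat_times=beats, **{**meta, "channel": "ibi"})
        )
    return epochs


_CS_ORDER = {
    # pseudo-random within phase: never more than two consecutive same type
    "habituation": ["cs_plus", "cs_minus", "cs_minus", "cs_plus", "cs_plus",
                    "cs_minus", "cs_plus", "cs_minus", "cs_minus", "cs_plus"],
    "acquisition": ["cs_minus", "cs_plus", "cs_plus", "cs_minus", "cs_plus",
                    "cs_minus", "cs_minus", "cs_plus", "cs_plus", "cs_minus"],
    "extinction": ["cs_plus", "cs_minus", "cs_plus", "cs_plus", "cs_minus",
                   "cs_minus", "cs_plus", "cs_minus", "cs_plus", "cs_minus",
                   "cs_plus", "cs_plus", "cs_minus", "cs_plus", "cs_minus",
                   "cs_minus", "cs_plus", "cs_minus", "cs_minus", "cs_plus"],
}


def generate_conditioning_session(
    traits: SubjectTraits,
    rng: np.random.Generator,
    subject_id: str = "SYN",
    fs: float = DEFAULT_FS,
) -> List[SignalEpoch]:
    """Differential-conditioning session (5+5 / 5+5 / 10+10), 8-s CS.

    Epochs span [-4, +15] s around CS onset; acquisition CS+ trials carry a
    0.5-s shock at CS offset and an unconditioned response whose peak lies
    within the [UCS onset, offset + 6 s) scoring window.  Scored features do
    not depend on the intertrial interval (legal range 15-25 s), so epochs
    are generated independently per trial.
    """
    pre, post = 4.0, 15.0
    n_samp = int(round((pre + post) * fs))
    t = np.arange(n_samp) / fs - pre
    epochs: List[SignalEpoch] = []
    trial_counter: Dict[str, int] = {"cs_plus": 0, "cs_minus": 0}
    trial_index = 0
    for phase in ("habituation", "acquisition", "extinction"):
        for stim in _CS_ORDER[phase]:
            trial_index += 1
            trial_counter[stim] += 1
            shock = phase == "acquisition" and stim == "cs_plus"
            meta = dict(
                subject_id=subject_id,
                paradigm="conditioning",
                trial_index=trial_index,
                stimulus=stim,
                phase=phase,
                onset_time=pre,
                offset_time=pre + 8.0,
                ucs_onset_time=pre + 8.0 if shock else None,
                ucs_offset_time=pre + 8.5 if shock else None,
            )
            sc_sig = traits.sc_tonic + traits.conditioning_amp["sc"][phase][stim] * _kernel_biexp(t, 0.5)
            emg_sig = traits.emg_tonic + traits.conditioning_amp["corrugator_emg"][phase][stim] * _kernel_burst(t, 0.5, 1.5)
            hr_kernel = _plateau(t, 0.5, 1.0, 4.5, 5.8)
            hr_amp = traits.conditioning_amp["hr"][phase][stim]
            ucr_hr_kernel = np.zeros_like(t)
            if shock:
                sc_sig = sc_sig + traits.ucr_amp["sc"] * _kernel_biexp(t, 8.7)
                emg_sig = emg_sig + traits.ucr_amp["corrugator_emg"] * _kernel_burst(t, 8.6, 0.6)
                ucr_hr_kernel = _plateau(t, 8.8, 9.3, 11.5, 13.0)
            sc_sig = sc_sig + _ou_noise(rng, n_samp, 1 / fs, traits.noise["sc"], traits.noise_tau)
            emg_sig = emg_sig + _ou_noise(rng, n_samp, 1 / fs, traits.noise["corrugator_emg"], traits.noise_tau)
            epochs.append(_sampled_epoch(sc_sig, fs, **{**meta, "channel": "sc"}))
            epochs.append(_sampled_epoch(emg_sig, fs, **{**meta, "channel": "corrugator_emg"}))

            def hr_of_t(tt, _k=hr_kernel, _u=ucr_hr_kernel, _a=hr_amp):
                idx = min(int(tt * fs), n_samp - 1)
                return traits.hr_tonic + _a * _k[idx] + traits.ucr_amp["hr"] * _u[idx]

            beats = _ibi_epoch_from_hr(rng, hr_of_t, pre + post, traits.noise["hr"], traits.noise_tau)
            epochs.append(SignalEpoch(beat_times=beats, **{**meta, "channel": "ibi"}))
    return epochs


def generate_imagery_session(
    traits: SubjectTraits,
    rng: np.random.Generator,
    subject_id: str = "SYN",
    fs: float = DEFAULT_FS,
    period_s: float = 30.0,
) -> List[SignalEpoch]:
    """Two trauma scripts, each a 30-s baseline and 30-s imagery period.

    Imagery periods sit at the baseline level plus the trait reactivity
    delta per channel; mean-minus-mean scoring recovers the deltas.
    """
    n_samp = int(round(period_s * fs))
    epochs: List[SignalEpoch] = []
    tonic = {
        "sc": traits.sc_tonic,
        "frontalis_emg": traits.emg_tonic,
        "corrugator_emg": traits.emg_tonic,
    }
    for script in (1, 2):
        for phase in ("baseline", "imagery"):
            bump = 1.0 if phase == "imagery" else 0.0
            meta = dict(
                subject_id=subject_id,
                paradigm="imagery",
                trial_index=script,
                stimulus="script_trauma",
                phase=phase,
                onset_time=0.0,
                offset_time=period_s,
            )
            for ch, level in tonic.items():
                sig = (
                    level
                    + bump * traits.imagery_delta[ch]
                    + _ou_noise(rng, n_samp, 1 / fs, traits.noise[ch], traits.noise_tau)
                )
                epochs.append(_sampled_epoch(sig, fs, **{**meta, "channel": ch}))
            hr_level = traits.hr_tonic + bump * traits.imagery_delta["hr"]
            beats = _ibi_epoch_from_hr(
                rng, lambda tt: hr_level, period_s, traits.noise["hr"], traits.noise_tau
            )
            epochs.append(SignalEpoch(beat_times=beats, **{**meta, "channel": "ibi"}))
    return epochs


def generate_session(
    traits: SubjectTraits,
    paradigm: str,
    seed: Union[int, np.random.Generator],
    subject_id: str = "SYN",
    fs: float = DEFAULT_FS,
) -> List[SignalEpoch]:
    """Generate one session of the requested paradigm from subject traits."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if paradigm == "loud_tones":
        return generate_loud_tone_session(traits, rng, subject_id, fs)
    if paradigm == "conditioning":
        return generate_conditioning_session(traits, rng, subject_id, fs)
    if paradigm == "imagery":
        return generate_imagery_session(traits, rng, subject_id, fs)
    raise InvalidInputError(f"unknown paradigm {paradigm!r}")


def generate_calibration_cohort(
    n_per_class: int = 60,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
):
    """Labelled (HR, SC, frontalis EMG) imagery-response triplets for
    discriminant calibration.

    The synthetic PTSD-like class responds more strongly on every channel;
    the class structure is chosen so that a threshold-0.5 classification is
    specific but not sensitive (misses a substantial share of the PTSD-like
    class), mirroring the operating character of the published function.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    cov = np.diag([9.0, 0.04, 1.0])  # bpm^2, uS^2, uV^2
    mu0 = np.array([0.5, 0.05, 0.2])
    mu1 = np.array([3.5, 0.25, 1.2])
    L = np.linalg.cholesky(cov)
    X0 = mu0 + rng.standard_normal((n_per_class, 3)) @ L.T
    # PTSD-like class: a responder majority and a physiologic non-responder
    # minority near the control centroid -> sensitivity < specificity at 0.5.
    n_nonresp = int(round(0.35 * n_per_class))
    X1a = mu1 + rng.standard_normal((n_per_class - n_nonresp, 3)) @ L.T
    X1b = mu0 + 0.3 * (mu1 - mu0) + rng.standard_normal((n_nonresp, 3)) @ L.T
    X = np.vstack([X0, X1a, X1b])
    y = np.array([0] * n_per_class + [1] * n_per_class)
    return X, y
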