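"""Script-driven imagery scoring and the physiologic PTSS posterior index.

During imagery of a personalized trauma narrative, each channel's response
score is the mean level during the imagery period minus the mean level
during the immediately preceding baseline period; scores are averaged over
the two trauma scripts.  A two-group linear discriminant over the HR, SC and
lateral-frontalis-EMG responses (shared-covariance Gaussian classes) then
yields a single posterior probability of belonging to the PTSD-like class --
the study's objective physiologic outcome measure.

The published discriminant's coefficients are not available, so the model is
either loaded from a JSON coefficients file (for exact reproduction when
known) or trained on a labelled calibration sample, e.g. the synthetic
calibration cohort shipped with the generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import expit

from .epochs import SignalEpoch
from .exceptions import (
    DegenerateCalibrationError,
    InvalidInputError,
    SessionShapeError,
    ValidationError,
)

#: Channels entering the discriminant, in weight order.
DISCRIMINANT_CHANNELS = ("hr", "sc", "frontalis_emg")

N_TRAUMA_SCRIPTS = 2


def period_mean(epoch: SignalEpoch) -> float:
    """Mean level over a whole baseline/imagery period epoch.

    Sampled channels average their samples; the cardiac channel averages the
    HR of all interbeat intervals terminating within the period.
    """
    if epoch.channel == "ibi":
        ibis = np.diff(epoch.beat_times)
        if len(ibis) == 0:
            raise ValidationError("imagery period holds no complete interbeat interval")
        return float(np.mean(60000.0 / ibis))
    if epoch.samples is None or len(epoch.samples) == 0:
        raise ValidationError("imagery period holds no samples")
    return float(np.mean(epoch.samples))


def imagery_response_score(baseline_epoch: SignalEpoch, imagery_epoch: SignalEpoch) -> float:
    """Imagery-period mean minus preceding-baseline mean, one script/channel."""
    if baseline_epoch.channel != imagery_epoch.channel:
        raise ValidationError("baseline and imagery epochs must share a channel")
    return period_mean(imagery_epoch) - period_mean(baseline_epoch)


@dataclass(frozen=True)
class ImageryFeatures:
    hr_response: float  # bpm
    sc_response: float  # uS
    frontalis_response: float  # uV
    corrugator_response: float  # uV (computed; not used by the discriminant)
    posterior_probability: float

    def to_feature_dict(self) -> Dict[str, float]:
        return {
            "imagery_hr_response": self.hr_response,
            "imagery_sc_response": self.sc_response,
            "imagery_frontalis_response": self.frontalis_response,
            "imagery_corrugator_response": self.corrugator_response,
            "posterior_probability": self.posterior_probability,
        }


@dataclass
class DiscriminantModel:
    """Two-group Fisher linear discriminant with pooled covariance.

    ``means`` holds the class centroids (row 0: non-PTSD, row 1: PTSD) over
    (HR, SC, frontalis EMG) responses; ``pooled_cov`` the within-class
    covariance; ``priors`` the class prior probabilities.  The posterior of
    the PTSD class under the shared-covariance Gaussian model is
    ``sigmoid(w.x + b)`` with ``w = Sigma^-1 (mu1 - mu0)``.
    """

    means: np.ndarray  # (2, 3)
    pooled_cov: np.ndarray  # (3, 3)
    priors: np.ndarray = field(default_factory=lambda: np.array([0.5, 0.5]))

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float)
        self.pooled_cov = np.asarray(self.pooled_cov, dtype=float)
        self.priors = np.asarray(self.priors, dtype=float)
        if self.means.shape[0] != 2:
            raise ValidationError("means must stack exactly two class centroids")
        if np.any(self.priors <= 0) or abs(self.priors.sum() - 1.0) > 1e-8:
            raise ValidationError("priors must be in (0,1) and sum to 1")
        if not np.allclose(self.pooled_cov, self.pooled_cov.T):
            raise ValidationError("pooled covariance must be symmetric")
        try:
            np.linalg.cholesky(self.pooled_cov)
        except np.linalg.LinAlgError as exc:
            raise DegenerateCalibrationError(
                "pooled covariance is not positive definite"
            ) from exc

    @property
    def weights(self) -> np.ndarray:
        return np.linalg.solve(self.pooled_cov, self.means[1] - self.means[0])

    @property
    def threshold(self) -> float:
        """Intercept of the posterior logit (includes the prior log-odds)."""
        w = self.weights
        return float(-0.5 * w @ (self.means[0] + self.means[1]) + np.log(self.priors[1] / self.priors[0]))

    def to_json(self) -> str:
        return json.dumps(
            {
                "channels": list(DISCRIMINANT_CHANNELS),
                "means": self.means.tolist(),
                "pooled_cov": self.pooled_cov.tolist(),
                "priors": self.priors.tolist(),
                "weights": self.weights.tolist(),
                "threshold": self.threshold,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "DiscriminantModel":
        d = json.loads(text)
        return cls(
            means=np.array(d["means"]),
            pooled_cov=np.array(d["pooled_cov"]),
            priors=np.array(d["priors"]),
        )


def train_discriminant(
    triplets: np.ndarray,
    labels: Sequence[int],
    priors: Optional[Sequence[float]] = None,
) -> DiscriminantModel:
    """Fit the two-group discriminant on labelled (HR, SC, frontalis) triplets.

    Pooled within-class covariance; priors default to the calibration class
    proportions (configurable, e.g. to equal priors).
    """
    X = np.asarray(triplets, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2 or len(X) != len(y):
        raise InvalidInputError("triplets must be (n, k) with one label per row")
    n0, n1 = np.sum(y == 0), np.sum(y == 1)
    if n0 < 2 or n1 < 2:
        raise InvalidInputError("need >= 2 calibration examples per class")
    X0, X1 = X[y == 0], X[y == 1]
    mu = np.vstack([X0.mean(axis=0), X1.mean(axis=0)])
    pooled = ((n0 - 1) * np.cov(X0, rowvar=False) + (n1 - 1) * np.cov(X1, rowvar=False)) / (
        n0 + n1 - 2
    )
    pooled = np.atleast_2d(pooled)
    if priors is None:
        priors = np.array([n0, n1]) / (n0 + n1)
    return DiscriminantModel(means=mu, pooled_cov=pooled, priors=np.asarray(priors, float))


def posterior_probability(model: DiscriminantModel, triplet: Sequence[float]) -> float:
    """Bayes posterior of the PTSD class for one response triplet."""
    x = np.asarray(triplet, dtype=float)
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("triplet must be finite")
    return float(expit(model.weights @ x + model.threshold))


def score_imagery_session(
    epochs: Iterable[SignalEpoch], model: DiscriminantModel
) -> ImageryFeatures:
    """Score a two-trauma-script imagery session and apply the discriminant.

    Expects, per script (``trial_index`` 1 and 2) and per channel, one
    baseline-phase epoch and one imagery-phase epoch.
    """
    periods: Dict[tuple, SignalEpoch] = {}
    for ep in epochs:
        if ep.paradigm != "imagery":
            raise SessionShapeError("non-imagery epoch in imagery session")
        periods[(ep.trial_index, ep.channel, ep.phase)] = ep

    def script_score(script: int, channel: str) -> float:
        try:
            base = periods[(script, channel, "baseline")]
            imag = periods[(script, channel, "imagery")]
        except KeyError as exc:
            raise SessionShapeError(
                f"script {script} channel {channel!r}: missing {exc.args[0][2]} period"
            ) from exc
        return imagery_response_score(base, imag)

    def mean_score(channel: str) -> float:
        return float(
            np.mean([script_score(s, channel) for s in range(1, N_TRAUMA_SCRIPTS + 1)])
        )

    hr = mean_score("ibi")
    sc = mean_score("sc")
    frontalis = mean_score("frontalis_emg")
    corrugator = mean_score("corrugator_emg")
    post = posterior_probability(model, (hr, sc, frontalis))
    return ImageryFeatures(
        hr_response=hr,
        sc_response=sc,
        frontalis_response=frontalis,
        corrugator_response=corrugator,
        posterior_probability=post,
    )
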