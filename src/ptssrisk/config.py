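"""Pipeline configuration: window constants, thresholds and analysis settings.

Defaults are the study's data-reduction constants (eyeblink peak 40-200 ms,
SC/HR peak 1-4 s, 2-s CS baseline, 8-s CS interval, UCR search through 6 s
past shock offset, non-response criteria .05 uS / .30 uV) and the analysis
settings (upper-tertile dichotomization, screening alpha 0.20, stepwise
entry/stay p = 0.15).  Every default applied at run time is echoed to the
pipeline log for auditability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from .epochs import WindowSpec
from .exceptions import ValidationError
from .tones import EMG_CRITERION_UV, SC_CRITERION_US, TONE_WINDOWS


@dataclass
class AnalysisSettings:
    outcomes: List[str] = field(
        default_factory=lambda: ["ies_r_total", "posterior_probability"]
    )
    scheme: str = "T_upper_vs_rest"
    alpha_screen: float = 0.20
    p_enter: float = 0.15
    p_remove: float = 0.15
    covariates: List[str] = field(
        default_factory=lambda: ["time_since_trauma", "severity_rating"]
    )


@dataclass
class PipelineConfig:
    n_subjects: int = 99
    seed: int = 0
    missing_rate: float = 0.05
    prevalence: float = 1 / 3
    analysis: AnalysisSettings = field(default_factory=AnalysisSettings)
    tone_windows: Dict[str, WindowSpec] = field(default_factory=lambda: dict(TONE_WINDOWS))
    cs_baseline_s: float = 2.0
    cs_interval_s: float = 8.0
    ucr_post_offset_s: float = 6.0
    sc_criterion_us: float = SC_CRITERION_US
    emg_criterion_uv: float = EMG_CRITERION_UV
    imagery_period_s: float = 30.0
    discriminant_source: str = "train-on-calibration"  # or path to a JSON file
    discriminant_priors: Optional[List[float]] = None  # None -> calibration proportions

    def __post_init__(self):
        if self.sc_criterion_us <= 0 or self.emg_criterion_uv <= 0:
            raise ValidationError("non-response criteria must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValidationError("missing_rate must lie in [0, 1)")

    def defaults_log(self) -> List[str]:
        """Human-readable record of every configurable constant in effect."""
        lines = [
            f"dichotomization scheme = {self.analysis.scheme} (ties at cut -> low group)",
            f"screening alpha = {self.analysis.alpha_screen} (Welch t, uncorrected)",
            f"stepwise p_enter = {self.analysis.p_enter}, p_remove = {self.analysis.p_remove}",
            f"covariates for adjusted refit = {self.analysis.covariates}",
            f"CS baseline {self.cs_baseline_s} s, CS interval {self.cs_interval_s} s, "
            f"UCR search through {self.ucr_post_offset_s} s post offset",
            f"non-response criteria: SC < {self.sc_criterion_us} uS, "
            f"EMG < {self.emg_criterion_uv} uV",
            f"imagery period = {self.imagery_period_s} s per script",
            f"discriminant source = {self.discriminant_source}, priors = "
            f"{self.discriminant_priors or 'calibration proportions'}",
            "habituation slope: trials 2-15, natural-log trial number",
            "orienting response: first habituation-phase trial, sqrt scale",
            f"target high-group prevalence = {self.prevalence:.4f}",
            f"MCAR predictor missing rate = {self.missing_rate}",
            f"seed = {self.seed}",
        ]
        for ch, w in self.tone_windows.items():
            lines.append(
                f"tone window {ch}: baseline [{w.baseline_start}, {w.baseline_end}) s, "
                f"search [{w.search_start}, {w.search_end}) s, statistic {w.statistic}"
            )
        return lines

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["tone_windows"] = {
            ch: asdict(w) if not isinstance(w, dict) else w
            for ch, w in d["tone_windows"].items()
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "analysis" in d and isinstance(d["analysis"], dict):
            d["analysis"] = AnalysisSettings(**d["analysis"])
        if "tone_windows" in d:
            d["tone_windows"] = {
                ch: WindowSpec(**w) if isinstance(w, dict) else w
                for ch, w in d["tone_windows"].items()
            }
        return cls(**d)
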