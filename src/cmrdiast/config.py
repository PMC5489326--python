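"""Analysis configuration: every tunable convention in one place."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

from .echo_grading import GradingThresholds
from .errors import ParameterError

DT_FIT_MODES = ("least_squares", "two_point")
EE_MODES = ("mean_of_ratios", "e_over_mean_eprime")


@dataclass
class AnalysisConfig:
    """Pipeline-wide settings.

    smoothing
        Apply a cyclic 3-point moving average to filling rates before peak
        detection (off by default — smoothing shifts peaks on 30-frame
        curves and the default must be transparent).
    dt_fit_mode
        Deceleration-time downslope fit: ``least_squares`` (default) or
        ``two_point`` chord.
    eprime_window_fraction
        The early-diastolic E′ window runs from ES to
        ES + fraction·(RR − ES), truncated at the detected A-wave onset.
    e_over_eprime_mode
        How the mean CMR E/E′ is formed: ``mean_of_ratios`` (default) or
        ``e_over_mean_eprime``.
    echo_ratio_mode
        How the mean echo E/e′ used in grading is formed when not given
        explicitly: ``e_over_mean_eprime`` (default) or ``mean_of_ratios``.
    """

    smoothing: bool = False
    dt_fit_mode: str = "least_squares"
    eprime_window_fraction: float = 0.6
    e_over_eprime_mode: str = "mean_of_ratios"
    echo_ratio_mode: str = "e_over_mean_eprime"
    thresholds: GradingThresholds = field(default_factory=GradingThresholds)
    fisher_table_limit: int = 2_000_000
    seed: int | None = None

    def __post_init__(self):
        if self.dt_fit_mode not in DT_FIT_MODES:
            raise ParameterError(f"dt_fit_mode must be one of {DT_FIT_MODES}")
        if self.e_over_eprime_mode not in EE_MODES:
            raise ParameterError(f"e_over_eprime_mode must be one of {EE_MODES}")
        if self.echo_ratio_mode not in EE_MODES:
            raise ParameterError(f"echo_ratio_mode must be one of {EE_MODES}")
        if not 0 < self.eprime_window_fraction <= 1:
            raise ParameterError("eprime_window_fraction must be in (0, 1]")
        t = self.thresholds
        if isinstance(t, dict):
            t = GradingThresholds(**t)
            self.thresholds = t
        if min(t.septal_eprime, t.lateral_eprime, t.mean_ratio,
               t.lvmi_male, t.lvmi_female) <= 0:
            raise ParameterError("grading thresholds must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def config_hash(self) -> str:
        """Short provenance hash of the configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
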