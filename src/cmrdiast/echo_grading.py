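"""Echocardiographic measures and ASE diastolic-dysfunction grading.

The echo grade is the reference standard against which the volumetric CMR
indices are evaluated.  Three ASE tissue-Doppler criteria are used:

1. septal e′ < 8 cm/s
2. lateral e′ < 10 cm/s
3. average-E over average-e′ ratio ≥ 10

All three present → **type II (reduced)**.  Exactly two, or one plus LV
hypertrophy → **type I (impaired)**.  Otherwise **normal**.  Restrictive
physiology (a type III) is out of scope for this population.

LV hypertrophy: LV mass index > 115 g/m² (men) or > 95 g/m² (women),
strict inequalities as recommended.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

from .errors import IncompleteMeasuresError, ParameterError

__all__ = [
    "EchoDiastolicMeasures",
    "GradeCriteria",
    "DysfunctionGrade",
    "SubjectRecord",
    "GradingThresholds",
    "lv_hypertrophy",
    "ase_criteria",
    "grade_diastolic_function",
    "heart_rate_compatible",
    "HEART_RATE_MAX_DIFF",
]

HEART_RATE_MAX_DIFF = 15.0  # beats/min between modalities (exclusion rule)


class DysfunctionGrade(enum.Enum):
    NORMAL = "normal"
    TYPE_I = "type I (impaired)"
    TYPE_II = "type II (reduced)"

    @property
    def severity(self) -> int:
        return {"normal": 0, "type I (impaired)": 1, "type II (reduced)": 2}[self.value]


@dataclass
class EchoDiastolicMeasures:
    """Doppler / tissue-Doppler measures for one subject.

    Velocities are cm/s, times ms.  ``E_over_e_mean`` may be given
    directly (as read from the report) or derived from E and mean e′.
    """

    E: Optional[float] = None
    A: Optional[float] = None
    DT: Optional[float] = None
    e_prime_septal: Optional[float] = None
    e_prime_lateral: Optional[float] = None
    e_prime_mean: Optional[float] = None
    E_over_e_septal: Optional[float] = None
    E_over_e_lateral: Optional[float] = None
    E_over_e_mean: Optional[float] = None
    relative_TPE: Optional[float] = None
    relative_TPA: Optional[float] = None
    rr_interval: Optional[float] = None

    def __post_init__(self):
        for name in ("E", "A", "e_prime_septal", "e_prime_lateral", "e_prime_mean"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ParameterError(f"{name} must be positive when present")
        if self.e_prime_mean is None and None not in (
            self.e_prime_septal, self.e_prime_lateral
        ):
            self.e_prime_mean = (self.e_prime_septal + self.e_prime_lateral) / 2.0

    def mean_ratio(self, mode: str = "e_over_mean_eprime") -> Optional[float]:
        """Average-E/average-e′; explicit value wins, else derived per mode."""
        if self.E_over_e_mean is not None:
            return self.E_over_e_mean
        if mode == "mean_of_ratios":
            if None not in (self.E_over_e_septal, self.E_over_e_lateral):
                return (self.E_over_e_septal + self.E_over_e_lateral) / 2.0
            return None
        if self.E is not None and self.e_prime_mean:
            return self.E / self.e_prime_mean
        return None


@dataclass(frozen=True)
class GradeCriteria:
    septal_low: bool   # septal e' < 8 cm/s
    lateral_low: bool  # lateral e' < 10 cm/s
    ratio_high: bool   # mean E/e' >= 10
    lvh: bool

    @property
    def n_met(self) -> int:
        return int(self.septal_low) + int(self.lateral_low) + int(self.ratio_high)


@dataclass(frozen=True)
class GradingThresholds:
    """ASE cutoffs; defaults are the recommended values."""

    septal_eprime: float = 8.0    # cm/s, strict <
    lateral_eprime: float = 10.0  # cm/s, strict <
    mean_ratio: float = 10.0      # dimensionless, >= (non-strict)
    lvmi_male: float = 115.0      # g/m², strict >
    lvmi_female: float = 95.0     # g/m², strict >


@dataclass
class SubjectRecord:
    """One subject: paired echo and CMR data plus covariates."""

    id: str
    echo: Optional[EchoDiastolicMeasures] = None
    cmr: object = None  # CmrDiastolicIndices when analysed
    age: Optional[float] = None
    sex: Optional[str] = None          # "male" / "female"
    lvmi: Optional[float] = None       # g/m²
    heart_rate_echo: Optional[float] = None
    heart_rate_cmr: Optional[float] = None
    grade: Optional[DysfunctionGrade] = None
    covariates: dict = field(default_factory=dict)


def lv_hypertrophy(lvmi: float, sex: str,
                   thresholds: GradingThresholds = GradingThresholds()) -> bool:
    """LV hypertrophy flag from the sex-specific LVMi cutoff (strict >)."""
    if lvmi <= 0:
        raise ParameterError("LVMi must be positive")
    s = sex.strip().lower()
    if s in ("male", "m", "men"):
        return lvmi > thresholds.lvmi_male
    if s in ("female", "f", "women"):
        return lvmi > thresholds.lvmi_female
    raise ParameterError(f"unknown sex label: {sex!r}")


def ase_criteria(echo: EchoDiastolicMeasures, lvh: bool,
                 thresholds: GradingThresholds = GradingThresholds(),
                 ratio_mode: str = "e_over_mean_eprime") -> GradeCriteria:
    """Evaluate the three ASE criteria on an echo record."""
    ratio = echo.mean_ratio(ratio_mode)
    if echo.e_prime_septal is None or echo.e_prime_lateral is None or ratio is None:
        raise IncompleteMeasuresError(
            "grading requires septal e', lateral e' and the mean E/e' ratio"
        )
    return GradeCriteria(
        septal_low=echo.e_prime_septal < thresholds.septal_eprime,
        lateral_low=echo.e_prime_lateral < thresholds.lateral_eprime,
        ratio_high=ratio >= thresholds.mean_ratio,
        lvh=bool(lvh),
    )


def grade_diastolic_function(criteria: GradeCriteria) -> DysfunctionGrade:
    """Map criteria to a grade.

    3 criteria → type II; exactly 2 criteria, or exactly 1 plus LVH →
    type I; otherwise normal.  Two criteria plus LVH stay type I — LVH
    cannot promote past the all-three rule.
    """
    n = criteria.n_met
    if n == 3:
        return DysfunctionGrade.TYPE_II
    if n == 2 or (n == 1 and criteria.lvh):
        return DysfunctionGrade.TYPE_I
    return DysfunctionGrade.NORMAL


def heart_rate_compatible(record: SubjectRecord,
                          max_diff: float = HEART_RATE_MAX_DIFF) -> bool:
    """Same-day comparability rule: heart rates within ``max_diff`` bpm.

    Records with a missing rate on either modality are considered
    compatible (the rule cannot be evaluated); exclusion is reported by
    the caller, never silent.
    """
    if record.heart_rate_echo is None or record.heart_rate_cmr is None:
        return True
    return abs(record.heart_rate_echo - record.heart_rate_cmr) <= max_diff
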