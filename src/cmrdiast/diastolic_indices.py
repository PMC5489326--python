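"""Diastolic filling indices from a time-volume curve.

The derivative of the LV time-volume curve over diastole shows an early
filling wave (E) and — unless the waves are fused — a second, atrial
wave (A), mirroring the transmitral Doppler inflow pattern:

* **E** (mL/s): first maximum filling rate after end-systole (ES);
  **RTPE** (ms) its delay from ES.
* **A** (mL/s): second peak filling rate after ES; **RTPA** its delay
  from ES.  Absent when the waves are fused.
* **NE, NA** (s⁻¹): E and A normalised by end-diastolic volume.
* **DT** (ms): deceleration time — from the E peak to where the
  extrapolated E-wave downslope crosses the zero-rate baseline.
* **DVR** (ms): diastolic volume recovery — from ES to the instant the
  cavity has refilled 80% of the stroke volume.
* **E/A**: ratio of the two peaks.

Together with the annulus-derived longitudinal relaxation rate E′ these
populate :class:`CmrDiastolicIndices`; note the E/E′ ratio carries units
mL/mm because the volumetric E is a flow rate, not a velocity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .annulus_kinematics import AnnulusTrack, early_relaxation_rate, e_over_eprime
from .errors import (
    DegenerateDownslopeError,
    InsufficientSamplingError,
    NoFillingError,
    NoRecoveryError,
    ParameterError,
)
from .volume_curves import (
    FillingRateCurve,
    VolumeCurve,
    derive_filling_rate,
    locate_end_systole,
)

__all__ = [
    "CmrDiastolicIndices",
    "detect_e_peak",
    "detect_a_peak",
    "normalize_peak",
    "deceleration_time",
    "diastolic_volume_recovery",
    "ea_ratio",
    "analyze_curve",
]


@dataclass
class CmrDiastolicIndices:
    """Full derived parameter set for one subject's volume curve.

    A-wave fields are ``None`` (never zero-filled) when the E and A waves
    are fused; E′ fields are ``None`` when no annulus tracks were supplied.
    """

    E: float                      # mL/s
    NE: float                     # 1/s
    RTPE: float                   # ms from ES
    DT: float                     # ms
    DVR: float                    # ms from ES
    A: Optional[float] = None     # mL/s
    NA: Optional[float] = None    # 1/s
    RTPA: Optional[float] = None  # ms from ES
    EA_ratio: Optional[float] = None
    e_prime_septal: Optional[float] = None   # mm/s
    e_prime_lateral: Optional[float] = None  # mm/s
    e_prime_mean: Optional[float] = None     # mm/s
    E_over_Eprime_septal: Optional[float] = None   # mL/mm
    E_over_Eprime_lateral: Optional[float] = None  # mL/mm
    E_over_Eprime_mean: Optional[float] = None     # mL/mm
    edv: Optional[float] = None   # mL
    esv: Optional[float] = None   # mL
    sv: Optional[float] = None    # mL
    es_time: Optional[float] = None  # ms
    warnings: tuple = ()


def _post_es_slice(times: np.ndarray, es_time: float) -> np.ndarray:
    """Indices of samples strictly after end-systole (no wrap: diastole
    ends at the next R wave)."""
    return np.nonzero(times > es_time)[0]


def _first_local_max(rates: np.ndarray, idx: np.ndarray) -> Optional[int]:
    """First local maximum among ``idx`` (global indices, ascending).

    A sample counts as a local maximum when it is >= its successor and
    strictly greater than its predecessor (so the first sample of a
    plateau wins).  The last frame of the cycle has no successor inside
    diastole and is not a candidate.
    """
    n = rates.size
    for i in idx:
        if i == 0 or i >= n - 1:
            continue
        if rates[i] > rates[i - 1] and rates[i] >= rates[i + 1]:
            return int(i)
    return None


def _first_local_min_after(rates: np.ndarray, start: int) -> Optional[int]:
    n = rates.size
    for i in range(start + 1, n - 1):
        if rates[i] < rates[i - 1] and rates[i] <= rates[i + 1]:
            return int(i)
    return None


def detect_e_peak(rate: FillingRateCurve, es_time: float) -> tuple[float, float]:
    """Early peak filling rate E (mL/s) and its delay RTPE (ms) from ES.

    E is the value at the first local maximum of the rate after ES.  If the
    post-ES rates are positive but monotonically decreasing (no interior
    maximum), the first post-ES sample is taken with a warning — a
    curve-shape degeneracy must not crash batch analyses.
    """
    idx = _post_es_slice(rate.times, es_time)
    if idx.size == 0:
        raise NoFillingError("no samples after end-systole")
    if not np.any(rate.rates[idx] > 0):
        raise NoFillingError("no positive filling rate after end-systole")
    peak = _first_local_max(rate.rates, idx)
    if peak is None:
        first = int(idx[0])
        if rate.rates[first] <= 0:
            raise NoFillingError("first post-ES sample is non-positive")
        warnings.warn(
            "no interior local maximum after ES; using the first post-ES "
            "sample as E",
            stacklevel=2,
        )
        peak = first
    e_value = float(rate.rates[peak])
    if e_value <= 0:
        raise NoFillingError("detected E peak is non-positive")
    return e_value, float(rate.times[peak] - es_time)


def detect_a_peak(
    rate: FillingRateCurve, es_time: float, e_time: float
) -> Optional[tuple[float, float]]:
    """Atrial peak filling rate A (mL/s) and RTPA (ms), or ``None`` if fused.

    A is the first local maximum strictly after the post-E trough; its time
    is reported relative to ES.  Absence of a second peak is a valid
    physiological outcome (fused E/A), not an error.
    """
    e_idx_candidates = np.nonzero(np.isclose(rate.times, e_time + es_time))[0]
    if e_idx_candidates.size:
        e_idx = int(e_idx_candidates[0])
    else:
        e_idx = int(np.searchsorted(rate.times, e_time + es_time))
    trough = _first_local_min_after(rate.rates, e_idx)
    if trough is None:
        return None
    peak = _first_local_max(rate.rates, np.arange(trough + 1, rate.times.size))
    if peak is None:
        return None
    return float(rate.rates[peak]), float(rate.times[peak] - es_time)


def normalize_peak(peak: float, edv: float) -> float:
    """Normalise a peak filling rate by end-diastolic volume → s⁻¹."""
    if edv <= 0:
        raise ParameterError("EDV must be positive")
    return peak / edv


def deceleration_time(
    rate: FillingRateCurve, e_peak_time: float, mode: str = "least_squares"
) -> float:
    """Deceleration time DT (ms) of the E wave.

    A line is fitted to the descending limb of the E lobe — all samples
    from the peak (inclusive) to the first subsequent local minimum
    (exclusive) — and extrapolated to the zero-rate baseline; DT is the
    crossing time minus the peak time.  ``mode`` selects a least-squares
    fit (default) or a two-point chord through the first and last samples
    of the limb.
    """
    if mode not in ("least_squares", "two_point"):
        raise ParameterError(f"unknown DT fit mode: {mode!r}")
    peak_candidates = np.nonzero(np.isclose(rate.times, e_peak_time))[0]
    if peak_candidates.size:
        peak = int(peak_candidates[0])
    else:
        peak = int(np.argmin(np.abs(rate.times - e_peak_time)))
    trough = _first_local_min_after(rate.rates, peak)
    end = trough if trough is not None else rate.times.size
    t = rate.times[peak:end]
    r = rate.rates[peak:end]
    if t.size < 2:
        raise InsufficientSamplingError(
            "descending limb of the E wave has fewer than 2 samples"
        )
    if mode == "two_point":
        slope = (r[-1] - r[0]) / (t[-1] - t[0])
        intercept = r[0] - slope * t[0]
    else:
        slope, intercept = np.polyfit(t, r, 1)
    if slope >= 0:
        raise DegenerateDownslopeError("E-wave downslope has non-negative slope")
    t_zero = -intercept / slope
    return float(t_zero - rate.times[peak])


def diastolic_volume_recovery(curve: VolumeCurve, es_time: float) -> float:
    """DVR (ms): time from ES until the volume refills 80% of the stroke volume.

    The first upward crossing of ESV + 0.8·SV after ES is located by linear
    interpolation between the bracketing frames (nearest-frame rounding
    would bias by up to half the temporal resolution).
    """
    if curve.sv <= 0:
        raise ParameterError("stroke volume must be positive")
    threshold = curve.esv + 0.8 * curve.sv
    t, v = curve.times, curve.volumes
    start = int(np.searchsorted(t, es_time))
    for i in range(start, t.size):
        if v[i] >= threshold:
            if i == start or v[i - 1] >= threshold or t[i - 1] < es_time:
                return float(t[i] - es_time)
            frac = (threshold - v[i - 1]) / (v[i] - v[i - 1])
            crossing = t[i - 1] + frac * (t[i] - t[i - 1])
            return float(crossing - es_time)
    raise NoRecoveryError("volume never reaches ESV + 0.8·SV after end-systole")


def ea_ratio(E: float, A: Optional[float]) -> Optional[float]:
    """E/A ratio; ``None`` propagates when the A wave is absent."""
    if A is None:
        return None
    if A <= 0:
        raise ParameterError("A must be positive when present")
    return E / A


def analyze_curve(
    curve: VolumeCurve,
    septal_track: Optional[AnnulusTrack] = None,
    lateral_track: Optional[AnnulusTrack] = None,
    config=None,
) -> CmrDiastolicIndices:
    """Compute the full index set for one subject.

    Orchestrates ES detection, differentiation, E/A peak detection, DT,
    DVR, normalised rates, and — when annulus tracks are supplied — E′ and
    E/E′ at each site.  A-wave fields are ``None`` when the waves are
    fused.  Component errors propagate with a stage label prefixed.
    """
    from .config import AnalysisConfig  # local import to avoid cycle

    cfg = config if config is not None else AnalysisConfig()
    warns: list[str] = []

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            exc.args = (f"[{name}] {exc}",) + exc.args[1:]
            raise

    es_idx, es_time = _stage("locate_end_systole", locate_end_systole, curve)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        rate = _stage("derive_filling_rate", derive_filling_rate, curve, cfg.smoothing)
        E, RTPE = _stage("detect_e_peak", detect_e_peak, rate, es_time)
    warns.extend(str(w.message) for w in caught)

    a_result = _stage("detect_a_peak", detect_a_peak, rate, es_time, RTPE)
    A = RTPA = None
    if a_result is not None:
        A, RTPA = a_result
    DT = _stage("deceleration_time", deceleration_time, rate, es_time + RTPE, cfg.dt_fit_mode)
    DVR = _stage("diastolic_volume_recovery", diastolic_volume_recovery, curve, es_time)

    edv = curve.edv
    NE = normalize_peak(E, edv)
    NA = normalize_peak(A, edv) if A is not None else None
    EA = ea_ratio(E, A)

    # early-diastolic window for E': ES to ES + frac·(cycle remainder), or
    # the A-lobe onset (post-E trough) when detected, whichever is earlier
    window_end = es_time + cfg.eprime_window_fraction * (curve.rr_interval - es_time)
    if RTPA is not None:
        trough = _first_local_min_after(
            rate.rates, int(np.argmin(np.abs(rate.times - (es_time + RTPE))))
        )
        if trough is not None:
            window_end = min(window_end, float(rate.times[trough]))

    ep_sep = ep_lat = ep_mean = ee_sep = ee_lat = ee_mean = None
    if septal_track is not None:
        ep_sep = _stage(
            "early_relaxation_rate(septal)", early_relaxation_rate,
            septal_track, es_time, window_end,
        )
        ee_sep = e_over_eprime(E, ep_sep)
    if lateral_track is not None:
        ep_lat = _stage(
            "early_relaxation_rate(lateral)", early_relaxation_rate,
            lateral_track, es_time, window_end,
        )
        ee_lat = e_over_eprime(E, ep_lat)
    if ep_sep is not None and ep_lat is not None:
        ep_mean = (ep_sep + ep_lat) / 2.0
        if cfg.e_over_eprime_mode == "mean_of_ratios":
            ee_mean = (ee_sep + ee_lat) / 2.0
        else:  # "e_over_mean_eprime"
            ee_mean = e_over_eprime(E, ep_mean)

    return CmrDiastolicIndices(
        E=E, NE=NE, RTPE=RTPE, DT=DT, DVR=DVR,
        A=A, NA=NA, RTPA=RTPA, EA_ratio=EA,
        e_prime_septal=ep_sep, e_prime_lateral=ep_lat, e_prime_mean=ep_mean,
        E_over_Eprime_septal=ee_sep, E_over_Eprime_lateral=ee_lat,
        E_over_Eprime_mean=ee_mean,
        edv=edv, esv=curve.esv, sv=curve.sv, es_time=es_time,
        warnings=tuple(warns),
    )
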