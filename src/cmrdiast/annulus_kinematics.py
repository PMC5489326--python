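"""Mitral-annulus kinematics: the longitudinal relaxation rate E′.

Guide points at the septal and lateral junctions of the LV wall with the
mitral annulus are tracked through the cycle; the distance from each point
to the model apex lengthens in early diastole as the ventricle relaxes.
The maximum rate of that lengthening within the early-diastolic window is
E′ (mm/s) — the volumetric analogue of the tissue-Doppler e′ velocity.

Unlike the filling-rate indices (mL/s), E′ is a true linear velocity, so
the CMR E/E′ ratio carries units of mL/mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    InsufficientSamplingError,
    NoRelaxationError,
    ParameterError,
    StructuralInputError,
)
from .volume_curves import cyclic_central_difference

SITES = ("septal", "lateral")

__all__ = ["AnnulusTrack", "SITES", "apex_annulus_distance_series",
           "early_relaxation_rate", "e_over_eprime"]


@dataclass(frozen=True)
class AnnulusTrack:
    """Apex-to-annulus distance per frame for one guide-point site."""

    times: np.ndarray      # ms, same grid as the volume curve
    distances: np.ndarray  # mm
    site: str
    rr_interval: float = 0.0

    def __post_init__(self):
        times = np.asarray(self.times, float)
        distances = np.asarray(self.distances, float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "distances", distances)
        if times.size != distances.size:
            raise StructuralInputError("times and distances must have equal length")
        if np.any(distances <= 0):
            raise StructuralInputError("apex-annulus distances must be positive")
        if self.site not in SITES:
            raise StructuralInputError(f"site must be one of {SITES}, got {self.site!r}")


def apex_annulus_distance_series(
    times, apex, annulus, site: str, rr_interval: float = 0.0
) -> AnnulusTrack:
    """Per-frame Euclidean distance (mm) between apex and annulus points.

    ``apex`` and ``annulus`` are (n_frames, 3) coordinate arrays in mm.
    """
    apex = np.asarray(apex, float)
    annulus = np.asarray(annulus, float)
    if apex.shape != annulus.shape:
        raise StructuralInputError(
            f"apex {apex.shape} and annulus {annulus.shape} frame counts differ"
        )
    if apex.ndim != 2 or apex.shape[1] != 3:
        raise StructuralInputError("point tracks must have shape (n_frames, 3)")
    d = np.linalg.norm(annulus - apex, axis=1)
    return AnnulusTrack(np.asarray(times, float), d, site, rr_interval)


def early_relaxation_rate(
    track: AnnulusTrack, es_time: float, window_end: float
) -> float:
    """E′ (mm/s): maximum annulus-lengthening rate in (es_time, window_end].

    The distance track is differentiated with the same cyclic
    central-difference machinery as the volume curves; only positive
    derivatives (annulus moving away from the apex) count.  The window must
    contain at least 3 samples.
    """
    if window_end <= es_time:
        raise ParameterError("window_end must exceed es_time")
    period = track.rr_interval if track.rr_interval > 0 else (
        track.times[-1] - track.times[0] + np.median(np.diff(track.times))
    )
    deriv = cyclic_central_difference(track.times, track.distances, period) * 1000.0
    mask = (track.times > es_time) & (track.times <= window_end)
    if np.count_nonzero(mask) < 3:
        raise InsufficientSamplingError(
            "early-diastolic window contains fewer than 3 samples"
        )
    windowed = deriv[mask]
    best = float(windowed.max())
    if best <= 0:
        raise NoRelaxationError("no positive lengthening rate in the early window")
    return best


def e_over_eprime(E: float, eprime: float) -> float:
    """E/E′ ratio (mL/mm): volumetric early filling over annular relaxation."""
    if eprime <= 0:
        raise ParameterError("E' must be positive")
    return E / eprime
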