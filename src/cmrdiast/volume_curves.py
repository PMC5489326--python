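"""LV time-volume curves: containers, differentiation, end-systole detection.

A cine acquisition yields one left-ventricular cavity volume sample per
cardiac phase over a single R-R interval (typically 30 frames). Everything
downstream — peak filling rates, deceleration time, diastolic volume
recovery — is computed from this curve and its time derivative.

Conventions
-----------
* Time is stored in milliseconds from the R-wave trigger; frame 0 is
  end-diastole by definition and ``times[0] == 0``.
* Volumes are millilitres; filling rates are mL/s (the ms→s conversion is
  done exactly once, in :func:`derive_filling_rate`).
* The cycle is periodic: frame ``n-1`` wraps to frame 0 one R-R later.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientSamplingError, ParameterError, StructuralInputError

MIN_FRAMES = 8

__all__ = [
    "VolumeCurve",
    "FillingRateCurve",
    "MaskStack",
    "MIN_FRAMES",
    "cyclic_central_difference",
    "derive_filling_rate",
    "locate_end_systole",
    "temporal_resolution",
    "mask_stack_volumes",
    "volume_from_mask_stack",
]


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise StructuralInputError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise StructuralInputError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class VolumeCurve:
    """One cardiac cycle of LV cavity volume.

    Parameters
    ----------
    times : array-like
        Milliseconds from the R-wave trigger, strictly increasing,
        ``times[0] == 0`` and ``times[-1] < rr_interval``.
    volumes : array-like
        Cavity volume in mL, all positive.
    rr_interval : float
        Cycle length in ms.
    """

    times: np.ndarray
    volumes: np.ndarray
    rr_interval: float

    def __post_init__(self):
        times = _as_float_array(self.times, "times")
        volumes = _as_float_array(self.volumes, "volumes")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "volumes", volumes)
        if times.size != volumes.size:
            raise StructuralInputError("times and volumes must have equal length")
        if times.size < MIN_FRAMES:
            raise InsufficientSamplingError(
                f"need at least {MIN_FRAMES} frames, got {times.size}"
            )
        if times[0] != 0.0:
            raise StructuralInputError("times must start at 0 (R-wave trigger)")
        if np.any(np.diff(times) <= 0):
            raise StructuralInputError("times must be strictly increasing")
        if self.rr_interval <= times[-1]:
            raise StructuralInputError("rr_interval must exceed the last frame time")
        if np.any(volumes <= 0):
            raise StructuralInputError("all volumes must be positive")
        if np.isclose(volumes.max(), volumes.min()):
            # EDV > ESV is a type invariant; a perfectly flat curve carries no
            # cardiac cycle.  Allow construction only if strictly different.
            if volumes.max() == volumes.min():
                raise StructuralInputError("EDV must exceed ESV (flat curve)")

    @property
    def n_frames(self) -> int:
        return self.times.size

    @property
    def edv(self) -> float:
        """End-diastolic volume (mL): maximum over the cycle."""
        return float(self.volumes.max())

    @property
    def esv(self) -> float:
        """End-systolic volume (mL): minimum over the cycle."""
        return float(self.volumes.min())

    @property
    def sv(self) -> float:
        """Stroke volume EDV − ESV (mL)."""
        return self.edv - self.esv


@dataclass(frozen=True)
class FillingRateCurve:
    """dV/dt on the same time grid as its source curve, in mL/s."""

    times: np.ndarray
    rates: np.ndarray
    rr_interval: float = field(default=0.0)

    def __post_init__(self):
        times = _as_float_array(self.times, "times")
        rates = _as_float_array(self.rates, "rates")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "rates", rates)
        if times.size != rates.size:
            raise StructuralInputError("times and rates must have equal length")


@dataclass(frozen=True)
class MaskStack:
    """Short-axis binary segmentation masks, one list of slices per frame.

    ``masks[frame][slice]`` is a 2-D boolean/0-1 array.  Geometry follows the
    acquisition: each slice contributes ``pixel_area × (thickness + gap)`` of
    volume per foreground pixel (disc summation with gap included, so that
    contiguous slices tile the ventricle).
    """

    masks: list
    pixel_area_mm2: float
    slice_thickness_mm: float
    slice_gap_mm: float
    rr_interval: float

    def __post_init__(self):
        if not self.masks:
            raise StructuralInputError("mask stack has no frames")
        n_slices = len(self.masks[0])
        if n_slices == 0:
            raise StructuralInputError("mask stack frames have no slices")
        for i, frame in enumerate(self.masks):
            if len(frame) != n_slices:
                raise StructuralInputError(
                    f"frame {i} has {len(frame)} slices, expected {n_slices}"
                )
        if self.pixel_area_mm2 <= 0:
            raise StructuralInputError("pixel_area_mm2 must be positive")
        if self.slice_thickness_mm <= 0:
            raise StructuralInputError("slice_thickness_mm must be positive")
        if self.slice_gap_mm < 0:
            raise StructuralInputError("slice_gap_mm must be non-negative")

    @property
    def n_frames(self) -> int:
        return len(self.masks)


def cyclic_central_difference(times: np.ndarray, values: np.ndarray, period: float) -> np.ndarray:
    """Central differences with periodic wrap across the cycle boundary.

    For interior samples the standard (possibly non-uniform) central
    difference is used; the first and last samples use their periodic
    neighbours shifted by one period.  Returns d(values)/d(times) in the
    input units (per ms when times are ms).
    """
    t = np.asarray(times, float)
    v = np.asarray(values, float)
    n = t.size
    if n < 3:
        raise InsufficientSamplingError("central differences need >= 3 samples")
    tp = np.concatenate(([t[-1] - period], t, [t[0] + period]))
    vp = np.concatenate(([v[-1]], v, [v[0]]))
    return (vp[2:] - vp[:-2]) / (tp[2:] - tp[:-2])


def derive_filling_rate(curve: VolumeCurve, smooth: bool = False) -> FillingRateCurve:
    """Differentiate a volume curve into a filling-rate curve (mL/s).

    Central differences with cyclic continuation across the R-R boundary;
    the cardiac cycle is periodic so frame 0 and the last frame use each
    other as neighbours.  With ``smooth=True`` a cyclic 3-point moving
    average is applied to the rates (off by default: 30-frame curves are
    coarse and smoothing shifts peaks).
    """
    if curve.n_frames < MIN_FRAMES:
        raise InsufficientSamplingError("curve has too few frames to differentiate")
    rates_ml_per_ms = cyclic_central_difference(
        curve.times, curve.volumes, curve.rr_interval
    )
    rates = rates_ml_per_ms * 1000.0  # ms -> s
    if smooth:
        rates = (np.roll(rates, 1) + rates + np.roll(rates, -1)) / 3.0
    fc = FillingRateCurve(curve.times, rates, rr_interval=curve.rr_interval)
    _warn_if_not_conservative(fc, curve)
    return fc


def closed_cycle_integral(rate: FillingRateCurve) -> float:
    """∮ dV/dt dt over the closed cycle (mL), trapezoid rule with wrap."""
    t = rate.times
    r = rate.rates / 1000.0  # back to mL/ms for integration against ms
    if rate.rr_interval <= 0:
        raise ParameterError("rate curve has no rr_interval; cannot close the cycle")
    dt = np.diff(np.concatenate((t, [t[0] + rate.rr_interval])))
    r_next = np.roll(r, -1)
    return float(np.sum((r + r_next) / 2.0 * dt))


def _warn_if_not_conservative(rate: FillingRateCurve, curve: VolumeCurve) -> None:
    residual = abs(closed_cycle_integral(rate))
    if curve.sv > 0 and residual > 0.01 * curve.sv:
        warnings.warn(
            f"filling-rate curve violates volume conservation: |∮dV/dt dt| = "
            f"{residual:.3f} mL exceeds 1% of SV ({curve.sv:.1f} mL)",
            stacklevel=3,
        )


def locate_end_systole(curve: VolumeCurve) -> tuple[int, float]:
    """Frame index and time (ms) of end-systole (minimum volume).

    Ties are broken toward the earliest frame.  End-diastole is frame 0 by
    convention.
    """
    idx = int(np.argmin(curve.volumes))  # argmin returns the first minimum
    return idx, float(curve.times[idx])


def temporal_resolution(rr_interval: float, n_frames: int) -> float:
    """Reconstructed temporal resolution: R-R interval / number of phases (ms)."""
    if n_frames <= 0:
        raise ParameterError("n_frames must be positive")
    if rr_interval <= 0:
        raise ParameterError("rr_interval must be positive")
    return rr_interval / n_frames


def mask_stack_volumes(stack: MaskStack) -> np.ndarray:
    """Per-frame cavity volume (mL) by disc summation over slices.

    volume = Σ_slices pixel_count × pixel_area × (slice thickness + gap),
    converted from mm³ to mL.
    """
    per_slice_height = stack.slice_thickness_mm + stack.slice_gap_mm
    vols = np.empty(stack.n_frames)
    for i, frame in enumerate(stack.masks):
        count = 0
        for sl in frame:
            arr = np.asarray(sl)
            count += int(np.count_nonzero(arr))
        vols[i] = count * stack.pixel_area_mm2 * per_slice_height / 1000.0
    return vols


def volume_from_mask_stack(stack: MaskStack) -> VolumeCurve:
    """Reduce a segmentation mask stack to a validated volume curve.

    Frame times are taken as a uniform grid over the R-R interval
    (``i · rr / n_frames``).  Raises if any frame has zero volume or the
    stack has fewer than :data:`MIN_FRAMES` frames.
    """
    vols = mask_stack_volumes(stack)
    if np.any(vols <= 0):
        raise StructuralInputError("mask stack contains a frame with zero volume")
    if stack.n_frames < MIN_FRAMES:
        raise InsufficientSamplingError(
            f"mask stack has {stack.n_frames} frames; need {MIN_FRAMES}"
        )
    dt = stack.rr_interval / stack.n_frames
    times = np.arange(stack.n_frames) * dt
    return VolumeCurve(times, vols, stack.rr_interval)
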