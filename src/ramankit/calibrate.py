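"""Instrument-response (y-axis) and Raman-shift (x-axis) calibration.

The y-axis is corrected with a standard-reference-material (SRM) spectrum:
the instrument response function is the elementwise ratio of the measured
SRM spectrum (fully preprocessed) to the certificate's theoretical
fluorescence curve, and spectra are corrected by dividing by it.

The x-axis is calibrated from a reference sample (acetaminophen / nylon)
with narrow, well-spread peaks: detected peak pixel positions are matched to
known shifts and a low-order polynomial maps pixel index to cm^-1. All
spectra in a batch should then be interpolated onto one common shift grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy.signal import find_peaks

from .errors import CalibrationError, DimensionError, RangeError
from .types import Spectrum

__all__ = [
    "IRFModel",
    "ShiftCalibration",
    "srm_theoretical",
    "compute_irf",
    "apply_irf",
    "calibrate_xaxis",
    "resample_common_axis",
    "default_shift_grid",
]


@dataclass(frozen=True)
class IRFModel:
    """Instrument response function: one strictly positive ratio per pixel."""

    irf: np.ndarray

    def __post_init__(self):
        irf = np.asarray(self.irf, dtype=float)
        if irf.ndim != 1:
            raise DimensionError("irf must be a 1-D vector")
        if np.any(irf <= 0) or not np.all(np.isfinite(irf)):
            raise ValueError("irf values must be finite and strictly positive")
        irf.setflags(write=False)
        object.__setattr__(self, "irf", irf)

    def __len__(self) -> int:
        return self.irf.size


@dataclass(frozen=True)
class ShiftCalibration:
    """Polynomial map from camera pixel index to Raman shift (cm^-1).

    ``coeffs`` are in increasing-power order (``shift = sum c_k * pixel**k``).
    The map must be strictly increasing over the calibrated pixel range.
    """

    coeffs: np.ndarray
    order: int
    reference_peaks: tuple  # ((pixel, shift_cm1), ...)
    residuals: np.ndarray = field(default_factory=lambda: np.zeros(0))
    pixel_range: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        coeffs = np.asarray(self.coeffs, dtype=float)
        if coeffs.size != self.order + 1:
            raise ValueError("coeffs length must equal order + 1")
        if len(self.reference_peaks) < self.order + 1:
            raise CalibrationError(
                f"need >= {self.order + 1} reference peaks for order {self.order}"
            )
        coeffs.setflags(write=False)
        object.__setattr__(self, "coeffs", coeffs)
        object.__setattr__(self, "residuals", np.asarray(self.residuals, float))
        object.__setattr__(self, "reference_peaks",
                           tuple((float(p), float(s)) for p, s in self.reference_peaks))
        lo, hi = self.pixel_range
        if hi > lo and not _strictly_increasing(coeffs, lo, hi):
            raise CalibrationError("fitted pixel->shift map is not strictly increasing")

    def pixel_to_shift(self, pixels) -> np.ndarray:
        return npoly.polyval(np.asarray(pixels, dtype=float), self.coeffs)


def _strictly_increasing(coeffs: np.ndarray, lo: float, hi: float) -> bool:
    dense = np.linspace(lo, hi, 512)
    return bool(np.all(np.diff(npoly.polyval(dense, coeffs)) > 0))


def srm_theoretical(coeffs, axis) -> np.ndarray:
    """Evaluate the certificate polynomial (increasing-power coefficients) on
    ``axis``; the result must be strictly positive."""
    curve = npoly.polyval(np.asarray(axis, dtype=float),
                          np.asarray(coeffs, dtype=float))
    if np.any(curve <= 0):
        raise ValueError(
            "certificate polynomial is nonpositive on the given axis; "
            "check the validity range"
        )
    return curve


def compute_irf(srm_measured: Spectrum, srm_theoretical_curve) -> IRFModel:
    """IRF = measured / theoretical, elementwise (measured spectrum must be
    truncated, cosmic-ray filtered and background-subtracted already)."""
    theo = np.asarray(srm_theoretical_curve, dtype=float)
    if theo.size != len(srm_measured):
        raise DimensionError("measured and theoretical lengths differ")
    if np.any(theo <= 0):
        raise ValueError("theoretical SRM curve must be strictly positive")
    return IRFModel(srm_measured.intensity / theo)


def apply_irf(spec: Spectrum, irf: IRFModel) -> Spectrum:
    """Correct a spectrum by elementwise division by the IRF."""
    if len(irf) != len(spec):
        raise DimensionError(
            f"irf length {len(irf)} != spectrum length {len(spec)}"
        )
    return spec.replace_intensity(spec.intensity / irf.irf)


def calibrate_xaxis(reference_spec: Spectrum, known_shifts, order: int = 2,
                    prominence_frac: float = 0.05, min_distance: int = 10,
                    reference_rbr: float | None = None) -> ShiftCalibration:
    """Fit the pixel -> Raman shift map from a reference-sample spectrum.

    The most prominent local maxima are detected (prominence threshold
    ``prominence_frac`` of the signal range, minimum separation
    ``min_distance`` samples), the top ``len(known_shifts)`` are kept and
    matched to the known shifts in increasing axis order, and a least-squares
    polynomial of the given order is fitted. ``reference_rbr``, when
    provided, triggers a warning below 0.2 (the recommended minimum for a
    calibration reference).
    """
    known = np.sort(np.asarray(known_shifts, dtype=float))
    if order not in (2, 3):
        raise ValueError("order must be 2 or 3")
    if known.size < order + 1:
        raise CalibrationError(
            f"{known.size} known shifts cannot determine an order-{order} map"
        )
    if reference_rbr is not None and reference_rbr < 0.2:
        warnings.warn(
            f"reference spectrum RBR {reference_rbr:.3g} < 0.2; "
            "calibration peaks may be unreliable", stacklevel=2)
    s = reference_spec.intensity
    prominence = prominence_frac * (s.max() - s.min())
    peaks, props = find_peaks(s, prominence=prominence, distance=min_distance)
    if peaks.size < known.size:
        raise CalibrationError(
            f"found {peaks.size} prominent peaks but {known.size} known shifts"
        )
    top = np.argsort(props["prominences"])[::-1][:known.size]
    sel = np.sort(peaks[top])
    pixels = reference_spec.axis[sel]
    coeffs = npoly.polyfit(pixels, known, order)
    residuals = npoly.polyval(pixels, coeffs) - known
    lo, hi = float(reference_spec.axis[0]), float(reference_spec.axis[-1])
    return ShiftCalibration(
        coeffs=coeffs,
        order=order,
        reference_peaks=tuple(zip(pixels, known)),
        residuals=residuals,
        pixel_range=(lo, hi),
    )


def resample_common_axis(spec: Spectrum, cal: ShiftCalibration, grid) -> Spectrum:
    """Map the spectrum's pixel axis to shifts and linearly interpolate onto
    ``grid`` (no extrapolation allowed)."""
    grid = np.asarray(grid, dtype=float)
    shift_axis = cal.pixel_to_shift(spec.axis)
    if grid[0] < shift_axis[0] or grid[-1] > shift_axis[-1]:
        raise RangeError(
            f"grid [{grid[0]:.6g}, {grid[-1]:.6g}] exceeds the calibrated range "
            f"[{shift_axis[0]:.6g}, {shift_axis[-1]:.6g}]"
        )
    intensity = np.interp(grid, shift_axis, spec.intensity)
    return Spectrum(grid, intensity, "shift", spec.metadata)


def default_shift_grid(start: float = 400.0, stop: float = 1800.0,
                       step: float = 2.0) -> np.ndarray:
    """Default common Raman-shift grid: 400-1800 cm^-1 at 2 cm^-1 steps."""
    return np.arange(start, stop + step / 2, step)
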