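"""Truncation, cosmic-ray removal, background subtraction and accumulation
combination.

Cosmic-ray artifacts are sharp spikes spanning 1-5 camera pixels. Two
complementary filters are provided: :func:`crfilter_single` works on one
spectrum via the modified z-score of its first difference;
:func:`crfilter_multi` exploits the fact that two accumulations essentially
never exhibit a spike at the same pixel, flagging per-pixel outliers against
the cross-accumulation median. Flagged regions are repaired by linear
interpolation along the wavelength axis.
"""

from __future__ import annotations

import numpy as np

from .types import RawAcquisition, Spectrum

__all__ = [
    "truncate",
    "crfilter_single",
    "crfilter_multi",
    "combine_accumulations",
    "subtract_background",
]

# 0.6745 makes the MAD-based score comparable to a z-score for Gaussian data
_MAD_SCALE = 0.6745


def truncate(spec, cut_low: int, cut_high: int | None = None):
    """Keep the half-open pixel-index range ``[cut_low, cut_high)``.

    Works on :class:`Spectrum` and :class:`RawAcquisition`; for the latter the
    background (when present) is truncated identically.
    """
    if isinstance(spec, Spectrum):
        n = len(spec)
    elif isinstance(spec, RawAcquisition):
        n = spec.n_pix
    else:
        raise TypeError("truncate expects a Spectrum or RawAcquisition")
    hi = n if cut_high is None else cut_high
    if not (0 <= cut_low < hi <= n):
        raise ValueError(
            f"invalid truncation range [{cut_low}, {hi}) for {n} pixels"
        )
    sl = slice(cut_low, hi)
    if isinstance(spec, Spectrum):
        return Spectrum(spec.axis[sl], spec.intensity[sl], spec.axis_kind, spec.metadata)
    return spec.replace(
        accumulations=spec.accumulations[:, sl],
        background=None if spec.background is None else spec.background[sl],
        axis=None if spec.axis is None else spec.axis[sl],
    )


def _interpolate_flagged(values: np.ndarray, flagged: np.ndarray) -> np.ndarray:
    """Replace flagged samples by linear interpolation between the nearest
    unflagged neighbors; leading/trailing runs take the nearest valid value."""
    out = values.copy()
    good = ~flagged
    if not flagged.any():
        return out
    if not good.any():  # nothing to anchor on; leave untouched
        return out
    idx = np.arange(values.size)
    out[flagged] = np.interp(idx[flagged], idx[good], values[good])
    return out


def _widen(flagged: np.ndarray, widen_px: int) -> np.ndarray:
    if widen_px <= 0 or not flagged.any():
        return flagged
    out = flagged.copy()
    for shift in range(1, widen_px + 1):
        out[shift:] |= flagged[:-shift]
        out[:-shift] |= flagged[shift:]
    return out


def crfilter_single(spec: Spectrum, threshold_mads: float = 10.0,
                    widen_px: int = 2) -> Spectrum:
    """Remove cosmic-ray spikes from a single spectrum.

    Pixels whose first difference deviates from the median difference by more
    than ``threshold_mads`` MAD-scaled units are flagged (on both sides of the
    jump), the flag widened by ``widen_px`` pixels, and the flagged region
    replaced by linear interpolation.
    """
    s = spec.intensity
    if s.size < 5:
        raise ValueError("crfilter_single needs at least 5 samples")
    d = np.diff(s)
    med = np.median(d)
    mad = np.median(np.abs(d - med))
    if mad == 0:
        # constant (or mostly constant) derivative spread: no adaptive scale
        return spec.replace_intensity(s.copy())
    score = _MAD_SCALE * (d - med) / mad
    jumps = np.abs(score) > threshold_mads
    flagged = np.zeros(s.size, dtype=bool)
    flagged[:-1] |= jumps
    flagged[1:] |= jumps
    flagged = _widen(flagged, widen_px)
    return spec.replace_intensity(_interpolate_flagged(s, flagged))


def crfilter_multi(acq: RawAcquisition, threshold_mads: float = 7.0,
                   widen_px: int = 2) -> RawAcquisition:
    """Remove cosmic-ray spikes by comparing accumulations pixel by pixel.

    For every pixel the residual of each accumulation from the
    cross-accumulation median is scored against the global MAD of all
    residuals; outlier cells are widened along the wavelength axis and
    repaired by interpolation within their own accumulation. Requires at
    least 3 accumulations.
    """
    if acq.n_acc < 3:
        raise ValueError(
            "crfilter_multi needs >= 3 accumulations; use crfilter_single instead"
        )
    acc = acq.accumulations
    med = np.median(acc, axis=0)
    resid = acc - med[None, :]
    mad = np.median(np.abs(resid))
    if mad == 0:
        return acq.replace(accumulations=acc.copy())
    score = _MAD_SCALE * resid / mad
    flagged = np.abs(score) > threshold_mads
    out = acc.copy()
    for i in range(acq.n_acc):
        row_flags = _widen(flagged[i], widen_px)
        if row_flags.any():
            out[i] = _interpolate_flagged(acc[i], row_flags)
    return acq.replace(accumulations=out)


def combine_accumulations(acq: RawAcquisition) -> Spectrum:
    """Arithmetic mean of the accumulations (SNR improves as sqrt(n_acc))."""
    mean = acq.accumulations.mean(axis=0)
    return Spectrum(acq.pixel_axis(), mean, acq.axis_kind, acq.metadata)


def subtract_background(spec: Spectrum, acq: RawAcquisition) -> Spectrum:
    """Subtract the exposure-normalized background from a combined spectrum.

    ``output = spectrum - background * (exposure_acq / exposure_bg)``.
    Apply after :func:`combine_accumulations`, and cosmic-ray-filter the
    background first to avoid introducing downward spikes.
    """
    if acq.background is None:
        raise ValueError("acquisition has no background spectrum")
    if acq.background.size != len(spec):
        raise ValueError(
            f"background length {acq.background.size} != spectrum length {len(spec)}"
        )
    if acq.exposure_acq <= 0 or acq.exposure_bg <= 0:
        raise ValueError("exposure times must be positive")
    scale = acq.exposure_acq / acq.exposure_bg
    return spec.replace_intensity(spec.intensity - acq.background * scale)
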