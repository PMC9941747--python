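"""Baseline-removal algorithms: BubbleFill, MorphBR and iModPoly.

BubbleFill estimates the autofluorescence baseline by growing circular
"bubbles" underneath the spectrum. The signal is first detrended with a
low-order polynomial and rescaled to a square aspect ratio (both axes span
the same range), then bubbles of decreasing diameter are grown: each bubble
is an upper half-circle lifted until it touches the signal, the baseline is
updated to the pointwise maximum of itself and the bubble, and the interval
splits at the contact point. A branch stops once its width falls below the
local minimum bubble width (the single tuning parameter, optionally varying
across the x-axis). The finished baseline is scaled back, re-trended and
Savitzky-Golay smoothed.

Geometry notes (reconstruction; the original arc parameterization is not
published): interior bubbles over ``[l, r]`` are half-circles of radius
``(r - l) / 2``; intervals touching the first or last sample grow an
edge-anchored quarter-circle of doubled radius so the baseline can rise at
the spectrum boundaries. Contact ties break to the leftmost sample; contact
at an interval endpoint drops that endpoint and continues with a single
child, which guarantees termination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import Polynomial
from scipy.ndimage import grey_dilation, grey_erosion
from scipy.signal import savgol_filter

from .types import BaselineFit, Spectrum

__all__ = ["BubbleParams", "bubble_lift", "bubblefill", "imodpoly", "morphbr"]


@dataclass(frozen=True)
class BubbleParams:
    """Tuning parameters for :func:`bubblefill`.

    ``min_width`` is the smallest allowed bubble diameter — a scalar or a
    per-pixel vector. Values below 1 are fractions of the axis span (the
    canonical form, which survives resampling); values >= 1 are in samples.
    ``smooth_window`` defaults to a width commensurate with ``min_width``.
    """

    min_width: float | np.ndarray = 0.1
    slope_order: int = 1
    smooth_window: int | None = None
    smooth_polyorder: int = 2

    def __post_init__(self):
        mw = np.atleast_1d(np.asarray(self.min_width, dtype=float))
        if np.any(mw <= 0):
            raise ValueError("min_width must be positive")
        if self.slope_order < 0:
            raise ValueError("slope_order must be >= 0")
        if self.smooth_window is not None:
            if self.smooth_window % 2 == 0 or self.smooth_window < 3:
                raise ValueError("smooth_window must be an odd integer >= 3")
            if self.smooth_polyorder >= self.smooth_window:
                raise ValueError("smooth_polyorder must be < smooth_window")

    def width_samples(self, n: int) -> np.ndarray:
        """Per-pixel minimum bubble width in samples for a length-n spectrum."""
        mw = np.atleast_1d(np.asarray(self.min_width, dtype=float))
        if mw.size not in (1, n):
            raise ValueError(
                f"per-pixel min_width has length {mw.size}, spectrum has {n}"
            )
        widths = np.where(mw < 1.0, mw * (n - 1), mw)
        if mw.size == 1:
            widths = np.full(n, widths[0])
        return widths


def bubble_lift(signal: np.ndarray, left: int, right: int,
                anchored: str = "none") -> tuple[np.ndarray, int]:
    """Grow one bubble under ``signal[left:right+1]``.

    Returns the lifted arc (same length as the interval, ``arc <= signal``
    everywhere with equality at the contact) and the global index of the
    contact point. ``anchored`` selects the geometry: ``"none"`` is a
    half-circle of diameter ``right - left``; ``"left_edge"``/``"right_edge"``
    anchor a quarter-circle of doubled radius at the corresponding edge.
    """
    signal = np.asarray(signal, dtype=float)
    if right - left < 1:
        return signal[left:left + 1].copy(), left
    x = np.arange(left, right + 1, dtype=float)
    width = float(right - left)
    if anchored == "none":
        radius = width / 2.0
        center = (left + right) / 2.0
        arc = np.sqrt(np.maximum(radius**2 - (x - center) ** 2, 0.0))
    elif anchored == "left_edge":
        arc = np.sqrt(np.maximum(width**2 - (x - left) ** 2, 0.0))
    elif anchored == "right_edge":
        arc = np.sqrt(np.maximum(width**2 - (x - right) ** 2, 0.0))
    else:
        raise ValueError("anchored must be 'none', 'left_edge' or 'right_edge'")
    gap = signal[left:right + 1] - arc
    contact = int(np.argmin(gap))  # argmin takes the leftmost tie
    return arc + gap[contact], left + contact


def _grow_bubbles(scaled: np.ndarray, widths: np.ndarray) -> np.ndarray:
    """Run the bubble growth loop on a square-aspect-scaled signal."""
    n = scaled.size
    baseline = np.zeros(n)
    stack = [(0, n - 1)]
    while stack:
        l, r = stack.pop()
        if r - l < widths[(l + r) // 2]:
            continue
        if l == 0 and r == n - 1:
            anchored = "none"
        elif l == 0:
            anchored = "left_edge"
        elif r == n - 1:
            anchored = "right_edge"
        else:
            anchored = "none"
        arc, contact = bubble_lift(scaled, l, r, anchored)
        np.maximum(baseline[l:r + 1], arc, out=baseline[l:r + 1])
        if contact == l:
            if r - (l + 1) >= 1:
                stack.append((l + 1, r))
        elif contact == r:
            if (r - 1) - l >= 1:
                stack.append((l, r - 1))
        else:
            stack.append((l, contact))
            stack.append((contact, r))
    return baseline


def bubblefill(spec: Spectrum, params: BubbleParams | None = None) -> BaselineFit:
    """Morphological baseline removal by recursive bubble growth."""
    if params is None:
        params = BubbleParams()
    s = spec.intensity
    n = s.size
    if n < 8:
        raise ValueError("bubblefill needs at least 8 samples")
    if s.max() == s.min():
        # degenerate constant input: the signal is its own baseline
        return BaselineFit(s.copy(), np.zeros(n), "bubblefill",
                           _bubble_param_dict(params))
    widths = params.width_samples(n)
    x = np.arange(n, dtype=float)
    trend = Polynomial.fit(x, s, params.slope_order)(x)
    detrended = s - trend
    lo, hi = detrended.min(), detrended.max()
    yrange = hi - lo
    if yrange == 0:
        # degenerate constant residual: the input is its own baseline
        return BaselineFit(s.copy(), np.zeros(n), "bubblefill",
                           _bubble_param_dict(params))
    # square aspect ratio: y rescaled to span [0, n-1] like the x index
    scale = (n - 1) / yrange
    scaled = (detrended - lo) * scale
    raw_baseline = _grow_bubbles(scaled, widths)
    # bubbles grow underneath the signal: B <= S before smoothing
    assert np.all(raw_baseline <= scaled + 1e-9 * (n - 1))
    baseline = raw_baseline / scale + lo + trend
    window = params.smooth_window
    if window is None:
        # twice the minimum bubble width works well: wide enough to diffuse
        # the narrow ridges left where arcs met the signal on peak flanks
        window = max((2 * int(widths.min())) | 1, 5)
    window = min(window, n if n % 2 == 1 else n - 1)
    polyorder = min(params.smooth_polyorder, window - 1)
    baseline = savgol_filter(baseline, window, polyorder)
    return BaselineFit(baseline, s - baseline, "bubblefill",
                       _bubble_param_dict(params))


def _bubble_param_dict(params: BubbleParams) -> dict:
    mw = params.min_width
    if isinstance(mw, np.ndarray):
        mw = mw.tolist()
    return {
        "min_width": mw,
        "slope_order": params.slope_order,
        "smooth_window": params.smooth_window,
        "smooth_polyorder": params.smooth_polyorder,
    }


def imodpoly(spec: Spectrum, order: int = 5, tol: float = 0.05,
             max_iter: int = 100) -> BaselineFit:
    """Iterative modified polynomial baseline fitting.

    Fit a polynomial of the given order, clip the signal to ``fit + DEV``
    (DEV = residual standard deviation) to progressively reject peaks, and
    repeat until the relative DEV change drops below ``tol`` or ``max_iter``
    is reached (``converged=False`` in that case).
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    s = spec.intensity
    if s.size <= order + 1:
        raise ValueError("spectrum too short for the requested order")
    x = spec.axis
    y = s.copy()
    prev_dev = None
    converged = False
    fit = y
    for _ in range(max_iter):
        fit = Polynomial.fit(x, y, order)(x)
        dev = float(np.std(y - fit))
        if dev == 0 or (prev_dev is not None
                        and abs(dev - prev_dev) / dev < tol):
            converged = True
            break
        y = np.minimum(y, fit + dev)
        prev_dev = dev
    return BaselineFit(fit, s - fit, "imodpoly",
                       {"order": order, "tol": tol, "max_iter": max_iter},
                       converged=converged)


def morphbr(spec: Spectrum, window: int = 101,
            variant: str = "half_sum") -> BaselineFit:
    """Morphological baseline removal with a flat structuring element.

    The opening (dilation of the erosion) removes peaks narrower than the
    window; ``variant="half_sum"`` (default) then takes
    ``baseline = min(opening, (erosion(opening) + dilation(opening)) / 2)``
    to soften the opening's flat plateaus, while ``variant="opening"`` keeps
    the plain opening. Window edges are handled with nearest-value padding,
    equivalent to shrinking the window at the boundaries.
    """
    s = spec.intensity
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if not 3 <= window < s.size:
        raise ValueError(f"window must satisfy 3 <= window < {s.size}")
    if variant not in ("half_sum", "opening"):
        raise ValueError("variant must be 'half_sum' or 'opening'")
    erosion = grey_erosion(s, size=window, mode="nearest")
    opening = grey_dilation(erosion, size=window, mode="nearest")
    if variant == "half_sum":
        half = (grey_erosion(opening, size=window, mode="nearest")
                + grey_dilation(opening, size=window, mode="nearest")) / 2.0
        baseline = np.minimum(opening, half)
    else:
        baseline = opening
    return BaselineFit(baseline, s - baseline, "morphbr",
                       {"window": window, "variant": variant})
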