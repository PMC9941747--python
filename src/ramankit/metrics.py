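"""Smoothing, normalization and spectral-quality metrics.

The quality score used throughout is the average signed squared intensity
(ASSI): the input is SNV-normalized, each sample is mapped to
``sgn(r) * r**2`` and the mean is taken. The score is bounded in [-1, 1],
is invariant under positive affine transforms of the input, is ~0 for pure
stochastic noise and grows with few large narrow peaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import Spectrum

__all__ = [
    "QualityReport",
    "smooth_moving_average",
    "normalize_minmax",
    "snv",
    "snv_vector",
    "rbr",
    "assi",
    "assi_vector",
    "quality_tiers",
]


@dataclass(frozen=True)
class QualityReport:
    """Per-spectrum quality summary; ``tier`` is assigned in batch context."""

    assi: float
    rbr: float | None = None
    tier: str = "none"

    def __post_init__(self):
        if not -1.0 <= self.assi <= 1.0:
            raise ValueError("assi must lie in [-1, 1]")
        if self.rbr is not None and self.rbr < 0:
            raise ValueError("rbr must be >= 0")
        if self.tier not in ("high", "average", "low", "none"):
            raise ValueError("tier must be high/average/low/none")


def smooth_moving_average(spec: Spectrum, window: int) -> Spectrum:
    """Centered moving mean; the window shrinks symmetrically at the edges."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window >= len(spec):
        raise ValueError("window must be smaller than the spectrum length")
    return spec.replace_intensity(moving_average(spec.intensity, window))


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving mean of a vector with edge shrinkage."""
    values = np.asarray(values, dtype=float)
    n = values.size
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(values)))
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def normalize_minmax(spec: Spectrum, anchor_shift: float | None = None) -> Spectrum:
    """Scale so the minimum is 0 and the maximum (or the intensity at
    ``anchor_shift``) is 1."""
    s = spec.intensity
    lo = s.min()
    if anchor_shift is None:
        denom = s.max() - lo
    else:
        i = int(np.argmin(np.abs(spec.axis - anchor_shift)))
        denom = s[i] - lo
    if denom == 0:
        raise ValueError("cannot min-max normalize a constant spectrum "
                         "(or anchor at the minimum)")
    return spec.replace_intensity((s - lo) / denom)


def snv_vector(values: np.ndarray) -> np.ndarray:
    """Standard normal variate of a vector: (s - mean) / populationSD."""
    values = np.asarray(values, dtype=float)
    mean = values.mean()
    sd = np.sqrt(np.mean((values - mean) ** 2))  # population (1/N) SD
    if sd == 0:
        raise ValueError("SNV is undefined for a constant signal")
    return (values - mean) / sd


def snv(spec: Spectrum) -> Spectrum:
    """Standard-normal-variate normalization: output mean 0, population SD 1."""
    return spec.replace_intensity(snv_vector(spec.intensity))


def rbr(raman: np.ndarray, baseline: np.ndarray) -> float:
    """Raman-to-baseline ratio: max(raman) / max(baseline)."""
    raman = np.asarray(raman, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    bmax = baseline.max()
    if bmax <= 0:
        raise ValueError("baseline maximum must be positive")
    return float(raman.max() / bmax)


def assi_vector(values: np.ndarray) -> float:
    """Average signed squared intensity of a vector (see module docstring)."""
    r = snv_vector(values)
    return float(np.mean(np.sign(r) * r**2))


def assi(spec: Spectrum) -> float:
    """Average signed squared intensity of a spectrum; bounded in [-1, 1]."""
    return assi_vector(spec.intensity)


def quality_tiers(batch: list[Spectrum], fits=None) -> list[QualityReport]:
    """Rank a batch by ASSI into high / average / low tiers.

    The top 20% by ASSI are "high", the bottom 20% "low" and the 40th-60th
    percentile band "average"; everything else gets tier "none". Ties break
    by input order (stable sort). When ``fits`` (matching list of
    :class:`~ramankit.types.BaselineFit`) is given, the per-spectrum RBR is
    reported as well.
    """
    if len(batch) < 5:
        raise ValueError("quality tiering needs a batch of at least 5 spectra")
    if fits is not None and len(fits) != len(batch):
        raise ValueError("fits must match the batch length")
    n = len(batch)
    scores = [assi(s) for s in batch]
    order = np.argsort(scores, kind="stable")  # ascending ASSI
    k = max(1, int(n * 0.2))
    tiers = ["none"] * n
    for pos in order[:k]:
        tiers[pos] = "low"
    for pos in order[n - k:]:
        tiers[pos] = "high"
    mid_lo = int(n * 0.4)
    mid_hi = int(n * 0.6)
    for pos in order[mid_lo:mid_hi]:
        if tiers[pos] == "none":
            tiers[pos] = "average"
    reports = []
    for i in range(n):
        r = None
        if fits is not None:
            r = rbr(fits[i].raman, fits[i].baseline)
        reports.append(QualityReport(assi=scores[i], rbr=r, tier=tiers[i]))
    return reports
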