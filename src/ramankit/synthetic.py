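"""Synthetic benchmark spectra and the baseline-algorithm comparison sweeps.

A benchmark spectrum mixes a unit-max Raman component R (sum of Gaussians),
a unit-max baseline component B and Gaussian noise:

    S = (sbr * R + B) / max(sbr * R + B) + N(0, noise_sigma**2)

Because both components are max-normalized, the ``sbr`` knob equals the
realized Raman-to-baseline ratio (RBR) of the noiseless mixture. The
measured components the original benchmark used are unpublished, so this
module ships parameterized analogs: peak presets ("tylenol_like" dense,
"nylon_like" moderate, "pdms_like" sparse) and two baseline morphologies
("smooth" single broad hump, "bumpy" several localized humps). Benchmark
numbers are therefore trend-level, not value-level, reproductions.

Algorithms are compared by normalized mean squared error against the Raman
contribution actually present in the spectrum, with each algorithm swept
over its tuning grid and scored at its best ("best-case scenario" tuning).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .baseline import BubbleParams, bubblefill, imodpoly, morphbr
from .metrics import moving_average
from .types import BenchmarkResult, RawAcquisition, Spectrum, SyntheticSpec

__all__ = [
    "PeakModel",
    "BaselineModel",
    "PEAK_PRESETS",
    "BASELINE_PRESETS",
    "make_raman_component",
    "make_baseline_component",
    "generate_spectrum",
    "inject_cosmic_rays",
    "nmse",
    "default_tuning_grids",
    "sweep_benchmark",
    "rbr_curve",
]


@dataclass(frozen=True)
class PeakModel:
    """Gaussian peak superposition: centers/widths in axis units (cm^-1)."""

    centers: tuple[float, ...]
    widths: tuple[float, ...]
    amplitudes: tuple[float, ...]

    def __post_init__(self):
        if not (len(self.centers) == len(self.widths) == len(self.amplitudes)):
            raise ValueError("centers, widths and amplitudes must have equal length")
        if len(self.centers) == 0:
            raise ValueError("peak model needs at least one peak")
        if any(w <= 0 for w in self.widths):
            raise ValueError("widths must be positive")
        if any(a <= 0 for a in self.amplitudes):
            raise ValueError("amplitudes must be positive")
        object.__setattr__(self, "centers", tuple(float(c) for c in self.centers))
        object.__setattr__(self, "widths", tuple(float(w) for w in self.widths))
        object.__setattr__(self, "amplitudes", tuple(float(a) for a in self.amplitudes))


# Hand-designed analogs of common reference materials (cm^-1): a dense
# acetaminophen-like table, a moderate nylon-like one and a sparse PDMS-like
# one. Values are plausible band positions, not measured data.
PEAK_PRESETS: Mapping[str, PeakModel] = {
    "tylenol_like": PeakModel(
        centers=(465, 520, 575, 651, 710, 797, 857, 912, 968, 1045, 1105,
                 1168, 1236, 1296, 1371, 1440, 1515, 1590, 1648),
        widths=(5, 4, 6, 5, 6, 5, 5, 4, 6, 5, 5, 6, 5, 6, 5, 6, 5, 6, 7),
        amplitudes=(0.5, 0.35, 0.3, 0.75, 0.3, 0.55, 1.0, 0.7, 0.4, 0.35,
                    0.35, 0.45, 0.8, 0.35, 0.9, 0.4, 0.3, 0.55, 0.6),
    ),
    "nylon_like": PeakModel(
        centers=(635, 932, 1063, 1128, 1235, 1296, 1370, 1440, 1635),
        widths=(8, 7, 6, 7, 9, 7, 8, 10, 9),
        amplitudes=(0.3, 0.55, 0.6, 0.5, 0.35, 0.85, 0.3, 1.0, 0.45),
    ),
    "pdms_like": PeakModel(
        centers=(488, 618, 709, 789, 1262, 1412),
        widths=(7, 6, 6, 8, 7, 9),
        amplitudes=(1.0, 0.35, 0.75, 0.3, 0.6, 0.4),
    ),
}


@dataclass(frozen=True)
class BaselineModel:
    """Control parameters for synthetic baseline morphologies.

    ``kind="smooth"`` produces one broad monotone-ish fluorescence hump
    (nigrosin-like); ``kind="bumpy"`` superposes several overlapping humps
    yielding localized bumps on a broad pedestal (aluminium-substrate-like).
    The curve is finished with a moving-average polish of width
    ``smoothing_window`` — useful when a model is fitted over measured,
    noise-bearing curves; for purely parametric bumps a wide polish flattens
    the ridge tops the morphology is meant to exercise, so the bumpy preset
    below keeps it minimal.
    """

    kind: str = "smooth"
    n_bumps: int = 6
    bump_width_range: tuple[float, float] = (0.01, 0.03)  # fraction of span
    bump_amp_range: tuple[float, float] = (0.35, 1.0)
    smoothing_window: int = 50

    def __post_init__(self):
        if self.kind not in ("smooth", "bumpy"):
            raise ValueError("kind must be 'smooth' or 'bumpy'")
        if self.n_bumps < 1:
            raise ValueError("n_bumps must be >= 1")


# Benchmark analogs of the measured reference baselines: a smooth decaying
# fluorescence curve and a sharply bumpy substrate-like curve.
BASELINE_PRESETS: Mapping[str, BaselineModel] = {
    "nigrosin_like": BaselineModel(kind="smooth"),
    "aluminium_like": BaselineModel(
        kind="bumpy", n_bumps=10, bump_width_range=(0.008, 0.018),
        bump_amp_range=(0.5, 1.0), smoothing_window=5),
}


def _gaussian(x, center, sigma):
    return np.exp(-0.5 * ((x - center) / sigma) ** 2)


def make_raman_component(peaks: PeakModel, axis) -> np.ndarray:
    """Sum of Gaussian peaks on ``axis``, max-normalized to 1."""
    axis = np.asarray(axis, dtype=float)
    if axis.size < 2 or not np.all(np.diff(axis) > 0):
        raise ValueError("axis must be increasing with >= 2 samples")
    curve = np.zeros_like(axis)
    for c, w, a in zip(peaks.centers, peaks.widths, peaks.amplitudes):
        curve += a * _gaussian(axis, c, w)
    peak = curve.max()
    if peak == 0:
        raise ValueError("no peak falls on the given axis")
    return curve / peak


def make_baseline_component(model: BaselineModel, axis, seed: int) -> np.ndarray:
    """Nonnegative smooth baseline curve on ``axis``, max-normalized to 1.

    Deterministic for a given (model, axis, seed) triple.
    """
    axis = np.asarray(axis, dtype=float)
    rng = np.random.default_rng(seed)
    span = axis[-1] - axis[0]
    if model.kind == "smooth":
        # broad decaying hump anchored before the axis start
        center = axis[0] - span * rng.uniform(0.05, 0.3)
        sigma = span * rng.uniform(0.5, 0.9)
        curve = _gaussian(axis, center, sigma)
        curve += 0.05 * _gaussian(axis, axis[0] + span * rng.uniform(0.3, 0.7),
                                  span * 0.6)
    else:
        # decaying fluorescence edge plus stratified localized bumps
        curve = 0.3 * _gaussian(axis, axis[0] - span * 0.05, span * 0.15)
        edges = np.linspace(axis[0], axis[-1], model.n_bumps + 1)
        for i in range(model.n_bumps):
            center = rng.uniform(edges[i], edges[i + 1])
            sigma = span * rng.uniform(*model.bump_width_range)
            amp = rng.uniform(*model.bump_amp_range)
            curve += amp * _gaussian(axis, center, sigma)
    window = min(model.smoothing_window, axis.size - 1)
    if window > 1:
        curve = moving_average(curve, window | 1)
    curve = np.clip(curve, 0.0, None)
    return curve / curve.max()


def generate_spectrum(raman, baseline, sbr: float, noise_sigma: float,
                      seed: int, axis=None) -> SyntheticSpec:
    """Mix components into a benchmark spectrum (see module docstring)."""
    raman = np.asarray(raman, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if raman.size != baseline.size:
        raise ValueError("raman and baseline lengths differ")
    mixture = sbr * raman + baseline
    peak = mixture.max()
    if peak <= 0:
        raise ValueError("mixture is identically zero; nothing to normalize")
    clean = mixture / peak
    noise = np.random.default_rng(seed).normal(0.0, noise_sigma, raman.size) \
        if noise_sigma > 0 else np.zeros(raman.size)
    return SyntheticSpec(
        raman_target=raman,
        baseline_component=baseline,
        noise_sigma=noise_sigma,
        sbr=sbr,
        seed=seed,
        spectrum=clean + noise,
        axis=axis,
    )


def inject_cosmic_rays(acq: RawAcquisition, n_spikes: int, amplitude: float,
                       width_px=3, seed: int = 0):
    """Add sharp positive spikes to random (accumulation, pixel) loci.

    ``width_px`` is an int or an inclusive (lo, hi) range in 1..5 sampled per
    spike. Spikes are disjoint within each accumulation. Returns the spiked
    acquisition and a truth list of ``(accumulation, (start, stop))`` entries
    (half-open pixel ranges).
    """
    if n_spikes < 0:
        raise ValueError("n_spikes must be >= 0")
    rng = np.random.default_rng(seed)
    if isinstance(width_px, (tuple, list)):
        wlo, whi = int(width_px[0]), int(width_px[1])
    else:
        wlo = whi = int(width_px)
    if not 1 <= wlo <= whi <= 5:
        raise ValueError("width_px must lie in 1..5")
    acc = acq.accumulations.copy()
    n_acc, n_pix = acc.shape
    truth = []
    occupied = [np.zeros(n_pix, dtype=bool) for _ in range(n_acc)]
    attempts = 0
    while len(truth) < n_spikes:
        attempts += 1
        if attempts > 200 * max(n_spikes, 1):
            raise ValueError("could not place the requested number of spikes")
        a = int(rng.integers(n_acc))
        w = int(rng.integers(wlo, whi + 1))
        start = int(rng.integers(0, n_pix - w + 1))
        lo = max(start - 2, 0)
        hi = min(start + w + 2, n_pix)  # keep loci separated by a margin
        if occupied[a][lo:hi].any():
            continue
        occupied[a][lo:hi] = True
        shape = _gaussian(np.arange(w), (w - 1) / 2.0, max(w / 4.0, 0.5))
        acc[a, start:start + w] += amplitude * shape / shape.max()
        truth.append((a, (start, start + w)))
    return acq.replace(accumulations=acc), truth


def nmse(raman_computed, raman_target) -> float:
    """Normalized MSE: sum((Rt - Rc)**2) / (sum(Rt))**2."""
    rc = np.asarray(raman_computed, dtype=float)
    rt = np.asarray(raman_target, dtype=float)
    if rc.size != rt.size:
        raise ValueError("vectors must have equal length")
    total = rt.sum()
    if total == 0:
        raise ValueError("target sum is zero; nMSE undefined")
    return float(np.sum((rt - rc) ** 2) / total**2)


def default_tuning_grids(n_pix: int) -> dict:
    """Default tuning-parameter grids for the three algorithms.

    BubbleFill and MorphBR sweep the same set of physical widths (given as
    axis-span fractions and odd sample windows respectively); iModPoly
    sweeps the polynomial order.
    """
    fractions = (0.009, 0.013, 0.017, 0.023, 0.029, 0.041, 0.06, 0.09, 0.13)
    windows = sorted({max(3, (int(f * n_pix) | 1)) for f in fractions})
    return {
        "bubblefill": fractions,  # min_width as fraction of span
        "morphbr": tuple(w for w in windows if w < n_pix),
        "imodpoly": (3, 4, 5, 6, 7, 8),  # polynomial order
    }


def _run_algorithm(name: str, spec: Spectrum, param):
    if name == "bubblefill":
        return bubblefill(spec, BubbleParams(min_width=param))
    if name == "morphbr":
        return morphbr(spec, window=int(param))
    if name == "imodpoly":
        return imodpoly(spec, order=int(param))
    raise ValueError(f"unknown algorithm '{name}'")


def sweep_benchmark(spec: SyntheticSpec,
                    algorithms: Sequence[str] = ("bubblefill", "morphbr", "imodpoly"),
                    tuning_grids: Mapping[str, Sequence] | None = None) -> dict:
    """Run every algorithm at every tuning grid point on one synthetic
    spectrum and score it against the known Raman contribution.

    Returns ``{algorithm: {"grid": ..., "nmse": ..., "best_param": ...,
    "best_nmse": ...}}``; a failing grid point scores +inf instead of
    aborting the sweep.
    """
    if tuning_grids is None:
        tuning_grids = default_tuning_grids(spec.spectrum.size)
    target = spec.raman_in_spectrum
    s = spec.to_spectrum()
    out = {}
    for name in algorithms:
        grid = tuple(tuning_grids[name])
        if not grid:
            raise ValueError(f"empty tuning grid for '{name}'")
        errors = []
        for param in grid:
            try:
                fit = _run_algorithm(name, s, param)
                errors.append(nmse(fit.raman, target))
            except Exception:
                errors.append(float("inf"))
        best = int(np.argmin(errors))
        out[name] = {
            "grid": grid,
            "nmse": tuple(errors),
            "best_param": grid[best],
            "best_nmse": errors[best],
        }
    return out


def rbr_curve(raman_kind: str, baseline_kind: str, rbr_grid,
              algorithms: Sequence[str] = ("bubblefill", "morphbr", "imodpoly"),
              noise_sigma: float = 0.0, seeds: Sequence[int] = (0,),
              axis=None, tuning_grids: Mapping[str, Sequence] | None = None,
              baseline_model: BaselineModel | None = None) -> BenchmarkResult:
    """Mean best-case nMSE per algorithm across an RBR grid and seeds.

    ``raman_kind`` names a peak preset; ``baseline_kind`` is "smooth" or
    "bumpy". Each seed draws a fresh baseline realization and noise vector.
    """
    rbr_grid = np.asarray(rbr_grid, dtype=float)
    if rbr_grid.size == 0 or len(seeds) == 0:
        raise ValueError("rbr_grid and seeds must be non-empty")
    if axis is None:
        axis = np.linspace(400.0, 1800.0, 1000)
    axis = np.asarray(axis, dtype=float)
    if baseline_model is None:
        preset = "aluminium_like" if baseline_kind == "bumpy" else "nigrosin_like"
        baseline_model = BASELINE_PRESETS[preset]
    raman = make_raman_component(PEAK_PRESETS[raman_kind], axis)
    if tuning_grids is None:
        tuning_grids = default_tuning_grids(axis.size)
    matrix = np.zeros((len(algorithms), rbr_grid.size))
    records = []
    for j, sbr in enumerate(rbr_grid):
        sums = np.zeros(len(algorithms))
        for seed in seeds:
            base = make_baseline_component(baseline_model, axis, seed)
            spec = generate_spectrum(raman, base, sbr, noise_sigma, seed, axis=axis)
            result = sweep_benchmark(spec, algorithms, tuning_grids)
            for i, name in enumerate(algorithms):
                sums[i] += result[name]["best_nmse"]
                records.append((name, float(sbr), int(seed),
                                result[name]["best_param"],
                                result[name]["best_nmse"]))
        matrix[:, j] = sums / len(seeds)
    return BenchmarkResult(
        algorithms=tuple(algorithms),
        rbr_grid=rbr_grid,
        tuning_grids={k: tuple(v) for k, v in tuning_grids.items()},
        nmse=matrix,
        records=tuple(records),
    )
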