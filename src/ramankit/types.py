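"""Core domain types shared by every processing stage.

All containers are immutable by convention: operations never modify the
arrays they receive and always return freshly allocated objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

from .errors import DimensionError

AXIS_KINDS = ("pixel", "shift")
BASELINE_ALGORITHMS = ("bubblefill", "morphbr", "imodpoly")


def _as_float_vector(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise DimensionError(f"{name} must be a 1-D vector, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class Spectrum:
    """A single spectrum: one axis vector plus one intensity vector.

    Parameters
    ----------
    axis
        Strictly increasing vector — camera-pixel index (``axis_kind="pixel"``)
        or Raman shift in cm^-1 (``axis_kind="shift"``).
    intensity
        Detector counts or normalized units, same length as ``axis``.
    axis_kind
        Either ``"pixel"`` or ``"shift"``.
    metadata
        Free-form key/value map carried through the pipeline.
    """

    axis: np.ndarray
    intensity: np.ndarray
    axis_kind: str = "pixel"
    metadata: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        axis = _as_float_vector(self.axis, "axis")
        intensity = _as_float_vector(self.intensity, "intensity")
        if axis.size != intensity.size:
            raise DimensionError(
                f"axis ({axis.size}) and intensity ({intensity.size}) lengths differ"
            )
        if axis.size < 2:
            raise ValueError("a spectrum needs at least 2 samples")
        if not np.all(np.diff(axis) > 0):
            raise ValueError("axis must be strictly increasing")
        if self.axis_kind not in AXIS_KINDS:
            raise ValueError(f"axis_kind must be one of {AXIS_KINDS}")
        axis.setflags(write=False)
        intensity.setflags(write=False)
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "intensity", intensity)
        object.__setattr__(self, "metadata", dict(self.metadata))

    def __len__(self) -> int:
        return self.intensity.size

    def replace_intensity(self, intensity, **meta_updates) -> "Spectrum":
        """Return a copy with a new intensity vector (axis unchanged)."""
        metadata = {**self.metadata, **meta_updates}
        return Spectrum(self.axis, intensity, self.axis_kind, metadata)


@dataclass(frozen=True)
class RawAcquisition:
    """One acquisition site: accumulation matrix + optional background.

    ``accumulations`` is an ``n_acc x n_pix`` matrix of detector counts,
    ``background`` (when present) a length ``n_pix`` vector measured with the
    excitation source off. Exposure times are in seconds.
    """

    accumulations: np.ndarray
    background: np.ndarray | None = None
    exposure_acq: float = 1.0
    exposure_bg: float = 1.0
    axis: np.ndarray | None = None
    axis_kind: str = "pixel"
    metadata: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        acc = np.asarray(self.accumulations, dtype=float)
        if acc.ndim == 1:
            acc = acc[None, :]
        if acc.ndim != 2:
            raise DimensionError(
                f"accumulations must be 2-D (n_acc x n_pix), got shape {acc.shape}"
            )
        acc.setflags(write=False)
        object.__setattr__(self, "accumulations", acc)
        if self.background is not None:
            bg = _as_float_vector(self.background, "background")
            if bg.size != acc.shape[1]:
                raise DimensionError(
                    f"background length {bg.size} != accumulation length {acc.shape[1]}"
                )
            bg.setflags(write=False)
            object.__setattr__(self, "background", bg)
        if self.exposure_acq <= 0 or self.exposure_bg <= 0:
            raise ValueError("exposure times must be positive")
        if self.axis is not None:
            ax = _as_float_vector(self.axis, "axis")
            if ax.size != acc.shape[1]:
                raise DimensionError("axis length does not match accumulations")
            ax.setflags(write=False)
            object.__setattr__(self, "axis", ax)
        if self.axis_kind not in AXIS_KINDS:
            raise ValueError(f"axis_kind must be one of {AXIS_KINDS}")
        object.__setattr__(self, "metadata", dict(self.metadata))

    @property
    def n_acc(self) -> int:
        return self.accumulations.shape[0]

    @property
    def n_pix(self) -> int:
        return self.accumulations.shape[1]

    def pixel_axis(self) -> np.ndarray:
        if self.axis is not None:
            return self.axis
        return np.arange(self.n_pix, dtype=float)

    def replace(self, **changes) -> "RawAcquisition":
        fields = dict(
            accumulations=self.accumulations,
            background=self.background,
            exposure_acq=self.exposure_acq,
            exposure_bg=self.exposure_bg,
            axis=self.axis,
            axis_kind=self.axis_kind,
            metadata=self.metadata,
        )
        fields.update(changes)
        return RawAcquisition(**fields)


@dataclass(frozen=True)
class BaselineFit:
    """Decomposition of a spectrum into baseline + Raman components.

    The invariant ``baseline + raman == input`` holds exactly because the
    Raman part is always computed as ``input - baseline``.
    """

    baseline: np.ndarray
    raman: np.ndarray
    algorithm: str
    params: Mapping[str, Any] = field(default_factory=dict)
    converged: bool = True

    def __post_init__(self):
        baseline = _as_float_vector(self.baseline, "baseline")
        raman = _as_float_vector(self.raman, "raman")
        if baseline.size != raman.size:
            raise DimensionError("baseline and raman lengths differ")
        if self.algorithm not in BASELINE_ALGORITHMS:
            raise ValueError(f"algorithm must be one of {BASELINE_ALGORITHMS}")
        baseline.setflags(write=False)
        raman.setflags(write=False)
        object.__setattr__(self, "baseline", baseline)
        object.__setattr__(self, "raman", raman)
        object.__setattr__(self, "params", dict(self.params))

    def reconstruct(self) -> np.ndarray:
        """Return baseline + raman (the original input, exactly)."""
        return self.baseline + self.raman


@dataclass(frozen=True)
class SyntheticSpec:
    """One synthetic benchmark spectrum with its generating components.

    ``spectrum = (sbr * raman_target + baseline_component) / M + noise`` with
    ``M = max(sbr * raman_target + baseline_component)`` and Gaussian noise of
    standard deviation ``noise_sigma`` drawn from ``seed``. The components are
    retained so recovery error stays computable.
    """

    raman_target: np.ndarray
    baseline_component: np.ndarray
    noise_sigma: float
    sbr: float
    seed: int
    spectrum: np.ndarray
    axis: np.ndarray | None = None

    def __post_init__(self):
        r = _as_float_vector(self.raman_target, "raman_target")
        b = _as_float_vector(self.baseline_component, "baseline_component")
        s = _as_float_vector(self.spectrum, "spectrum")
        if not (r.size == b.size == s.size):
            raise DimensionError("component vectors must have equal length")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.sbr < 0:
            raise ValueError("sbr must be >= 0")
        for name, arr in (("raman_target", r), ("baseline_component", b), ("spectrum", s)):
            arr.setflags(write=False)
            object.__setattr__(self, name, arr)
        if self.axis is not None:
            ax = _as_float_vector(self.axis, "axis")
            if ax.size != s.size:
                raise DimensionError("axis length does not match spectrum")
            ax.setflags(write=False)
            object.__setattr__(self, "axis", ax)

    @property
    def mixture_max(self) -> float:
        """Normalization constant M = max(sbr*R + B)."""
        return float(np.max(self.sbr * self.raman_target + self.baseline_component))

    @property
    def raman_in_spectrum(self) -> np.ndarray:
        """The Raman contribution on the spectrum's normalized scale."""
        return self.sbr * self.raman_target / self.mixture_max

    @property
    def baseline_in_spectrum(self) -> np.ndarray:
        """The baseline contribution on the spectrum's normalized scale."""
        return self.baseline_component / self.mixture_max

    def to_spectrum(self) -> Spectrum:
        axis = self.axis if self.axis is not None else np.arange(self.spectrum.size, dtype=float)
        kind = "shift" if self.axis is not None else "pixel"
        return Spectrum(axis, self.spectrum, kind, {"sbr": self.sbr, "seed": self.seed})


@dataclass(frozen=True)
class BenchmarkResult:
    """Best-case nMSE per algorithm over an RBR sweep.

    ``nmse`` is an ``n_algorithms x n_rbr`` matrix of best-case (tuning-swept,
    seed-averaged) errors; ``records`` retains every individual grid point as
    ``(algorithm, rbr, seed, param, nmse)`` tuples for inspection.
    """

    algorithms: tuple[str, ...]
    rbr_grid: np.ndarray
    tuning_grids: Mapping[str, tuple]
    nmse: np.ndarray
    records: tuple = ()

    def __post_init__(self):
        grid = _as_float_vector(self.rbr_grid, "rbr_grid")
        nmse = np.asarray(self.nmse, dtype=float)
        if nmse.shape != (len(self.algorithms), grid.size):
            raise DimensionError(
                f"nmse shape {nmse.shape} != (n_algorithms={len(self.algorithms)}, "
                f"n_rbr={grid.size})"
            )
        finite = nmse[np.isfinite(nmse)]
        if finite.size and np.any(finite < 0):
            raise ValueError("nMSE values must be nonnegative")
        grid.setflags(write=False)
        nmse.setflags(write=False)
        object.__setattr__(self, "rbr_grid", grid)
        object.__setattr__(self, "nmse", nmse)
        object.__setattr__(self, "algorithms", tuple(self.algorithms))
        object.__setattr__(self, "tuning_grids", dict(self.tuning_grids))

    def best_nmse(self, algorithm: str) -> np.ndarray:
        return self.nmse[self.algorithms.index(algorithm)]
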