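"""End-to-end pipeline driver: raw acquisitions -> truncation/cosmic-ray
removal -> background + calibration -> baseline removal -> SNV, with batch
averaging and a quality report.

Stage composition is strictly equal to calling the module operations in the
same order — the driver holds no hidden state. Stages operating on single
spectra automatically combine accumulations first (arithmetic mean) when the
current state is still a raw acquisition.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np

from . import baseline as _baseline
from . import calibrate as _calibrate
from . import metrics as _metrics
from . import preprocess as _preprocess
from .errors import FormatError
from .types import RawAcquisition, Spectrum

logger = logging.getLogger("ramankit.pipeline")

__all__ = ["StageConfig", "PipelineConfig", "PipelineResult", "run_pipeline"]

# stage name -> (allowed parameter keys, operates on raw acquisitions?)
_STAGE_REGISTRY: dict[str, tuple[set, bool]] = {
    "truncate": ({"cut_low", "cut_high"}, True),
    "crfilter_single": ({"threshold_mads", "widen_px"}, False),
    "crfilter_multi": ({"threshold_mads", "widen_px"}, True),
    "combine": (set(), True),
    "background": (set(), False),
    "apply_irf": ({"irf"}, False),
    "resample": ({"calibration", "grid"}, False),
    "baseline": ({"algo", "min_width", "slope_order", "order", "tol",
                  "max_iter", "window", "variant"}, False),
    "smooth": ({"window"}, False),
    "normalize": ({"anchor_shift"}, False),
    "snv": (set(), False),
}

# (earlier, later) pairs that must appear in this order when both present
_ORDERING = [
    ("truncate", "crfilter_multi"),
    ("truncate", "background"),
    ("crfilter_multi", "background"),
    ("background", "baseline"),
    ("baseline", "snv"),
    ("baseline", "normalize"),
]


@dataclass(frozen=True)
class StageConfig:
    name: str
    params: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in _STAGE_REGISTRY:
            raise ValueError(
                f"unknown stage '{self.name}'; known: {sorted(_STAGE_REGISTRY)}"
            )
        allowed, _ = _STAGE_REGISTRY[self.name]
        unknown = set(self.params) - allowed
        if unknown:
            raise ValueError(
                f"unknown parameter(s) {sorted(unknown)} for stage '{self.name}'"
            )
        object.__setattr__(self, "params", dict(self.params))


@dataclass(frozen=True)
class PipelineConfig:
    """Ordered stage list plus output options; unknown keys are rejected."""

    stages: tuple[StageConfig, ...]
    output_dir: str | None = None
    save_intermediate: bool = False

    def __post_init__(self):
        stages = tuple(
            s if isinstance(s, StageConfig) else StageConfig(**s) for s in self.stages
        )
        names = [s.name for s in stages]
        for earlier, later in _ORDERING:
            if earlier in names and later in names:
                if names.index(earlier) > names.index(later):
                    raise ValueError(
                        f"stage '{earlier}' must come before '{later}'"
                    )
        object.__setattr__(self, "stages", stages)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        known = {"stages", "output_dir", "save_intermediate"}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config key(s): {sorted(unknown)}")
        if "stages" not in data:
            raise FormatError("missing field 'stages' in pipeline config")
        return cls(
            stages=tuple(StageConfig(s["name"], s.get("params", {}))
                         for s in data["stages"]),
            output_dir=data.get("output_dir"),
            save_intermediate=bool(data.get("save_intermediate", False)),
        )

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class PipelineResult:
    processed: list[Spectrum]
    stage_outputs: dict[str, list]
    quality: list[_metrics.QualityReport] | None
    average: np.ndarray | None
    sd: np.ndarray | None


def _ensure_spectrum(state, acq_ref):
    """Combine accumulations if the state is still a raw acquisition."""
    if isinstance(state, RawAcquisition):
        return _preprocess.combine_accumulations(state), state
    return state, acq_ref


def _apply_stage(stage: StageConfig, state, acq_ref):
    p = stage.params
    name = stage.name
    if name == "truncate":
        return _preprocess.truncate(state, p.get("cut_low", 0), p.get("cut_high")), acq_ref
    if name == "crfilter_multi":
        if not isinstance(state, RawAcquisition):
            raise ValueError("crfilter_multi requires raw accumulations")
        out = _preprocess.crfilter_multi(state, **{k: p[k] for k in p})
        return out, out
    if name == "combine":
        if not isinstance(state, RawAcquisition):
            raise ValueError("combine requires raw accumulations")
        return _preprocess.combine_accumulations(state), state
    state, acq_ref = _ensure_spectrum(state, acq_ref)
    if name == "crfilter_single":
        return _preprocess.crfilter_single(state, **p), acq_ref
    if name == "background":
        if acq_ref is None or acq_ref.background is None:
            raise ValueError("no background available for subtraction")
        bg_acq = acq_ref
        if bg_acq.background is not None:
            # filter the background to avoid injecting downward spikes
            bg_spec = Spectrum(bg_acq.pixel_axis(), bg_acq.background,
                               bg_acq.axis_kind)
            clean_bg = _preprocess.crfilter_single(bg_spec).intensity
            bg_acq = bg_acq.replace(background=clean_bg)
        return _preprocess.subtract_background(state, bg_acq), acq_ref
    if name == "apply_irf":
        return _calibrate.apply_irf(state, p["irf"]), acq_ref
    if name == "resample":
        return _calibrate.resample_common_axis(state, p["calibration"], p["grid"]), acq_ref
    if name == "baseline":
        algo = p.get("algo", "bubblefill")
        if algo == "bubblefill":
            params = _baseline.BubbleParams(
                min_width=p.get("min_width", 0.1),
                slope_order=p.get("slope_order", 1))
            fit = _baseline.bubblefill(state, params)
        elif algo == "imodpoly":
            fit = _baseline.imodpoly(state, order=p.get("order", 5),
                                     tol=p.get("tol", 0.05),
                                     max_iter=p.get("max_iter", 100))
        elif algo == "morphbr":
            fit = _baseline.morphbr(state, window=p.get("window", 101),
                                    variant=p.get("variant", "half_sum"))
        else:
            raise ValueError(f"unknown baseline algorithm '{algo}'")
        return state.replace_intensity(fit.raman), acq_ref
    if name == "smooth":
        return _metrics.smooth_moving_average(state, p.get("window", 5)), acq_ref
    if name == "normalize":
        return _metrics.normalize_minmax(state, p.get("anchor_shift")), acq_ref
    if name == "snv":
        return _metrics.snv(state), acq_ref
    raise ValueError(f"unknown stage '{name}'")  # unreachable


def run_pipeline(config: PipelineConfig, inputs: Sequence) -> PipelineResult:
    """Run every input through the configured stages.

    ``inputs`` is a sequence of :class:`Spectrum`/:class:`RawAcquisition`
    objects. Errors abort with the stage name and input index; stage outputs
    collected so far are kept on the raised exception (``partial`` attribute).
    Batch statistics (mean +- SD) are computed when all outputs share one
    axis, and a quality report is attached for batches of >= 5 spectra.
    """
    stage_outputs: dict[str, list] = {s.name: [] for s in config.stages}
    processed: list[Spectrum] = []
    for idx, item in enumerate(inputs):
        state = item
        acq_ref = item if isinstance(item, RawAcquisition) else None
        for stage in config.stages:
            t0 = time.perf_counter()
            try:
                state, acq_ref = _apply_stage(stage, state, acq_ref)
            except Exception as exc:
                err = RuntimeError(
                    f"stage '{stage.name}' failed on input {idx}: {exc}"
                )
                err.partial = stage_outputs
                raise err from exc
            logger.info("input %d stage %s: %.3f ms", idx, stage.name,
                        1e3 * (time.perf_counter() - t0))
            stage_outputs[stage.name].append(state)
        state, _ = _ensure_spectrum(state, acq_ref)
        processed.append(state)

    average = sd = None
    if processed and all(len(s) == len(processed[0]) and
                         np.array_equal(s.axis, processed[0].axis)
                         for s in processed):
        stack = np.vstack([s.intensity for s in processed])
        average = stack.mean(axis=0)
        sd = stack.std(axis=0)
    quality = None
    if len(processed) >= 5:
        try:
            quality = _metrics.quality_tiers(processed)
        except ValueError:
            quality = None
    result = PipelineResult(processed, stage_outputs, quality, average, sd)
    if config.output_dir is not None:
        _persist(config, result)
    return result


def _persist(config: PipelineConfig, result: PipelineResult) -> None:
    from .io import write_spectra

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_spectra(result.processed, out / "processed.json")
    if config.save_intermediate:
        for name, specs in result.stage_outputs.items():
            flat = [s for s in specs if isinstance(s, (Spectrum, RawAcquisition))]
            write_spectra(flat, out / f"stage_{name}.json")
    if result.average is not None and result.processed:
        axis = result.processed[0].axis
        payload = {"axis": axis.tolist(), "average": result.average.tolist(),
                   "sd": result.sd.tolist()}
        with open(out / "average.json", "w") as fh:
            json.dump(payload, fh)
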