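"""Reading and writing the JSON and CSV spectrum formats.

JSON schema (defined by this package — see README): a file holds either one
object or a list of objects. A raw-acquisition object has keys

    accumulations   list of equal-length lists (n_acc x n_pix counts)
    background      list or null
    exposure_acq_s  seconds > 0
    exposure_bg_s   seconds > 0
    axis            optional list
    axis_kind       "pixel" | "shift"
    metadata        object

A plain-spectrum object has keys ``axis``, ``intensity``, ``axis_kind`` and
``metadata``. CSV holds a single spectrum as two comma-separated columns
(axis, intensity) with an optional single header row; the axis kind is
inferred from the header ("shift"/"cm" -> shift, otherwise pixel).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import DimensionError, FormatError
from .types import RawAcquisition, Spectrum

__all__ = ["read_spectra", "write_spectra"]


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in ("json", "csv"):
            raise ValueError("format must be 'json' or 'csv'")
        return format
    return "csv" if path.suffix.lower() == ".csv" else "json"


def _acq_from_obj(obj: dict) -> RawAcquisition:
    for key in ("accumulations", "exposure_acq_s", "exposure_bg_s"):
        if key not in obj:
            raise FormatError(f"missing field '{key}' in raw-acquisition object")
    rows = obj["accumulations"]
    if not rows:
        raise FormatError("'accumulations' must contain at least one row")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise DimensionError(f"ragged accumulation rows (lengths {sorted(lengths)})")
    return RawAcquisition(
        accumulations=np.asarray(rows, dtype=float),
        background=None if obj.get("background") is None else np.asarray(obj["background"], float),
        exposure_acq=float(obj["exposure_acq_s"]),
        exposure_bg=float(obj["exposure_bg_s"]),
        axis=None if obj.get("axis") is None else np.asarray(obj["axis"], float),
        axis_kind=obj.get("axis_kind", "pixel"),
        metadata=obj.get("metadata", {}),
    )


def _spectrum_from_obj(obj: dict) -> Spectrum:
    for key in ("axis", "intensity"):
        if key not in obj:
            raise FormatError(f"missing field '{key}' in spectrum object")
    return Spectrum(
        axis=np.asarray(obj["axis"], dtype=float),
        intensity=np.asarray(obj["intensity"], dtype=float),
        axis_kind=obj.get("axis_kind", "pixel"),
        metadata=obj.get("metadata", {}),
    )


def _obj_from(item) -> dict:
    if isinstance(item, RawAcquisition):
        return {
            "accumulations": item.accumulations.tolist(),
            "background": None if item.background is None else item.background.tolist(),
            "exposure_acq_s": item.exposure_acq,
            "exposure_bg_s": item.exposure_bg,
            "axis": None if item.axis is None else item.axis.tolist(),
            "axis_kind": item.axis_kind,
            "metadata": dict(item.metadata),
        }
    if isinstance(item, Spectrum):
        return {
            "axis": item.axis.tolist(),
            "intensity": item.intensity.tolist(),
            "axis_kind": item.axis_kind,
            "metadata": dict(item.metadata),
        }
    raise TypeError(f"cannot serialize object of type {type(item).__name__}")


def read_spectra(path, format: str | None = None) -> list:
    """Read spectra or raw acquisitions from a JSON or CSV file.

    Returns a list of :class:`Spectrum` and/or :class:`RawAcquisition`
    objects, in file order, with metadata preserved verbatim.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        return [_read_csv(path)]
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"invalid JSON in {path}: {exc}") from exc
    objs = data if isinstance(data, list) else [data]
    out = []
    for obj in objs:
        if not isinstance(obj, dict):
            raise FormatError("each JSON entry must be an object")
        if "accumulations" in obj:
            out.append(_acq_from_obj(obj))
        elif "intensity" in obj:
            out.append(_spectrum_from_obj(obj))
        else:
            raise FormatError("missing field 'accumulations' or 'intensity'")
    return out


def _read_csv(path: Path) -> Spectrum:
    axis, intensity = [], []
    axis_kind = "pixel"
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise FormatError(f"empty CSV file: {path}")
    start = 0
    try:
        float(rows[0][0])
    except (ValueError, IndexError):
        header = ",".join(rows[0]).lower()
        if "shift" in header or "cm" in header:
            axis_kind = "shift"
        start = 1
    for row in rows[start:]:
        if not row:
            continue
        if len(row) < 2:
            raise FormatError(f"CSV rows need 2 columns, got {row!r}")
        axis.append(float(row[0]))
        intensity.append(float(row[1]))
    return Spectrum(np.asarray(axis), np.asarray(intensity), axis_kind)


def write_spectra(objects, path, format: str | None = None) -> None:
    """Write spectra/acquisitions to ``path`` so that :func:`read_spectra`
    round-trips them exactly (floats serialized at full precision)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if isinstance(objects, (Spectrum, RawAcquisition)):
        objects = [objects]
    objects = list(objects)
    if fmt == "csv":
        if len(objects) != 1 or not isinstance(objects[0], Spectrum):
            raise ValueError("CSV output supports exactly one Spectrum")
        _write_csv(objects[0], path)
        return
    payload = [_obj_from(o) for o in objects]
    with open(path, "w") as fh:
        json.dump(payload, fh)


def _write_csv(spec: Spectrum, path: Path) -> None:
    header = ("shift_cm-1", "intensity") if spec.axis_kind == "shift" else ("pixel", "intensity")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for a, i in zip(spec.axis, spec.intensity):
            writer.writerow([repr(float(a)), repr(float(i))])
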