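# ramankit

A Raman spectroscopy preprocessing toolkit for biological samples: cosmic-ray
removal, background subtraction, instrument-response (y-axis) and Raman-shift
(x-axis) calibration, three baseline-removal algorithms centered on the
BubbleFill morphological method, spectral-quality metrics (SNV / ASSI / RBR)
and a synthetic-spectrum benchmark framework for comparing baseline
algorithms by normalized MSE.

## Modules

| module | contents |
| --- | --- |
| `ramankit.types` | `Spectrum`, `RawAcquisition`, `BaselineFit`, `SyntheticSpec`, `BenchmarkResult` |
| `ramankit.io` | JSON/CSV readers and writers (schema below) |
| `ramankit.preprocess` | `truncate`, `crfilter_single`, `crfilter_multi`, `combine_accumulations`, `subtract_background` |
| `ramankit.calibrate` | SRM-based IRF (y-axis) and reference-peak shift calibration (x-axis) |
| `ramankit.baseline` | `bubblefill`, `morphbr`, `imodpoly` |
| `ramankit.metrics` | moving-average smoothing, min-max & SNV normalization, RBR, ASSI, quality tiering |
| `ramankit.synthetic` | synthetic benchmark spectra, cosmic-ray injection, nMSE, best-case tuning sweeps |
| `ramankit.pipeline` / `ramankit.cli` | declarative pipeline driver and the `ramankit` command |

## JSON spectrum schema

This schema is defined by this package (no public standard exists for the
format). A file holds one object or a list. Raw acquisitions:

```json
{
  "accumulations": [[...], [...]],
  "background": [...] ,
  "exposure_acq_s": 2.0,
  "exposure_bg_s": 1.0,
  "axis": null,
  "axis_kind": "pixel",
  "metadata": {}
}
```

Plain spectra carry `axis`, `intensity`, `axis_kind`, `metadata`. CSV files
are two comma-separated columns (axis, intensity) with an optional header.
Pixel indices are 0-based.

## CLI

```bash
# end-to-end preprocessing
ramankit process acq.json --truncate 51 --cr multi --baseline bubblefill --snv -o out.json

# calibration (certificate coefficients are licensed; supply your own)
ramankit calibrate --srm srm.json --certificate cert.json \
                   --reference ref.json --shifts shifts.txt --order 2

# baseline removal only
ramankit baseline spec.json --algo bubblefill --min-width 0.1

# quality report (CSV: id, assi, rbr, tier)
ramankit quality batch.json --tiers -o quality.csv

# synthetic benchmark
ramankit simulate --raman nylon_like --baseline bumpy --sbr 0.05 --seed 7 -o spec.json
ramankit benchmark --algos all --rbr-grid 0.01:0.5:10 --seeds 50 -o result.csv
```

## BubbleFill in one paragraph

The spectrum is detrended with a low-order polynomial and rescaled so both
axes span the same range (square aspect ratio). Circular "bubbles" are then
grown underneath the signal, starting with one spanning the whole axis: each
bubble rises until it touches the signal, the baseline estimate is updated
to the pointwise maximum of itself and the bubble, and the interval splits
at the contact point. Branches stop once their width falls below the minimum
bubble width — the single tuning parameter, which may vary across the x-axis
to protect chosen peak regions. The finished baseline is rescaled,
re-trended and Savitzky–Golay smoothed; the Raman signal is the input minus
the baseline. Smaller minimum widths fit more aggressively.

The exact arc parameterization of the original method is unpublished; this
implementation uses interior half-circles and edge-anchored quarter-circles
of doubled radius (see `ramankit/baseline.py` for the full geometry notes).

## Synthetic benchmarks

`ramankit.synthetic` mixes a unit-max Gaussian-peak Raman component `R`, a
unit-max baseline component `B` and Gaussian noise:

```
S = (sbr*R + B) / max(sbr*R + B) + N(0, sigma^2)
```

Because both components are max-normalized the `sbr` knob equals the
realized Raman-to-baseline ratio. The measured reference components the
original benchmarks used are unpublished, so peak presets (`tylenol_like`,
`nylon_like`, `pdms_like`) and baseline presets (`nigrosin_like` smooth,
`aluminium_like` sharply bumpy) are parameterized analogs; benchmark numbers
are trend-level reproductions. Algorithms are scored by
`nMSE = sum((Rt - Rc)^2) / (sum Rt)^2` at their best tuning over a sweep.

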