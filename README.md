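# thermospread

Measurement of electrosurgical lateral thermal spread from radiometric
thermogram sequences, plus a bioheat-simulation synthetic-data generator so
the whole analysis can be exercised and validated in silico.

The measurement pipeline mirrors a compact-thermal-camera workflow:

1. **thermogram I/O** (`thermospread.io`) — read/write temperature-calibrated
   sequences as CSV directories (`frame_0001.csv`, …) or multi-page 32-bit
   float TIFF stacks, values always in °C, with a `meta.yaml` sidecar for
   frame rate and ambient conditions.
2. **calibration** (`thermospread.calibration`) — convert pixels to mm using
   an in-scene fiducial of known length (two pixel endpoints + length in mm).
3. **spread analysis** (`thermospread.spread`) — segment pixels whose
   temperature strictly exceeds a threshold (default 60 °C) over the **entire
   sequence** (cumulative union), and report the spread area in mm², the
   per-frame area series and the peak temperature.
4. **bioheat simulation** (`thermospread.bioheat`) — explicit finite-difference
   heat diffusion in a ~30×30×20 mm tissue block with a two-prong bipolar
   source, convective/insulated/fixed boundaries, and a mandatory stability
   check (`dt ≤ voxel²/(6α)`).
5. **synthetic cohorts** (`thermospread.cohort`) — render simulated fields
   through a 60×80 microbolometer camera model (10 Hz, NETD 0.1 °C, ±2 °C
   bias budget, saturation at 150 °C) and generate deterministic multi-sample
   cohorts over the 30/60 W × 2/4 s group grid with lognormal physical
   parameter jitter, ground-truth damage area/depth, and an emulated
   macrophotography necrosis area.
6. **statistics** (`thermospread.stats` / `thermospread.report`) — median/IQR,
   two-sided Wilcoxon rank-sum with exact enumeration for n₁+n₂ ≤ 20,
   Spearman correlation on mid-ranks, and OLS fits; all implemented directly
   so small-sample behavior is exact.
7. **pipeline + CLI** (`thermospread.pipeline` / `thermospread.cli`) —
   orchestrate simulate → analyze → report into reproducible run directories.

## CLI

```sh
# full synthetic experiment into runs/run-001/
thermospread full --config examples/run.yaml --seed 1 --out runs

# generate a cohort only (per-sample TIFF stacks + manifest.csv)
thermospread simulate --config examples/run.yaml --out runs

# measure one recorded sequence (CSV dir or float TIFF, °C)
thermospread analyze --input seq.tiff --threshold 60 \
    --calibration cal.yaml --out result.csv

# group summaries / rank tests / correlations / regressions
thermospread report --manifest runs/run-001/spread_results.csv --out report/
```

`cal.yaml` holds either `mm_per_pixel: 1.0` or a fiducial block
(`p1: [r, c]`, `p2: [r, c]`, `known_length_mm: x`). A config file follows the
structure of `thermospread.config.default_config()`; every CLI flag overrides
the file and the resolved config is written into the run directory. Exit code
is 2 on configuration validation failure.

A run directory contains `config_resolved.yaml`, `manifest.csv`,
`spread_results.csv`, `group_summary.csv` (N/median/IQR per group),
`pairwise_tests.csv` (30-vs-60 W within time and 2-vs-4 s within power),
`correlations.csv`, `regression.csv` and `run.log`. Reruns with the same
config are bit-identical apart from log timestamps.

## Conventions

- Pixel values are always °C; readers reject values outside [−40, 400] as
  probable unit errors. Proprietary radiometric containers are not parsed —
  convert to float-TIFF first.
- Images: row 0 is the top, indices 0-based, coordinates at pixel centers.
  Simulation grids are indexed `[z, y, x]` with z = 0 the observed surface;
  depth of layer z is `(z + 0.5)·voxel_mm`.
- Segmentation is strict (`>` threshold) and cumulative over the sequence.
- Quantile convention: linear interpolation at position `p·(n−1)`.

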