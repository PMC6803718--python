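# apotrack

Active-shape-model tracking of the three aponeurosis boundaries in B-mode
ultrasound sequences of the plantar flexors, extraction of muscle thickness
at 20 sites across the stride cycle, and one-dimensional statistical
parametric mapping (SPM) of the resulting thickness-change fields.  Every
stage is exercised end-to-end on synthetic phantom data with known ground
truth, so no imaging data download is required.

## What is in the package

| module | purpose |
| --- | --- |
| `apotrack.synthdata` | phantom ultrasound sequences (three bright curved bands over speckle), synthetic vertical ground-reaction-force traces, smooth 1D Gaussian random fields with known FWHM and injected effects |
| `apotrack.shape_model` | point-distribution model: PCA over 57-landmark shapes (19 per boundary), 98.5% variance retention, plausible-shape projection with the ±3 SD coefficient clip |
| `apotrack.appearance_model` | Gaussian image pyramids; per-landmark Gaussian models of L1-normalized intensity-gradient profiles (5 samples) at every resolution level; Mahalanobis scoring |
| `apotrack.asm_search` | coarse-to-fine landmark search along boundary normals, shape-constrained iteration, two-start first-frame initialization, frame-to-frame tracking |
| `apotrack.thickness` | monotone cubic boundary interpolation, vertical thickness at 20 equally spaced sites (+ mean), foot-strike detection from GRF (20 N threshold, 50 ms debounce), 200-node stride normalization, quiet-standing baseline subtraction |
| `apotrack.spm` | pointwise repeated-measures ANOVA and paired-t fields, residual-based FWHM estimation, random-field-theory critical thresholds (expected Euler characteristic), suprathreshold clusters in % stride, Bonferroni post-hoc families |
| `apotrack.geometry` | planar thickness / fascicle-length / pennation relations (`thickness = L sin θ`) |
| `apotrack.io` / `apotrack.cli` | TIFF/JSON/CSV readers and writers, declarative run configuration, full pipeline orchestration |

## CLI

```bash
apotrack simulate --out demo --seed 1          # phantom + labels + GRF
apotrack train --images demo/phantom.tiff --labels demo/labels.json --out demo/model.json
apotrack track --images demo/phantom.tiff --model demo/model.json --out demo/fits.json
apotrack thickness --fits demo/fits.json --grf demo/grf.csv --muscle SO --out demo/thickness.csv
apotrack spm --input demo/thickness.csv --effect region --out demo/spm.json
apotrack geometry                              # planar-model worked example
apotrack run --seed 1 --out demo_run           # the whole pipeline in one go
```

`apotrack run` simulates two training trials and a main phantom sequence,
emulates hand labelling by subsampling truth frames, trains the shape and
profile models, tracks the sequence, extracts stride-normalized thickness
change for LG and SO, and runs the region-effect SPM — deterministically
from a single seed, with every output file tagged with the config hash.

## Conventions

Images are grayscale in [0, 1]; pixel coordinates are 0-based with x =
column and y = row (depth, increasing downward).  Landmark coordinates map
between pyramid levels by powers of two.  Stride-cycle fields have 200
nodes (0.5% stride each); cluster extents are reported as half-open
intervals in % stride.
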