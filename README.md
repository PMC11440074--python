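# spherosim

A self-contained toolkit that turns 3D single-cell label masks of tumor
spheroids into Cellular Potts Model (CPM) simulations and calibrates the
model against the imaging data:

1. **synthetic** — generate spheroid-like label masks (Voronoi-packed
   digital balls) with controllable segmentation artifacts, so the whole
   pipeline is testable without microscopy data.
2. **preprocess** — clean label masks: remove sub-threshold labels,
   per-label morphological closing/opening, merge or delete labels
   confined to one or two z-planes, and nearest-neighbor z-upsampling to
   an isotropic voxel size.
3. **morphology** — per-cell features: volume, border-voxel surface,
   major/minor principal axes, eccentricity, V/A ratio, sphericity.
4. **io_formats** — multi-page TIFF label stacks (JSON sidecar for voxel
   spacing), the CompuCell3D PIF text format (one voxel per line,
   `cell_ID celltype x1 x2 y1 y2 z1 z2`), CSV feature tables, JSON reports.
5. **cpm** — a minimal 3D Potts engine: quadratic volume/surface
   constraints plus cell–cell / cell–medium / cell–wall contact energies,
   Metropolis dynamics in Monte Carlo Steps (one copy attempt per interior
   site), a frozen Wall shell at the lattice boundary, and per-cell target
   assignment with donor resampling for out-of-band cells (below 15 % of
   the mean volume or above mean + 2 SD).
6. **similarity** — per-feature Wasserstein distances between start and
   current feature distributions (RMS-of-ordered-differences form by
   default, classical L1 optional), per-cell IoU, and the WIP objective
   (mean W × mean IoU).
7. **calibration** — grid scans over `J_cm`, `J_cc`, `lambda_V`,
   `lambda_A`, ranked ascending by WIP, with replicate seeds and a helper
   that drops boundary-clipped cells.

The numerics-heavy Metropolis kernel is JIT-compiled with numba; a 47³
lattice runs ~40 MCS in well under a second after warm-up.

## CLI

All stages are exposed under one executable:

```sh
spherosim synth --n-cells 60 --radius 21 --seed 1 --debris 3 --slivers 2 --out sphere.tiff
spherosim preprocess sphere.tiff --out clean.tiff --no-upsample --log log.json
spherosim features clean.tiff --out features.csv
spherosim pif clean.tiff --out initial.pif
spherosim simulate clean.tiff --mcs 100 --seed 1 --report-every 10 --out run/
spherosim score clean.tiff run/snapshot_mcs000100.tiff --out score.json
spherosim scan clean.tiff --config scan.yaml --mcs 50 --out scan.json --csv ranked.csv
```

`scan.yaml` is a flat key-value file: the four scan axes as lists
(`J_cm`, `J_cc`, `lambda_V`, `lambda_A`), optional `seeds`, and any fixed
`ModelParams` field (e.g. `temperature: 10.0`).

## Conventions

- In-memory axis order is `(x, y, z)`; TIFF pages are z-slices.
- Label 0 is medium; PIF coordinates are 0-based inclusive ranges.
- The feature table's `surface` is the border-voxel count (the metric
  surface); the engine's `A_i` is the face-contact count (the constrained
  surface). Both are exposed; target assignment for simulations uses the
  face-contact surface so in-band cells start exactly at their targets.
- Energies are in arbitrary `J/pix^k` units; `temperature` shares them.
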