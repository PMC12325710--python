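# blurscan

Simulation and analysis pipeline for a continuous blur-scanning brightfield
microscope applied to HER2-stained tissue microarrays (TMAs):

1. **`blurscan.synthslide`** — renders synthetic TMA slides with
   score-graded membrane staining (brown intensity and arc continuity
   increase with HER2 score 0 → 3+) plus a ground-truth layout manifest.
2. **`blurscan.scansim`** — simulates the continuous zigzag acquisition:
   the stage moves at constant speed while the camera exposes, so each
   moving frame is a slide window convolved along the scan direction with a
   normalized rectangular kernel of width `stage_speed x exposure_time`.
   Line-end pauses yield unblurred static frames. Includes the throughput
   arithmetic (`(s_x + FOV_width) x FOV_height`).
3. **`blurscan.stitch`** — reconstructs the whole-slide mosaic from the
   frame stream alone: consecutive-frame correlation classifies frames as
   moving/static, a square-wave motion-model fit repairs featureless-region
   errors, moving runs become alternating-direction scan lines, and frames
   are placed at the uniform per-frame advance.
4. **`blurscan.cores`** — white-balances the mosaic against an
   automatically sampled background block, finds the tissue bounding box
   (threshold → smooth → clear border), segments it into the layout grid
   and emits labeled per-core crops.
5. **`blurscan.stacks`** — builds the 5-image multi-scale input stack per
   core (1 global downsample + 4 random full-resolution crops, each
   `S x S`, channel-stacked for the classifier).
6. **`blurscan.net`** — a Fourier-domain classification network written in
   pure numpy with analytic gradients: spectral blocks (FFT → learnable
   per-frequency complex map → inverse FFT → GELU → 1x1 conv → pool)
   ending in global average pooling, trained with AdamW (weight decay 1e-4,
   lr 1e-3) under cosine annealing with warm restarts.
7. **`blurscan.agg`** — repeat-scan aggregation (all scans / max-CI /
   CI-weighted), mode-consistency, accuracy-vs-indeterminate threshold
   curves, confusion matrices and ROC/AUC for the binary task.

## CLI

All stages are exposed under one entry point:

```bash
blurscan simulate-slide --rows 2 --cols 3 --scores random --seed 1 --out slide/
blurscan scan    --slide slide/slide.tiff --config scan.yaml --out frames/
blurscan stitch  --frames frames/ --config scan.yaml --out stitched/
blurscan extract --mosaic stitched/mosaic.tiff --layout slide/layout.yaml \
                 --manifest slide/manifest.csv --repeat 1 --out crops/
blurscan stack   --crops crops/ --size 512 --n-crops 4 --seed 1 --out stacks/
blurscan train   --stacks stacks/ --classes 4 --out model/
blurscan predict --model model/model.npz --stacks stacks/ --out preds.csv
blurscan aggregate --predictions preds.csv --labels labels.csv \
                   --method maxci --indeterminate-rate 0.15 --out report/
```

`scan.yaml` holds the `ScanConfig` fields (stage speed, exposure, fps, FOV,
pause, row step, optional jitter); see `blurscan.scansim.ScanConfig`.

## Notes

- Everything is deterministic given the seeds passed in; synthetic data is
  generated programmatically, nothing is downloaded.
- The classifier is implemented in numpy (no GPU/autograd dependency); the
  spectral-layer adjoint is validated against finite differences in the
  test suite.
- The default scan geometry (640 x 480 px FOV at 1 um/px, 5000 um/s,
  30 fps, 39 um blur) reproduces the hardware arithmetic; tests use a
  scaled-down geometry for speed.
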