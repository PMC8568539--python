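# renalseg

Kidney CT segmentation with a residual dual-attention U-Net, implemented in
pure NumPy (hand-written forward/backward passes — no deep-learning
framework required), together with everything needed to exercise it end to
end on synthetic data:

- **`renalseg.phantom`** — synthetic abdominal-CT slice/series generator
  (body, bright spine, two kidney ellipsoids, optional low-attenuation
  cysts, Gaussian noise) with exact ground-truth masks, side labels and
  analytically known kidney volumes.
- **`renalseg.preprocess`** — DICOM series / NIfTI / PNG readers, HU
  conversion via rescale slope/intercept, display windowing (default width
  420 HU, centre 60 HU) mapped linearly to [0, 1], bilinear/nearest
  resizing to 256×256, and deterministic horizontal-flip dataset doubling.
- **`renalseg.network`** — the residual dual-attention block (two 3×3
  convolutions, a single-channel spatial sigmoid gate and a per-channel
  sigmoid gate summed elementwise, identity residual, ReLU) assembled into
  an encoder / bottleneck / decoder / classifier U-shape with max-pool
  downsampling, transposed-convolution upsampling, skip concatenation and a
  per-pixel softmax; plain U-Net (±BN) baselines share the topology.
- **`renalseg.training`** — soft Dice loss on the kidney class, Adam with
  β₁ = 0.95 and coupled 1e-4 L2 decay, learning rate 1e-3 dropping to 1e-4
  after epoch 30, 50-epoch default run, checkpoint selection by smallest
  loss, CSV logs and loss-curve plots.
- **`renalseg.metrics`** — DSC, precision, recall from exact pixel counts;
  left/right scoring split at the spine column (radiological display
  convention by default); pooled (micro) or per-slice macro averaging.
- **`renalseg.volume`** — stacks per-slice masks into a side-labelled 3-D
  volume, estimates per-kidney and total kidney volume (TKV) in mm³ by
  voxel counting, and exports NIfTI label volumes for external viewers.
- **`renalseg.dicomio`** — minimal reader/writer for uncompressed
  Explicit-VR-little-endian single-frame CT DICOM (the only DICOM subset
  the pipeline needs; no third-party DICOM dependency).

## CLI

All functionality is exposed through one entry point:

```sh
# 1. generate a synthetic series (NIfTI image+mask, or --format png)
renalseg phantom --n-slices 40 --seed 1 --out data/

# 2. train (config YAML can set network/training/window sections)
renalseg train --data data/ --epochs 50 --seed 1 --arch rda_unet --out run/

# 3. segment new slices: writes *_pred.png masks + red-contour overlays
renalseg segment --model run/model.npz --image data/ --out seg/

# 4. per-side DSC/precision/recall table for one or more checkpoints
renalseg evaluate --model run/model.npz --data data/ --out table.csv

# 5. stack masks into a labelled NIfTI volume and print TKV as JSON
renalseg reconstruct --data seg/ --pixel-spacing-mm 0.625 \
    --inter-slice-mm 1.0 --out volume.nii

# or run the whole pipeline on phantoms in one go
renalseg demo --seed 0 --out demo/
```

Every subcommand writes its resolved configuration next to its outputs and
is deterministic given config + seed.

## Notes

- Arrays are row-major with row 0 at the top; under the default
  radiological display convention the patient's anatomical left is the
  image right, so "left kidney" metrics cover columns greater than the
  dividing column (`--display-convention neurological` swaps this).
- Checkpoints are NumPy `.npz` archives with the architecture config
  embedded; `renalseg.network.load_checkpoint` rebuilds the model.
- TKV uses the inter-slice distance (not slice thickness) as the voxel
  depth, since volume integration follows the sampling distance.
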