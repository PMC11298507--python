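# interpsplit

Multi-scale interpolation + tiling pipeline for 2D slice-based segmentation
of airway-like tubular trees in volumetric CT.

Each axial slice is magnified by an integer interpolation ratio (`ir`) —
bilinear for images, nearest-neighbour for masks — and split into
fixed-size, non-overlapping tiles that feed any 2D tile-level segmenter.
Predictions are merged and nearest-neighbour down-sampled back to source
resolution; binary masks from several ratios are fused by voxelwise union
followed by largest-connected-component extraction. A synthetic airway
phantom generator with exact ground truth makes the whole pipeline testable
at desk scale, and analysis utilities quantify the seam and blur artefacts
of the crop-then-upscale alternative.

All four resampling directions share one grid convention (half-pixel
centres, edge clamping, nearest-neighbour ties toward the smaller index),
which makes `downsample_nn(upsample_mask(m, ir), ir) == m` a bit-exact
identity and the bilinear up-sampler exact against the four-corner cell
formula.

## Modules

| Module | Purpose |
| --- | --- |
| `interpsplit.phantom` | Seeded synthetic airway-tree volumes (branching tubes, wall shells, noise, PSF blur) with exact lumen ground truth; affine ramp test images |
| `interpsplit.io` | NIfTI / TIFF / DICOM readers, writers, window-level normalisation (default W=1500, L=−500 → [0, 255]), slice extraction, unsharp mask |
| `interpsplit.tiling` | Up-sampling, tile split/merge, nearest-neighbour down-sampling, tile-count arithmetic, training-pair preparation |
| `interpsplit.mathmodel` | Bilinear cell formula, crop-then-upscale comparator, seam-discontinuity statistic, diagonal-Laplacian sharpness, paired t-test study |
| `interpsplit.metrics` | BCE, Dice (soft and binary), combined loss, per-case DSC (%), performance gain, ablation mean ± SD tables |
| `interpsplit.ensemble` | Segmenter backend contract, threshold + morphological-opening reference backend, pure-NumPy trainable logistic backend, per-ratio prediction, union + largest-component fusion |
| `interpsplit.cli` | `interpsplit` command-line interface |

DICOM reading needs the optional `pydicom` dependency
(`pip install interpsplit[dicom]`).

## CLI

```bash
# generate a phantom fixture (image + exact lumen mask + JSON sidecar)
interpsplit phantom --seed 1 --out fixtures/ --grid-shape 64,96,96

# normalise to [0, 255] with the lung window
interpsplit preprocess --input fixtures/image.nii.gz --output norm.nii.gz \
    --window 1500 --level -500

# full pipeline: per-ratio prediction, union, largest connected component
interpsplit run --input fixtures/image.nii.gz --mask fixtures/mask.nii.gz \
    --out out/ --irs 1,2,4,8 --tile-size 64 --tau 60 --opening-radius 2

# tile export / reassembly with a grid manifest
interpsplit split --input norm.nii.gz --ir 2 --tile-size 512 --out tiles/
interpsplit merge --manifest tiles/grid.json --out merged.nii.gz

# artefact analyses
interpsplit mathmodel-demo --n 4 --ir 2 --block 2 --out demo/
interpsplit sharpness-study --seed 0 --ir 4 --out study/
interpsplit evaluate --pred out/final_mask.nii.gz --gt fixtures/mask.nii.gz
```

Defaults (tile size 512, ratios {1,2,4,8}, binarisation threshold 0.5,
window 1500/−500) can be set in a YAML config passed via `--config`; every
command writes a JSON provenance record next to its outputs.

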