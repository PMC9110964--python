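# renalseg

Dual-phase CT segmentation, volumetry and surface meshing of the renal
collecting system, kidney stones and bone — a headless pipeline for
percutaneous nephrolithotomy (PCNL) access planning, plus a synthetic
dual-phase CT phantom that makes the whole chain testable offline.

Given a native (non-contrast) and a delayed (excretory-phase) CT volume of
the same patient, the pipeline:

1. **Band-shifts** intensities from the Hounsfield band [−548, 800] onto the
   continuous 0–255 display scale (values outside the band are clamped).
2. **Denoises** both phases with a 3-D median filter (radius 1 by default).
3. **Co-registers** the delayed phase onto the native grid: rigid transform,
   mutual-information criterion (partial-volume joint histogram over
   jittered samples), Powell optimisation at two resolution levels,
   trilinear resampling. Deterministic for a fixed sampling seed.
4. **Segments** three structures by histogram thresholding with
   morphological particle removal (opening + closing, solid cube elements):
   - *skeleton* (bone): native band [117, 180] cleaned and dilated,
     intersected with the delayed band [130, 255] cleaned;
   - *collecting system*: the cleaned delayed-band mask minus the skeleton;
   - *calculus* (stone): native band [250, 255] cleaned with a cube of edge 2.
5. **Measures** stone volume (SV), pelvicalyceal-system volume (PSV, union
   or exclusive stone-counting convention) and the SV/PSV ratio.
6. **Meshes** each mask with Marching Cubes and exports binary or ASCII STL.

All thresholds and structuring-element sizes live in `SegmentationConfig`
and can be overridden from a YAML/JSON config file.

## CLI

```sh
renalseg config                             # print default configuration
renalseg phantom --out ph --seed 42         # synthetic dual-phase phantom + ground truth
renalseg segment --native DIR_OR_MHA --delayed DIR_OR_MHA --out run \
                 [--config config.yaml] [--psv-convention union|exclusive]
renalseg metrics --result run --out metrics.json
renalseg mesh --mask run/calculus.mha --out stone.stl [--ascii]
renalseg all --phantom --seed 42 --out run1 # end-to-end on a phantom
```

`segment`/`all` write the three masks (`.mha`), `metrics.json`, one STL per
structure and a `manifest.json` recording config, seeds, per-stage voxel
counts and the output file list. Usage errors exit 2; stage failures exit 1
with the failing stage named on stderr.

## Phantom

`renalseg.phantom.generate_phantom` builds paired native/delayed volumes on
a 96³ grid (1 mm voxels by default): a kidney ellipsoid, two bone cylinders,
a contrast-filled pelvis + calyces present only in the delayed phase, an
ellipsoidal stone present in both, Gaussian noise, and a known rigid
misalignment between the phases. Ground truth includes the label map, the
closed-form stone volume (4/3·π·abc), a supersampled collecting-system
volume and the recoverable misalignment transform — so segmentation
accuracy, volumetry and registration can all be scored analytically.

## Conventions

- Arrays are indexed `(slice, row, column)` = `(z, y, x)`; spacing, origin
  and physical points use the same order, in millimetres. Voxel `i` is
  centred at `origin + direction @ (i * spacing)`.
- Readers return Hounsfield units (DICOM rescale slope/intercept applied);
  the shifted 0–255 domain is tracked explicitly and kept continuous (no
  8-bit rounding), with thresholds inclusive on both ends.
- Mesh vertices are exported in `(x, y, z)` mm with outward-oriented faces.
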