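# ctprep

CT DICOM pre-processing for large-scale skeletal and anatomical research.

Clinical and post-mortem CT studies arrive as flat dumps of DICOM slices that
mix several series and always include non-patient structures — above all the
scanner couch ("sliding table") — that contaminate any downstream
segmentation, morphometry or machine-learning dataset. Cleaning them by hand
in a viewer does not scale past a handful of scans. `ctprep` automates the
whole chain:

1. **sort** — purge non-DICOM/corrupted files, group slices into one folder
   per series (folder named by Series Number, identity keyed on Series
   Instance UID);
2. **denoise** — remove the couch and background by Hounsfield-unit (HU)
   thresholding plus connected-component patient masking, overwriting each
   DICOM in place with metadata untouched;
3. **export** — three discrete output classes: windowed 8-bit PNG/JPEG per
   slice, one NIfTI-1 volume per series (RAS affine built from the DICOM
   geometry), and an STL bone-surface mesh per series (marching cubes at the
   bone threshold).

A synthetic phantom generator (`ctprep.phantom_fixtures`) emits complete
DICOM studies — elliptical soft-tissue body, bone inserts, a disjoint couch
arc, optional noise and decoy files — with analytic ground-truth masks, so
every stage is testable without access to any real scan.

## The core operation

Stored pixel values map to radiodensity via the per-file linear rescale
`HU = stored · slope + intercept` (air ≈ −1000 HU, water = 0, soft tissue
≈ 40, trabecular→cortical bone ≈ 200–3000). The patient mask for a slice is

```
M = fill_holes( largest_component( close( tissue_lower ≤ HU ≤ tissue_upper ) ) )
```

with a disk-radius-3 closing and default tissue band [−300, 3000] HU. The
couch is radiodense enough to survive thresholding but is a separate, smaller
connected component, so `largest_component` removes it; interior air spaces
(lungs, bowel) are restored by hole filling. Outside `M` the stored value is
set to 0 (≈ −1024 HU at the usual intercept) and the file is rewritten in
place. A `volumetric` mode selects the largest 3-D component across the
stacked series instead.

## Worked example

```bash
ctprep phantom scans/case01 --slices 16 --series 2 --noise-sd 10 --seed 7
ctprep all scans
```

prints

```
wrote phantom study to scans/case01
processed 1 study(ies); 3 output class(es); 0 failure(s)
```

and leaves `scans_outputs/` containing `images/` (32 windowed PNGs, bone
band 200–3000 HU mapped to 0–255), `nifti/` (two volumes, e.g.
`case01_series2.nii`, int16 HU with the voxel-to-world RAS affine), `stl/`
(two binary meshes of the bone insert) and `run_manifest.json` recording
every file read, classified, overwritten or emitted. The phantom's couch arc
is gone from the denoised slices: every ground-truth table pixel reads back
as stored 0.

The same steps from Python:

```python
from ctprep import PhantomSpec, make_phantom_study, PipelineConfig, run_pipeline

study, truth = make_phantom_study(PhantomSpec(n_series=2, noise_sd=10.0, seed=7),
                                  "scans/case01")
manifest = run_pipeline(PipelineConfig(input_root="scans"))
assert manifest.n_output_classes == 3
```

**Warning:** `denoise` overwrites DICOM files in place by design. Use
`--copy-first` to work on a snapshot instead.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
generates a seeded two-series phantom study (with decoy files), runs the full
sort → denoise → images/NIfTI/STL pipeline on it, reports the output counts,
and writes the results JSON. A non-zero exit signals a pipeline failure.

## Layout

- `src/ctprep/dicom_core.py` — slice decode/validate/rewrite, HU conversion
- `src/ctprep/_dicomio.py` — minimal DICOM Part-10 codec
- `src/ctprep/series_sorter.py` — purge, per-series sorting, metadata deletes
- `src/ctprep/noise_removal.py` — thresholding, patient mask, in-place denoise
- `src/ctprep/export_images.py` / `export_volume.py` / `export_mesh.py` — S3–S5
- `src/ctprep/phantom_fixtures.py` — synthetic studies + ground truth
- `src/ctprep/pipeline.py`, `cli.py` — orchestration, config, `ctprep` CLI
- `docs/methods.md` — models, parameters, numerical choices, limitations
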