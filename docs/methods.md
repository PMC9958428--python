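# Methods

## Scope and model

`ctprep` treats a CT study as a set of single-frame DICOM slices carrying
(a) a stored integer pixel matrix, (b) the linear rescale to Hounsfield
units, and (c) per-slice geometry (position, orientation, pixel spacing,
slice thickness) in the patient LPS frame. Every stage is defined on those
quantities only, which is what makes the pipeline scanner-agnostic.

### DICOM I/O

Reading and writing are handled by an in-package Part-10 codec restricted to
the file class the pipeline consumes and emits: 128-byte preamble + `DICM`
magic, explicit- or implicit-VR little-endian transfer syntaxes, uncompressed
pixel data (8- or 16-bit). Elements are kept as raw value bytes keyed by tag,
so rewriting a file reproduces every unmodified element byte-for-byte — this
is what makes the metadata-preservation and idempotence guarantees checkable
as byte equality rather than "semantic" equality. Undefined-length sequences,
compressed syntaxes, big-endian files, multi-frame enhanced CT and DICOMDIR
are out of scope and classify as unsupported.

File classification is three-valued and total: `non_dicom` (no signature),
`corrupted` (signature present but parsing, pixel decoding, or a required
attribute fails — required means: pixel data, rows/cols, pixel spacing,
slice thickness, position, orientation, rescale slope/intercept, and at
least one series identifier, since every downstream stage needs them), else
`valid`.

### Series identity

A series is identified by Series Instance UID; the per-series folder is
*named* by Series Number because that is what humans recognise. When two
UIDs share a number the folders are suffixed `-2`, `-3`, … and the collision
is recorded in the index. Within a series, files order by instance number
(ties by filename). Files are moved, not copied (a copy mode exists);
sorting an already-sorted tree is a no-op.

### Noise removal

Per slice: threshold the HU matrix to the tissue band, close with a disk of
radius 3 px, keep the largest connected component, fill interior holes
(border flood-fill complement), then set stored values outside the mask to 0
and rewrite the file. Choices and rationale:

- **Tissue band [−300, 3000] HU (default).** Wide enough that the whole
  patient — fat through cortical bone — forms one component; the couch falls
  inside this band too in general, which is deliberate: removal must rely on
  connectedness, not on the threshold. Fully configurable.
- **Bone band [200, 3000] HU (default).** Used only by the 2-D window
  default and as the isosurface level; it does not participate in mask
  construction.
- **Closing radius 3 px.** Bridges thresholding dropouts at tissue
  interfaces; small enough not to bridge the ≥ several-mm body–couch gap of
  real scanner geometry.
- **Largest component by pixel area.** The body cross-section dominates the
  couch cross-section in axial slices. For slices where the per-slice
  largest is ambiguous (two legs, scan padding), `volumetric` mode labels
  the stacked binary volume with 26-connectivity, keeps the largest 3-D
  component, and applies its per-slice sections; hole filling stays 2-D so
  open-ended air channels (trachea) are not sealed shut axially.
- **Background value: stored 0,** not a fixed HU. With the common intercept
  −1024 this reads back as −1024 HU (just below air). The HU meaning of the
  background therefore depends on each file's intercept; this is documented
  behaviour, not an accident.
- **Degenerate slices** (nothing in the band) become all-background and are
  flagged `empty`, not errors.
- The stage has no randomness; identical inputs give identical bytes, and
  the operation is idempotent (masking an already-masked slice reselects
  the same component).

What is *not* removed: anything inside the patient envelope (stents, tubes
within the body outline) — the mask keeps the full patient selection.

### Volume export

Slices are ordered by the projection of their position onto the slice normal
(cross product of the orientation vectors), not by instance number; the two
orders disagreeing is logged. Inter-slice gaps must be uniform within
1e-3 mm — otherwise the stage fails naming the offending gap, because
silently resampling across missing slices would corrupt morphometry. The
voxel→world affine is assembled from orientation × spacing with the
first-slice position as translation, then converted LPS→RAS by negating the
first two world axes; voxel data are never flipped. Output is single-file
NIfTI-1, int16 HU, scaling slope 1 / intercept 0. (Rounding to int16 is
exact for the integer-HU phantoms; for exotic rescale slopes producing
fractional HU it quantises to 1 HU.)

### Mesh export

Isosurface extraction uses topology-consistent (Lewiner) marching cubes at
`bone_lower`. Post-processing: exact-duplicate vertices are welded (the case
table can emit coincident vertices, which otherwise appear as zero-area
slivers and break edge pairing), index-degenerate and sub-1e-9 mm² triangles
are dropped, vertices are mapped to world mm through the volume affine, and
the winding is globally flipped if the majority of facet normals oppose the
gradient-based vertex normals (the LPS→RAS affine has negative determinant
for standard axial orientation, which reverses winding). No smoothing or
decimation by default; an optional vertex-clustering decimator is provided
for size reduction only. Surfaces that exit the grid remain open — no
capping.

Binary STL is bit-specified: 80-byte null-padded header, little-endian
uint32 triangle count, then per triangle 12 float32 (normal, three vertices)
plus a zero uint16 attribute — 84 + 50·T bytes total. ASCII STL follows the
`solid`/`facet normal`/`outer loop` grammar.

## The phantom: what it emulates and what it does not

The generator states a fixed world: 512×512 matrix, 0.5 mm pixels and slice
thickness, 12-bit unsigned stored values with slope 1 / intercept −1024
(a common clinical acquisition regime); an elliptical body of 40 HU
(soft tissue) with semi-axes 90×60 mm; spherical or cylindrical bone inserts
at 700 HU; and a couch modelled as a 100–104 mm annulus arc ±60° about
straight-down at 150 HU. The couch HU is deliberately *inside* the tissue
band so that its removal genuinely tests component logic. Noise is additive
Gaussian in HU before quantisation; at SD 0 stored values are exactly the
quantised scene. The seed determines every emitted byte, UIDs included.
Ground-truth masks are computed from the same analytic geometry (pixel-centre
point tests), independent of the pipeline's mask code.

Tests scale this world down proportionally (96 px/48 mm field in the unit
suite, 128 px in the 20-seed acceptance sweep) to stay fast; geometric
relationships (couch disjoint from body by ≫ the closing diameter, inserts
inside the body) are preserved.

For isosurface accuracy tests a separate sphere phantom provides a smooth
field: 700 HU inside, −1000 HU outside, with a 2 mm linear radial shell
calibrated so the 200 HU level set is exactly the requested sphere. A hard
binary sphere would hand marching cubes a staircase whose area is biased
high by ~7% *independent of resolution*; the shell models the scanner PSF's
partial-volume blur and makes the analytic area/volume a meaningful oracle
(measured: −0.08% area error at 0.5 mm, −0.02% at 0.25 mm).

A green phantom suite establishes the geometric and bookkeeping contracts.
It does not establish robustness to anatomy texture, beam-hardening or metal
streaks, contrast phases, gantry tilt, or couch shapes that touch the
patient outline.

## Pipeline and configuration

Stages run in the fixed order sort → denoise → images → nifti → stl.
Configuration is a flat YAML file mirrored by CLI flags; unknown keys are
rejected so typos fail loudly. Ordering invariants are validated up front:
denoise requires sort (or `assume_sorted`), exports require denoise (or
`raw_exports`) — single-stage CLI commands set those flags implicitly so a
user can run one stage on an already-prepared tree. Studies are processed
independently: one failing study is recorded in the manifest and does not
abort the run. The JSON run manifest maps every input file to the actions
applied to it and groups outputs by format class; the `ctprep` exit code is
non-zero iff any study failed. The in-place overwrite is the default
(matching the destructive semantics of the original workflow); `copy_first`
snapshots each study into the output tree first.

## Known limitations

- Compressed transfer syntaxes and enhanced multi-frame CT are rejected, not
  converted.
- The couch must be disconnected from the body after thresholding; a couch
  touching the patient outline (obese patients, blankets) would be kept.
- NIfTI int16 output quantises non-integer HU values.
- The decimator is a size reducer (vertex clustering), not a
  quality-preserving simplifier, and may change topology.
- Anonymisation is limited to what `delete_by_metadata` can remove; no
  policy-level de-identification is attempted.
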