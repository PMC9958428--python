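"""Synthetic CT phantom studies with analytic ground truth.

Emulates the scene a clinical torso CT presents to the pipeline: an
elliptical soft-tissue body cross-section (≈40 HU) containing bone-density
inserts (≈700 HU), and — crucially — a curved patient-couch ("sliding
table") arc below the body, radiodense enough (150 HU) to survive naive
tissue thresholding so that its removal genuinely exercises the
connected-component logic rather than the threshold alone.

Defaults mirror a common clinical acquisition regime: 512×512 matrix,
0.5 mm pixels and 0.5 mm slice thickness, 12-bit unsigned stored values
with slope 1 / intercept −1024. Files are written interleaved across
series to emulate an uncollated study dump, optionally alongside decoy
files (plain text, truncated DICOM) for the purge stage.

What the phantom does **not** emulate: anatomical texture, beam-hardening
or streak artifacts, contrast phases, non-axial gantry tilt. A green test
on phantoms establishes the geometric/logic contracts, not robustness to
scanner-specific artifact content.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import _dicomio as dio
from ._dicomio import Element, encode_ds, encode_is, encode_string, encode_us

AIR_HU = -1000.0
HU_MIN, HU_MAX = -1024.0, 3071.0
_INTERCEPT = -1024.0
_SLOPE = 1.0


@dataclass(frozen=True)
class SphereInsert:
    """Bone-density sphere: center (x, y, z) in mm, radius in mm."""

    center: tuple[float, float, float]
    radius: float
    hu: float = 700.0


@dataclass(frozen=True)
class CylinderInsert:
    """Bone-density cylinder along z: center (x, y) mm, radius mm, full height."""

    center: tuple[float, float]
    radius: float
    hu: float = 700.0


@dataclass(frozen=True)
class TableSpec:
    """Couch arc: annulus sector centred below the body.

    The arc spans ``inner_radius..outer_radius`` (mm from the body centre)
    over ``half_angle_deg`` either side of straight-down (+y in image
    coordinates), mimicking the crescent a CT couch cuts through an axial
    slice.
    """

    inner_radius: float = 100.0
    outer_radius: float = 104.0
    half_angle_deg: float = 60.0
    hu: float = 150.0


@dataclass(frozen=True)
class PhantomSpec:
    matrix_size: int = 512
    n_slices: int = 16
    pixel_spacing: float = 0.5  # mm
    slice_thickness: float = 0.5  # mm
    body_semi_axes: tuple[float, float] = (90.0, 60.0)  # mm (x, y)
    body_hu: float = 40.0
    bone_inserts: tuple = (SphereInsert(center=(30.0, 0.0, 3.75), radius=3.0),)
    table: TableSpec = TableSpec()
    noise_sd: float = 0.0  # HU
    seed: int = 0
    n_series: int = 1
    first_series_number: int = 2
    n_non_dicom_decoys: int = 0
    n_truncated_decoys: int = 0

    def __post_init__(self) -> None:
        if self.matrix_size < 8 or self.n_slices < 1 or self.n_series < 1:
            raise ValueError("degenerate phantom dimensions")
        if self.pixel_spacing <= 0 or self.slice_thickness <= 0:
            raise ValueError("spacings must be positive")
        if not (HU_MIN <= self.body_hu <= HU_MAX and HU_MIN <= self.table.hu <= HU_MAX):
            raise ValueError("HU values outside CT range")
        # Body/table disjointness: the table annulus must clear the body
        # ellipse entirely (max ellipse radius < inner table radius).
        if max(self.body_semi_axes) >= self.table.inner_radius:
            raise ValueError(
                "table annulus overlaps body ellipse: "
                f"max semi-axis {max(self.body_semi_axes)} >= "
                f"inner radius {self.table.inner_radius}"
            )

    @property
    def field_of_view(self) -> float:
        return self.matrix_size * self.pixel_spacing

    def slice_z(self, k: int) -> float:
        return k * self.slice_thickness


@dataclass
class GroundTruth:
    """Analytic per-slice masks (computed from geometry, not from pipeline code)."""

    body: np.ndarray  # (rows, cols, n_slices) bool
    table: np.ndarray
    bone: np.ndarray
    spec: PhantomSpec
    seed: int


# ---------------------------------------------------------------------------
# Geometry (pixel-centre point tests; the same functions serve the image
# synthesis and the ground-truth masks, so the truth is exact by definition)


def _pixel_grid(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    n = spec.matrix_size
    half = (n - 1) / 2.0
    coords = (np.arange(n) - half) * spec.pixel_spacing
    # x increases with column index, y with row index (image convention:
    # +y towards the couch).
    y, x = np.meshgrid(coords, coords, indexing="ij")
    return x, y


def _body_mask_2d(spec: PhantomSpec) -> np.ndarray:
    x, y = _pixel_grid(spec)
    a, b = spec.body_semi_axes
    return (x / a) ** 2 + (y / b) ** 2 <= 1.0


def _table_mask_2d(spec: PhantomSpec) -> np.ndarray:
    x, y = _pixel_grid(spec)
    t = spec.table
    r = np.hypot(x, y)
    ring = (r >= t.inner_radius) & (r <= t.outer_radius)
    # Angle measured from straight-down (+y).
    ang = np.degrees(np.abs(np.arctan2(x, y)))
    return ring & (ang <= t.half_angle_deg)


def _bone_mask_slice(spec: PhantomSpec, k: int) -> np.ndarray:
    x, y = _pixel_grid(spec)
    z = spec.slice_z(k)
    mask = np.zeros_like(x, dtype=bool)
    for ins in spec.bone_inserts:
        if isinstance(ins, SphereInsert):
            cx, cy, cz = ins.center
            dz2 = (z - cz) ** 2
            if dz2 <= ins.radius**2:
                r2 = ins.radius**2 - dz2
                mask |= (x - cx) ** 2 + (y - cy) ** 2 <= r2
        elif isinstance(ins, CylinderInsert):
            cx, cy = ins.center
            mask |= (x - cx) ** 2 + (y - cy) ** 2 <= ins.radius**2
        else:  # pragma: no cover - spec validation
            raise TypeError(f"unknown insert type {type(ins)!r}")
    return mask


def ground_truth_masks(spec: PhantomSpec) -> GroundTruth:
    """Per-slice body / table / bone boolean masks, straight from geometry."""
    n, ns = spec.matrix_size, spec.n_slices
    body2d = _body_mask_2d(spec)
    table2d = _table_mask_2d(spec)
    body = np.repeat(body2d[:, :, None], ns, axis=2)
    table = np.repeat(table2d[:, :, None], ns, axis=2)
    bone = np.stack([_bone_mask_slice(spec, k) for k in range(ns)], axis=2)
    bone &= body  # inserts are defined inside the body
    return GroundTruth(body=body, table=table, bone=bone, spec=spec, seed=spec.seed)


def _hu_slice(spec: PhantomSpec, k: int, gt: GroundTruth) -> np.ndarray:
    img = np.full((spec.matrix_size, spec.matrix_size), AIR_HU)
    img[gt.body[:, :, k]] = spec.body_hu
    img[gt.table[:, :, k]] = spec.table.hu
    bone = gt.bone[:, :, k]
    img[bone] = _bone_hu_slice(spec, k, bone)
    return img


def _bone_hu_slice(spec: PhantomSpec, k: int, bone: np.ndarray) -> np.ndarray:
    # Supports per-insert HU; later inserts win on overlap.
    x, y = _pixel_grid(spec)
    z = spec.slice_z(k)
    hu = np.full(bone.shape, np.nan)
    for ins in spec.bone_inserts:
        if isinstance(ins, SphereInsert):
            cx, cy, cz = ins.center
            dz2 = (z - cz) ** 2
            if dz2 <= ins.radius**2:
                m = (x - cx) ** 2 + (y - cy) ** 2 <= ins.radius**2 - dz2
                hu[m] = ins.hu
        else:
            cx, cy = ins.center
            m = (x - cx) ** 2 + (y - cy) ** 2 <= ins.radius**2
            hu[m] = ins.hu
    return hu[bone]


# ---------------------------------------------------------------------------
# DICOM emission


def sphere_phantom_volume(
    radius: float = 10.0,
    spacing: float = 0.5,
    inside_hu: float = 700.0,
    outside_hu: float = -1000.0,
    iso_hu: float = 200.0,
    shell_width: float = 2.0,
):
    """A bone-density sphere as a :class:`~ctprep.export_volume.Volume`.

    The HU field is ``inside_hu`` deep inside and ``outside_hu`` far outside,
    with a linear radial transition shell of ``shell_width`` mm calibrated so
    the ``iso_hu`` level set is exactly the sphere of the requested radius —
    emulating the partial-volume blur a scanner PSF imposes on a sharp bone
    boundary. A hard binary field would give marching cubes a staircase
    surface whose area is biased high and never converges; the blurred shell
    is both the physically realistic model and an exact analytic oracle
    (area 4·pi·r², volume 4/3·pi·r³) for isosurface tests.
    """
    from .export_volume import Volume

    span = inside_hu - outside_hu
    # hu(r) = inside - span * (r - r0)/w on the shell; solve hu(radius) = iso.
    r0 = radius - (inside_hu - iso_hu) / span * shell_width
    margin = shell_width + 4 * spacing
    n = int(np.ceil(2 * (radius + margin) / spacing)) + 1
    c = (n - 1) / 2.0
    idx = np.arange(n)
    ii, jj, kk = np.meshgrid(idx, idx, idx, indexing="ij")
    r = np.sqrt((ii - c) ** 2 + (jj - c) ** 2 + (kk - c) ** 2) * spacing
    hu = inside_hu - span * np.clip((r - r0) / shell_width, 0.0, 1.0)
    affine = np.diag([spacing, spacing, spacing, 1.0])
    affine[:3, 3] = -c * spacing
    return Volume(voxels=hu, affine=affine, spacing=(spacing,) * 3)


def _uid(rng: np.random.Generator) -> str:
    return dio.UID_ROOT + "".join(str(rng.integers(0, 10)) for _ in range(24))


def _slice_dataset(
    spec: PhantomSpec,
    stored: np.ndarray,
    series_number: int,
    series_uid: str,
    study_uid: str,
    sop_uid: str,
    instance_number: int,
    k: int,
) -> dio.DicomFile:
    n = spec.matrix_size
    half = (n - 1) / 2.0 * spec.pixel_spacing
    els = {}

    def put(tag, vr, value: bytes) -> None:
        els[tag] = Element(tag, vr, value)

    put((0x0008, 0x0016), "UI", encode_string(dio.CT_IMAGE_STORAGE))
    put((0x0008, 0x0018), "UI", encode_string(sop_uid))
    put((0x0008, 0x0020), "DA", b"20230101")
    put((0x0008, 0x0021), "DA", b"20230101")
    put((0x0008, 0x0030), "TM", b"120000")
    put((0x0008, 0x0060), "CS", b"CT")
    put((0x0010, 0x0010), "PN", b"PHANTOM^CTPREP")
    put((0x0010, 0x0020), "LO", b"PHANTOM-000")
    put((0x0010, 0x0040), "CS", b"O ")
    put((0x0010, 0x1010), "AS", b"045Y")
    put((0x0018, 0x0050), "DS", encode_ds([spec.slice_thickness]))
    put((0x0020, 0x000D), "UI", encode_string(study_uid))
    put((0x0020, 0x000E), "UI", encode_string(series_uid))
    put((0x0020, 0x0011), "IS", encode_is([series_number]))
    put((0x0020, 0x0013), "IS", encode_is([instance_number]))
    put(
        (0x0020, 0x0032),
        "DS",
        encode_ds([-half, -half, spec.slice_z(k)]),
    )
    put((0x0020, 0x0037), "DS", encode_ds([1, 0, 0, 0, 1, 0]))
    put((0x0028, 0x0002), "US", encode_us(1))
    put((0x0028, 0x0004), "CS", b"MONOCHROME2 ")
    put((0x0028, 0x0010), "US", encode_us(n))
    put((0x0028, 0x0011), "US", encode_us(n))
    put((0x0028, 0x0030), "DS", encode_ds([spec.pixel_spacing, spec.pixel_spacing]))
    put((0x0028, 0x0100), "US", encode_us(16))
    put((0x0028, 0x0101), "US", encode_us(12))
    put((0x0028, 0x0102), "US", encode_us(11))
    put((0x0028, 0x0103), "US", encode_us(0))
    put((0x0028, 0x1052), "DS", encode_ds([_INTERCEPT]))
    put((0x0028, 0x1053), "DS", encode_ds([_SLOPE]))
    put(
        dio.PIXEL_DATA,
        "OW",
        stored.astype(np.dtype(np.uint16).newbyteorder("<")).tobytes(),
    )
    return dio.DicomFile(
        meta=dio.make_meta(sop_uid), elements=els, transfer_syntax=dio.EXPLICIT_VR_LE
    )


def make_phantom_study(
    spec: PhantomSpec, out_dir: str | Path, write_ground_truth: bool = True
) -> tuple[Path, GroundTruth]:
    """Write one synthetic CT study (all series interleaved in one directory).

    Returns the study directory and the analytic ground truth. The seed in
    ``spec`` fully determines the emitted bytes (UIDs included). When
    ``write_ground_truth`` is set, masks are saved as NIfTI beside the study
    in ``<out_dir>_truth/`` along with a JSON manifest of the spec.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    gt = ground_truth_masks(spec)
    study_uid = _uid(rng)
    series_uids = [_uid(rng) for _ in range(spec.n_series)]

    # Interleave series within the directory (uncollated dump layout).
    idx = 0
    for k in range(spec.n_slices):
        base = _hu_slice(spec, k, gt)
        for s in range(spec.n_series):
            hu = base
            if spec.noise_sd > 0:
                hu = base + rng.normal(0.0, spec.noise_sd, base.shape)
            stored = np.clip(np.rint(hu - _INTERCEPT), 0, 4095).astype(np.uint16)
            df = _slice_dataset(
                spec,
                stored,
                series_number=spec.first_series_number + s,
                series_uid=series_uids[s],
                study_uid=study_uid,
                sop_uid=_uid(rng),
                instance_number=k + 1,
                k=k,
            )
            dio.write_file(out_dir / f"IM{idx:06d}.dcm", df)
            idx += 1

    for d in range(spec.n_non_dicom_decoys):
        (out_dir / f"decoy_{d}.txt").write_text(
            "not a scan; free-text report placeholder\n"
        )
    for d in range(spec.n_truncated_decoys):
        src = out_dir / "IM000000.dcm"
        data = src.read_bytes()
        (out_dir / f"truncated_{d}.dcm").write_bytes(data[: len(data) // 2])

    if write_ground_truth:
        _write_truth_bundle(out_dir, gt)
    return out_dir, gt


def _write_truth_bundle(study_dir: Path, gt: GroundTruth) -> None:
    import nibabel as nib

    truth_dir = study_dir.parent / (study_dir.name + "_truth")
    truth_dir.mkdir(parents=True, exist_ok=True)
    sp = gt.spec
    affine = np.diag([sp.pixel_spacing, sp.pixel_spacing, sp.slice_thickness, 1.0])
    for name, mask in (("body", gt.body), ("table", gt.table), ("bone", gt.bone)):
        img = nib.Nifti1Image(mask.astype(np.uint8), affine)
        nib.save(img, truth_dir / f"{name}_mask.nii")
    manifest = asdict(sp)
    manifest["bone_inserts"] = [
        {**asdict(i), "kind": type(i).__name__} for i in sp.bone_inserts
    ]
    (truth_dir / "phantom_manifest.json").write_text(
        json.dumps(manifest, indent=2, default=list)
    )
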