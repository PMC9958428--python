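"""Stage S4: stack one DICOM series into a 3-D HU volume and write NIfTI.

DICOM geometry lives in the patient LPS frame (x → left, y → posterior,
z → superior); NIfTI convention is RAS. The conversion happens entirely in
the affine — the first two world axes are negated — so voxel data are never
flipped or resampled. HU values are written as signed 16-bit with NIfTI
scaling slope 1 / intercept 0 (the values are already HU).
"""

from __future__ import annotations

import logging
import shutil
from dataclasses import dataclass
from pathlib import Path
from typing import List

import nibabel as nib
import numpy as np

from . import dicom_core as dc
from .dicom_core import SliceRecord

log = logging.getLogger(__name__)

#: Maximum allowed jitter in inter-slice spacing (mm). A gap beyond this is
#: a hard error: silently resampling across missing slices would corrupt
#: any downstream morphometry.
SPACING_TOL = 1e-3

_LPS_TO_RAS = np.diag([-1.0, -1.0, 1.0, 1.0])


@dataclass
class Volume:
    """3-D HU grid (rows × cols × slices) with a voxel→world-mm RAS affine."""

    voxels: np.ndarray
    affine: np.ndarray
    spacing: tuple[float, float, float]  # (row, col, slice) mm
    series_number: int | None = None
    series_uid: str | None = None

    def world(self, ijk) -> np.ndarray:
        """Map voxel indices (N×3 or 3-vector) to world mm through the affine."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        homog = np.hstack([ijk, np.ones((len(ijk), 1))])
        out = (self.affine @ homog.T).T[:, :3]
        return out[0] if out.shape[0] == 1 else out


class SpacingError(ValueError):
    """Inter-slice spacing is non-uniform beyond tolerance."""


def stack_series(series_dir: str | Path) -> Volume:
    """Read a sorted single-series directory into a :class:`Volume`.

    Slices are ordered by the projection of their position onto the slice
    normal (robust to reversed acquisitions); a disagreement with the
    instance-number order is logged, not fatal. Mixed orientations or a
    non-uniform slice spacing abort with a descriptive error.
    """
    series_dir = Path(series_dir)
    records = [
        dc.read_slice(p)
        for p in sorted(series_dir.iterdir())
        if p.is_file() and dc.classify_file(p).status == dc.VALID
    ]
    if len(records) < 2:
        raise ValueError(f"{series_dir}: need at least 2 slices, found {len(records)}")
    if len({r.series_uid for r in records}) > 1:
        raise ValueError(f"{series_dir} mixes multiple series UIDs")

    first = records[0]
    for r in records[1:]:
        if not (
            np.allclose(r.image_orientation[0], first.image_orientation[0], atol=1e-6)
            and np.allclose(r.image_orientation[1], first.image_orientation[1], atol=1e-6)
        ):
            raise ValueError(f"{series_dir}: mixed slice orientations")
        if r.stored_pixels.shape != first.stored_pixels.shape:
            raise ValueError(f"{series_dir}: inconsistent matrix sizes")

    normal = first.slice_normal
    proj = np.array([float(r.image_position @ normal) for r in records])
    order = np.argsort(proj, kind="stable")
    records = [records[i] for i in order]
    proj = proj[order]

    inst = [r.instance_number for r in records]
    if all(i is not None for i in inst) and inst != sorted(inst):
        log.info(
            "%s: geometric slice order differs from instance-number order", series_dir
        )

    gaps = np.diff(proj)
    if np.any(gaps <= 0):
        raise SpacingError(f"{series_dir}: duplicate or non-increasing slice positions")
    if np.ptp(gaps) > SPACING_TOL:
        k = int(np.argmax(np.abs(gaps - np.median(gaps))))
        raise SpacingError(
            f"{series_dir}: non-uniform slice spacing — gap between slices "
            f"{k} and {k + 1} is {gaps[k]:.4f} mm vs median {np.median(gaps):.4f} mm"
        )
    slice_spacing = float(np.mean(gaps))

    voxels = np.stack([r.hu() for r in records], axis=2)
    affine = _build_affine(first, slice_spacing, normal)
    return Volume(
        voxels=voxels,
        affine=affine,
        spacing=(first.pixel_spacing_row, first.pixel_spacing_col, slice_spacing),
        series_number=first.series_number,
        series_uid=first.series_uid,
    )


def _build_affine(
    first: SliceRecord, slice_spacing: float, normal: np.ndarray
) -> np.ndarray:
    row_dir, col_dir = first.image_orientation
    lps = np.eye(4)
    # Voxel axis 0 = image row index (direction of increasing row = col_dir,
    # step = row spacing); axis 1 = column index; axis 2 = slice index.
    lps[:3, 0] = col_dir * first.pixel_spacing_row
    lps[:3, 1] = row_dir * first.pixel_spacing_col
    lps[:3, 2] = normal * slice_spacing
    lps[:3, 3] = first.image_position
    return _LPS_TO_RAS @ lps


def write_volume_nifti(
    volume: Volume, out_path: str | Path, compress: bool = False
) -> Path:
    """Write a single-file NIfTI-1 image; HU as int16, slope 1 / intercept 0."""
    out_path = Path(out_path)
    if compress and not out_path.name.endswith(".nii.gz"):
        out_path = out_path.with_suffix(".nii.gz")
    data = np.rint(volume.voxels).astype(np.int16)
    img = nib.Nifti1Image(data, volume.affine)
    img.header.set_zooms(tuple(abs(s) for s in volume.spacing))
    img.header["scl_slope"] = 1.0
    img.header["scl_inter"] = 0.0
    out_path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, out_path)
    return out_path


def export_series_nifti(
    series_dir: str | Path, out_dir: str | Path, compress: bool = False
) -> Path:
    """stack + write: one NIfTI file for one series directory."""
    series_dir = Path(series_dir)
    volume = stack_series(series_dir)
    label = (
        str(volume.series_number)
        if volume.series_number is not None
        else series_dir.name
    )
    suffix = ".nii.gz" if compress else ".nii"
    out = Path(out_dir) / f"{series_dir.parent.name}_series{label}{suffix}"
    return write_volume_nifti(volume, out, compress=compress)


def collect_outputs(search_root: str | Path, dest: str | Path) -> List[Path]:
    """Move every NIfTI file under ``search_root`` into ``dest``.

    Name collisions get ``-2``/``-3`` suffixes; the moved paths are returned.
    """
    search_root = Path(search_root)
    dest = Path(dest)
    dest.mkdir(parents=True, exist_ok=True)
    moved: List[Path] = []
    for path in sorted(search_root.rglob("*.nii")) + sorted(
        search_root.rglob("*.nii.gz")
    ):
        if dest in path.parents:
            continue
        target = dest / path.name
        n = 1
        while target.exists():
            n += 1
            stem = path.name
            for ext in (".nii.gz", ".nii"):
                if stem.endswith(ext):
                    target = dest / f"{stem[: -len(ext)]}-{n}{ext}"
                    break
        shutil.move(str(path), str(target))
        moved.append(target)
    return moved
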