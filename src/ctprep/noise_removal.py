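"""Stage S2: couch/table and background removal by patient masking.

The chain per slice is: convert stored pixels to HU → threshold the
tissue band → morphological closing → keep the largest connected
component (the patient cross-section; the couch arc is smaller and
disconnected) → fill interior holes (air-filled lumina) → zero every
stored pixel outside the mask → overwrite the DICOM file in place,
metadata untouched.

"Zero" is written in stored-pixel space: with the usual intercept of
−1024 a stored 0 reads back as −1024 HU, i.e. slightly below air — a
physically sensible background. The HU meaning of the background
therefore depends on each file's rescale intercept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Literal

import numpy as np
from scipy import ndimage
from skimage import morphology

from . import dicom_core as dc
from .dicom_core import SliceRecord

log = logging.getLogger(__name__)

#: Closing radius (px) applied before component labelling; bridges small
#: threshold dropouts at tissue interfaces without merging body and couch
#: (which sit many pixels apart in practice).
DEFAULT_CLOSE_RADIUS = 3


@dataclass(frozen=True)
class ThresholdSpec:
    """HU bands: a wide tissue band to detect the patient for masking, and a
    narrower bone band used by the 2-D export and isosurface stages.

    Defaults span soft tissue through cortical bone for the mask (so the
    whole patient, not just the skeleton, is preserved) and start at
    trabecular-bone density for the bone band. Both are configurable; the
    same machinery highlights any tissue of interest.
    """

    tissue_lower: float = -300.0
    tissue_upper: float = 3000.0
    bone_lower: float = 200.0
    bone_upper: float = 3000.0

    def __post_init__(self) -> None:
        if not self.tissue_lower < self.tissue_upper:
            raise ValueError("tissue band: lower must be < upper")
        if not self.bone_lower < self.bone_upper:
            raise ValueError("bone band: lower must be < upper")


@dataclass
class MaskImage:
    """Boolean patient mask for one slice, with provenance."""

    mask: np.ndarray
    source: Path | None = None
    spec: ThresholdSpec | None = None
    empty: bool = False  # no tissue found (e.g. scan padding slice)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.dtype != bool:
            raise ValueError("mask must be boolean")


@dataclass
class SliceReport:
    path: Path
    status: str  # "denoised" | "skipped" | "empty"
    detail: str = ""


def tissue_threshold(hu_matrix: np.ndarray, spec: ThresholdSpec) -> np.ndarray:
    """True where tissue_lower <= HU <= tissue_upper."""
    hu = np.asarray(hu_matrix, dtype=float)
    if not np.all(np.isfinite(hu)):
        raise ValueError("HU matrix contains non-finite values")
    return (hu >= spec.tissue_lower) & (hu <= spec.tissue_upper)


def build_patient_mask(
    binary: np.ndarray,
    close_radius: int = DEFAULT_CLOSE_RADIUS,
    source: Path | None = None,
    spec: ThresholdSpec | None = None,
) -> MaskImage:
    """Closing → largest connected component → hole fill.

    An all-false input (no tissue in the band) yields an all-false mask
    flagged ``empty`` — degenerate padding slices are not an error.
    """
    binary = np.asarray(binary)
    if binary.ndim != 2 or binary.dtype != bool:
        raise ValueError("expected a 2-D boolean matrix")
    if not binary.any():
        return MaskImage(np.zeros_like(binary), source=source, spec=spec, empty=True)
    closed = morphology.closing(binary, morphology.disk(close_radius))
    mask = _largest_component(closed)
    mask = ndimage.binary_fill_holes(mask)
    return MaskImage(mask, source=source, spec=spec)


def _largest_component(binary: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(binary)
    if n <= 1:
        return binary.astype(bool)
    areas = np.bincount(labels.ravel())
    areas[0] = 0
    return labels == int(np.argmax(areas))


def apply_mask(record: SliceRecord, mask: MaskImage) -> np.ndarray:
    """Stored pixels with everything outside the mask set to stored value 0."""
    if mask.mask.shape != record.stored_pixels.shape:
        raise ValueError(
            f"mask {mask.mask.shape} does not match slice {record.stored_pixels.shape}"
        )
    out = record.stored_pixels.copy()
    out[~mask.mask] = 0
    return out


def denoise_slice(
    path: str | Path,
    spec: ThresholdSpec,
    close_radius: int = DEFAULT_CLOSE_RADIUS,
) -> SliceReport:
    """Run the full Original Image → Mask → Final Image chain on one file,
    overwriting it in place. Invalid files are skipped, not raised."""
    path = Path(path)
    cls = dc.classify_file(path)
    if cls.status != dc.VALID:
        log.warning("skipping %s: %s (%s)", path, cls.status, cls.detail)
        return SliceReport(path, "skipped", f"{cls.status}: {cls.detail}")
    record = dc.read_slice(path)
    binary = tissue_threshold(record.hu(), spec)
    mask = build_patient_mask(binary, close_radius, source=path, spec=spec)
    dc.overwrite_pixels(record, apply_mask(record, mask))
    return SliceReport(path, "empty" if mask.empty else "denoised")


def denoise_series(
    series_dir: str | Path,
    spec: ThresholdSpec,
    mode: Literal["per-slice", "volumetric"] = "per-slice",
    close_radius: int = DEFAULT_CLOSE_RADIUS,
) -> List[SliceReport]:
    """Denoise every slice of one sorted series.

    ``volumetric`` mode thresholds the stacked 3-D grid, keeps the largest
    3-D connected component (26-connectivity) and applies its per-slice
    sections — useful where the per-slice largest component is ambiguous
    (e.g. slices through both legs). A directory mixing series UIDs is
    rejected before anything is modified.
    """
    series_dir = Path(series_dir)
    if not series_dir.is_dir():
        raise NotADirectoryError(series_dir)
    paths = sorted(p for p in series_dir.iterdir() if p.is_file())
    records: List[SliceRecord] = []
    reports: List[SliceReport] = []
    valid_paths: List[Path] = []
    for p in paths:
        cls = dc.classify_file(p)
        if cls.status != dc.VALID:
            reports.append(SliceReport(p, "skipped", f"{cls.status}: {cls.detail}"))
        else:
            records.append(dc.read_slice(p))
            valid_paths.append(p)
    uids = {r.series_uid for r in records}
    if len(uids) > 1:
        raise ValueError(
            f"{series_dir} mixes {len(uids)} series UIDs; sort the study first"
        )

    if mode == "per-slice":
        for rec in records:
            binary = tissue_threshold(rec.hu(), spec)
            mask = build_patient_mask(
                binary, close_radius, source=rec.source_path, spec=spec
            )
            dc.overwrite_pixels(rec, apply_mask(rec, mask))
            reports.append(
                SliceReport(rec.source_path, "empty" if mask.empty else "denoised")
            )
    elif mode == "volumetric":
        if records:
            masks = _volumetric_masks(records, spec, close_radius)
            for rec, m in zip(records, masks):
                dc.overwrite_pixels(
                    rec, apply_mask(rec, MaskImage(m, source=rec.source_path, spec=spec))
                )
                reports.append(
                    SliceReport(rec.source_path, "denoised" if m.any() else "empty")
                )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return reports


def _volumetric_masks(
    records: List[SliceRecord], spec: ThresholdSpec, close_radius: int
) -> List[np.ndarray]:
    order = np.argsort(
        [float(r.image_position @ r.slice_normal) for r in records], kind="stable"
    )
    binary = np.stack(
        [tissue_threshold(records[i].hu(), spec) for i in order], axis=2
    )
    # In-plane closing per slice (matches per-slice mode), 3-D component
    # selection across the stack.
    selem = morphology.disk(close_radius)
    for k in range(binary.shape[2]):
        if binary[:, :, k].any():
            binary[:, :, k] = morphology.closing(binary[:, :, k], selem)
    labels, n = ndimage.label(binary, structure=np.ones((3, 3, 3), dtype=int))
    if n > 1:
        areas = np.bincount(labels.ravel())
        areas[0] = 0
        binary = labels == int(np.argmax(areas))
    masks_sorted = []
    for k in range(binary.shape[2]):
        m = binary[:, :, k]
        if m.any():
            m = ndimage.binary_fill_holes(m)
        masks_sorted.append(m)
    out: List[np.ndarray] = [None] * len(records)  # type: ignore[list-item]
    for pos, i in enumerate(order):
        out[i] = masks_sorted[pos]
    return out


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap coefficient between two boolean masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
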