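"""Decode, validate and re-write CT DICOM slices; Hounsfield-unit conversion.

A CT slice stores raw scanner integers; the linear rescale
``HU = stored * RescaleSlope + RescaleIntercept`` maps them to Hounsfield
units (air ~ -1000 HU, water = 0 HU). Everything downstream — thresholding,
masking, volume stacking — works in HU, and results are converted back to
stored units when a file is overwritten in place.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict

import numpy as np

from . import _dicomio as dio
from ._dicomio import (
    CorruptedDicomError,
    DicomFile,
    Element,
    NotDicomError,
    Tag,
)

log = logging.getLogger(__name__)

VALID = "valid"
NON_DICOM = "non_dicom"
CORRUPTED = "corrupted"

#: Attributes every pipeline stage needs; a file missing any of them is
#: unusable and classified as corrupted.
REQUIRED_TAGS: tuple[Tag, ...] = (
    (0x0028, 0x0010),  # Rows
    (0x0028, 0x0011),  # Columns
    (0x0028, 0x0030),  # Pixel Spacing
    (0x0018, 0x0050),  # Slice Thickness
    (0x0020, 0x0032),  # Image Position (Patient)
    (0x0020, 0x0037),  # Image Orientation (Patient)
    (0x0028, 0x1052),  # Rescale Intercept
    (0x0028, 0x1053),  # Rescale Slope
    (0x7FE0, 0x0010),  # Pixel Data
)

_NAMED_TAGS: frozenset[Tag] = frozenset(REQUIRED_TAGS) | {
    (0x0020, 0x000E),
    (0x0020, 0x0011),
    (0x0020, 0x0013),
}

#: Attribute keywords resolvable by metadata predicates, beyond the
#: SliceRecord field names themselves.
KEYWORD_TAGS: Dict[str, Tag] = {
    "patient_sex": (0x0010, 0x0040),
    "patient_age": (0x0010, 0x1010),
    "patient_name": (0x0010, 0x0010),
    "series_date": (0x0008, 0x0021),
    "study_date": (0x0008, 0x0020),
    "modality": (0x0008, 0x0060),
    "sop_instance_uid": (0x0008, 0x0018),
}

_ORTHO_TOL = 1e-4


@dataclass(frozen=True)
class FileClassification:
    """Outcome of inspecting one file: valid / non_dicom / corrupted."""

    status: str
    detail: str = ""

    def __post_init__(self) -> None:
        if self.status not in (VALID, NON_DICOM, CORRUPTED):
            raise ValueError(f"unknown status {self.status!r}")
        if self.status != VALID and not self.detail:
            raise ValueError("non-valid classification requires a detail message")


class InvalidSliceError(Exception):
    """Raised when an operation is attempted on a non-valid file."""

    def __init__(self, classification: FileClassification, path: Path):
        self.classification = classification
        self.path = path
        super().__init__(f"{path}: {classification.status} ({classification.detail})")


@dataclass
class SliceRecord:
    """One decoded CT slice: stored pixels plus the metadata the pipeline uses.

    ``extra_tags`` carries every attribute not mapped to a named field, as
    raw (VR, value-bytes) pairs, so an unmodified record round-trips
    byte-for-byte through :func:`overwrite_pixels`.
    """

    stored_pixels: np.ndarray
    rescale_slope: float
    rescale_intercept: float
    pixel_spacing_row: float
    pixel_spacing_col: float
    slice_thickness: float
    image_position: np.ndarray
    image_orientation: tuple[np.ndarray, np.ndarray]
    series_number: int | None
    series_uid: str | None
    instance_number: int | None
    source_path: Path
    bits_stored: int
    pixel_representation: int
    extra_tags: Dict[Tag, tuple[str, bytes]] = field(default_factory=dict)
    _dicom: DicomFile | None = field(default=None, repr=False, compare=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.stored_pixels.shape  # type: ignore[return-value]

    @property
    def slice_normal(self) -> np.ndarray:
        """Unit normal of the slice plane (row_dir x col_dir)."""
        r, c = self.image_orientation
        return np.cross(r, c)

    def hu(self) -> np.ndarray:
        """Pixel matrix in Hounsfield units (float64)."""
        return stored_to_hu(
            self.stored_pixels, self.rescale_slope, self.rescale_intercept
        )

    def stored_range(self) -> tuple[int, int]:
        """(min, max) representable stored value for this slice's bit depth."""
        if self.pixel_representation == 1:
            return -(1 << (self.bits_stored - 1)), (1 << (self.bits_stored - 1)) - 1
        return 0, (1 << self.bits_stored) - 1


# ---------------------------------------------------------------------------
# Classification and reading


def classify_file(path: str | Path) -> FileClassification:
    """Classify ``path`` as valid, non_dicom or corrupted.

    Valid means: Part-10 signature present, the whole file parses under a
    supported transfer syntax, pixel data decodes, and every attribute the
    pipeline requires is present and well-formed.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    try:
        _load_record(path)
    except NotDicomError as exc:
        return FileClassification(NON_DICOM, str(exc))
    except CorruptedDicomError as exc:
        return FileClassification(CORRUPTED, str(exc))
    return FileClassification(VALID)


def read_slice(path: str | Path) -> SliceRecord:
    """Read a valid DICOM slice into a :class:`SliceRecord`.

    Raises :class:`InvalidSliceError` when the file is not valid.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    try:
        return _load_record(path)
    except NotDicomError as exc:
        raise InvalidSliceError(FileClassification(NON_DICOM, str(exc)), path) from exc
    except CorruptedDicomError as exc:
        raise InvalidSliceError(FileClassification(CORRUPTED, str(exc)), path) from exc


def _load_record(path: Path) -> SliceRecord:
    df = dio.read_file(path)

    for tag in REQUIRED_TAGS:
        if tag not in df.elements:
            raise CorruptedDicomError(f"missing required attribute {_name(tag)}")
    if (0x0020, 0x000E) not in df.elements and (0x0020, 0x0011) not in df.elements:
        raise CorruptedDicomError("missing both series UID and series number")

    rows = df.ushort((0x0028, 0x0010))
    cols = df.ushort((0x0028, 0x0011))
    if not rows or not cols:
        raise CorruptedDicomError("zero-sized pixel matrix")
    bits_alloc = df.ushort((0x0028, 0x0100), 16)
    bits_stored = df.ushort((0x0028, 0x0101), bits_alloc)
    pixel_rep = df.ushort((0x0028, 0x0103), 0)
    if bits_alloc not in (8, 16):
        raise CorruptedDicomError(f"unsupported bits allocated {bits_alloc}")

    pix = df.elements[dio.PIXEL_DATA].value
    itemsize = bits_alloc // 8
    expected = rows * cols * itemsize
    if len(pix) < expected:
        raise CorruptedDicomError(
            f"pixel data truncated: {len(pix)} bytes, expected {expected}"
        )
    dtype = {(8, 0): np.uint8, (8, 1): np.int8, (16, 0): np.uint16, (16, 1): np.int16}[
        (bits_alloc, pixel_rep)
    ]
    stored = np.frombuffer(pix[:expected], dtype=np.dtype(dtype).newbyteorder("<"))
    stored = stored.reshape(rows, cols)

    spacing = df.floats((0x0028, 0x0030))
    if len(spacing) != 2 or min(spacing) <= 0:
        raise CorruptedDicomError(f"bad pixel spacing {spacing}")
    thickness = df.floats((0x0018, 0x0050))
    if len(thickness) != 1 or thickness[0] <= 0:
        raise CorruptedDicomError(f"bad slice thickness {thickness}")
    position = df.floats((0x0020, 0x0032))
    if len(position) != 3:
        raise CorruptedDicomError(f"bad image position {position}")
    orient = df.floats((0x0020, 0x0037))
    if len(orient) != 6:
        raise CorruptedDicomError(f"bad image orientation {orient}")
    row_dir = np.asarray(orient[:3], dtype=float)
    col_dir = np.asarray(orient[3:], dtype=float)
    if abs(np.linalg.norm(row_dir) - 1) > _ORTHO_TOL or abs(
        np.linalg.norm(col_dir) - 1
    ) > _ORTHO_TOL:
        raise CorruptedDicomError("orientation vectors are not unit length")
    if abs(float(row_dir @ col_dir)) > _ORTHO_TOL:
        raise CorruptedDicomError("orientation vectors are not orthogonal")

    slope = df.floats((0x0028, 0x1053))
    intercept = df.floats((0x0028, 0x1052))
    if len(slope) != 1 or slope[0] == 0:
        raise CorruptedDicomError(f"bad rescale slope {slope}")
    if len(intercept) != 1:
        raise CorruptedDicomError(f"bad rescale intercept {intercept}")

    series_numbers = df.ints((0x0020, 0x0011)) if (0x0020, 0x0011) in df.elements else []
    instance_numbers = (
        df.ints((0x0020, 0x0013)) if (0x0020, 0x0013) in df.elements else []
    )

    extra = {
        tag: (el.vr, el.value)
        for tag, el in df.elements.items()
        if tag not in _NAMED_TAGS and tag != dio.PIXEL_DATA
    }
    return SliceRecord(
        stored_pixels=stored,
        rescale_slope=slope[0],
        rescale_intercept=intercept[0],
        pixel_spacing_row=spacing[0],
        pixel_spacing_col=spacing[1],
        slice_thickness=thickness[0],
        image_position=np.asarray(position, dtype=float),
        image_orientation=(row_dir, col_dir),
        series_number=series_numbers[0] if series_numbers else None,
        series_uid=df.string((0x0020, 0x000E)),
        instance_number=instance_numbers[0] if instance_numbers else None,
        source_path=Path(path),
        bits_stored=bits_stored,
        pixel_representation=pixel_rep,
        extra_tags=extra,
        _dicom=df,
    )


def _name(tag: Tag) -> str:
    return f"({tag[0]:04X},{tag[1]:04X})"


# ---------------------------------------------------------------------------
# Hounsfield conversion


def stored_to_hu(stored, slope: float, intercept: float):
    """Linear rescale of stored scanner values to Hounsfield units."""
    if slope == 0:
        raise ValueError("rescale slope must be non-zero")
    return np.asarray(stored, dtype=np.float64) * slope + intercept


def hu_to_stored(
    hu,
    slope: float,
    intercept: float,
    bits_stored: int = 16,
    pixel_representation: int = 0,
):
    """Invert the rescale, rounding to nearest and clamping to the stored range.

    Clamping prevents silent integer wrap-around when an HU value falls
    outside what the slice's declared bit depth can represent.
    """
    if slope == 0:
        raise ValueError("rescale slope must be non-zero")
    if pixel_representation == 1:
        lo, hi = -(1 << (bits_stored - 1)), (1 << (bits_stored - 1)) - 1
    else:
        lo, hi = 0, (1 << bits_stored) - 1
    raw = np.rint((np.asarray(hu, dtype=np.float64) - intercept) / slope)
    clipped = np.clip(raw, lo, hi)
    if np.isscalar(hu) or np.ndim(hu) == 0:
        return int(clipped)
    return clipped.astype(np.int64)


# ---------------------------------------------------------------------------
# In-place rewrite


def overwrite_pixels(record: SliceRecord, new_pixels: np.ndarray) -> None:
    """Replace the pixel payload of ``record``'s file, keeping all metadata.

    The file at ``record.source_path`` is rewritten atomically. Dimension
    mismatches are rejected before anything is touched.
    """
    new_pixels = np.asarray(new_pixels)
    if new_pixels.shape != record.stored_pixels.shape:
        raise ValueError(
            f"pixel matrix {new_pixels.shape} does not match slice "
            f"{record.stored_pixels.shape}; file untouched"
        )
    df = record._dicom
    if df is None:
        raise ValueError("record was not read from a file")
    lo, hi = record.stored_range()
    vals = np.asarray(new_pixels, dtype=np.int64)
    if vals.min() < lo or vals.max() > hi:
        raise ValueError(
            f"pixel values outside stored range [{lo}, {hi}] for "
            f"{record.bits_stored}-bit data"
        )
    payload = vals.astype(record.stored_pixels.dtype.newbyteorder("<")).tobytes()
    old = df.elements[dio.PIXEL_DATA]
    df.elements[dio.PIXEL_DATA] = Element(dio.PIXEL_DATA, old.vr, payload)
    dio.write_file(record.source_path, df)
    log.debug("overwrote pixel data of %s", record.source_path)


def diff_metadata(path_a: str | Path, path_b: str | Path) -> list[Tag]:
    """Tags (excluding pixel data) whose raw values differ between two files."""
    a = dio.read_file(path_a)
    b = dio.read_file(path_b)
    tags = (set(a.elements) | set(b.elements)) - {dio.PIXEL_DATA}
    diffs = []
    for tag in sorted(tags):
        ea, eb = a.elements.get(tag), b.elements.get(tag)
        if ea is None or eb is None or ea.value != eb.value or ea.vr != eb.vr:
            diffs.append(tag)
    return diffs


def get_attribute(record: SliceRecord, name: str):
    """Resolve a metadata attribute by name for predicate evaluation.

    Accepts SliceRecord field names (``slice_thickness``, ``series_number``,
    ...) plus a small set of common DICOM keywords (``patient_sex``,
    ``patient_age``, ...). Raises ``KeyError`` if unresolvable.
    """
    simple = {
        "slice_thickness": record.slice_thickness,
        "series_number": record.series_number,
        "series_uid": record.series_uid,
        "instance_number": record.instance_number,
        "pixel_spacing_row": record.pixel_spacing_row,
        "pixel_spacing_col": record.pixel_spacing_col,
        "rescale_slope": record.rescale_slope,
        "rescale_intercept": record.rescale_intercept,
        "rows": record.stored_pixels.shape[0],
        "columns": record.stored_pixels.shape[1],
    }
    if name in simple:
        val = simple[name]
        if val is None:
            raise KeyError(name)
        return val
    tag = KEYWORD_TAGS.get(name)
    if tag is None or tag not in record.extra_tags:
        raise KeyError(name)
    vr, raw = record.extra_tags[tag]
    text = raw.decode("ascii", errors="replace").rstrip(" \x00")
    if vr == "DS":
        return float(text)
    if vr in ("IS", "US", "UL"):
        return int(text) if vr == "IS" else int.from_bytes(raw[:2], "little")
    return text
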