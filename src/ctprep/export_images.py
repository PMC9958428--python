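"""Stage S3: window denoised slices into 8-bit PNG/JPEG images.

Windowing maps an HU interval linearly onto display intensities 0–255 with
clipping; the default window is the bone band, so bone renders bright and
soft tissue dark. A binary mode (0/255 at the window) is available for
strict thresholded output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import List, Literal

import numpy as np
from PIL import Image

from . import dicom_core as dc

log = logging.getLogger(__name__)

_FORMATS = {"png": "PNG", "jpeg": "JPEG", "jpg": "JPEG"}


@dataclass(frozen=True)
class WindowSpec:
    hu_min: float = 200.0
    hu_max: float = 3000.0
    format: str = "png"
    jpeg_quality: int = 95
    binary: bool = False  # emit 0/255 instead of a linear ramp

    def __post_init__(self) -> None:
        if not self.hu_min < self.hu_max:
            raise ValueError("hu_min must be < hu_max")
        if self.format.lower() not in _FORMATS:
            raise ValueError(f"unsupported format {self.format!r}; use png or jpeg")
        if not 1 <= self.jpeg_quality <= 100:
            raise ValueError("jpeg_quality must be in 1..100")

    @property
    def suffix(self) -> str:
        return ".jpg" if _FORMATS[self.format.lower()] == "JPEG" else ".png"


def window_to_8bit(hu_matrix: np.ndarray, window: WindowSpec) -> np.ndarray:
    """intensity = round(255·(HU−hu_min)/(hu_max−hu_min)), clipped to [0,255].

    Rounding is half-up so the exact window midpoint maps to 128. In binary
    mode, pixels inside [hu_min, hu_max] become 255 and the rest 0.
    """
    hu = np.asarray(hu_matrix, dtype=float)
    if not np.all(np.isfinite(hu)):
        raise ValueError("HU matrix contains non-finite values")
    if window.binary:
        inside = (hu >= window.hu_min) & (hu <= window.hu_max)
        return np.where(inside, 255, 0).astype(np.uint8)
    scaled = 255.0 * (hu - window.hu_min) / (window.hu_max - window.hu_min)
    return np.clip(np.floor(scaled + 0.5), 0, 255).astype(np.uint8)


def slice_to_image(
    hu_matrix: np.ndarray, window: WindowSpec, out_path: str | Path
) -> Path:
    """Write one HU matrix as an 8-bit grayscale image file."""
    out_path = Path(out_path)
    arr = window_to_8bit(hu_matrix, window)
    img = Image.fromarray(arr, mode="L")
    fmt = _FORMATS[window.format.lower()]
    if fmt == "JPEG":
        img.save(out_path, format=fmt, quality=window.jpeg_quality)
    else:
        img.save(out_path, format=fmt)
    return out_path


def export_series_images(
    series_dir: str | Path, window: WindowSpec, out_dir: str | Path
) -> List[Path]:
    """One image per valid slice; filenames carry the instance number."""
    series_dir = Path(series_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    for path in sorted(p for p in series_dir.iterdir() if p.is_file()):
        cls = dc.classify_file(path)
        if cls.status != dc.VALID:
            log.warning("skipping %s: %s", path, cls.status)
            continue
        record = dc.read_slice(path)
        inst = record.instance_number if record.instance_number is not None else 0
        name = f"{path.stem}_i{inst:04d}{window.suffix}"
        written.append(slice_to_image(record.hu(), window, out_dir / name))
    return written
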