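"""Minimal DICOM Part-10 codec.

Supports exactly the file class this pipeline consumes and emits:
128-byte preamble + ``DICM`` magic, explicit or implicit VR little-endian
transfer syntaxes, uncompressed pixel data. Sequences with defined length
are carried opaquely; undefined-length elements are rejected. Everything
outside that envelope (compressed syntaxes, big-endian, DICOMDIR,
multi-frame enhanced CT) is out of scope and classified as unsupported.

Elements are kept as raw value bytes keyed by tag, so re-serialising a file
that was read under the same transfer syntax is byte-preserving for every
element we do not explicitly modify.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Tuple

Tag = Tuple[int, int]

EXPLICIT_VR_LE = "1.2.840.10008.1.2.1"
IMPLICIT_VR_LE = "1.2.840.10008.1.2"
SUPPORTED_SYNTAXES = (EXPLICIT_VR_LE, IMPLICIT_VR_LE)

CT_IMAGE_STORAGE = "1.2.840.10008.5.1.4.1.1.2"
# Root used for generated UIDs ("2.25." + decimal UUID is the standard
# registration-free form).
UID_ROOT = "2.25."
IMPLEMENTATION_UID = UID_ROOT + "680042251093011"

# VRs whose explicit encoding uses a 2-byte reserved field + 4-byte length.
_LONG_VRS = frozenset({"OB", "OW", "OF", "OD", "OL", "SQ", "UC", "UR", "UT", "UN"})
_UNDEFINED_LENGTH = 0xFFFFFFFF

# Tag -> VR for the attributes the pipeline interprets; also used to assign
# VRs when reading implicit-VR files. Unknown implicit tags become UN.
VR_DICT: Dict[Tag, str] = {
    (0x0002, 0x0000): "UL",  # File Meta Information Group Length
    (0x0002, 0x0001): "OB",  # File Meta Information Version
    (0x0002, 0x0002): "UI",  # Media Storage SOP Class UID
    (0x0002, 0x0003): "UI",  # Media Storage SOP Instance UID
    (0x0002, 0x0010): "UI",  # Transfer Syntax UID
    (0x0002, 0x0012): "UI",  # Implementation Class UID
    (0x0008, 0x0016): "UI",  # SOP Class UID
    (0x0008, 0x0018): "UI",  # SOP Instance UID
    (0x0008, 0x0020): "DA",  # Study Date
    (0x0008, 0x0021): "DA",  # Series Date
    (0x0008, 0x0030): "TM",  # Study Time
    (0x0008, 0x0060): "CS",  # Modality
    (0x0010, 0x0010): "PN",  # Patient Name
    (0x0010, 0x0020): "LO",  # Patient ID
    (0x0010, 0x0040): "CS",  # Patient Sex
    (0x0010, 0x1010): "AS",  # Patient Age
    (0x0018, 0x0050): "DS",  # Slice Thickness
    (0x0020, 0x000D): "UI",  # Study Instance UID
    (0x0020, 0x000E): "UI",  # Series Instance UID
    (0x0020, 0x0011): "IS",  # Series Number
    (0x0020, 0x0013): "IS",  # Instance Number
    (0x0020, 0x0032): "DS",  # Image Position (Patient)
    (0x0020, 0x0037): "DS",  # Image Orientation (Patient)
    (0x0028, 0x0002): "US",  # Samples per Pixel
    (0x0028, 0x0004): "CS",  # Photometric Interpretation
    (0x0028, 0x0010): "US",  # Rows
    (0x0028, 0x0011): "US",  # Columns
    (0x0028, 0x0030): "DS",  # Pixel Spacing
    (0x0028, 0x0100): "US",  # Bits Allocated
    (0x0028, 0x0101): "US",  # Bits Stored
    (0x0028, 0x0102): "US",  # High Bit
    (0x0028, 0x0103): "US",  # Pixel Representation
    (0x0028, 0x1052): "DS",  # Rescale Intercept
    (0x0028, 0x1053): "DS",  # Rescale Slope
    (0x7FE0, 0x0010): "OW",  # Pixel Data
}

PIXEL_DATA: Tag = (0x7FE0, 0x0010)


class DicomError(Exception):
    """Base class for codec failures."""


class NotDicomError(DicomError):
    """The file lacks the Part-10 signature."""


class CorruptedDicomError(DicomError):
    """Signature present, but the file cannot be fully parsed/decoded."""


@dataclass
class Element:
    tag: Tag
    vr: str
    value: bytes

    def __post_init__(self) -> None:
        if len(self.value) % 2:
            pad = b"\x00" if self.vr in ("UI", "OB", "UN") else b" "
            self.value = self.value + pad


@dataclass
class DicomFile:
    """A parsed single-frame DICOM file: file-meta group + main data set."""

    meta: Dict[Tag, Element]
    elements: Dict[Tag, Element]
    transfer_syntax: str
    path: Path | None = None

    def get(self, tag: Tag) -> Element | None:
        return self.elements.get(tag)

    def set(self, tag: Tag, vr: str, value: bytes) -> None:
        self.elements[tag] = Element(tag, vr, value)

    # -- typed accessors -------------------------------------------------
    def string(self, tag: Tag, default: str | None = None) -> str | None:
        el = self.elements.get(tag)
        if el is None:
            return default
        return el.value.decode("ascii", errors="replace").rstrip(" \x00")

    def floats(self, tag: Tag) -> list[float]:
        s = self.string(tag)
        if s is None or s == "":
            return []
        return [float(part) for part in s.split("\\")]

    def ints(self, tag: Tag) -> list[int]:
        s = self.string(tag)
        if s is None or s == "":
            return []
        return [int(part) for part in s.split("\\")]

    def ushort(self, tag: Tag, default: int | None = None) -> int | None:
        el = self.elements.get(tag)
        if el is None:
            return default
        if len(el.value) < 2:
            raise CorruptedDicomError(f"tag {_fmt_tag(tag)}: US value too short")
        return struct.unpack("<H", el.value[:2])[0]


def _fmt_tag(tag: Tag) -> str:
    return f"({tag[0]:04X},{tag[1]:04X})"


# ---------------------------------------------------------------------------
# Value encoding helpers


def encode_string(value: str) -> bytes:
    return value.encode("ascii")

def encode_ds(values: Iterable[float]) -> bytes:
    parts = []
    for v in values:
        s = f"{v:.10g}"
        parts.append(s)
    return "\\".join(parts).encode("ascii")

def encode_is(values: Iterable[int]) -> bytes:
    return "\\".join(str(int(v)) for v in values).encode("ascii")

def encode_us(value: int) -> bytes:
    return struct.pack("<H", int(value))


# ---------------------------------------------------------------------------
# Parsing


def read_file(path: str | Path) -> DicomFile:
    """Parse a Part-10 file.

    Raises ``NotDicomError`` when the DICM signature is absent,
    ``CorruptedDicomError`` when the signature is present but the file does
    not parse under a supported transfer syntax.
    """
    path = Path(path)
    data = path.read_bytes()
    if len(data) < 132 or data[128:132] != b"DICM":
        raise NotDicomError("no DICM signature at offset 128")
    try:
        meta, pos = _parse_meta_group(data, 132)
        ts_el = meta.get((0x0002, 0x0010))
        ts = (
            ts_el.value.decode("ascii").rstrip(" \x00")
            if ts_el is not None
            else EXPLICIT_VR_LE
        )
        if ts not in SUPPORTED_SYNTAXES:
            raise CorruptedDicomError(f"unsupported transfer syntax {ts!r}")
        elements = _parse_dataset(data, pos, explicit=(ts == EXPLICIT_VR_LE))
    except CorruptedDicomError:
        raise
    except NotDicomError:
        raise
    except Exception as exc:  # struct errors, decode errors, truncation
        raise CorruptedDicomError(f"parse failure: {exc}") from exc
    return DicomFile(meta=meta, elements=elements, transfer_syntax=ts, path=path)


def _parse_meta_group(data: bytes, pos: int) -> tuple[Dict[Tag, Element], int]:
    """File meta group (0002,xxxx) is always explicit VR little-endian."""
    meta: Dict[Tag, Element] = {}
    end = len(data)
    while pos + 8 <= end:
        group = struct.unpack_from("<H", data, pos)[0]
        if group != 0x0002:
            break
        el, pos = _parse_explicit_element(data, pos)
        meta[el.tag] = el
        if el.tag == (0x0002, 0x0000):
            # Group length tells us exactly where the meta group ends.
            glen = struct.unpack("<I", el.value[:4])[0]
            meta_end = pos + glen
            while pos < meta_end:
                el, pos = _parse_explicit_element(data, pos)
                if el.tag[0] != 0x0002:
                    raise CorruptedDicomError("non-0002 tag inside file meta group")
                meta[el.tag] = el
            break
    if not meta:
        raise CorruptedDicomError("empty file meta group")
    return meta, pos


def _parse_explicit_element(data: bytes, pos: int) -> tuple[Element, int]:
    if pos + 8 > len(data):
        raise CorruptedDicomError("truncated element header")
    group, elem = struct.unpack_from("<HH", data, pos)
    pos += 4
    vr = data[pos : pos + 2].decode("ascii", errors="replace")
    pos += 2
    if not vr.isalpha() or not vr.isupper():
        raise CorruptedDicomError(f"invalid VR {vr!r} at tag {_fmt_tag((group, elem))}")
    if vr in _LONG_VRS:
        if pos + 6 > len(data):
            raise CorruptedDicomError("truncated long-VR header")
        length = struct.unpack_from("<I", data, pos + 2)[0]
        pos += 6
    else:
        if pos + 2 > len(data):
            raise CorruptedDicomError("truncated short-VR header")
        length = struct.unpack_from("<H", data, pos)[0]
        pos += 2
    if length == _UNDEFINED_LENGTH:
        raise CorruptedDicomError(
            f"undefined-length element {_fmt_tag((group, elem))} not supported"
        )
    if pos + length > len(data):
        raise CorruptedDicomError(
            f"element {_fmt_tag((group, elem))} value truncated "
            f"({pos + length - len(data)} bytes missing)"
        )
    value = data[pos : pos + length]
    return Element((group, elem), vr, value), pos + length


def _parse_implicit_element(data: bytes, pos: int) -> tuple[Element, int]:
    if pos + 8 > len(data):
        raise CorruptedDicomError("truncated element header")
    group, elem, length = struct.unpack_from("<HHI", data, pos)
    pos += 8
    if length == _UNDEFINED_LENGTH:
        raise CorruptedDicomError(
            f"undefined-length element {_fmt_tag((group, elem))} not supported"
        )
    if pos + length > len(data):
        raise CorruptedDicomError(f"element {_fmt_tag((group, elem))} value truncated")
    vr = VR_DICT.get((group, elem), "UN")
    return Element((group, elem), vr, data[pos : pos + length]), pos + length


def _parse_dataset(data: bytes, pos: int, explicit: bool) -> Dict[Tag, Element]:
    parse = _parse_explicit_element if explicit else _parse_implicit_element
    elements: Dict[Tag, Element] = {}
    while pos < len(data):
        el, pos = parse(data, pos)
        elements[el.tag] = el
    return elements


# ---------------------------------------------------------------------------
# Serialisation


def _encode_element(el: Element, explicit: bool) -> bytes:
    group, elem = el.tag
    if explicit:
        vr = el.vr
        if vr in _LONG_VRS:
            head = struct.pack("<HH2sHI", group, elem, vr.encode(), 0, len(el.value))
        else:
            if len(el.value) > 0xFFFF:
                raise DicomError(
                    f"value of {_fmt_tag(el.tag)} too long for short-VR encoding"
                )
            head = struct.pack("<HH2sH", group, elem, vr.encode(), len(el.value))
    else:
        head = struct.pack("<HHI", group, elem, len(el.value))
    return head + el.value


def write_file(
    path: str | Path,
    dicom: DicomFile,
    transfer_syntax: str | None = None,
) -> None:
    """Serialise ``dicom`` to ``path`` atomically (tmp file + rename)."""
    ts = transfer_syntax or dicom.transfer_syntax
    if ts not in SUPPORTED_SYNTAXES:
        raise DicomError(f"unsupported transfer syntax {ts!r}")
    explicit = ts == EXPLICIT_VR_LE

    meta = dict(dicom.meta)
    meta[(0x0002, 0x0010)] = Element((0x0002, 0x0010), "UI", encode_string(ts))
    body_meta = b"".join(
        _encode_element(meta[tag], explicit=True)
        for tag in sorted(meta)
        if tag != (0x0002, 0x0000)
    )
    group_len = Element((0x0002, 0x0000), "UL", struct.pack("<I", len(body_meta)))
    meta_bytes = _encode_element(group_len, explicit=True) + body_meta

    body = b"".join(
        _encode_element(dicom.elements[tag], explicit) for tag in sorted(dicom.elements)
    )
    payload = b"\x00" * 128 + b"DICM" + meta_bytes + body

    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_bytes(payload)
    tmp.replace(path)


def make_meta(
    sop_instance_uid: str,
    sop_class_uid: str = CT_IMAGE_STORAGE,
    transfer_syntax: str = EXPLICIT_VR_LE,
) -> Dict[Tag, Element]:
    """Build a fresh file-meta group for a new file."""
    return {
        (0x0002, 0x0001): Element((0x0002, 0x0001), "OB", b"\x00\x01"),
        (0x0002, 0x0002): Element((0x0002, 0x0002), "UI", encode_string(sop_class_uid)),
        (0x0002, 0x0003): Element(
            (0x0002, 0x0003), "UI", encode_string(sop_instance_uid)
        ),
        (0x0002, 0x0010): Element(
            (0x0002, 0x0010), "UI", encode_string(transfer_syntax)
        ),
        (0x0002, 0x0012): Element(
            (0x0002, 0x0012), "UI", encode_string(IMPLEMENTATION_UID)
        ),
    }
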