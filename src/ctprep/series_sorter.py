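"""Stage S1: purge invalid files, sort a study into per-series folders,
and delete files matching metadata predicates.

A CT study directory typically arrives as one flat, uncollated dump of
slices from several series. Sorting groups slices by Series Instance UID
(the globally unique identity) into subfolders named after the Series
Number (the human-facing label radiologists see); when two distinct UIDs
share a number the folder name gets a ``-2``/``-3`` suffix.
"""

from __future__ import annotations

import json
import logging
import operator
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Tuple

from . import dicom_core as dc
from .dicom_core import FileClassification

log = logging.getLogger(__name__)

_OPS: Dict[str, Callable] = {
    "==": operator.eq,
    "!=": operator.ne,
    "<": operator.lt,
    "<=": operator.le,
    ">": operator.gt,
    ">=": operator.ge,
}


@dataclass
class SeriesIndex:
    """Final per-series layout of a sorted study.

    ``series`` maps the folder name (series number, possibly suffixed on
    UID collision) to the ordered list of file paths; ``collisions`` lists
    (series_number, uid) pairs that required a suffixed folder.
    """

    study_dir: Path
    series: Dict[str, List[Path]] = field(default_factory=dict)
    collisions: List[Tuple[int, str]] = field(default_factory=list)

    @property
    def counts(self) -> Dict[str, int]:
        return {k: len(v) for k, v in self.series.items()}

    @property
    def total_files(self) -> int:
        return sum(len(v) for v in self.series.values())

    def to_json(self) -> str:
        return json.dumps(
            {
                "study": str(self.study_dir),
                "series": {k: [str(p) for p in v] for k, v in self.series.items()},
                "collisions": [[n, u] for n, u in self.collisions],
            },
            indent=2,
        )


@dataclass(frozen=True)
class MetadataPredicate:
    """``attribute comparator value``, e.g. ``slice_thickness > 1.0``."""

    attribute: str
    comparator: str
    value: object

    def __post_init__(self) -> None:
        if self.comparator not in _OPS:
            raise ValueError(
                f"unknown comparator {self.comparator!r}; use one of {sorted(_OPS)}"
            )
        if not self.attribute:
            raise ValueError("empty attribute name")

    def matches(self, record) -> bool:
        actual = dc.get_attribute(record, self.attribute)  # may raise KeyError
        return _OPS[self.comparator](actual, self.value)


@dataclass
class DeletionReport:
    deleted: List[Path] = field(default_factory=list)
    skipped: List[Path] = field(default_factory=list)  # attribute unresolvable


def _iter_files(root: Path) -> List[Path]:
    return sorted(p for p in root.rglob("*") if p.is_file())


def purge_invalid(
    study_dir: str | Path, delete: bool = False
) -> List[Tuple[Path, FileClassification]]:
    """Find (and optionally delete) non-DICOM and corrupted files.

    Returns every non-valid file with its classification; valid files are
    never touched. Index files this package wrote are ignored.
    """
    study_dir = Path(study_dir)
    if not study_dir.is_dir():
        raise NotADirectoryError(study_dir)
    bad: List[Tuple[Path, FileClassification]] = []
    for path in _iter_files(study_dir):
        if path.name == INDEX_FILENAME:
            continue
        cls = dc.classify_file(path)
        if cls.status != dc.VALID:
            bad.append((path, cls))
            log.info("%s: %s (%s)", path, cls.status, cls.detail)
    if delete:
        for path, _ in bad:
            path.unlink()
    return bad


INDEX_FILENAME = "series_index.json"


def sort_study(study_dir: str | Path, copy: bool = False) -> SeriesIndex:
    """Sort every valid DICOM file under ``study_dir`` into per-series folders.

    Files are moved (copied when ``copy`` is set) to
    ``<study>/<series_number>/<original name>``; within a folder the index
    orders files by instance number (ties broken by filename). Already
    sorted trees are left untouched, so the operation is idempotent. The
    resulting index is also written as JSON beside the study.
    """
    study_dir = Path(study_dir)
    if not study_dir.is_dir():
        raise NotADirectoryError(study_dir)

    # Group by UID; remember the series number each UID declares.
    groups: Dict[str, List[Tuple[int, str, Path]]] = {}
    numbers: Dict[str, int | None] = {}
    for path in _iter_files(study_dir):
        if path.name == INDEX_FILENAME:
            continue
        record = dc.read_slice(path)  # precondition: purge ran first
        uid = record.series_uid or f"number:{record.series_number}"
        inst = record.instance_number if record.instance_number is not None else 0
        groups.setdefault(uid, []).append((inst, path.name, path))
        numbers.setdefault(uid, record.series_number)

    # Assign folder names: series number, disambiguated per UID on collision.
    by_number: Dict[str, List[str]] = {}
    for uid in sorted(groups, key=lambda u: (numbers[u] if numbers[u] is not None else -1, u)):
        label = str(numbers[uid]) if numbers[uid] is not None else "unknown"
        by_number.setdefault(label, []).append(uid)

    index = SeriesIndex(study_dir=study_dir)
    for label, uids in by_number.items():
        for i, uid in enumerate(uids):
            folder = label if i == 0 else f"{label}-{i + 1}"
            if i > 0:
                index.collisions.append((numbers[uid], uid))
                log.warning(
                    "series number %s shared by multiple UIDs; using folder %s",
                    label,
                    folder,
                )
            dest_dir = study_dir / folder
            dest_dir.mkdir(exist_ok=True)
            placed: List[Path] = []
            for inst, name, path in sorted(groups[uid]):
                dest = dest_dir / name
                if dest != path:
                    if copy:
                        shutil.copy2(path, dest)
                    else:
                        path.rename(dest)
                placed.append(dest)
            index.series[folder] = placed

    (study_dir / INDEX_FILENAME).write_text(index.to_json())
    # Drop now-empty directories left behind by the move.
    for sub in sorted(study_dir.rglob("*"), reverse=True):
        if sub.is_dir() and not any(sub.iterdir()):
            sub.rmdir()
    return index


def delete_by_metadata(
    study_dir: str | Path,
    predicate: MetadataPredicate,
    dry_run: bool = False,
) -> DeletionReport:
    """Delete every valid DICOM file whose metadata matches ``predicate``.

    Files on which the attribute cannot be resolved are skipped and
    reported, never deleted. A malformed predicate raises before any file
    is examined (MetadataPredicate validates on construction).
    """
    study_dir = Path(study_dir)
    if not study_dir.is_dir():
        raise NotADirectoryError(study_dir)
    report = DeletionReport()
    to_delete: List[Path] = []
    for path in _iter_files(study_dir):
        if path.name == INDEX_FILENAME:
            continue
        record = dc.read_slice(path)
        try:
            if predicate.matches(record):
                to_delete.append(path)
        except KeyError:
            report.skipped.append(path)
    if not dry_run:
        for path in to_delete:
            path.unlink()
            log.info("deleted %s (matched %s)", path, predicate)
    report.deleted = to_delete
    return report
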