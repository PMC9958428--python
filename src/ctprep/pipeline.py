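"""Pipeline orchestration: sort → denoise → images / NIfTI / STL per study.

A run walks every study directory under ``input_root``, executes the
enabled stages in order, and records everything it read, classified,
overwrote or emitted in a JSON run manifest. One failing study is isolated:
it is reported in the manifest and the run continues with the others.

The in-place overwrite of stage S2 is destructive by design; ``copy_first``
snapshots each study into the output tree and operates on the copy instead.
"""

from __future__ import annotations

import json
import logging
import shutil
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List

import yaml

from . import noise_removal, series_sorter
from .export_images import WindowSpec, export_series_images
from .export_mesh import series_to_stl
from .export_volume import collect_outputs, export_series_nifti
from .noise_removal import ThresholdSpec

log = logging.getLogger(__name__)

STAGE_ORDER = ("sort", "denoise", "images", "nifti", "stl")


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run.

    Stage ordering invariants: ``denoise`` requires ``sort`` (or
    ``assume_sorted``); the three export stages require ``denoise`` (or
    ``raw_exports``). Unknown keys in a config file are rejected so typos
    fail loudly rather than silently falling back to defaults.
    """

    input_root: str = "."
    stages: tuple = STAGE_ORDER
    threshold: ThresholdSpec = field(default_factory=ThresholdSpec)
    window: WindowSpec = field(default_factory=WindowSpec)
    output_root: str | None = None  # default: <input_root>/../<name>_outputs
    copy_first: bool = False
    mask_mode: str = "per-slice"
    assume_sorted: bool = False
    raw_exports: bool = False
    delete_invalid: bool = True
    compress_nifti: bool = False
    stl_ascii: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.stages = tuple(self.stages)
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if not self.stages:
            raise ValueError("at least one stage must be enabled")
        if "denoise" in self.stages and "sort" not in self.stages and not self.assume_sorted:
            raise ValueError(
                "denoise requires the sort stage (or assume_sorted: true)"
            )
        for stage in ("images", "nifti", "stl"):
            if stage in self.stages and "denoise" not in self.stages and not self.raw_exports:
                raise ValueError(
                    f"{stage} requires the denoise stage (or raw_exports: true)"
                )
        if self.mask_mode not in ("per-slice", "volumetric"):
            raise ValueError(f"unknown mask_mode {self.mask_mode!r}")
        # order stages canonically
        self.stages = tuple(s for s in STAGE_ORDER if s in self.stages)

    def resolved_output_root(self) -> Path:
        if self.output_root:
            return Path(self.output_root)
        root = Path(self.input_root)
        return root.parent / f"{root.name}_outputs"


def load_config(path: str | Path) -> PipelineConfig:
    """Parse a YAML config file; defaults fill anything unstated."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    if "threshold" in raw:
        raw["threshold"] = ThresholdSpec(**raw["threshold"])
    if "window" in raw:
        raw["window"] = WindowSpec(**raw["window"])
    return PipelineConfig(**raw)


@dataclass
class RunManifest:
    """Record of one pipeline run, serialisable to JSON.

    ``files`` maps every input file to the actions applied to it;
    ``outputs`` groups emitted artefacts by format class (images, volumes,
    meshes) — the pipeline's three discrete output classes.
    """

    config: dict
    started: float = field(default_factory=time.time)
    finished: float | None = None
    studies: Dict[str, dict] = field(default_factory=dict)
    files: Dict[str, List[str]] = field(default_factory=dict)
    outputs: Dict[str, List[str]] = field(default_factory=lambda: {
        "images": [],
        "volumes": [],
        "meshes": [],
    })
    failures: Dict[str, str] = field(default_factory=dict)

    def record(self, path: Path, action: str) -> None:
        self.files.setdefault(str(path), []).append(action)

    @property
    def n_output_classes(self) -> int:
        return sum(1 for v in self.outputs.values() if v)

    def write(self, out_path: Path) -> Path:
        out_path.parent.mkdir(parents=True, exist_ok=True)
        out_path.write_text(json.dumps(asdict(self), indent=2, default=str))
        return out_path


def _study_dirs(input_root: Path) -> List[Path]:
    if any(p.is_file() for p in input_root.iterdir()):
        return [input_root]
    # "*_truth" directories are phantom ground-truth bundles, not studies.
    return sorted(
        p
        for p in input_root.iterdir()
        if p.is_dir() and not p.name.endswith("_truth")
    )


def _series_dirs(study_dir: Path) -> List[Path]:
    return sorted(
        p
        for p in study_dir.iterdir()
        if p.is_dir() and any(f.is_file() for f in p.iterdir())
    )


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the enabled stages over every study under ``input_root``."""
    input_root = Path(config.input_root)
    if not input_root.is_dir():
        raise NotADirectoryError(input_root)
    out_root = config.resolved_output_root()
    manifest = RunManifest(config=_config_dict(config))

    for study in _study_dirs(input_root):
        try:
            _run_study(study, config, out_root, manifest)
        except Exception as exc:  # isolate per-study failures
            log.exception("study %s failed", study)
            manifest.failures[str(study)] = f"{type(exc).__name__}: {exc}"
    manifest.finished = time.time()
    manifest.write(out_root / "run_manifest.json")
    return manifest


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["stages"] = list(config.stages)
    return d


def _run_study(
    study: Path, config: PipelineConfig, out_root: Path, manifest: RunManifest
) -> None:
    name = study.name
    record: dict = {"stages": {}}
    manifest.studies[name] = record

    if config.copy_first:
        work = out_root / "studies" / name
        if not work.exists():
            shutil.copytree(study, work)
        study = work

    if "sort" in config.stages:
        bad = series_sorter.purge_invalid(study, delete=config.delete_invalid)
        for path, cls in bad:
            manifest.record(path, f"purged:{cls.status}")
        index = series_sorter.sort_study(study)
        for folder, paths in index.series.items():
            for p in paths:
                manifest.record(p, f"sorted:{folder}")
        record["stages"]["sort"] = {
            "purged": len(bad),
            "series": index.counts,
        }

    series = _series_dirs(study)

    if "denoise" in config.stages:
        counts = {"denoised": 0, "empty": 0, "skipped": 0}
        for sdir in series:
            for rep in noise_removal.denoise_series(
                sdir, config.threshold, mode=config.mask_mode
            ):
                counts[rep.status] += 1
                manifest.record(rep.path, f"denoise:{rep.status}")
        record["stages"]["denoise"] = counts

    if "images" in config.stages:
        written: List[Path] = []
        for sdir in series:
            out_dir = out_root / "images" / name / sdir.name
            written += export_series_images(sdir, config.window, out_dir)
        manifest.outputs["images"] += [str(p) for p in written]
        record["stages"]["images"] = {"files": len(written)}

    if "nifti" in config.stages:
        staging = out_root / "nifti_staging" / name
        for sdir in series:
            export_series_nifti(sdir, staging, compress=config.compress_nifti)
        moved = collect_outputs(staging, out_root / "nifti")
        manifest.outputs["volumes"] += [str(p) for p in moved]
        record["stages"]["nifti"] = {"files": len(moved)}

    if "stl" in config.stages:
        written = []
        for sdir in series:
            out = out_root / "stl" / f"{name}_series{sdir.name}.stl"
            written.append(
                series_to_stl(
                    sdir,
                    config.threshold,
                    out,
                    mode="ascii" if config.stl_ascii else "binary",
                )
            )
        manifest.outputs["meshes"] += [str(p) for p in written]
        record["stages"]["stl"] = {"files": len(written)}
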