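"""Shared fixtures: small phantom specs sized for fast tests.

The small spec scales the clinical-regime defaults (512 px / 0.5 mm) down
to a 96 px grid while keeping every geometric relationship intact: body
ellipse well inside the field, couch arc disjoint from the body by several
closing diameters, bone insert inside the body.
"""

from __future__ import annotations

from pathlib import Path

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from ctprep.phantom_fixtures import (
    PhantomSpec,
    SphereInsert,
    TableSpec,
    make_phantom_study,
)


def small_spec(**overrides) -> PhantomSpec:
    """A 96×96, 8-slice phantom (48 mm field of view at 0.5 mm pixels)."""
    params = dict(
        matrix_size=96,
        n_slices=8,
        pixel_spacing=0.5,
        slice_thickness=0.5,
        body_semi_axes=(16.0, 12.0),
        table=TableSpec(inner_radius=20.0, outer_radius=22.0, half_angle_deg=50.0),
        bone_inserts=(SphereInsert(center=(6.0, 0.0, 1.75), radius=1.5),),
        seed=0,
    )
    params.update(overrides)
    return PhantomSpec(**params)


@pytest.fixture
def phantom_study(tmp_path: Path):
    """One clean single-series small phantom study with its ground truth."""
    spec = small_spec()
    study, gt = make_phantom_study(spec, tmp_path / "study", write_ground_truth=False)
    return study, gt, spec


@pytest.fixture
def mixed_study(tmp_path: Path):
    """Two interleaved series plus one text decoy and one truncated decoy."""
    spec = small_spec(n_series=2, n_non_dicom_decoys=1, n_truncated_decoys=1, seed=3)
    study, gt = make_phantom_study(spec, tmp_path / "study", write_ground_truth=False)
    return study, gt, spec
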