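"""noise_removal: thresholding, patient-mask construction, in-place denoise."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

import ctprep.dicom_core as dc
from ctprep.noise_removal import (
    MaskImage,
    ThresholdSpec,
    apply_mask,
    build_patient_mask,
    denoise_series,
    denoise_slice,
    dice,
    tissue_threshold,
)
from ctprep.phantom_fixtures import make_phantom_study
from conftest import small_spec

SPEC = ThresholdSpec()


class TestTissueThreshold:
    def test_uniform_air_is_all_false(self):
        assert not tissue_threshold(np.full((8, 8), -1000.0), SPEC).any()

    def test_band_covering_range_is_all_true(self):
        hu = np.linspace(-500, 500, 64).reshape(8, 8)
        spec = ThresholdSpec(tissue_lower=-1000, tissue_upper=1000)
        assert tissue_threshold(hu, spec).all()

    def test_phantom_slice_matches_elementwise_oracle(self, phantom_study):
        study, gt, spec = phantom_study
        rec = dc.read_slice(sorted(study.glob("*.dcm"))[0])
        hu = rec.hu()
        got = tissue_threshold(hu, SPEC)
        oracle = (hu >= SPEC.tissue_lower) & (hu <= SPEC.tissue_upper)
        assert np.array_equal(got, oracle)
        # Body (40 HU) in band, air (-1000) out; table (150) is also in band,
        # which is the point: thresholding alone cannot remove the couch.
        assert got[gt.body[:, :, 0]].all()
        assert got[gt.table[:, :, 0]].all()

    def test_nonfinite_rejected(self):
        hu = np.full((4, 4), np.nan)
        with pytest.raises(ValueError):
            tissue_threshold(hu, SPEC)

    def test_inverted_band_rejected(self):
        with pytest.raises(ValueError):
            ThresholdSpec(tissue_lower=100, tissue_upper=-100)


def _disk(shape, center, radius):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


class TestBuildPatientMask:
    def test_largest_component_wins(self):
        """Disk (~2000 px) kept, thin arc (~300 px) dropped — area oracle."""
        binary = np.zeros((120, 120), dtype=bool)
        body = _disk((120, 120), (50, 60), 25)  # ~1963 px
        yy, xx = np.mgrid[:120, :120]
        r = np.hypot(yy - 50, xx - 60)
        arc = (r >= 45) & (r <= 47) & (yy > 90)  # thin couch-like arc
        binary |= body | arc
        # Oracle: rank components by area with scipy, pick the largest.
        labels, _ = ndimage.label(binary)
        areas = np.bincount(labels.ravel())
        areas[0] = 0
        oracle = labels == int(np.argmax(areas))
        mask = build_patient_mask(binary)
        assert mask.mask[body].all()
        assert not mask.mask[arc].any()
        assert dice(mask.mask, oracle) > 0.99  # closing may add boundary px

    def test_all_false_input_flagged_empty(self):
        mask = build_patient_mask(np.zeros((32, 32), dtype=bool))
        assert not mask.mask.any()
        assert mask.empty

    def test_annulus_hole_filled(self):
        """Body wall around an air cavity: flood-fill-from-border oracle."""
        outer = _disk((100, 100), (50, 50), 30)
        inner = _disk((100, 100), (50, 50), 18)
        annulus = outer & ~inner
        mask = build_patient_mask(annulus)
        oracle = ndimage.binary_fill_holes(annulus)  # independent fill route
        assert np.array_equal(mask.mask, oracle)
        assert mask.mask[inner].all()

    def test_non_boolean_rejected(self):
        with pytest.raises(ValueError):
            build_patient_mask(np.zeros((4, 4), dtype=int))


class TestApplyMask:
    def test_all_true_mask_is_identity(self, phantom_study):
        study, _, _ = phantom_study
        rec = dc.read_slice(sorted(study.glob("*.dcm"))[0])
        mask = MaskImage(np.ones_like(rec.stored_pixels, dtype=bool))
        assert np.array_equal(apply_mask(rec, mask), rec.stored_pixels)

    def test_all_false_mask_zeroes_everything(self, phantom_study):
        study, _, _ = phantom_study
        rec = dc.read_slice(sorted(study.glob("*.dcm"))[0])
        mask = MaskImage(np.zeros_like(rec.stored_pixels, dtype=bool))
        assert not apply_mask(rec, mask).any()

    def test_ground_truth_masked_copy_oracle(self, phantom_study):
        study, gt, _ = phantom_study
        rec = dc.read_slice(sorted(study.glob("*.dcm"))[0])
        body = gt.body[:, :, 0]
        out = apply_mask(rec, MaskImage(body))
        oracle = np.where(body, rec.stored_pixels, 0)
        assert np.array_equal(out, oracle)

    def test_dimension_mismatch(self, phantom_study):
        study, _, _ = phantom_study
        rec = dc.read_slice(sorted(study.glob("*.dcm"))[0])
        with pytest.raises(ValueError):
            apply_mask(rec, MaskImage(np.ones((2, 2), dtype=bool)))


class TestDenoiseSlice:
    def test_table_pixels_become_background(self, phantom_study):
        study, gt, _ = phantom_study
        path = sorted(study.glob("*.dcm"))[0]
        denoise_slice(path, SPEC)
        rec = dc.read_slice(path)
        assert (rec.stored_pixels[gt.table[:, :, 0]] == 0).all()
        # Body preserved: every ground-truth body pixel keeps soft-tissue HU.
        assert dice(rec.stored_pixels != 0, gt.body[:, :, 0]) >= 0.99

    def test_idempotent(self, phantom_study):
        study, _, _ = phantom_study
        path = sorted(study.glob("*.dcm"))[1]
        denoise_slice(path, SPEC)
        once = path.read_bytes()
        denoise_slice(path, SPEC)
        assert path.read_bytes() == once

    def test_metadata_unchanged(self, phantom_study, tmp_path):
        study, _, _ = phantom_study
        path = sorted(study.glob("*.dcm"))[2]
        backup = tmp_path / "orig.dcm"
        backup.write_bytes(path.read_bytes())
        denoise_slice(path, SPEC)
        assert dc.diff_metadata(backup, path) == []

    def test_invalid_file_skipped_with_classification(self, tmp_path):
        p = tmp_path / "noise.txt"
        p.write_text("free text")
        report = denoise_slice(p, SPEC)
        assert report.status == "skipped"
        assert "non_dicom" in report.detail


class TestDenoiseSeries:
    @pytest.mark.parametrize("mode", ["per-slice", "volumetric"])
    def test_all_table_voxels_removed(self, tmp_path, mode):
        spec = small_spec(seed=21)
        study, gt = make_phantom_study(spec, tmp_path / "s", write_ground_truth=False)
        reports = denoise_series(study, SPEC, mode=mode)
        assert len(reports) == spec.n_slices
        assert all(r.status == "denoised" for r in reports)
        stored = np.stack(
            [dc.read_slice(p).stored_pixels for p in sorted(study.glob("*.dcm"))],
            axis=2,
        )
        assert (stored[gt.table] == 0).all()
        assert dice(stored != 0, gt.body) >= 0.99

    def test_modes_agree_when_table_disconnected_in_3d(self, tmp_path):
        spec = small_spec(seed=23, noise_sd=5.0)
        a, _ = make_phantom_study(spec, tmp_path / "a", write_ground_truth=False)
        b, _ = make_phantom_study(spec, tmp_path / "b", write_ground_truth=False)
        denoise_series(a, SPEC, mode="per-slice")
        denoise_series(b, SPEC, mode="volumetric")
        for pa, pb in zip(sorted(a.glob("*.dcm")), sorted(b.glob("*.dcm"))):
            assert np.array_equal(
                dc.read_slice(pa).stored_pixels, dc.read_slice(pb).stored_pixels
            )

    def test_empty_directory(self, tmp_path):
        d = tmp_path / "empty"
        d.mkdir()
        assert denoise_series(d, SPEC) == []

    def test_mixed_series_rejected_before_modification(self, mixed_study):
        study, _, _ = mixed_study
        before = {p.name: p.read_bytes() for p in study.glob("*.dcm")}
        with pytest.raises(ValueError):
            denoise_series(study, SPEC)
        after = {p.name: p.read_bytes() for p in study.glob("*.dcm")}
        assert before == after


@pytest.mark.parametrize("noise_sd", [0.0, 10.0, 20.0])
def test_body_dice_across_noise_levels(tmp_path, noise_sd):
    """Mask recovery stays >= 0.99 Dice for noise SD up to 20 HU."""
    spec = small_spec(n_slices=2, noise_sd=noise_sd, seed=int(noise_sd) + 31)
    study, gt = make_phantom_study(spec, tmp_path / "s", write_ground_truth=False)
    denoise_series(study, SPEC)
    for k, p in enumerate(sorted(study.glob("*.dcm"))):
        recovered = dc.read_slice(p).stored_pixels != 0
        assert dice(recovered, gt.body[:, :, k]) >= 0.99
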