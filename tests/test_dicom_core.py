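"""dicom_core: classification, reading, HU conversion, in-place rewrite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ctprep.dicom_core as dc
from ctprep import _dicomio as dio
from ctprep.dicom_core import (
    classify_file,
    diff_metadata,
    hu_to_stored,
    overwrite_pixels,
    read_slice,
    stored_to_hu,
)


class TestClassifyFile:
    def test_plain_text_is_non_dicom(self, tmp_path):
        p = tmp_path / "report.txt"
        p.write_text("radiology report, not an image\n")
        cls = classify_file(p)
        assert cls.status == "non_dicom"
        assert cls.detail

    def test_truncated_slice_is_corrupted(self, phantom_study):
        study, _, _ = phantom_study
        src = next(iter(sorted(study.glob("*.dcm"))))
        data = src.read_bytes()
        trunc = src.with_name("half.dcm")
        trunc.write_bytes(data[: len(data) // 2])
        cls = classify_file(trunc)
        assert cls.status == "corrupted"
        assert cls.detail

    def test_generated_slice_is_valid(self, phantom_study):
        study, _, _ = phantom_study
        for p in study.glob("*.dcm"):
            assert classify_file(p).status == "valid"

    def test_missing_path_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            classify_file(tmp_path / "absent.dcm")

    def test_missing_required_attribute_is_corrupted(self, phantom_study, tmp_path):
        study, _, _ = phantom_study
        df = dio.read_file(next(iter(sorted(study.glob("*.dcm")))))
        del df.elements[(0x0028, 0x1053)]  # rescale slope
        out = tmp_path / "noslope.dcm"
        dio.write_file(out, df)
        cls = classify_file(out)
        assert cls.status == "corrupted"
        assert "1053" in cls.detail or "slope" in cls.detail.lower()

    def test_every_file_in_mixed_directory_gets_one_status(self, mixed_study):
        study, _, spec = mixed_study
        statuses = [classify_file(p).status for p in sorted(study.iterdir())]
        assert len(statuses) == spec.n_series * spec.n_slices + 2
        assert statuses.count("valid") == spec.n_series * spec.n_slices
        assert statuses.count("non_dicom") == 1
        assert statuses.count("corrupted") == 1


class TestReadSlice:
    def test_fields_match_generator(self, phantom_study):
        study, _, spec = phantom_study
        rec = read_slice(sorted(study.glob("*.dcm"))[0])
        assert rec.series_number == spec.first_series_number
        assert rec.instance_number == 1
        assert rec.pixel_spacing_row == rec.pixel_spacing_col == spec.pixel_spacing
        assert rec.slice_thickness == spec.slice_thickness
        assert rec.stored_pixels.shape == (spec.matrix_size, spec.matrix_size)
        assert rec.series_uid and rec.series_uid.startswith("2.25.")
        r, c = rec.image_orientation
        assert abs(np.linalg.norm(r) - 1) < 1e-4
        assert abs(np.linalg.norm(c) - 1) < 1e-4
        assert abs(float(r @ c)) < 1e-4

    def test_extra_tags_preserved(self, phantom_study):
        study, _, _ = phantom_study
        rec = read_slice(sorted(study.glob("*.dcm"))[0])
        assert (0x0010, 0x0040) in rec.extra_tags  # patient sex, unmapped field
        vr, raw = rec.extra_tags[(0x0010, 0x0040)]
        assert vr == "CS"

    def test_invalid_file_raises_with_classification(self, tmp_path):
        p = tmp_path / "junk.dcm"
        p.write_bytes(b"\x00" * 200)
        with pytest.raises(dc.InvalidSliceError) as exc:
            read_slice(p)
        assert exc.value.classification.status == "non_dicom"

    def test_implicit_vr_file_reads_identically(self, phantom_study, tmp_path):
        """Re-encoding a slice as implicit-VR little-endian loses nothing."""
        study, _, _ = phantom_study
        src = sorted(study.glob("*.dcm"))[0]
        a = read_slice(src)
        df = dio.read_file(src)
        out = tmp_path / "implicit.dcm"
        dio.write_file(out, df, transfer_syntax=dio.IMPLICIT_VR_LE)
        b = read_slice(out)
        assert np.array_equal(a.stored_pixels, b.stored_pixels)
        assert a.series_uid == b.series_uid
        assert a.slice_thickness == b.slice_thickness
        assert np.allclose(a.image_position, b.image_position)


class TestHounsfieldConversion:
    @pytest.mark.parametrize(
        "stored,slope,intercept,hu",
        [(1024, 1.0, -1024.0, 0.0), (0, 1.0, -1024.0, -1024.0), (500, 2.0, -1000.0, 0.0)],
    )
    def test_stored_to_hu_linear(self, stored, slope, intercept, hu):
        assert stored_to_hu(stored, slope, intercept) == hu

    def test_hu_to_stored_water(self):
        assert hu_to_stored(0.0, 1.0, -1024.0) == 1024

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            stored_to_hu(1, 0.0, 0.0)
        with pytest.raises(ValueError):
            hu_to_stored(1.0, 0.0, 0.0)

    def test_clamp_matches_explicit_oracle(self):
        # Oracle: clamp((hu - intercept)/slope rounded, lo, hi) computed by hand.
        bits, rep = 12, 0  # unsigned 12-bit: [0, 4095]
        for hu, expected in [(-5000.0, 0), (10000.0, 4095), (-1024.0, 0), (3071.0, 4095)]:
            assert hu_to_stored(hu, 1.0, -1024.0, bits, rep) == expected
        # signed 8-bit: [-128, 127]
        assert hu_to_stored(-1000.0, 1.0, 0.0, 8, 1) == -128
        assert hu_to_stored(1000.0, 1.0, 0.0, 8, 1) == 127

    @settings(max_examples=100, deadline=None)
    @given(stored=st.integers(min_value=0, max_value=4095))
    def test_round_trip_identity_slope_one(self, stored):
        hu = stored_to_hu(stored, 1.0, -1024.0)
        assert hu_to_stored(hu, 1.0, -1024.0, 12, 0) == stored


class TestOverwritePixels:
    def test_identity_overwrite_is_byte_preserving(self, phantom_study):
        study, _, _ = phantom_study
        path = sorted(study.glob("*.dcm"))[0]
        before = path.read_bytes()
        rec = read_slice(path)
        overwrite_pixels(rec, rec.stored_pixels)
        assert path.read_bytes() == before

    def test_full_round_trip_field_for_field(self, phantom_study):
        study, _, _ = phantom_study
        path = sorted(study.glob("*.dcm"))[1]
        a = read_slice(path)
        overwrite_pixels(a, a.stored_pixels)
        b = read_slice(path)
        assert np.array_equal(a.stored_pixels, b.stored_pixels)
        assert a.rescale_slope == b.rescale_slope
        assert a.rescale_intercept == b.rescale_intercept
        assert np.array_equal(a.image_position, b.image_position)
        assert a.series_uid == b.series_uid
        assert a.instance_number == b.instance_number
        assert a.extra_tags == b.extra_tags

    def test_matrix_size_preserved(self, phantom_study):
        study, _, spec = phantom_study
        path = sorted(study.glob("*.dcm"))[0]
        rec = read_slice(path)
        overwrite_pixels(rec, np.zeros_like(rec.stored_pixels))
        again = read_slice(path)
        assert again.stored_pixels.shape == (spec.matrix_size, spec.matrix_size)

    def test_dimension_mismatch_leaves_file_intact(self, phantom_study):
        study, _, _ = phantom_study
        path = sorted(study.glob("*.dcm"))[0]
        before = path.read_bytes()
        rec = read_slice(path)
        with pytest.raises(ValueError):
            overwrite_pixels(rec, np.zeros((16, 16), dtype=np.uint16))
        assert path.read_bytes() == before

    def test_out_of_range_values_rejected(self, phantom_study):
        study, _, _ = phantom_study
        rec = read_slice(sorted(study.glob("*.dcm"))[0])
        bad = np.full_like(rec.stored_pixels, 5000)  # > 12-bit max
        with pytest.raises(ValueError):
            overwrite_pixels(rec, bad)


def test_diff_metadata_detects_only_real_changes(phantom_study, tmp_path):
    study, _, _ = phantom_study
    paths = sorted(study.glob("*.dcm"))
    assert diff_metadata(paths[0], paths[0]) == []
    diffs = diff_metadata(paths[0], paths[1])
    assert (0x0020, 0x0013) in diffs  # instance number differs
    assert (0x7FE0, 0x0010) not in diffs  # pixel data excluded by contract
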