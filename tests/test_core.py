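"""Domain model and conformance validator."""
import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from niftimrs import (
    MrsImage,
    classify_key,
    gen_example,
    make_minimal,
    validate,
)
from niftimrs.core import COMPLEX64_CODE, NiftiHeaderFields
from niftimrs.errors import NiftiMrsError


def _codes(report, severity="error"):
    return [f.code for f in report.findings if f.severity == severity]


class TestValidate:
    def test_minimal_image_is_conformant(self, minimal_image):
        report = validate(minimal_image)
        assert report.conformant
        assert _codes(report) == []

    def test_untagged_used_dimension_is_flagged(self, minimal_image):
        img = dataclasses.replace(
            minimal_image, data=minimal_image.data.reshape(1, 1, 1, 128, 4)
        )
        img.header.dim = [5, 1, 1, 1, 128, 4, 1, 1]
        assert "MISSING_DIM_TAG" in _codes(validate(img))

    def test_real_datatype_is_flagged(self, minimal_image):
        img = dataclasses.replace(minimal_image, data=minimal_image.data.real)
        img.header.datatype = 16  # float32
        assert "NON_COMPLEX_DATATYPE" in _codes(validate(img))

    @pytest.mark.parametrize("rank", [4, 5, 6, 7, 8])
    def test_rank_window(self, rank):
        """Ranks 4-7 are conformant; the 7-dimension limit rejects rank 8."""
        shape = (1, 1, 1, 64) + (2,) * (min(rank, 7) - 4)
        img = make_minimal(
            np.ones(shape, dtype=np.complex64), 5e-4, 123.2, "1H"
        )
        if rank == 8:
            img.header.dim[0] = 8
            assert "RANK_OUT_OF_RANGE" in _codes(validate(img))
        else:
            assert validate(img).conformant

    def test_nonpositive_dwell_flagged(self, minimal_image):
        minimal_image.header.pixdim[4] = 0.0
        assert "NONPOSITIVE_DWELL" in _codes(validate(minimal_image))

    def test_bad_intent_name_flagged(self, minimal_image):
        minimal_image.header.intent_name = "spectroscopy"
        assert "BAD_INTENT_NAME" in _codes(validate(minimal_image))

    def test_newer_version_warns_but_conforms(self, minimal_image):
        minimal_image.header.intent_name = "mrs_v9_1"
        report = validate(minimal_image)
        assert report.conformant
        assert "UNSUPPORTED_VERSION" in _codes(report, "warning")

    def test_mutations_flip_exactly_the_matching_finding(self, minimal_image):
        """Each defect produces its own finding and no other error."""
        mutations = {
            "MISSING_MANDATORY_KEY": lambda im: im.extension.__setattr__(
                "spectrometer_frequency", []
            ),
            "NON_COMPLEX_DATATYPE": lambda im: im.header.__setattr__(
                "datatype", 16
            ),
        }
        for code, mutate in mutations.items():
            img = dataclasses.replace(
                minimal_image,
                header=dataclasses.replace(minimal_image.header),
                extension=dataclasses.replace(minimal_image.extension),
            )
            mutate(img)
            assert _codes(validate(img)) == [code]

    def test_conformant_iff_no_errors(self, minimal_image):
        report = validate(minimal_image)
        assert report.conformant == (not report.errors)
        minimal_image.header.datatype = 16
        report = validate(minimal_image)
        assert not report.conformant and report.errors

    def test_unknown_capitalized_key_warns_only(self, minimal_image):
        minimal_image.extension.user_keys["MySiteNotes"] = "hello"
        report = validate(minimal_image)
        assert report.conformant
        assert "UNKNOWN_KEY" in _codes(report, "warning")


class TestMakeMinimal:
    def test_vector_becomes_single_voxel(self):
        img = make_minimal(np.ones(512, dtype=np.complex64), 5e-4, 123.2, "1H")
        assert img.header.dim == [4, 1, 1, 1, 512, 1, 1, 1]
        assert img.header.pixdim[4] == 5e-4
        assert img.header.intent_name == "mrs_v0_6"
        assert img.header.datatype == COMPLEX64_CODE

    def test_extension_has_exactly_mandatory_keys(self):
        img = make_minimal(np.ones(16, dtype=np.complex64), 1e-3, 49.9, "31P")
        ext = img.extension
        assert ext.spectrometer_frequency == [49.9]
        assert ext.resonant_nucleus == ["31P"]
        assert not ext.standard_keys and not ext.user_keys and not ext.dim_tags

    def test_coil_dimension_defaults_to_dim_coil(self):
        img = make_minimal(
            np.ones((1, 1, 1, 512, 8), dtype=np.complex64), 5e-4, 123.2, "1H"
        )
        assert img.extension.dim_tags[5] == "DIM_COIL"
        assert validate(img).conformant

    def test_unlocalized_default_applied_without_geometry(self):
        img = make_minimal(np.ones(64, dtype=np.complex64), 1e-3, 123.2, "1H")
        assert img.header.qform_code == 0
        assert img.header.pixdim[1:4] == [10000.0] * 3  # 10 m in mm

    def test_empty_fid_rejected(self):
        with pytest.raises(NiftiMrsError, match="empty"):
            make_minimal(np.array([], dtype=np.complex64), 5e-4, 123.2, "1H")

    @given(
        n=st.integers(16, 256),
        extra=st.lists(st.integers(1, 3), max_size=3),
        dwell=st.floats(1e-5, 1e-2),
        f0=st.floats(10.0, 500.0),
    )
    def test_every_built_image_validates(self, n, extra, dwell, f0):
        shape = (1, 1, 1, n) + tuple(extra)
        img = make_minimal(np.ones(shape, dtype=np.complex64), dwell, f0, "1H")
        assert validate(img).conformant


class TestClassifyKey:
    @pytest.mark.parametrize(
        "name,category",
        [
            ("ResonantNucleus", "mandatory"),
            ("SpectrometerFrequency", "mandatory"),
            ("dim_6_info", "dimension"),
            ("dim_5", "dimension"),
            ("dim_7_header", "dimension"),
            ("EchoTime", "standard"),
            ("PatientName", "standard"),
            ("MySiteNotes", "user"),
            ("dim_4", "user"),  # only dims 5-7 are dimension keys
        ],
    )
    def test_examples(self, name, category):
        assert classify_key(name) == category

    @given(st.text(min_size=1, max_size=30))
    def test_total_with_four_categories(self, name):
        assert classify_key(name) in {"mandatory", "dimension", "standard", "user"}

    def test_empty_name_rejected(self):
        with pytest.raises(ValueError):
            classify_key("")


def test_examples_from_generator_all_validate():
    for kind in ("svs_raw", "mrsi_proc", "edited", "fingerprint"):
        assert validate(gen_example(kind, seed=7)).conformant, kind
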