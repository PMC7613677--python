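"""Header-extension model: registry, privacy, anonymization, editing."""
import dataclasses
import json

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from niftimrs import (
    HeaderExtension,
    ProvenanceEntry,
    anonymize,
    append_provenance,
    edit_key,
    get_dim_header_value,
    is_private,
    key_definition,
    make_minimal,
    remove_key,
    set_dim_tag,
    validate,
)
from niftimrs.errors import (
    DynamicHeaderError,
    KeyTypeError,
    MandatoryKeyError,
    UnknownTagError,
)
from niftimrs.nifti_io import parse_extension, serialize_extension
from niftimrs.registry import standard_key_registry


def _parse_bundled_table_independently():
    """Minimal direct parse of the shipped TSV, bypassing the registry code."""
    from importlib import resources

    rows = {}
    text = resources.files("niftimrs.data").joinpath("standard_keys.tsv").read_text()
    for line in text.splitlines():
        if line.strip() and not line.startswith("#"):
            name, vtype, units, private, doc = line.split("\t")
            rows[name] = (vtype, units, private == "true")
    return rows


class TestRegistry:
    def test_lookup_matches_independent_table_parse(self):
        table = _parse_bundled_table_independently()
        for name, (vtype, units, private) in table.items():
            definition = key_definition(name)
            assert definition is not None
            assert definition.value_type == vtype
            assert definition.private == private
            assert definition.units == (None if units == "-" else units)

    def test_echo_time_definition(self):
        d = key_definition("EchoTime")
        assert d.value_type == "number" and d.units == "s" and not d.private

    def test_patient_keys_are_private(self):
        assert key_definition("PatientName").private
        assert key_definition("PatientDoB").private

    def test_unknown_key_is_absent(self):
        assert key_definition("NotAKey") is None

    def test_minimum_coverage_and_uniqueness(self):
        registry = standard_key_registry()
        required = {
            "EchoTime", "RepetitionTime", "InversionTime", "SequenceName",
            "TxOffset", "Manufacturer", "ManufacturersModelName",
            "DeviceSerialNumber", "SoftwareVersions", "PatientName",
            "PatientID", "PatientDoB", "PatientSex", "PatientWeight",
        }
        assert required <= set(registry)
        assert len({d.name for d in registry.values()}) == len(registry)


class TestIsPrivate:
    @pytest.mark.parametrize(
        "name,expected",
        [
            ("private_notes", True),
            ("SpectrometerFrequency", False),
            ("PatientDoB", True),
            ("EchoTime", False),
            ("private_", True),
        ],
    )
    def test_examples(self, name, expected):
        assert is_private(name) is expected


def _image_with_keys(standard=None, user=None):
    img = make_minimal(np.ones(64, dtype=np.complex64), 5e-4, 123.2, "1H")
    ext = img.extension
    for name, value in (standard or {}).items():
        ext.standard_keys[name] = value
    for name, value in (user or {}).items():
        ext.user_keys[name] = value
    return dataclasses.replace(img, extension=ext)


def _collect_private_paths(obj, prefix=""):
    """Brute-force oracle: every nested key satisfying is_private."""
    found = []
    if isinstance(obj, dict):
        for key, value in obj.items():
            path = f"{prefix}.{key}" if prefix else key
            if is_private(key):
                found.append(path)
            found.extend(_collect_private_paths(value, path))
    elif isinstance(obj, list):
        for i, value in enumerate(obj):
            found.extend(_collect_private_paths(value, f"{prefix}[{i}]"))
    return found


class TestAnonymize:
    def test_nested_private_key_removed_sibling_kept(self):
        img = _image_with_keys(user={"Custom": {"private_id": "X", "field": 1}})
        out, removed = anonymize(img)
        assert removed == ["Custom.private_id"]
        assert out.extension.user_keys["Custom"] == {"field": 1}

    def test_registry_private_key_removed(self):
        img = _image_with_keys(standard={"PatientName": "DOE"})
        out, removed = anonymize(img)
        assert "PatientName" not in out.extension.standard_keys
        assert removed == ["PatientName"]

    def test_idempotent_and_noop_on_clean_input(self):
        img = _image_with_keys(standard={"EchoTime": 0.03})
        once, removed1 = anonymize(img)
        assert removed1 == []
        twice, removed2 = anonymize(once)
        assert removed2 == []
        assert twice.extension == once.extension == img.extension

    def test_extra_keys_removed_but_mandatory_refused(self):
        img = _image_with_keys(user={"StudyCode": "S1"})
        out, removed = anonymize(img, extra_keys=["StudyCode"])
        assert removed == ["StudyCode"]
        with pytest.raises(MandatoryKeyError):
            anonymize(img, extra_keys=["ResonantNucleus"])

    def test_data_array_untouched(self):
        img = _image_with_keys(standard={"PatientID": "X"})
        out, _ = anonymize(img)
        assert out.data is img.data

    def test_conformance_preserved(self):
        img = _image_with_keys(standard={"PatientDoB": "19700101"})
        assert validate(img).conformant
        out, _ = anonymize(img)
        assert validate(out).conformant

    @given(
        st.recursive(
            st.dictionaries(
                st.sampled_from(
                    ["private_a", "PatientName", "EchoTime", "Note", "x", "private_z"]
                ),
                st.one_of(st.integers(), st.text(max_size=5)),
                max_size=4,
            ),
            lambda children: st.dictionaries(
                st.sampled_from(["Wrap", "private_b", "Deep"]), children, max_size=3
            ),
            max_leaves=6,
        )
    )
    def test_no_private_key_survives_at_any_depth(self, payload):
        img = _image_with_keys(user={"Blob": payload})
        out, _ = anonymize(img)
        serialized = out.extension.to_json_dict()
        assert _collect_private_paths(serialized) == []


class TestDynamicHeaders:
    def test_long_form_indexing(self):
        ext = HeaderExtension([123.2], ["1H"])
        ext.dim_headers[5] = {"EchoTime": [0.01, 0.02, 0.03]}
        assert get_dim_header_value(ext, 5, "EchoTime", 2) == 0.03

    def test_compact_form_matches_equivalent_long_form(self):
        ext = HeaderExtension([123.2], ["1H"])
        ext.dim_headers[5] = {
            "Short": {"start": 0.01, "increment": 0.01},
            "Long": [0.01 + 0.01 * i for i in range(8)],
        }
        for i in range(8):
            compact = get_dim_header_value(ext, 5, "Short", i)
            assert compact == pytest.approx(get_dim_header_value(ext, 5, "Long", i))

    def test_wrapper_form_is_transparent(self):
        ext = HeaderExtension([123.2], ["1H"])
        ext.dim_headers[7] = {
            "EditCondition": {"Value": ["ON", "OFF"], "Description": "editing pulse"}
        }
        assert get_dim_header_value(ext, 7, "EditCondition", 1) == "OFF"

    def test_missing_key_and_out_of_range(self):
        ext = HeaderExtension([123.2], ["1H"])
        ext.dim_headers[5] = {"EchoTime": [0.01]}
        with pytest.raises(KeyError):
            get_dim_header_value(ext, 5, "TR", 0)
        with pytest.raises(IndexError):
            get_dim_header_value(ext, 5, "EchoTime", 5)


class TestSetDimTag:
    def _five_dim_image(self, size5=2):
        return make_minimal(
            np.ones((1, 1, 1, 64, size5), dtype=np.complex64), 5e-4, 123.2, "1H"
        )

    def test_coil_tag_validates(self):
        img = set_dim_tag(self._five_dim_image(), 5, "DIM_COIL")
        assert img.extension.dim_tags[5] == "DIM_COIL"
        assert validate(img).conformant

    def test_edit_tag_with_matching_header(self):
        img = make_minimal(
            np.ones((1, 1, 1, 64, 1, 1, 2), dtype=np.complex64), 5e-4, 123.2, "1H"
        )
        img = set_dim_tag(img, 7, "DIM_EDIT", header={"EditCondition": ["ON", "OFF"]})
        assert validate(img).conformant
        assert get_dim_header_value(img.extension, 7, "EditCondition", 0) == "ON"

    def test_header_length_mismatch_rejected(self):
        with pytest.raises(DynamicHeaderError):
            set_dim_tag(
                self._five_dim_image(2), 5, "DIM_EDIT", header={"X": [1, 2, 3]}
            )

    def test_unknown_tag_rejected(self):
        with pytest.raises(UnknownTagError):
            set_dim_tag(self._five_dim_image(), 5, "DIM_BANANA")

    def test_info_set_only_when_given(self):
        tagged = set_dim_tag(self._five_dim_image(), 5, "DIM_USER_0", info="weights")
        assert tagged.extension.dim_infos[5] == "weights"
        plain = set_dim_tag(self._five_dim_image(), 5, "DIM_USER_0")
        assert 5 not in plain.extension.dim_infos


class TestProvenance:
    def test_append_preserves_order(self):
        ext = HeaderExtension([123.2], ["1H"])
        first = ProvenanceEntry("Coil combination", "toolA", "1.0")
        second = ProvenanceEntry("Averaging", "toolB", "2.0")
        ext = append_provenance(append_provenance(ext, first), second)
        assert [e.method for e in ext.processing_applied] == [
            "Coil combination",
            "Averaging",
        ]

    def test_existing_entries_unchanged(self):
        ext = HeaderExtension([123.2], ["1H"])
        ext1 = append_provenance(ext, ProvenanceEntry("A", "p", "1"))
        ext2 = append_provenance(ext1, ProvenanceEntry("B", "p", "1"))
        assert ext.processing_applied == []
        assert len(ext1.processing_applied) == 1
        assert ext2.processing_applied[0] == ext1.processing_applied[0]

    def test_missing_member_rejected(self):
        with pytest.raises(ValueError):
            ProvenanceEntry("Averaging", "", "1.0")


class TestEditRemove:
    def test_standard_key_type_checked(self, minimal_image):
        ext = edit_key(minimal_image.extension, "EchoTime", 0.030)
        assert ext.standard_keys["EchoTime"] == 0.030
        with pytest.raises(KeyTypeError):
            edit_key(minimal_image.extension, "EchoTime", "thirty")

    def test_remove_mandatory_refused(self, minimal_image):
        with pytest.raises(MandatoryKeyError):
            remove_key(minimal_image.extension, "SpectrometerFrequency")

    def test_user_key_roundtrip(self, minimal_image):
        ext = edit_key(minimal_image.extension, "siteNotes", {"a": [1, 2]})
        assert ext.user_keys["siteNotes"] == {"a": [1, 2]}
        ext = remove_key(ext, "siteNotes")
        assert "siteNotes" not in ext.user_keys


# ---------------------------------------------------------------------------
# serialization round trip over randomized extensions

_json_values = st.recursive(
    st.one_of(
        st.integers(-1000, 1000),
        st.floats(-1e6, 1e6, allow_nan=False),
        st.text(max_size=8),
        st.booleans(),
    ),
    lambda children: st.one_of(
        st.lists(children, max_size=3),
        st.dictionaries(st.text(min_size=1, max_size=8), children, max_size=3),
    ),
    max_leaves=8,
)


@given(
    freq=st.lists(st.floats(1.0, 1000.0), min_size=1, max_size=2),
    nuclei=st.sampled_from([["1H"], ["31P"], ["1H", "31P"]]),
    tag=st.sampled_from(["DIM_COIL", "DIM_DYN", "DIM_USER_1"]),
    user=st.dictionaries(st.sampled_from(["a", "Note", "zz"]), _json_values, max_size=3),
)
def test_serialize_parse_roundtrip(freq, nuclei, tag, user):
    """parse(serialize(ext)) == ext for extensions drawn from the grammar."""
    ext = HeaderExtension(spectrometer_frequency=freq, resonant_nucleus=nuclei)
    ext.dim_tags[5] = tag
    ext.dim_infos[5] = "generated"
    ext.dim_headers[5] = {"EchoTime": [0.01, 0.02]}
    ext.standard_keys["RepetitionTime"] = 2.0
    ext.user_keys.update(user)
    ext.processing_applied.append(ProvenanceEntry("Simulated", "gen", "0.1"))
    record = serialize_extension(ext)
    assert parse_extension(record) == ext
    # canonical JSON: payload is a parseable object with mandatory keys first
    obj = json.loads(record.payload)
    assert list(obj)[:2] == ["SpectrometerFrequency", "ResonantNucleus"]
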