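"""Header-extension model: the JSON metadata travelling inside the file.

The extension holds four categories of key:

* the two mandatory keys ``SpectrometerFrequency`` (MHz, array) and
  ``ResonantNucleus`` (array of nucleus strings such as ``"1H"``);
* dimension information ``dim_{n}`` / ``dim_{n}_info`` / ``dim_{n}_header``
  for the optional dynamic dimensions n = 5, 6, 7;
* standard-defined keys from the bundled registry;
* arbitrary user-defined keys.

Dynamic headers (``dim_{n}_header``) associate each element along a dynamic
dimension with a metadata value.  A per-key specification is either the long
form (an array whose length equals the dimension size), the compact form
``{"start": s, "increment": d}`` expanding to ``s + i*d``, and either may be
wrapped as ``{"Value": spec, "Description": text}``.
"""
from __future__ import annotations

import copy
import dataclasses
import re
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

from .errors import (
    DynamicHeaderError,
    KeyTypeError,
    MandatoryKeyError,
    UnknownTagError,
)
from .registry import (
    MANDATORY_KEYS,
    dim_tag_vocabulary,
    is_private,
    key_definition,
)

DYNAMIC_DIMS = (5, 6, 7)

_DIM_KEY_RE = re.compile(r"^dim_([567])(_info|_header)?$")


def classify_key(name: str) -> str:
    """Classify a metadata key name into one of the four categories.

    Returns ``"mandatory"``, ``"dimension"``, ``"standard"`` or ``"user"``.
    Total over all non-empty strings.
    """
    if not name:
        raise ValueError("key name must be non-empty")
    if name in MANDATORY_KEYS:
        return "mandatory"
    if _DIM_KEY_RE.match(name):
        return "dimension"
    if key_definition(name) is not None:
        return "standard"
    return "user"


@dataclass(frozen=True)
class ProvenanceEntry:
    """One step in the ``ProcessingApplied`` processing record."""

    method: str
    program: str
    version: str
    details: Any = None

    def __post_init__(self) -> None:
        for attr in ("method", "program", "version"):
            value = getattr(self, attr)
            if not isinstance(value, str) or not value:
                raise ValueError(f"provenance {attr} must be a non-empty string")

    def to_json(self) -> dict[str, Any]:
        out: dict[str, Any] = {
            "Method": self.method,
            "Program": self.program,
            "Version": self.version,
        }
        if self.details is not None:
            out["Details"] = self.details
        return out

    @classmethod
    def from_json(cls, obj: Mapping[str, Any]) -> "ProvenanceEntry":
        try:
            return cls(
                method=obj["Method"],
                program=obj["Program"],
                version=obj["Version"],
                details=obj.get("Details"),
            )
        except KeyError as exc:
            raise ValueError(f"provenance entry missing member {exc}") from exc


# --------------------------------------------------------------------------
# dynamic-header per-key specifications


def _unwrap_header_spec(spec: Any) -> Any:
    """Strip an optional {"Value": ..., "Description": ...} wrapper."""
    if isinstance(spec, Mapping) and "Value" in spec:
        return spec["Value"]
    return spec


def _is_compact(spec: Any) -> bool:
    return (
        isinstance(spec, Mapping)
        and set(spec) >= {"start", "increment"}
        and "Value" not in spec
    )


def expand_header_spec(spec: Any, size: int) -> list[Any]:
    """Return the long-form value array of one dynamic-header key spec."""
    inner = _unwrap_header_spec(spec)
    if _is_compact(inner):
        start, inc = inner["start"], inner["increment"]
        return [start + i * inc for i in range(size)]
    if isinstance(inner, list):
        if len(inner) != size:
            raise DynamicHeaderError(
                f"long-form header array has length {len(inner)}, dimension size is {size}"
            )
        return list(inner)
    raise DynamicHeaderError(f"unrecognized dynamic-header specification: {spec!r}")


@dataclass
class HeaderExtension:
    """In-memory model of the JSON header extension."""

    spectrometer_frequency: list[float]
    resonant_nucleus: list[str]
    dim_tags: dict[int, str] = field(default_factory=dict)
    dim_infos: dict[int, str] = field(default_factory=dict)
    dim_headers: dict[int, dict[str, Any]] = field(default_factory=dict)
    standard_keys: dict[str, Any] = field(default_factory=dict)
    user_keys: dict[str, Any] = field(default_factory=dict)
    processing_applied: list[ProvenanceEntry] = field(default_factory=list)

    # -- (de)serialization --------------------------------------------------

    def to_json_dict(self) -> dict[str, Any]:
        """Serializable dict with keys in a stable order.

        Order: mandatory, dim_* (ascending n), standard (sorted), user
        (sorted), ProcessingApplied.  Readers must not rely on this order;
        it exists so that output files diff cleanly.
        """
        out: dict[str, Any] = {
            "SpectrometerFrequency": list(self.spectrometer_frequency),
            "ResonantNucleus": list(self.resonant_nucleus),
        }
        for n in DYNAMIC_DIMS:
            if n in self.dim_tags:
                out[f"dim_{n}"] = self.dim_tags[n]
            if n in self.dim_infos:
                out[f"dim_{n}_info"] = self.dim_infos[n]
            if n in self.dim_headers:
                out[f"dim_{n}_header"] = copy.deepcopy(self.dim_headers[n])
        for name in sorted(self.standard_keys):
            out[name] = copy.deepcopy(self.standard_keys[name])
        for name in sorted(self.user_keys):
            out[name] = copy.deepcopy(self.user_keys[name])
        if self.processing_applied:
            out["ProcessingApplied"] = [e.to_json() for e in self.processing_applied]
        return out

    @classmethod
    def from_json_dict(cls, obj: Mapping[str, Any]) -> "HeaderExtension":
        """Build from a parsed JSON object; unknown keys land in user_keys."""
        ext = cls(
            spectrometer_frequency=list(_as_list(obj.get("SpectrometerFrequency", []))),
            resonant_nucleus=list(_as_list(obj.get("ResonantNucleus", []))),
        )
        for name, value in obj.items():
            if name in MANDATORY_KEYS:
                continue
            if name == "ProcessingApplied":
                ext.processing_applied = [
                    ProvenanceEntry.from_json(e) if isinstance(e, Mapping) else
                    ProvenanceEntry(method=str(e), program="unknown", version="unknown")
                    for e in value
                ]
                continue
            m = _DIM_KEY_RE.match(name)
            if m:
                n = int(m.group(1))
                kind = m.group(2)
                if kind is None:
                    ext.dim_tags[n] = value
                elif kind == "_info":
                    ext.dim_infos[n] = value
                else:
                    ext.dim_headers[n] = copy.deepcopy(dict(value))
                continue
            if key_definition(name) is not None:
                ext.standard_keys[name] = copy.deepcopy(value)
            else:
                ext.user_keys[name] = copy.deepcopy(value)
        return ext

    # -- queries ------------------------------------------------------------

    def normalized(self, dim_sizes: Mapping[int, int]) -> "HeaderExtension":
        """Copy with all dynamic headers expanded to canonical long form."""
        ext = copy.deepcopy(self)
        for n, header in ext.dim_headers.items():
            if n not in dim_sizes:
                continue
            ext.dim_headers[n] = {
                key: expand_header_spec(spec, dim_sizes[n])
                for key, spec in header.items()
            }
        return ext


def _as_list(value: Any) -> list:
    if isinstance(value, (list, tuple)):
        return list(value)
    return [value]


# --------------------------------------------------------------------------
# operations on extensions


def get_dim_header_value(ext: HeaderExtension, n: int, key: str, index: int) -> Any:
    """Value of dynamic-header ``key`` for element ``index`` of dimension n.

    Long-form arrays are indexed directly; the compact form expands to
    ``start + index * increment``; the Value/Description wrapper is
    transparent.
    """
    header = ext.dim_headers.get(n, {})
    if key not in header:
        raise KeyError(f"dim_{n}_header has no key {key!r}")
    spec = _unwrap_header_spec(header[key])
    if _is_compact(spec):
        if index < 0:
            raise IndexError("index must be non-negative")
        return spec["start"] + index * spec["increment"]
    if isinstance(spec, list):
        if not 0 <= index < len(spec):
            raise IndexError(f"index {index} out of range for length {len(spec)}")
        return spec[index]
    raise DynamicHeaderError(f"unrecognized dynamic-header specification: {spec!r}")


def append_provenance(ext: HeaderExtension, entry: ProvenanceEntry) -> HeaderExtension:
    """Return a copy of ``ext`` with ``entry`` appended to ProcessingApplied."""
    if not isinstance(entry, ProvenanceEntry):
        entry = ProvenanceEntry.from_json(entry)
    out = copy.deepcopy(ext)
    out.processing_applied = out.processing_applied + [entry]
    return out


_JSON_TYPE_CHECKS = {
    "number": lambda v: isinstance(v, (int, float)) and not isinstance(v, bool),
    "string": lambda v: isinstance(v, str),
    "bool": lambda v: isinstance(v, bool),
    "number-array": lambda v: isinstance(v, list)
    and all(isinstance(x, (int, float)) and not isinstance(x, bool) for x in v),
    "string-array": lambda v: isinstance(v, list) and all(isinstance(x, str) for x in v),
    "object": lambda v: isinstance(v, (dict, list)),
}


def edit_key(ext: HeaderExtension, name: str, value: Any) -> HeaderExtension:
    """Return a copy with key ``name`` set to ``value``.

    Standard-defined keys are type-checked against the registry; mandatory
    keys accept their array forms.
    """
    out = copy.deepcopy(ext)
    if name == "SpectrometerFrequency":
        value = _as_list(value)
        if not _JSON_TYPE_CHECKS["number-array"](value) or not value:
            raise KeyTypeError("SpectrometerFrequency must be a non-empty number array")
        out.spectrometer_frequency = value
        return out
    if name == "ResonantNucleus":
        value = _as_list(value)
        if not _JSON_TYPE_CHECKS["string-array"](value) or not value:
            raise KeyTypeError("ResonantNucleus must be a non-empty string array")
        out.resonant_nucleus = value
        return out
    definition = key_definition(name)
    if definition is not None:
        if not _JSON_TYPE_CHECKS[definition.value_type](value):
            raise KeyTypeError(
                f"{name} must be of JSON type {definition.value_type!r}, got {value!r}"
            )
        out.standard_keys[name] = value
        return out
    if _DIM_KEY_RE.match(name):
        raise KeyTypeError(f"use set_dim_tag to modify dimension key {name!r}")
    out.user_keys[name] = value
    return out


def remove_key(ext: HeaderExtension, name: str) -> HeaderExtension:
    """Return a copy with key ``name`` removed; mandatory keys are refused."""
    if name in MANDATORY_KEYS:
        raise MandatoryKeyError(f"{name} is mandatory and cannot be removed")
    out = copy.deepcopy(ext)
    if name == "ProcessingApplied":
        out.processing_applied = []
    out.standard_keys.pop(name, None)
    out.user_keys.pop(name, None)
    m = _DIM_KEY_RE.match(name)
    if m:
        n = int(m.group(1))
        {None: out.dim_tags, "_info": out.dim_infos, "_header": out.dim_headers}[
            m.group(2)
        ].pop(n, None)
    return out


def set_dim_tag(image, n: int, tag: str, info: str | None = None, header=None):
    """Return a copy of ``image`` with dimension ``n`` (5-7) tagged.

    ``header`` is a dim_{n}_header mapping; long-form arrays are checked
    against the dimension size.
    """
    if n not in DYNAMIC_DIMS:
        raise ValueError(f"dynamic dimensions are 5-7, got {n}")
    if tag not in dim_tag_vocabulary():
        raise UnknownTagError(f"unknown dimension tag {tag!r}")
    shape = image.data.shape
    if len(shape) < n:
        raise DynamicHeaderError(f"image has no dimension {n} (rank {len(shape)})")
    ext = copy.deepcopy(image.extension)
    ext.dim_tags[n] = tag
    if info is not None:
        ext.dim_infos[n] = info
    if header is not None:
        size = shape[n - 1]
        for key, spec in header.items():
            expand_header_spec(spec, size)  # raises on length mismatch
        ext.dim_headers[n] = copy.deepcopy(dict(header))
    return dataclasses.replace(image, extension=ext)


# --------------------------------------------------------------------------
# anonymization


def _scrub(obj: Any, path: str, extra: frozenset[str], removed: list[str]) -> Any:
    """Recursively drop private keys from nested JSON values."""
    if isinstance(obj, Mapping):
        out = {}
        for key, value in obj.items():
            child = f"{path}.{key}" if path else key
            if is_private(key) or key in extra:
                removed.append(child)
                continue
            out[key] = _scrub(value, child, extra, removed)
        return out
    if isinstance(obj, list):
        return [_scrub(v, f"{path}[{i}]", extra, removed) for i, v in enumerate(obj)]
    return obj


def anonymize(image, extra_keys: Iterable[str] = ()) -> tuple[Any, list[str]]:
    """Strip privacy-sensitive metadata from an image.

    Removes, at any nesting depth, every key whose standard definition is
    flagged private, every key carrying the ``private_`` prefix, and every
    key named in ``extra_keys``.  Removal is deletion — no placeholder is
    written.  The data array is untouched.

    Returns the anonymized image and the dotted paths of removed keys.
    """
    extra = frozenset(extra_keys)
    clash = extra & set(MANDATORY_KEYS)
    if clash:
        raise MandatoryKeyError(f"cannot anonymize mandatory keys: {sorted(clash)}")
    removed: list[str] = []
    ext = copy.deepcopy(image.extension)
    ext.standard_keys = _scrub(ext.standard_keys, "", extra, removed)
    ext.user_keys = _scrub(ext.user_keys, "", extra, removed)
    ext.dim_headers = {
        n: _scrub(h, f"dim_{n}_header", extra, removed)
        for n, h in ext.dim_headers.items()
    }
    ext.processing_applied = [
        ProvenanceEntry(
            method=e.method,
            program=e.program,
            version=e.version,
            details=_scrub(e.details, f"ProcessingApplied[{i}].Details", extra, removed)
            if e.details is not None
            else None,
        )
        for i, e in enumerate(ext.processing_applied)
    ]
    return dataclasses.replace(image, extension=ext), removed
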