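"""Domain types for NIfTI-MRS images and the conformance validator.

An :class:`MrsImage` is a complex data array of rank 4-7 (three spatial
dimensions, the time-domain FID along dimension 4, up to three optional
dynamic dimensions), the spectroscopy-relevant NIfTI-2 header fields, and
the JSON header extension.  :func:`validate` checks an image against the
conformance rules of the standard and returns an ordered report;
:func:`make_minimal` builds the smallest conformant image around a FID.
"""
from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import spatial
from .errors import NiftiMrsError
from .metadata import (
    DYNAMIC_DIMS,
    HeaderExtension,
    classify_key,
    _is_compact,
    _unwrap_header_spec,
)
from .registry import dim_tag_vocabulary, key_definition

__all__ = [
    "MRS_VERSION",
    "COMPLEX64_CODE",
    "COMPLEX128_CODE",
    "NiftiHeaderFields",
    "MrsImage",
    "Finding",
    "ValidationReport",
    "validate",
    "make_minimal",
    "classify_key",
]

#: Implemented version of the data standard, encoded in intent_name.
MRS_VERSION = (0, 6)

#: NIfTI datatype codes for complex storage.  The writer default is the
#: 32-bit-per-component code (DT_COMPLEX = 32).
COMPLEX64_CODE = 32
COMPLEX128_CODE = 1792
COMPLEX_CODES = (COMPLEX64_CODE, COMPLEX128_CODE)

#: xyzt_units bitmask: spatial millimeters (2) | temporal seconds (8).
XYZT_MM_SEC = 10

_INTENT_RE = re.compile(r"^mrs_v(\d+)_(\d+)$")

_DEFAULT_DIM_TAGS = {5: "DIM_COIL", 6: "DIM_DYN", 7: "DIM_INDIRECT"}


def intent_name_for_version(version: tuple[int, int] = MRS_VERSION) -> str:
    return f"mrs_v{version[0]}_{version[1]}"


@dataclass
class NiftiHeaderFields:
    """The NIfTI-2 header fields with spectroscopy-specific meaning.

    ``pixdim[1..3]`` hold the voxel size (mm), ``pixdim[4]`` the FID dwell
    time (s), ``pixdim[0]`` the qform handedness ``qfac``; the standard
    version is carried in ``intent_name``.
    """

    dim: list[int]
    pixdim: list[float]
    datatype: int = COMPLEX64_CODE
    intent_name: str = ""
    xyzt_units: int = XYZT_MM_SEC
    qform_code: int = 0
    sform_code: int = 0
    quatern_b: float = 0.0
    quatern_c: float = 0.0
    quatern_d: float = 0.0
    qoffset_x: float = 0.0
    qoffset_y: float = 0.0
    qoffset_z: float = 0.0
    sform_rows: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dim = [int(v) for v in self.dim]
        self.pixdim = [float(v) for v in self.pixdim]
        if len(self.dim) != 8 or len(self.pixdim) != 8:
            raise ValueError("dim and pixdim must have 8 entries")
        if self.sform_rows is not None:
            self.sform_rows = np.asarray(self.sform_rows, dtype=float).reshape(3, 4)

    @property
    def rank(self) -> int:
        return self.dim[0]

    @property
    def dwell_s(self) -> float:
        return self.pixdim[4]

    @property
    def qfac(self) -> float:
        # pixdim[0] of 0 is read as +1 per the NIfTI convention
        return -1.0 if self.pixdim[0] == -1.0 else 1.0

    @property
    def version(self) -> tuple[int, int] | None:
        m = _INTENT_RE.match(self.intent_name)
        return (int(m.group(1)), int(m.group(2))) if m else None

    def __eq__(self, other) -> bool:
        if not isinstance(other, NiftiHeaderFields):
            return NotImplemented
        same_sform = (
            (self.sform_rows is None) == (other.sform_rows is None)
            and (self.sform_rows is None or np.array_equal(self.sform_rows, other.sform_rows))
        )
        return same_sform and all(
            getattr(self, f.name) == getattr(other, f.name)
            for f in dataclasses.fields(self)
            if f.name != "sform_rows"
        )


@dataclass
class MrsImage:
    """A NIfTI-MRS dataset: data array + header fields + header extension."""

    data: np.ndarray
    header: NiftiHeaderFields
    extension: HeaderExtension
    #: extension records with ecodes other than 44, preserved on rewrite
    extra_extensions: tuple = ()

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def dwell_s(self) -> float:
        return self.header.dwell_s

    @property
    def spectrometer_frequency_mhz(self) -> float:
        return float(self.extension.spectrometer_frequency[0])

    @property
    def nucleus(self) -> str:
        return self.extension.resonant_nucleus[0]

    def geometry(self) -> spatial.Geometry:
        """Voxel-to-world geometry from the qform (authoritative) fields."""
        h = self.header
        if h.qform_code > 0:
            return spatial.affine_from_quaternion(
                h.quatern_b,
                h.quatern_c,
                h.quatern_d,
                h.qfac,
                tuple(h.pixdim[1:4]),
                (h.qoffset_x, h.qoffset_y, h.qoffset_z),
                frame_code=h.qform_code,
            )
        affine = np.diag(list(h.pixdim[1:4]) + [1.0])
        return spatial.Geometry(affine=affine, frame_code=0)


@dataclass(frozen=True)
class Finding:
    severity: str  # "error" | "warning"
    code: str
    path: str
    message: str


@dataclass
class ValidationReport:
    """Ordered findings; conformant iff no finding is an error."""

    findings: list[Finding] = field(default_factory=list)

    @property
    def conformant(self) -> bool:
        return not any(f.severity == "error" for f in self.findings)

    @property
    def errors(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "error"]

    @property
    def warnings(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "warning"]

    def to_json_dict(self) -> dict:
        return {
            "conformant": self.conformant,
            "findings": [dataclasses.asdict(f) for f in self.findings],
        }

    def __str__(self) -> str:
        lines = [
            f"{f.severity.upper():7s} {f.code:28s} {f.path}: {f.message}"
            for f in self.findings
        ]
        verdict = "conformant" if self.conformant else "NOT conformant"
        return "\n".join(lines + [f"-> {verdict}"])


def _add(report: ValidationReport, severity: str, code: str, path: str, message: str):
    report.findings.append(Finding(severity, code, path, message))


def validate(image: MrsImage) -> ValidationReport:
    """Check an image against the conformance rules of the standard.

    One finding is emitted per violated rule; each rule has a stable code.
    Unknown standard-looking keys produce warnings only — user-defined keys
    are permitted by the standard.
    """
    report = ValidationReport()
    h, ext = image.header, image.extension

    # rank and data
    rank = h.rank
    if not 4 <= rank <= 7:
        _add(report, "error", "RANK_OUT_OF_RANGE", "header.dim",
             f"data rank must be 4-7, got {rank}")
    if h.datatype not in COMPLEX_CODES or image.data.dtype.kind != "c":
        _add(report, "error", "NON_COMPLEX_DATATYPE", "header.datatype",
             f"only complex datatypes are permitted (code {h.datatype}, "
             f"dtype {image.data.dtype})")
    if not h.dwell_s > 0:
        _add(report, "error", "NONPOSITIVE_DWELL", "header.pixdim[4]",
             f"dwell time must be positive, got {h.dwell_s}")

    # version
    version = h.version
    if version is None:
        _add(report, "error", "BAD_INTENT_NAME", "header.intent_name",
             f"intent_name must match mrs_v<major>_<minor>, got {h.intent_name!r}")
    elif version > MRS_VERSION:
        _add(report, "warning", "UNSUPPORTED_VERSION", "header.intent_name",
             f"file declares version {version[0]}.{version[1]}, newer than "
             f"implemented {MRS_VERSION[0]}.{MRS_VERSION[1]}")

    # mandatory keys
    freq = ext.spectrometer_frequency
    if not freq:
        _add(report, "error", "MISSING_MANDATORY_KEY", "SpectrometerFrequency",
             "mandatory key absent or empty")
    elif not all(isinstance(v, (int, float)) and not isinstance(v, bool) and v > 0
                 for v in freq):
        _add(report, "error", "BAD_MANDATORY_KEY", "SpectrometerFrequency",
             f"must be an array of positive numbers (MHz), got {freq!r}")
    nuclei = ext.resonant_nucleus
    if not nuclei:
        _add(report, "error", "MISSING_MANDATORY_KEY", "ResonantNucleus",
             "mandatory key absent or empty")
    elif not all(isinstance(v, str) and v for v in nuclei):
        _add(report, "error", "BAD_MANDATORY_KEY", "ResonantNucleus",
             f"must be an array of non-empty strings, got {nuclei!r}")

    # dynamic dimensions
    vocabulary = dim_tag_vocabulary()
    for n in DYNAMIC_DIMS:
        size = h.dim[n] if n <= rank and n < len(h.dim) else 1
        used = n <= rank and size > 1
        tag = ext.dim_tags.get(n)
        if used and tag is None:
            _add(report, "error", "MISSING_DIM_TAG", f"dim_{n}",
                 f"dimension {n} has size {size} but carries no dim_{n} tag")
        if tag is not None and tag not in vocabulary:
            _add(report, "error", "UNKNOWN_DIM_TAG", f"dim_{n}",
                 f"tag {tag!r} is not in the vocabulary")
        header_spec = ext.dim_headers.get(n)
        if header_spec is not None and n <= rank:
            for key, spec in header_spec.items():
                inner = _unwrap_header_spec(spec)
                if isinstance(inner, list) and len(inner) != size:
                    _add(report, "error", "DIM_HEADER_LENGTH_MISMATCH",
                         f"dim_{n}_header.{key}",
                         f"long-form array length {len(inner)} != dimension "
                         f"size {size}")
                elif not isinstance(inner, list) and not _is_compact(inner):
                    _add(report, "error", "BAD_DIM_HEADER", f"dim_{n}_header.{key}",
                         f"unrecognized dynamic-header specification {spec!r}")

    # spatial conformance
    pix_ok = all(p > 0 for p in h.pixdim[1:4])
    if h.qform_code > 0:
        quat = (h.quatern_b, h.quatern_c, h.quatern_d)
        norm2 = sum(q * q for q in quat)
        if norm2 > 1.0 + 1e-6:
            _add(report, "error", "BAD_QUATERNION", "header.quatern",
                 f"quaternion norm^2 = {norm2:.9f} exceeds 1")
        if not all(np.isfinite(quat)) or not np.isfinite(
            [h.qoffset_x, h.qoffset_y, h.qoffset_z]
        ).all():
            _add(report, "error", "SPATIAL_NONCONFORMANT", "header",
                 "qform_code > 0 requires finite quaternion and offsets")
        if h.pixdim[0] not in (-1.0, 0.0, 1.0):
            _add(report, "error", "SPATIAL_NONCONFORMANT", "header.pixdim[0]",
                 f"qfac must be +/-1, got {h.pixdim[0]}")
        if not pix_ok:
            _add(report, "error", "SPATIAL_NONCONFORMANT", "header.pixdim",
                 "qform_code > 0 requires positive voxel dimensions")
    else:
        if not pix_ok:
            _add(report, "error", "SPATIAL_NONCONFORMANT", "header.pixdim",
                 "qform_code == 0 requires voxel dimensions set (10 m default "
                 "for unlocalized data)")

    # provenance
    for i, entry in enumerate(ext.processing_applied):
        for attr in ("method", "program", "version"):
            if not getattr(entry, attr, None):
                _add(report, "error", "BAD_PROVENANCE", f"ProcessingApplied[{i}]",
                     f"entry missing required member {attr!r}")

    # unknown standard-looking keys: warning, user keys are legal
    for name in ext.user_keys:
        if name[:1].isupper() and key_definition(name) is None:
            _add(report, "warning", "UNKNOWN_KEY", name,
                 "capitalized key is not in the standard registry; "
                 "interpreted as user-defined")
    return report


def make_minimal(
    fid: np.ndarray,
    dwell_s: float,
    f0_mhz: float | Sequence[float],
    nucleus: str | Sequence[str],
    geometry: spatial.Geometry | None = None,
    dim_tags: dict[int, str] | None = None,
) -> MrsImage:
    """Build the smallest conformant image around a FID array.

    A rank-1 input becomes a 1x1x1xN single-voxel array; rank-2/3 inputs are
    treated as a FID with dynamic dimensions and prefixed with singleton
    spatial dimensions; rank-4..7 inputs are stored as given.  Used dynamic
    dimensions default to the conventional tags (5: DIM_COIL, 6: DIM_DYN,
    7: DIM_INDIRECT) unless overridden via ``dim_tags``.  Without a
    ``geometry`` the unlocalized 10 m default is applied.
    """
    fid = np.asarray(fid)
    if fid.size == 0:
        raise NiftiMrsError("empty FID: cannot build an image from no data")
    if fid.dtype.kind != "c":
        fid = fid.astype(np.complex64)
    elif fid.dtype not in (np.complex64, np.complex128):
        fid = fid.astype(np.complex128)
    if fid.ndim == 1:
        fid = fid.reshape(1, 1, 1, -1)
    elif fid.ndim < 4:
        fid = fid.reshape((1, 1, 1) + fid.shape)
    if fid.ndim > 7:
        raise NiftiMrsError(f"rank {fid.ndim} exceeds the 7-dimension limit")
    if not dwell_s > 0:
        raise NiftiMrsError(f"dwell time must be positive, got {dwell_s}")

    f0_list = [float(v) for v in np.atleast_1d(f0_mhz)]
    if not all(v > 0 for v in f0_list):
        raise NiftiMrsError("spectrometer frequency must be positive (MHz)")
    nucleus_list = [nucleus] if isinstance(nucleus, str) else list(nucleus)
    if not all(isinstance(v, str) and v for v in nucleus_list):
        raise NiftiMrsError("nucleus must be a non-empty string")

    geom = geometry if geometry is not None else spatial.default_unlocalized_geometry()
    ext = HeaderExtension(
        spectrometer_frequency=f0_list, resonant_nucleus=nucleus_list
    )
    for n in DYNAMIC_DIMS:
        if fid.ndim >= n and fid.shape[n - 1] > 1:
            ext.dim_tags[n] = (dim_tags or {}).get(n, _DEFAULT_DIM_TAGS[n])

    header = header_fields_for(
        shape=fid.shape,
        dwell_s=float(dwell_s),
        datatype=COMPLEX64_CODE if fid.dtype == np.complex64 else COMPLEX128_CODE,
        geometry=geom,
    )
    return MrsImage(data=fid, header=header, extension=ext)


def header_fields_for(
    shape: tuple[int, ...],
    dwell_s: float,
    datatype: int,
    geometry: spatial.Geometry,
) -> NiftiHeaderFields:
    """Assemble header fields for a data shape, dwell time and geometry."""
    dim = [len(shape)] + list(shape) + [1] * (7 - len(shape))
    if geometry.frame_code > 0:
        q = spatial.quaternion_from_affine(geometry)
        pixdim = [q.qfac, *q.pixdim, dwell_s, 1.0, 1.0, 1.0]
        fields = NiftiHeaderFields(
            dim=dim,
            pixdim=pixdim,
            datatype=datatype,
            intent_name=intent_name_for_version(),
            qform_code=geometry.frame_code,
            sform_code=geometry.frame_code,
            quatern_b=q.b,
            quatern_c=q.c,
            quatern_d=q.d,
            qoffset_x=q.offsets[0],
            qoffset_y=q.offsets[1],
            qoffset_z=q.offsets[2],
            sform_rows=np.asarray(geometry.affine)[:3, :],
        )
    else:
        scales = np.linalg.norm(np.asarray(geometry.affine)[:3, :3], axis=0)
        pixdim = [1.0, *(float(s) for s in scales), dwell_s, 1.0, 1.0, 1.0]
        fields = NiftiHeaderFields(
            dim=dim,
            pixdim=pixdim,
            datatype=datatype,
            intent_name=intent_name_for_version(),
            qform_code=0,
            sform_code=0,
        )
    return fields
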