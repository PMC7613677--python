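"""Reading and writing NIfTI-2 files carrying the ecode-44 JSON extension.

A file on disk is a NIfTI-2 image whose header extension list contains
exactly one record with ecode 44; the record payload is the UTF-8 JSON
header extension, zero-padded so the record size (including the 8-byte
esize/ecode preamble) is a multiple of 16.  File I/O itself goes through
nibabel; this module owns the extension record handling, the header-field
mapping, and the conformance gate on write.

Writes are deterministic: gzip output is produced with a zero mtime, so
identical images yield byte-identical files.
"""
from __future__ import annotations

import gzip
import io as _io
import json
import warnings
from dataclasses import dataclass

import nibabel as nib
import numpy as np
from nibabel.nifti1 import Nifti1Extension

from .core import (
    COMPLEX64_CODE,
    COMPLEX128_CODE,
    MrsImage,
    NiftiHeaderFields,
    validate,
)
from .errors import (
    ExtensionParseError,
    NiftiMrsError,
    NotNiftiMrsError,
    WrongExtensionError,
)
from .metadata import HeaderExtension

#: Official NIfTI extension identification code for MRS metadata.
MRS_ECODE = 44

_DTYPE_FOR_CODE = {COMPLEX64_CODE: np.complex64, COMPLEX128_CODE: np.complex128}


@dataclass(frozen=True)
class ExtensionRecord:
    """One on-disk header-extension record."""

    ecode: int
    payload: bytes

    @property
    def esize(self) -> int:
        """Record size on disk: smallest multiple of 16 >= preamble+payload."""
        return -(-(8 + len(self.payload)) // 16) * 16

    @property
    def padded_payload(self) -> bytes:
        return self.payload + b"\x00" * (self.esize - 8 - len(self.payload))


def serialize_extension(ext: HeaderExtension) -> ExtensionRecord:
    """Encode a header extension as an ecode-44 record (canonical JSON)."""
    try:
        payload = json.dumps(ext.to_json_dict(), allow_nan=False).encode("utf-8")
    except (TypeError, ValueError) as exc:
        raise NiftiMrsError(f"extension is not JSON-serializable: {exc}") from exc
    return ExtensionRecord(ecode=MRS_ECODE, payload=payload)


def parse_extension(record: ExtensionRecord) -> HeaderExtension:
    """Decode an ecode-44 record back into a header extension.

    Trailing zero padding is stripped; unknown keys are preserved verbatim
    as user keys.
    """
    if record.ecode != MRS_ECODE:
        raise WrongExtensionError(
            f"expected extension code {MRS_ECODE}, got {record.ecode}"
        )
    text = record.payload.rstrip(b"\x00").decode("utf-8", errors="replace")
    try:
        obj = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ExtensionParseError(
            f"malformed JSON in header extension at byte {exc.pos}: {exc.msg}"
        ) from exc
    if not isinstance(obj, dict):
        raise ExtensionParseError("header extension must be a JSON object")
    return HeaderExtension.from_json_dict(obj)


# --------------------------------------------------------------------------
# file I/O


def _nib_header_from_fields(fields: NiftiHeaderFields, shape) -> nib.Nifti2Header:
    hdr = nib.Nifti2Header()
    hdr.set_data_shape(shape)
    hdr.set_data_dtype(_DTYPE_FOR_CODE.get(fields.datatype, np.complex64))
    hdr["pixdim"][: len(fields.pixdim)] = fields.pixdim
    hdr["intent_name"] = fields.intent_name.encode("ascii")
    hdr["xyzt_units"] = fields.xyzt_units
    hdr["qform_code"] = fields.qform_code
    hdr["sform_code"] = fields.sform_code
    hdr["quatern_b"] = fields.quatern_b
    hdr["quatern_c"] = fields.quatern_c
    hdr["quatern_d"] = fields.quatern_d
    hdr["qoffset_x"] = fields.qoffset_x
    hdr["qoffset_y"] = fields.qoffset_y
    hdr["qoffset_z"] = fields.qoffset_z
    if fields.sform_code > 0 and fields.sform_rows is not None:
        hdr["srow_x"] = fields.sform_rows[0]
        hdr["srow_y"] = fields.sform_rows[1]
        hdr["srow_z"] = fields.sform_rows[2]
    return hdr


def _fields_from_nib_header(hdr) -> NiftiHeaderFields:
    sform_rows = None
    if int(hdr["sform_code"]) > 0:
        sform_rows = np.vstack([hdr["srow_x"], hdr["srow_y"], hdr["srow_z"]])
    intent = np.asarray(hdr["intent_name"]).item()
    if isinstance(intent, bytes):
        intent = intent.decode("ascii", errors="replace")
    else:
        intent = str(intent)
    return NiftiHeaderFields(
        dim=[int(v) for v in hdr["dim"]],
        pixdim=[float(v) for v in hdr["pixdim"]],
        datatype=int(hdr["datatype"]),
        intent_name=intent.rstrip("\x00"),
        xyzt_units=int(hdr["xyzt_units"]),
        qform_code=int(hdr["qform_code"]),
        sform_code=int(hdr["sform_code"]),
        quatern_b=float(hdr["quatern_b"]),
        quatern_c=float(hdr["quatern_c"]),
        quatern_d=float(hdr["quatern_d"]),
        qoffset_x=float(hdr["qoffset_x"]),
        qoffset_y=float(hdr["qoffset_y"]),
        qoffset_z=float(hdr["qoffset_z"]),
        sform_rows=sform_rows,
    )


def write(image: MrsImage, path, force: bool = False) -> None:
    """Write an image to ``path`` (.nii, or .nii.gz for gzip compression).

    The image must pass :func:`validate` unless ``force`` is given, in
    which case a warning is emitted and the non-conformant file is written
    anyway.  Dynamic headers are normalized to long form on write.
    """
    report = validate(image)
    if not report.conformant:
        if not force:
            raise NiftiMrsError(
                "refusing to write non-conformant image (use force=True):\n"
                + str(report)
            )
        warnings.warn("writing non-conformant NIfTI-MRS file", stacklevel=2)

    dim_sizes = {
        n: image.data.shape[n - 1] for n in (5, 6, 7) if image.data.ndim >= n
    }
    record = serialize_extension(image.extension.normalized(dim_sizes))

    data = np.ascontiguousarray(
        image.data, dtype=_DTYPE_FOR_CODE.get(image.header.datatype, np.complex64)
    )
    hdr = _nib_header_from_fields(image.header, data.shape)
    for ecode, payload in image.extra_extensions:
        hdr.extensions.append(Nifti1Extension(int(ecode), payload))
    hdr.extensions.append(Nifti1Extension(MRS_ECODE, record.padded_payload))
    img = nib.Nifti2Image(data, affine=None, header=hdr)
    raw = img.to_bytes()

    path = str(path)
    if path.endswith(".gz"):
        buf = _io.BytesIO()
        with gzip.GzipFile(fileobj=buf, mode="wb", mtime=0) as fh:
            fh.write(raw)
        payload_bytes = buf.getvalue()
    else:
        payload_bytes = raw
    with open(path, "wb") as fh:
        fh.write(payload_bytes)


def read(path) -> MrsImage:
    """Read a NIfTI-MRS file.

    Plain NIfTI without an ecode-44 record is rejected with
    :class:`NotNiftiMrsError`; more than one ecode-44 record is ambiguous
    and also an error.  NIfTI-1 NIfTI-MRS files are read with a warning
    (they are upgraded to NIfTI-2 on the next write).  Records with other
    ecodes are preserved for rewrite.
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    if raw[:2] == b"\x1f\x8b":
        raw = gzip.decompress(raw)
    sizeof_hdr = int.from_bytes(raw[:4], "little")
    if sizeof_hdr in (348, 1543503872):  # NIfTI-1, either endianness
        warnings.warn(
            "NIfTI-1 NIfTI-MRS file; it will be upgraded to NIfTI-2 on write",
            stacklevel=2,
        )
        img = nib.Nifti1Image.from_bytes(raw)
    else:
        try:
            img = nib.Nifti2Image.from_bytes(raw)
        except Exception as exc:
            raise NiftiMrsError(f"not a readable NIfTI file: {exc}") from exc

    mrs_records = []
    extra = []
    for extension in img.header.extensions:
        code = int(extension.get_code())
        content = extension.get_content()
        if not isinstance(content, (bytes, bytearray)):
            content = extension.content  # raw bytes for structured extensions
        if code == MRS_ECODE:
            mrs_records.append(ExtensionRecord(ecode=code, payload=bytes(content)))
        else:
            extra.append((code, bytes(content)))
    if not mrs_records:
        raise NotNiftiMrsError(
            f"{path}: plain NIfTI file without the MRS header extension "
            f"(ecode {MRS_ECODE}); convert it first"
        )
    if len(mrs_records) > 1:
        raise NiftiMrsError(
            f"{path}: {len(mrs_records)} MRS extension records found; "
            "metadata is ambiguous"
        )
    ext = parse_extension(mrs_records[0])
    data = np.asanyarray(img.dataobj)
    return MrsImage(
        data=data,
        header=_fields_from_nib_header(img.header),
        extension=ext,
        extra_extensions=tuple(extra),
    )


def extract_extension_json(path) -> dict:
    """Return the parsed JSON object of the ecode-44 record in ``path``."""
    image = read(path)
    return image.extension.to_json_dict()
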