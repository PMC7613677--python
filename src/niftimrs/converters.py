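"""Import of text-based spectroscopy formats.

Three unambiguous text formats are handled: LCModel .RAW/.H2O (FORTRAN
namelist header + real/imaginary pairs), the jMRUI text export
("Key: value" header + signal columns), and bare two-column ASCII FIDs.
None of these formats carries orientation, so the output always uses the
unlocalized default geometry; metadata the source omits must be supplied
through :class:`ConversionOverrides` or conversion fails.

Field mapping applied:

========== =========================== =========================
format     source field                destination
========== =========================== =========================
LCModel    HZPPPM (MHz)                SpectrometerFrequency
LCModel    DELTAT (s)                  dwell time (pixdim[4])
LCModel    ECHOT (ms)                  EchoTime key (s)
jMRUI      TransmitterFrequency (Hz)   SpectrometerFrequency (MHz)
jMRUI      SamplingInterval (ms)       dwell time (s)
jMRUI      TypeOfNucleus               ResonantNucleus
jMRUI      PointsInDataset             FID length (checked)
jMRUI      DatasetsInFile              dimension 5 (DIM_USER_0)
========== =========================== =========================

Every successful conversion appends exactly one provenance entry naming
this converter, its version and the source.
"""
from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from ._version import __version__
from .core import MrsImage, make_minimal
from .errors import ConversionError
from .metadata import ProvenanceEntry, append_provenance, edit_key, set_dim_tag


@dataclass(frozen=True)
class ConversionOverrides:
    """User-supplied values filling gaps the source format omits."""

    dwell_s: float | None = None
    f0_mhz: float | None = None
    nucleus: str | None = None
    ref_shift: float | None = None
    note: str | None = None

    def __post_init__(self) -> None:
        if self.dwell_s is not None and not self.dwell_s > 0:
            raise ConversionError(f"override dwell_s must be positive, got {self.dwell_s}")
        if self.f0_mhz is not None and not self.f0_mhz > 0:
            raise ConversionError(f"override f0_mhz must be positive, got {self.f0_mhz}")
        if self.nucleus is not None and not self.nucleus:
            raise ConversionError("override nucleus must be a non-empty string")


def _finish(
    image: MrsImage,
    source_format: str,
    source: str,
    overrides: ConversionOverrides,
) -> MrsImage:
    details: dict = {"SourceFormat": source_format, "SourceFile": source}
    if overrides.note:
        details["Note"] = overrides.note
    entry = ProvenanceEntry(
        method=f"Conversion from {source_format}",
        program="niftimrs",
        version=__version__,
        details=details,
    )
    image.extension = append_provenance(image.extension, entry)
    return image


def _require(value, name: str, source_format: str):
    if value is None:
        raise ConversionError(
            f"{source_format} input does not provide {name}; supply it via overrides"
        )
    return value


# --------------------------------------------------------------------------
# LCModel RAW / H2O


_NAMELIST_BLOCK_RE = re.compile(
    r"\$(?P<name>[A-Za-z0-9_]+)(?P<body>.*?)\$END", re.DOTALL | re.IGNORECASE
)
_NAMELIST_ENTRY_RE = re.compile(
    r"([A-Za-z0-9_]+)\s*=\s*('[^']*'|\"[^\"]*\"|[^,\n]*)"
)


def parse_namelist(text: str) -> dict[str, str]:
    """Parse FORTRAN-namelist blocks ($NAME ... $END) into one flat dict.

    Keys are upper-cased; values keep their text form with quotes stripped.
    Accepts comma- or newline-separated entries and is case-insensitive —
    dialects in the wild vary.
    """
    entries: dict[str, str] = {}
    for block in _NAMELIST_BLOCK_RE.finditer(text):
        if block.group("name").upper() == "END":
            continue
        for key, value in _NAMELIST_ENTRY_RE.findall(block.group("body")):
            value = value.strip()
            if len(value) >= 2 and value[0] in "'\"" and value[-1] == value[0]:
                value = value[1:-1]
            entries[key.upper()] = value
    return entries


def _namelist_span(text: str) -> int:
    """Character offset just past the last $END marker."""
    end = 0
    for m in re.finditer(r"\$END", text, re.IGNORECASE):
        end = m.end()
    return end


def from_lcmodel_raw(
    text: str,
    overrides: ConversionOverrides | None = None,
    source: str = "<string>",
) -> MrsImage:
    """Convert LCModel .RAW/.H2O text to a single-voxel image.

    The numeric block after the namelist headers holds whitespace-separated
    (real, imaginary) pairs.  H2O water-reference files have the same layout
    and convert independently — no pairing logic.
    """
    overrides = overrides or ConversionOverrides()
    header = parse_namelist(text)
    body = text[_namelist_span(text):]
    try:
        values = np.array([float(v) for v in body.split()], dtype=float)
    except ValueError as exc:
        raise ConversionError(f"non-numeric data value in {source}: {exc}") from exc
    if values.size == 0:
        raise ConversionError(f"{source}: no data values after namelist header")
    if values.size % 2:
        raise ConversionError(
            f"{source}: odd number of data values ({values.size}); "
            "expected real/imaginary pairs"
        )
    fid = (values[0::2] + 1j * values[1::2]).astype(np.complex64)

    f0 = overrides.f0_mhz
    if f0 is None and "HZPPPM" in header:
        f0 = float(header["HZPPPM"])  # Hz per ppm is numerically MHz
    dwell = overrides.dwell_s
    if dwell is None and "DELTAT" in header:
        dwell = float(header["DELTAT"])
    nucleus = overrides.nucleus or "1H"
    image = make_minimal(
        fid,
        dwell_s=_require(dwell, "the dwell time (DELTAT)", "LCModel RAW"),
        f0_mhz=_require(f0, "the spectrometer frequency (HZPPPM)", "LCModel RAW"),
        nucleus=nucleus,
    )
    if "ECHOT" in header:  # LCModel stores the echo time in milliseconds
        image.extension = edit_key(
            image.extension, "EchoTime", float(header["ECHOT"]) / 1000.0
        )
    if "ID" in header:
        image.extension = edit_key(image.extension, "ProtocolName", header["ID"])
    return _finish(image, "LCModel RAW", source, overrides)


# --------------------------------------------------------------------------
# jMRUI text


def _parse_jmrui_header(lines: list[str]) -> dict[str, str]:
    header: dict[str, str] = {}
    for line in lines:
        m = re.match(r"^\s*([A-Za-z][A-Za-z0-9_ ]*?)\s*:\s*(.*)$", line)
        if m:
            header[m.group(1).strip()] = m.group(2).strip()
    return header


def from_jmrui_text(
    text: str,
    overrides: ConversionOverrides | None = None,
    source: str = "<string>",
) -> MrsImage:
    """Convert a jMRUI text export to NIfTI-MRS.

    Only the FID columns (first two) are ingested; spectrum columns, when
    present, are derivable and dropped.  Files holding several signals
    (``DatasetsInFile`` > 1) stack them along dimension 5 with the
    ``DIM_USER_0`` tag.
    """
    overrides = overrides or ConversionOverrides()
    header_lines: list[str] = []
    rows: list[tuple[float, float]] = []
    for line in text.splitlines():
        parts = line.split()
        try:
            numbers = [float(p) for p in parts]
        except ValueError:
            numbers = []
        if len(numbers) >= 2 and len(numbers) == len(parts):
            rows.append((numbers[0], numbers[1]))
        elif not rows:
            header_lines.append(line)
    header = _parse_jmrui_header(header_lines)

    n_points = int(header["PointsInDataset"]) if "PointsInDataset" in header else None
    n_datasets = int(header.get("DatasetsInFile", "1"))
    if n_points is None:
        if len(rows) % max(n_datasets, 1):
            raise ConversionError(f"{source}: cannot infer PointsInDataset")
        n_points = len(rows) // max(n_datasets, 1)
    if len(rows) != n_points * n_datasets:
        raise ConversionError(
            f"{source}: {len(rows)} data rows but PointsInDataset={n_points} "
            f"x DatasetsInFile={n_datasets} declared"
        )

    fid = (
        np.array([r + 1j * i for r, i in rows])
        .astype(np.complex64)
        .reshape(n_datasets, n_points)
    )

    dwell = overrides.dwell_s
    if dwell is None and "SamplingInterval" in header:
        dwell = float(header["SamplingInterval"]) / 1000.0  # ms -> s
    f0 = overrides.f0_mhz
    if f0 is None and "TransmitterFrequency" in header:
        f0 = float(header["TransmitterFrequency"]) / 1e6  # Hz -> MHz
    nucleus = overrides.nucleus or header.get("TypeOfNucleus") or None

    dwell = _require(dwell, "the dwell time (SamplingInterval)", "jMRUI")
    f0 = _require(f0, "the transmitter frequency", "jMRUI")
    nucleus = _require(nucleus, "the nucleus (TypeOfNucleus)", "jMRUI")

    if n_datasets == 1:
        image = make_minimal(fid[0], dwell_s=dwell, f0_mhz=f0, nucleus=nucleus)
    else:
        stacked = fid.T.reshape(1, 1, 1, n_points, n_datasets)
        image = make_minimal(stacked, dwell_s=dwell, f0_mhz=f0, nucleus=nucleus)
        image = set_dim_tag(
            image, 5, "DIM_USER_0", info="jMRUI signal index"
        )
    return _finish(image, "jMRUI text", source, overrides)


# --------------------------------------------------------------------------
# bare ASCII


def from_ascii(
    table,
    meta: ConversionOverrides,
    source: str = "<string>",
) -> MrsImage:
    """Convert a two-column (real, imaginary) table to NIfTI-MRS.

    ``table`` is either the file text or an (N, 2) array.  The format
    carries no metadata at all, so ``meta`` must provide the dwell time,
    spectrometer frequency and nucleus.
    """
    if isinstance(table, str):
        try:
            values = np.array([float(v) for v in table.split()], dtype=float)
        except ValueError as exc:
            raise ConversionError(f"non-numeric value in {source}: {exc}") from exc
        if values.size == 0 or values.size % 2:
            raise ConversionError(
                f"{source}: expected an even number of values (real/imaginary pairs)"
            )
        columns = values.reshape(-1, 2)
    else:
        columns = np.asarray(table, dtype=float)
        if columns.ndim != 2 or columns.shape[1] != 2:
            raise ConversionError("ASCII table must have two columns (real, imaginary)")
    fid = (columns[:, 0] + 1j * columns[:, 1]).astype(np.complex64)
    image = make_minimal(
        fid,
        dwell_s=_require(meta.dwell_s, "the dwell time", "ASCII"),
        f0_mhz=_require(meta.f0_mhz, "the spectrometer frequency", "ASCII"),
        nucleus=_require(meta.nucleus, "the nucleus", "ASCII"),
    )
    return _finish(image, "ASCII", source, meta)
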