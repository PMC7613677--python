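"""Synthetic acquisition simulator and example datasets.

Every other module is testable without downloads: :func:`simulate_fid`
synthesizes Lorentzian-line FIDs under the storage frequency convention,
and :func:`gen_example` builds small in-memory datasets exercising the
main layouts of the format — raw single-voxel data with coil and average
dimensions, a processed phosphorus MRSI grid, a spectral-editing
acquisition, and a fingerprinting-style acquisition where four parameters
vary along one dimension.

The signal model is a sum of exponentially damped complex tones,

    s(t_k) = sum_p A_p * exp(i phi_p) * exp(2 pi i f_p t_k) * exp(-pi LW_p t_k)

with ``f_p = (ref_shift - delta_p) * f0`` (Hz; ``delta_p`` the chemical
shift in ppm, ``f0`` in MHz), ``t_k = k * dwell`` and ``LW_p`` the
full-width-at-half-maximum of the resulting Lorentzian line in Hz.
Complex Gaussian noise (``noise_sd`` per real/imaginary component) is
drawn from a seeded generator, so identical (spec, seed) pairs produce
identical output — down to byte-identical files.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from . import spatial
from .core import MrsImage, make_minimal
from .metadata import ProvenanceEntry, append_provenance, edit_key, set_dim_tag


@dataclass(frozen=True)
class Peak:
    """One Lorentzian resonance."""

    shift_ppm: float
    amplitude: float = 1.0
    linewidth_hz: float = 5.0  # FWHM of the Lorentzian line
    phase_rad: float = 0.0

    def __post_init__(self) -> None:
        if not self.linewidth_hz > 0:
            raise ValueError("linewidth must be positive")


@dataclass(frozen=True)
class SyntheticSpec:
    """Declarative description of one simulated acquisition."""

    peaks: Sequence[Peak] = ()
    n_points: int = 512
    dwell_s: float = 5e-4
    f0_mhz: float = 123.2
    nucleus: str = "1H"
    ref_shift: float = 4.65
    noise_sd: float = 0.0
    seed: int = 0


def simulate_fid(spec: SyntheticSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Simulate one FID (complex128, length ``spec.n_points``).

    Pass an external ``rng`` to draw several noise realizations from one
    stream; by default a fresh generator is seeded from ``spec.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.n_points) * spec.dwell_s
    fid = np.zeros(spec.n_points, dtype=np.complex128)
    for peak in spec.peaks:
        offset_hz = (spec.ref_shift - peak.shift_ppm) * spec.f0_mhz
        fid += (
            peak.amplitude
            * np.exp(1j * peak.phase_rad)
            * np.exp(2j * np.pi * offset_hz * t)
            * np.exp(-np.pi * peak.linewidth_hz * t)
        )
    if spec.noise_sd > 0:
        fid += rng.normal(0.0, spec.noise_sd, spec.n_points) + 1j * rng.normal(
            0.0, spec.noise_sd, spec.n_points
        )
    return fid


#: Proton metabolite-like peaks used by the examples (shift ppm, A, LW Hz).
_PROTON_PEAKS = (
    Peak(4.65, 20.0, 18.0),  # residual water
    Peak(3.21, 1.5, 6.0),    # choline-like
    Peak(3.03, 2.0, 6.0),    # creatine-like
    Peak(2.01, 3.0, 7.0),    # NAA-like
)

_PHOSPHORUS_PEAKS = (
    Peak(4.8, 1.0, 10.0),    # Pi-like
    Peak(0.0, 5.0, 8.0),     # PCr reference
    Peak(-2.5, 2.0, 14.0),   # gamma-ATP-like
)

EXAMPLE_KINDS = ("svs_raw", "mrsi_proc", "edited", "fingerprint")


def gen_example(kind: str, seed: int = 0) -> MrsImage:
    """Build one of the example datasets (all pass ``validate``).

    ``svs_raw``     1x1x1x512x4x4 proton SVS before preprocessing: dim 5 is
                    uncombined coils (DIM_COIL, per-coil complex weights),
                    dim 6 repeated transients (DIM_DYN).
    ``mrsi_proc``   8x8x1x256 processed phosphorus MRSI with a scanner
                    geometry and subject metadata, including
                    privacy-flagged keys that anonymization removes.
    ``edited``      1x1x1x512x2x4x2 spectral-editing acquisition: dim 7 is
                    the editing condition (DIM_EDIT, ON/OFF dynamic header)
                    modulating a 3.0 ppm resonance; provenance prefilled.
    ``fingerprint`` 1x1x1x256x16 fingerprinting-style series: the four
                    acquisition parameters that vary together (TE, TR, TI,
                    flip angle) do not form a dense grid, so they are
                    stored as parallel arrays in the dim_5 dynamic header
                    over a single DIM_USER_0 dimension.
    """
    if kind not in EXAMPLE_KINDS:
        raise ValueError(f"unknown example kind {kind!r}; choose from {EXAMPLE_KINDS}")
    return _BUILDERS[kind](np.random.default_rng(seed))


def _svs_raw(rng: np.random.Generator) -> MrsImage:
    spec = SyntheticSpec(peaks=_PROTON_PEAKS, noise_sd=0.02)
    n_coils, n_dyn = 4, 4
    coil_weights = rng.normal(size=n_coils) * 0.25 + 1.0
    coil_phases = rng.uniform(-np.pi, np.pi, n_coils)
    weights = coil_weights * np.exp(1j * coil_phases)
    data = np.empty((1, 1, 1, spec.n_points, n_coils, n_dyn), dtype=np.complex64)
    for d in range(n_dyn):
        for c in range(n_coils):
            data[0, 0, 0, :, c, d] = weights[c] * simulate_fid(spec, rng=rng)
    image = make_minimal(data, spec.dwell_s, spec.f0_mhz, spec.nucleus)
    image = set_dim_tag(image, 5, "DIM_COIL")
    image = set_dim_tag(image, 6, "DIM_DYN")
    image.extension = edit_key(image.extension, "EchoTime", 0.011)
    image.extension = edit_key(image.extension, "RepetitionTime", 2.0)
    image.extension = edit_key(image.extension, "WaterSuppressed", False)
    return image


def _mrsi_proc(rng: np.random.Generator) -> MrsImage:
    spec = SyntheticSpec(
        peaks=_PHOSPHORUS_PEAKS,
        n_points=256,
        dwell_s=2e-4,
        f0_mhz=49.87,
        nucleus="31P",
        ref_shift=0.0,
        noise_sd=0.01,
    )
    nx = ny = 8
    data = np.empty((nx, ny, 1, spec.n_points), dtype=np.complex64)
    # smooth sensitivity-like amplitude profile across the grid
    xs = np.linspace(-1, 1, nx)[:, None]
    ys = np.linspace(-1, 1, ny)[None, :]
    profile = np.exp(-(xs**2 + ys**2))
    for i in range(nx):
        for j in range(ny):
            data[i, j, 0, :] = profile[i, j] * simulate_fid(spec, rng=rng)
    affine = np.diag([10.0, 10.0, 15.0, 1.0])
    affine[:3, 3] = (-35.0, -35.0, 40.0)
    geometry = spatial.Geometry(affine=affine, frame_code=spatial.XFORM_SCANNER_ANAT)
    image = make_minimal(data, spec.dwell_s, spec.f0_mhz, spec.nucleus, geometry=geometry)
    ext = image.extension
    for name, value in {
        "EchoTime": 0.00023,
        "RepetitionTime": 1.0,
        "SequenceName": "csi_fid",
        "Manufacturer": "Synthetic",
        "ManufacturersModelName": "Simulator 3T",
        "SoftwareVersions": "sim-1.0",
        "PatientName": "DOE^JANE",
        "PatientID": "SUB-0001",
        "PatientDoB": "19700101",
        "PatientSex": "F",
        "PatientWeight": 68.0,
    }.items():
        ext = edit_key(ext, name, value)
    image.extension = ext
    image.extension = append_provenance(
        image.extension,
        ProvenanceEntry(
            method="Spatial reconstruction and coil combination",
            program="niftimrs.fixtures",
            version="0.1.0",
            details="synthetic example data",
        ),
    )
    return image


def _edited(rng: np.random.Generator) -> MrsImage:
    base = SyntheticSpec(peaks=_PROTON_PEAKS, noise_sd=0.02)
    n_coils, n_dyn, n_cond = 2, 4, 2
    weights = (rng.normal(size=n_coils) * 0.25 + 1.0) * np.exp(
        1j * rng.uniform(-np.pi, np.pi, n_coils)
    )
    data = np.empty(
        (1, 1, 1, base.n_points, n_coils, n_dyn, n_cond), dtype=np.complex64
    )
    for k, edited_on in enumerate((True, False)):
        peaks = list(_PROTON_PEAKS)
        if edited_on:  # editing pulse refocuses a 3.0 ppm resonance
            peaks.append(Peak(3.00, 1.0, 9.0))
        spec = replace(base, peaks=tuple(peaks))
        for d in range(n_dyn):
            for c in range(n_coils):
                data[0, 0, 0, :, c, d, k] = weights[c] * simulate_fid(spec, rng=rng)
    image = make_minimal(data, base.dwell_s, base.f0_mhz, base.nucleus)
    image = set_dim_tag(image, 5, "DIM_COIL")
    image = set_dim_tag(image, 6, "DIM_DYN")
    image = set_dim_tag(
        image,
        7,
        "DIM_EDIT",
        header={"EditCondition": ["ON", "OFF"]},
    )
    image.extension = edit_key(image.extension, "EchoTime", 0.068)
    image.extension = edit_key(image.extension, "RepetitionTime", 2.0)
    for entry in (
        ProvenanceEntry(
            method="Coil combination",
            program="niftimrs.fixtures",
            version="0.1.0",
        ),
        ProvenanceEntry(
            method="Frequency and phase alignment",
            program="niftimrs.fixtures",
            version="0.1.0",
        ),
    ):
        image.extension = append_provenance(image.extension, entry)
    return image


def _fingerprint(rng: np.random.Generator) -> MrsImage:
    n_meas, n_points = 16, 256
    te = np.round(np.linspace(0.010, 0.100, n_meas), 4)
    tr = np.round(np.linspace(0.5, 3.5, n_meas), 3)
    ti = np.round(np.linspace(0.05, 1.25, n_meas), 3)
    flip = np.round(np.linspace(20.0, 90.0, n_meas), 1)
    t1, t2 = 1.2, 0.15  # seconds, single-compartment weighting
    data = np.empty((1, 1, 1, n_points, n_meas), dtype=np.complex64)
    for m in range(n_meas):
        weight = (
            np.sin(np.deg2rad(flip[m]))
            * (1.0 - 2.0 * np.exp(-ti[m] / t1) + np.exp(-tr[m] / t1))
            * np.exp(-te[m] / t2)
        )
        spec = SyntheticSpec(
            peaks=tuple(
                replace(p, amplitude=p.amplitude * abs(weight)) for p in _PROTON_PEAKS
            ),
            n_points=n_points,
            noise_sd=0.02,
        )
        data[0, 0, 0, :, m] = simulate_fid(spec, rng=rng)
    image = make_minimal(data, 5e-4, 123.2, "1H")
    image = set_dim_tag(
        image,
        5,
        "DIM_USER_0",
        info="fingerprinting acquisition index; four parameters vary jointly",
        header={
            "EchoTime": te.tolist(),
            "RepetitionTime": tr.tolist(),
            "InversionTime": ti.tolist(),
            "ExcitationFlipAngle": flip.tolist(),
        },
    )
    return image


_BUILDERS = {
    "svs_raw": _svs_raw,
    "mrsi_proc": _mrsi_proc,
    "edited": _edited,
    "fingerprint": _fingerprint,
}
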