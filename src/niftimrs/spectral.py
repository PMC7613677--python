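"""Frequency and phase conventions for stored FIDs.

The standard fixes the frequency convention of the stored time-domain data
(following Levitt's omega = -gamma * B0 sign choice): on display, the
absolute frequency axis increases left to right, so the chemical-shift
(ppm) axis increases right to left.  Operationally, a resonance at shift
delta ppm is stored with rotating-frame offset

    f = (ref_shift - delta) * f0   [Hz, f0 in MHz]

so that after a center-shifted DFT the ppm value at offset f is
``ref_shift - f / f0``; deshielded resonances (large delta) land at
negative offsets, i.e. on the left of the displayed spectrum.

DFT normalization: the forward transform is unnormalized, the inverse
carries the 1/N factor (numpy's default); Parseval then reads
``sum|fid|^2 == sum|spectrum|^2 / N``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Default reference shift (ppm at zero rotating-frame offset) per nucleus.
#: 4.65 ppm is water at body temperature for proton spectra; other nuclei
#: default to 0 ppm.  Always overridable — never baked into the math.
DEFAULT_REF_SHIFT = {"1H": 4.65}


def default_ref_shift(nucleus: str) -> float:
    return DEFAULT_REF_SHIFT.get(nucleus, 0.0)


@dataclass(frozen=True)
class SpectralAxis:
    """Frequency axis in display order.

    ``offsets_hz`` ascends left to right over [-BW/2, +BW/2); ``ppm``
    equals ``ref_shift - offsets_hz / f0_mhz`` and therefore descends.
    """

    offsets_hz: np.ndarray
    ppm: np.ndarray
    ref_shift: float
    f0_mhz: float

    def __len__(self) -> int:
        return len(self.offsets_hz)

    @property
    def bandwidth_hz(self) -> float:
        step = self.offsets_hz[1] - self.offsets_hz[0]
        return float(step * len(self.offsets_hz))

    @property
    def ppm_span(self) -> float:
        """Full spectral width in ppm: bandwidth / f0."""
        return self.bandwidth_hz / self.f0_mhz


def ppm_axis(
    n_points: int, dwell_s: float, f0_mhz: float, ref_shift: float = 0.0
) -> SpectralAxis:
    """Build the display-order spectral axis for an N-point FID.

    The offsets are the DFT bin frequencies for sampling interval
    ``dwell_s``, center-shifted to ascend over [-BW/2, +BW/2) with
    BW = 1/dwell.
    """
    if n_points < 2:
        raise ValueError("need at least 2 spectral points")
    if not dwell_s > 0 or not f0_mhz > 0:
        raise ValueError("dwell time and spectrometer frequency must be positive")
    offsets = np.fft.fftshift(np.fft.fftfreq(n_points, d=dwell_s))
    ppm = ref_shift - offsets / f0_mhz
    return SpectralAxis(
        offsets_hz=offsets, ppm=ppm, ref_shift=float(ref_shift), f0_mhz=float(f0_mhz)
    )


def fid_to_spectrum(fid: np.ndarray, axis: int = -1) -> np.ndarray:
    """Unnormalized DFT of a FID, reordered to display order.

    The output index runs parallel to :class:`SpectralAxis`: offset
    frequencies ascend (and ppm descends) with the array index.
    """
    return np.fft.fftshift(np.fft.fft(np.asarray(fid), axis=axis), axes=axis)


def spectrum_to_fid(spectrum: np.ndarray, axis: int = -1) -> np.ndarray:
    """Inverse of :func:`fid_to_spectrum` (carries the 1/N factor)."""
    return np.fft.ifft(np.fft.ifftshift(np.asarray(spectrum), axes=axis), axis=axis)


def apply_phase(
    spectrum: np.ndarray,
    axis: SpectralAxis,
    p0: float,
    p1: float = 0.0,
    pivot_hz: float = 0.0,
) -> np.ndarray:
    """Zeroth/first-order phase correction of a display-order spectrum.

    ``out[i] = spectrum[i] * exp(1j * (p0 + p1 * (offsets_hz[i] - pivot_hz)))``
    with ``p0`` in radians and ``p1`` in radians per Hz; the bin at the
    pivot frequency is left untouched by the first-order term.
    """
    spectrum = np.asarray(spectrum)
    if spectrum.shape[-1] != len(axis):
        raise ValueError(
            f"spectrum length {spectrum.shape[-1]} != axis length {len(axis)}"
        )
    phase = p0 + p1 * (axis.offsets_hz - pivot_hz)
    return spectrum * np.exp(1j * phase)


def flip_frequency_convention(fid: np.ndarray) -> np.ndarray:
    """Complex-conjugate a FID, mirroring its spectrum about zero offset.

    Converts data stored with the opposite frequency-sign convention into
    the convention of this standard (and back — the operation is an
    involution).  Real-valued FIDs are unchanged.
    """
    return np.conjugate(np.asarray(fid))
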