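# niftimrs

Create, read, write, validate, edit, anonymize and convert in-vivo magnetic
resonance spectroscopy (MRS) data stored in the **NIfTI-MRS** format
(version 0.6): NIfTI-2 files holding up-to-7-dimensional complex
time-domain arrays together with a JSON header extension (NIfTI extension
code 44).

## Who this is for

MRS and MRSI researchers who need a single, vendor-neutral container for
free-induction-decay (FID) data that plays well with the neuroimaging
ecosystem: any NIfTI viewer or library can open the files, while the JSON
extension carries the spectroscopy-specific metadata (transmitter
frequency, nucleus, dynamic-dimension semantics, provenance, subject
information with explicit privacy flags).

## The format in brief

* **Data block** — complex array of rank 4–7. Dimensions 1–3 are spatial
  (all size 1 for single-voxel data), dimension 4 is the time-domain FID,
  and dimensions 5–7 optionally hold interrelated signals (receive coils,
  repeated transients, editing conditions, …), each labelled by a
  `dim_{n}` tag such as `DIM_COIL` or `DIM_EDIT` in the header extension.
* **Header reuse** — the FID dwell time Δt lives in `pixdim[4]`; the voxel
  geometry uses the standard NIfTI qform/sform affines (with a 10 m default
  extent for unlocalized data); the standard version is encoded in
  `intent_name` as `mrs_v0_6`; only complex datatypes are legal
  (`DT_COMPLEX`, code 32, by default).
* **Header extension** — a JSON object with two mandatory keys,
  `SpectrometerFrequency` (MHz) and `ResonantNucleus`, plus
  dimension information, standard-defined keys from a bundled registry
  (each marked privacy-sensitive or not), and free-form user keys
  (self-markable as private via a `private_` prefix).
* **Frequency convention** — a resonance at chemical shift δ (ppm) is
  stored with rotating-frame offset f = (δ_ref − δ)·f₀ Hz, so that after a
  center-shifted DFT the frequency axis increases left→right and the
  displayed ppm axis increases right→left, as spectroscopists expect.

## Worked example

Simulate a water + NAA proton spectrum, round-trip it through a file, and
locate the peaks on the chemical-shift axis:

```python
import numpy as np
import niftimrs as nm

spec = nm.SyntheticSpec(
    peaks=[nm.Peak(4.65, 5.0, 6.0), nm.Peak(2.01, 3.0, 6.0)],
    n_points=2048, dwell_s=5e-4, f0_mhz=123.2, nucleus="1H", ref_shift=4.65,
)
fid = nm.simulate_fid(spec)
image = nm.make_minimal(fid, spec.dwell_s, spec.f0_mhz, spec.nucleus)
nm.write(image, "water_naa.nii.gz")

back = nm.read("water_naa.nii.gz")
print(nm.validate(back))
print("shape:", back.data.shape, "dwell:", back.dwell_s, "s")

axis = nm.ppm_axis(back.data.shape[3], back.dwell_s,
                   back.spectrometer_frequency_mhz, ref_shift=4.65)
spectrum = nm.fid_to_spectrum(back.data[0, 0, 0])
print(f"spectral width: {axis.bandwidth_hz:.0f} Hz = {axis.ppm_span:.2f} ppm")
peak = int(np.argmax(np.abs(spectrum)))
print(f"largest peak at {axis.ppm[peak]:.2f} ppm (display index {peak} of {len(axis)})")
```

prints

```
-> conformant
shape: (1, 1, 1, 2048) dwell: 0.0005 s
spectral width: 2000 Hz = 16.23 ppm
largest peak at 4.65 ppm (display index 1024 of 2048)
```

The file passes the conformance validator; the 2000 Hz bandwidth (1/Δt)
spans 16.23 ppm at 123.2 MHz; the water resonance sits at its reference
position of 4.65 ppm, at the zero-offset bin in the center of the display
axis, left of the 2.01 ppm NAA resonance.

## Command line

```sh
niftimrs gen svs_raw demo.nii.gz --seed 1    # synthetic example data
niftimrs validate demo.nii.gz                # conformance report, exit 0 iff ok
niftimrs dump demo.nii.gz                    # pretty-print the JSON extension
niftimrs anon in.nii.gz out.nii.gz --report removed.txt
niftimrs edit in.nii.gz out.nii.gz --set EchoTime 0.030
niftimrs convert lcmodel press.RAW out.nii.gz
niftimrs plot demo.nii.gz --out spectrum.png
```

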