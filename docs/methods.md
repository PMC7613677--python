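# Methods

This note records what the package implements, the conventions and
defaults it commits to, and what its synthetic data does and does not
show.

## The data model

A NIfTI-MRS dataset is a complex array of rank 4–7 inside a NIfTI-2 file.
Dimensions 1–3 are spatial (size 1 each for single-voxel spectroscopy),
dimension 4 holds the time-domain FID, and dimensions 5–7 optionally hold
interrelated signals. The seven-dimension ceiling is inherited from the
parent NIfTI format; exceeding it would break every downstream imaging
tool, so the validator rejects rank 8 outright rather than trying to be
lenient.

Header fields are reused rather than extended: the FID sampling interval
(dwell time, seconds by default via the `xyzt_units` code) lives in
`pixdim[4]`, the qform handedness `qfac` in `pixdim[0]`, and the standard
version in `intent_name` (`mrs_v0_6`). Only complex datatypes are legal;
the writer defaults to single-precision complex (NIfTI code 32) and
preserves double precision (code 1792) when the caller provides it.

The JSON header extension (NIfTI extension code 44) carries four key
categories: the two mandatory keys (`SpectrometerFrequency` in MHz and
`ResonantNucleus`, both arrays to allow multi-nucleus acquisitions),
dimension keys (`dim_{n}`, `dim_{n}_info`, `dim_{n}_header` for n = 5–7),
standard-defined keys, and user keys. The standard-key registry is data,
not code: `src/niftimrs/data/standard_keys.tsv` lists name, JSON value
type, units, privacy flag and a one-line description, and
`dim_tags.txt` lists the dimension-tag vocabulary
(DIM_COIL, DIM_DYN, DIM_INDIRECT, DIM_PHASE_CYCLE, DIM_EDIT, DIM_MEAS,
DIM_ISIS, plus DIM_USER_0–2 always). Both tables can grow without code
changes.

### Validator design

`validate()` emits one finding per violated rule, each with a stable code
(`RANK_OUT_OF_RANGE`, `NON_COMPLEX_DATATYPE`, `MISSING_DIM_TAG`, …), and
an image is conformant iff no finding is an error. Two deliberate severity
choices: unknown capitalized keys are warnings, not errors (user keys are
legal, and erroring would punish forward compatibility), and files
declaring a standard version newer than 0.6 are read with a warning (the
format is versioned precisely to allow this).

### Dynamic headers

`dim_{n}_header` associates each element along a dynamic dimension with a
metadata value. Three spellings are accepted on read: the long form (an
array whose length must equal the dimension size — validator-checked), the
compact form `{"start": s, "increment": d}` meaning `s + i·d` for 0-based
element i, and either wrapped as `{"Value": …, "Description": …}`. On
write, dynamic headers are normalized to the long form: compact and
wrapped spellings maximize interoperability on input, but a single
canonical output form keeps files diffable and dumb readers simple.

## Anonymization

A key is privacy-sensitive when its registry definition says so or when it
(at any nesting depth) carries the `private_` prefix. `anonymize()` walks
the whole extension — standard keys, user keys, dynamic headers,
provenance details — and deletes every such key, reporting dotted paths of
what it removed. Deletion, not masking: a placeholder would leak that a
value existed and invites accidental retention. Mandatory keys are never
removable (they carry no subject information), and naming one in
`extra_keys` is refused rather than ignored. The operation is idempotent
and preserves conformance; the test suite checks both with a brute-force
recursive scan as the oracle. In the shipped registry the private keys are
PatientName, PatientID, PatientDoB, DeviceSerialNumber,
AcquisitionStartTime and OriginalFile; PatientSex and PatientWeight are
retained as not uniquely identifying.

## Geometry

Voxel-to-world mapping follows NIfTI: 0-based voxel indices, coordinates
in millimeters at voxel centers. The qform is authoritative; the writer
populates the sform as a copy (equal codes) for viewer compatibility.
Quaternion handling reconstructs the scalar part as
`a = sqrt(max(0, 1 − b² − c² − d²))` (tolerance 1e-6 on the norm), scales
rotation columns by the voxel sizes with the third column multiplied by
`qfac = sign(det)`, and refuses affines with shear beyond 1e-5 — the
qform cannot encode shear, and silently dropping it would corrupt
geometry. Decomposition returns the quaternion with non-negative scalar
part; round-trip error over random rigid transforms is at the 1e-12
level (asserted < 1e-9).

Unlocalized data (simulations, or data localized only by coil
sensitivity) uses transform code 0 and a default voxel extent of 10 m,
stored as 10000 since the header unit is millimeters; a helper reports
the extent in meters. `check_contiguity` accepts per-voxel origins plus
the voxel size and requires a fully occupied rectilinear lattice whose
spacing equals the voxel size — data with inter-slice gaps must be split
into separate files. The check assumes an axis-aligned lattice; rotated
grids should be checked in voxel space before applying the affine.

## File I/O

nibabel performs the NIfTI-2 container serialization. This package owns
the extension record model (`esize` = smallest multiple of 16 ≥ 8 +
payload, ecode 44, zero padding), the JSON (de)serialization with a
stable key order (mandatory, dim_*, standard sorted, user sorted,
ProcessingApplied) for diffability, the header-field mapping, and a
conformance gate on write (`force=True` writes non-conformant files with
a warning, for debugging workflows). Exactly one ecode-44 record is
written; multiple records on read are an error (ambiguous metadata),
while records with other ecodes are preserved through rewrite. Gzip
output is produced with a zero mtime so identical images give
byte-identical files. NIfTI-1 NIfTI-MRS files are read with a warning
and upgraded to NIfTI-2 on the next write.

## Spectral conventions

Stored FIDs follow the convention that the absolute frequency axis of the
displayed spectrum increases left→right, hence ppm increases right→left.
Operationally: a resonance at shift δ is synthesized and interpreted with
rotating-frame offset `f = (ref_shift − δ)·f0` Hz, the display transform
is an unnormalized forward DFT followed by a center shift (inverse
carries 1/N; Parseval is asserted under this convention), and the axis is
`ppm[i] = ref_shift − offsets_hz[i]/f0` over offsets spanning
[−BW/2, +BW/2) with BW = 1/dwell. The same storage rule is applied for
nuclei of either gyromagnetic-ratio sign. `flip_frequency_convention`
(element-wise conjugation) converts data recorded under the opposite sign
convention and is an involution.

The reference shift is a parameter everywhere, never hard-coded: the
per-nucleus default table maps "1H" to 4.65 ppm (water at body
temperature) and everything else to 0. First-order phase is parameterized
in radians per Hz about a pivot frequency (default: zero offset); the CLI
additionally accepts degrees for convenience, the library does not.

## Converters

Only text formats with no vendor ambiguity are implemented: LCModel
.RAW/.H2O, jMRUI text, and bare two-column ASCII. None carries
orientation, so output always uses the unlocalized default geometry.
Field mappings (documented in `converters.py` so they can be diffed
against other converters): LCModel `HZPPPM`→MHz, `DELTAT`→s, `ECHOT`
milliseconds→`EchoTime` seconds; jMRUI `SamplingInterval` ms→s,
`TransmitterFrequency` Hz→MHz, `TypeOfNucleus`→nucleus, with multiple
signals stacked along dimension 5 as `DIM_USER_0`. jMRUI files carrying
spectrum columns beside the FID columns have only the FID ingested — the
spectrum is derivable. Namelist parsing is deliberately lenient (quoted
or bare values, comma or newline separation, case-insensitive keys).
Missing essential metadata is an error, never guessed; overrides fill the
gaps explicitly, and H2O reference files convert independently with no
pairing logic. Every successful conversion appends exactly one provenance
entry and is byte-deterministic.

## Synthetic data

`simulate_fid` evaluates a sum of exponentially damped complex tones:
amplitude, phase, chemical shift and Lorentzian full-width-at-half-maximum
(Hz) per peak, sampled at the dwell time, plus per-component Gaussian
noise from a seeded generator. The linewidth parameter equals the
absorption-mode FWHM of the resulting line; the magnitude-mode line is
√3 wider, and the test suite asserts both relations. Lorentzian lineshapes
only — Gaussian/Voigt profiles, metabolite basis sets from spin
simulation, macromolecule baselines, frequency drift and motion artifacts
are *not* modeled. Passing tests therefore demonstrate format-level
correctness (layout, metadata, conventions, losslessness), not robustness
of any spectral processing on realistic in-vivo signals.

The four example datasets are sized to keep the full test suite in
seconds (FIDs ≤ 2048 points, grids ≤ 8×8×1): `svs_raw`
(1×1×1×512×4×4, coils × transients, per-coil complex weights drawn once
per seed so downstream coil-combination tests are meaningful),
`mrsi_proc` (8×8×1×256 phosphorus grid with a scanner-anatomical affine
and privacy-flagged subject keys), `edited` (…×2 editing conditions with
an ON/OFF dynamic header and prefilled provenance), and `fingerprint`
(1×1×1×256×16 with four parallel parameter arrays — TE, TR, TI, flip
angle — in the dim-5 header, the case where jointly varying parameters
do not form a dense grid). Identical (kind, seed) pairs produce
byte-identical files.

## Numerical choices

* Quaternion norm tolerance 1e-6; shear tolerance 1e-5; round-trip
  assertion 1e-9.
* DFT: forward unnormalized, inverse 1/N; display order via fftshift.
* `qfac` stored in `pixdim[0]`; a stored 0 is read as +1 per NIfTI usage.
* Complex storage: float32 pairs by default; float64 pairs preserved.
* JSON floats are emitted at full repr precision; round trips are exact
  for IEEE doubles.
* Zero-length FIDs, non-positive dwell times or frequencies, empty
  nucleus strings, and over-long quaternions are rejected at
  construction rather than detected downstream.

## Known limitations

* Vendor binary formats (Twix, p-file, SDAT, Bruker, DICOM dialects) and
  k-space data are out of scope; only spatially reconstructed text
  formats convert.
* The validator implements the conformance rules of the format's core
  description; site-specific profiles may impose more.
* Writing distinct qform/sform frames is possible by editing header
  fields manually but not through the high-level API, which always
  writes matching frames.
* `check_contiguity` assumes an axis-aligned lattice of origins.
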