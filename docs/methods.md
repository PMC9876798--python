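# Methods

## Scope and model

echopatch models the imaging chain of a small conformal cardiac
ultrasound patch as three layers: a geometric transmit model (delay
laws on true element positions), a linear single-scattering acoustic
model (Born approximation), and standard receive processing
(delay-and-sum, coherent compounding, envelope detection, log
compression).  On top of that sit the characterization metrics used for
ultrasound systems and a mask-driven cardiac-function pipeline.

Conventions used throughout: x lateral, y elevational, z axial positive
into tissue, origin at the aperture centroid; SI units internally
(metres, seconds, Hz), with mm/µs/MHz only at I/O boundaries.  The
default medium is soft tissue at c = 1540 m/s, configurable everywhere
a sound speed enters.

### Array and pulse

The default array is the wearable device: 32 elements, 0.4 mm pitch
(0.78 wavelengths at 3 MHz), 0.3 mm element width, 2.3 mm element
length, 55% fractional bandwidth at −6 dB.  The physically sub-diced
elevational stack is modelled as one 2.3 mm element; it enters only
through the elevational directivity factor.  The transmit pulse is a
Gaussian-modulated sinusoid (`scipy.signal.gausspulse`), whose `bw`
convention is exactly the −6 dB amplitude-spectrum fractional bandwidth.

### Curved apertures

A surface profile (flat, convex cylinder, sampled arc-length/
displacement pairs, or explicit per-element positions) maps nominal
element positions onto the skin: inter-element arc length is preserved
(= pitch), normals follow the surface, and the aperture centroid is
re-centred at the origin.  Bending over a convex chest wraps the edge
elements toward the tissue; on a 100 mm cylinder the centre-to-edge sag
is R(1 − cos(6.2 mm/R)) ≈ 0.19 mm, about 0.75 rad of two-way phase at
3 MHz — enough to visibly distort an uncorrected image, which is what
the curvature-corrected beamforming A/B test measures.  Curvature is
assumed static per acquisition.

### Transmit laws

Plane: delay_i = (x_i sinθ + z_i cosθ)/c.  Mono-focus:
delay_i = (max_j d_j − d_i)/c with d_i the element-to-focus distance
(default focal depth 60 mm; the choice is a configurable convention).
Wide beam: a virtual point source behind the aperture at
v = centroid + (−z_v sinθ, 0, −z_v cosθ), anchored to the centroid so
all laws are translation invariant.  The default virtual depth makes
the geometric divergence cone cover the steered sector:
z_v = (A/2)/tan(span/2) = 8.08 mm for the 12.4 mm aperture and ±37.5°
span.  The default compounding sequence has 97 angles inclusive of both
endpoints; the exact step is 75°/96 = 0.78125°, which prints as 0.78°.
Transmit apodization is uniform; compounding weights are uniform.

### Acoustic simulation

Transmitted fields are evaluated in the time domain per grid point by
superposing per-element pulse replicas with 1/r spreading and the
far-field rectangular-aperture directivity
sinc(w sinθ_lat/λ)·sinc(L sinθ_el/λ), then reduced to the RMS
x_RMS = sqrt((x₁² + … + x_n²)/n) over an analysis window of fixed
length per event (first arrival to last arrival plus pulse support), so
the denominator n is identical across the map.  Multi-event fields
combine per-event RMS maps as the root of the sum of squares.

Channel data use a first-arrival transmit-time model:
t_tx(p) = min_e(delay_e + |p − r_e|/c), which is consistent across
plane, focused and diverging laws on flat or curved apertures.  Echo
amplitude is reflectivity × D_tx·D_rx/(r_tx·r_rx) with the transmit
factors taken from the first-arriving element.  Implementation: each
scatterer deposits a two-tap linearly interpolated impulse on each
element's trace and the trace is convolved once with the pulse kernel
(FFT overlap-add).  This is algebraically the same superposition as
evaluating the pulse per scatterer with linear time interpolation, at a
cost that is linear in scatterers instead of scatterers × pulse length;
it is what makes fully developed speckle phantoms (10⁴ scatterers, tens
of transmissions) tractable on one CPU core in seconds.  There is no
tissue attenuation, multiple scattering or nonlinearity; transducer
ring-down is not modelled, so dead-zone estimation is out of scope.

Sampling: fs = 20 MHz by default (≥ 4·fc enforced).  Additive channel
noise is white Gaussian with a stated RMS and an explicit seed;
identical seeds give bit-identical data.

### Image formation

Delay-and-sum runs directly on a Cartesian pixel grid (the polar
beamform-then-scan-convert path is available via `scan_convert`, with
the display pixel-spacing conventions Δy = depth/(N_v − 1),
Δx = width/(N_l − 1) and five-times upsampling by default).  Receive
uses the analytic (Hilbert) signal, linear interpolation in time,
dynamic aperture with f-number 1.5 and Hann apodization.  Because the
12.4 mm aperture images a wide sector, the dynamic-aperture centre is
the pixel's lateral position clamped to the aperture extent: pixels
steered beyond the array edge fall back to the edge elements instead of
an empty aperture.  The receive f-number and window are conventions the
hardware leaves unspecified; both are configurable.  Compounding is
coherent (pre-envelope).  Log compression I_new = 20·log₁₀(I_old) is
applied after normalizing the envelope to its maximum; the display
floor is −60 dB.

### Resolution measurement

PSF widths are full widths at half maximum of linear-scale envelope
profiles, with sub-sample crossings by linear interpolation.  Profiles
are taken along the beam (range) direction and across it (cross-range)
through the image peak.  For an on-axis target these are the vertical
and horizontal cuts; for an off-axis target a horizontal cut through
the rotated PSF would mostly sample the much narrower range direction
and report a misleadingly small "lateral" width, so the beam-frame
measurement is the physically meaningful one.  Elevational resolution
is measured by sweeping a point scatterer in y and taking the FWHM of
peak image amplitude versus offset — a simulation-native replacement
for the bench method of rotating the probe 45° against a wire.

### Characterization metrics

- Location accuracy: 1 − |computed distance/ground truth − 1|.
- Dynamic range: least-squares line of mean display grey value (0–255)
  against inclusion contrast, extrapolated to grey 0 and 255; the span
  equals 255/slope.  With exactly two points this is the two-point line.
- CNR: |μ_in − μ_out|/√(σ_in² + σ_out²) on linear-intensity pixels
  (the dB-domain alternative is deliberately not the default; linear
  statistics are the ones with known speckle theory: fully developed
  speckle has point SNR μ/σ ≈ 1.91).
- SNR: 20·log₁₀(peak linear amplitude / RMS of a target-free noise
  ROI).  The hardware characterization never printed its SNR formula;
  this peak-over-noise definition is the package's explicit choice.
- Penetration depth: deepest wire whose image peak exceeds the local
  same-depth background mean by 6 dB.
- Fractional bandwidth: spectral FWHM over the centre frequency, the
  centre being the midpoint of the half-maximum crossings.
- Insertion loss: |20 log₁₀(Vr/Vt) + 1.9 + 2.2·10⁻⁴·2d·fr²| with d in
  mm and fr in MHz (quartz-reflector transmission loss plus two-way
  water attenuation).
- Relative resistance: R/R₀ (stretchable-electrode utility).

## Synthetic data

The generators define the study conditions; their defaults are the
device/phantom parameters where those are known and documented
conventions where they are not.

**Wire phantoms.**  100 µm wires are far below the resolution limit and
are ideal unit point scatterers.  Presets: `lateral-row` (nine wires at
0, ±1, ±2, ±3, ±4 cm lateral offset, 50 mm deep) and `axial-stack`
(on-axis wires every 10 mm from 10 to 140 mm).

**Speckle/contrast phantoms.**  Uniformly random scatterer positions
(seeded), zero-mean Gaussian base amplitudes, scaled by
10^(contrast/20) inside each cylindrical inclusion.  Density is given
per nominal resolution cell (0.5 mm × 1.0 mm); ≥ 10 per cell gives
fully developed speckle.  The six-object contrast set defaults to
{−15, −6, −3, +3, +6, +15} dB: extremes and lowest pair as specified
for the greyscale phantom, middle pair chosen symmetric.  For CNR
studies the inclusion is placed off-centre and the background ROI at
its mirror position, so both ROIs see identical lateral imaging gain —
without this, the sector's field-of-view roll-off, not the contrast,
dominates the statistic.

**Beating left ventricle.**  A prolate spheroid with fixed long/short
axis ratio 2 (a typical healthy LV shape) whose volume follows a
piecewise-cosine cycle: end-diastolic plateau, systolic contraction to
an end-systolic plateau (systole ≈ 1/3 of the cycle), rapid filling,
diastasis, atrial kick.  The plateaus guarantee that sampled frames hit
the exact EDV and ESV.  Masks are the filled apical-long-axis ellipse
section; the returned truth volumes are the exact spheroid volumes.
Only EDV, ESV and heart rate are recoverable truth; the cycle shape is
a realism convention.  The generator emulates segmentation output, not
echo texture: passing tests show the geometry→volume→indices chain is
correct, not that a segmenter would produce such masks from real,
speckled, partially occluded images.

## Cardiac pipeline choices

- LV volume: single-plane Simpson's method of disks (clinical
  convention), default 20 disks, long axis from the mask's principal
  axis; each disk diameter is sampled in a one-pixel band at the slice
  midpoint (a midpoint rule — slice-wide extents overestimate curved
  chambers at coarse disk counts).  An area–length alternative
  (V = 8A²/(3πL)) is provided behind a flag.
- Cycle detection: end-diastolic peaks with prominence ≥ 10% of the
  waveform range; per cycle EDV = max, ESV = min, SV = EDV − ESV,
  EF = 100·SV/EDV, HR = 60/period, CO = SV·HR/1000.  The identities
  hold exactly by construction.
- M-mode tracking: per frame, each interface is the intensity-weighted
  centroid of the brightest ridge within ± a search window of its
  previous position (ridge = pixels within 6 dB of the window maximum);
  frames without a ridge above floor + 6 dB are flagged and linearly
  interpolated.  This is a deliberately simple documented tracker in
  place of a manual clinical procedure.
- Bland–Altman: limits of agreement mean ± 1.96·sd of the pairwise
  differences (sample sd, n − 1), with the within-limits fraction
  reported.

## Numerical choices and degenerate inputs

- Delays are normalized to min = 0; all delay laws are translation
  invariant (the wide-beam virtual source is anchored to the aperture
  centroid for exactly this reason).
- FWHM: rejected when the peak sits on the profile boundary, when a
  half-maximum crossing is missing, or when equal global maxima occur
  at separated positions (ambiguous main lobe); a contiguous plateau is
  accepted.
- Empty phantoms simulate to all-zero (valid) channel data; an all-zero
  beamformed frame cannot be log-compressed and is rejected.
- Pixels whose round-trip time leaves the recorded window contribute
  zero and are flagged in a coverage mask.
- A constant LVID waveform yields one degenerate cycle with
  LVIDd = LVIDs rather than an error; a constant volume waveform has no
  cycles and is rejected.
- Scan conversion of a single beam degenerates to a straight column
  copy.

## Problem sizes

The test suite and demo pipeline use deliberately scaled study sizes,
chosen once as representative: PSF behaviour uses the full 97-angle
sequence on 8–9 wire targets with per-wire image patches (≈ 0.05–0.1 mm
pixels); CNR uses 21 compounding angles, 3.5 mm inclusions and ≈ 7·10³
scatterers per realization at density 15 per cell; curvature A/B uses
21 angles on a 100 mm cylinder; the cardiac study uses EDV 120 ml,
ESV 50 ml, 75 bpm, 30 Hz, 4 cycles at 0.25 mm mask pixels.  Channel
noise in the SNR study is set so a single plane-wave wire image sits
near 30–40 dB SNR, the regime a single transmission of the hardware
operates in.

## Known limitations

- The Born model has no attenuation, reverberation or nonlinearity, so
  absolute penetration depth and absolute SNR are not hardware
  predictions; only orderings and trends transfer.
- The first-arrival transmit-time model treats the transmit field as a
  single wavefront; edge waves and apodization-dependent transmit
  beamplans are not represented.
- The elevational dimension enters only through element directivity;
  there is no elevational focusing (the physical device has none
  either).
- The orthogonal (Mills-cross) array type models geometry only; fusing
  the two perpendicular imaging planes into one volume is not
  attempted.
- The cardiac pipeline consumes segmentation masks; no image
  segmentation is performed.
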