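# Methods

`llsheet` simulates the illumination arm of a lattice light-sheet microscope
under the scalar approximation, characterizes every common light-sheet
family through its swept excitation and overall transfer functions, and
scores practical axial resolvability with a stripe-phantom deconvolution
benchmark.  This note records the model, its assumptions, the numerical
choices, and what the synthetic benchmark does and does not show.

## Physical model

**Coordinates.** `z` is the sheet-confinement / detection axis, `y` the
propagation axis, `x` the sweep axis.  Pupil coordinates are in NA units:
a pupil sample at `(NA_x, NA_z)` is a plane wave with transverse wave
vector `k_o (NA_x, NA_z)`, `k_o = 2*pi/lambda_exc`, and axial wave number
`k_y = k_o*sqrt(n^2 - NA_x^2 - NA_z^2)`.

**Propagation.** The stationary excitation field at offset `y` is the
inverse 2D Fourier transform of the pupil field multiplied by
`exp(i*k_y*y)` (angular spectrum).  Transforms are orthonormal, so total
power is conserved exactly at focus and to rounding under propagation;
grids are centered with odd sample counts so DC lies on a sample and the
conjugate spacings obey `dx * dNA * N = lambda_exc`.  Components beyond the
propagating circle `NA = n` are a configuration error and are rejected
(with a relative amplitude floor of 1e-9 so that analytically decaying
Gaussian tails, which are truncated at the circle, do not trip the check).

**Swept sheets and field synthesis.** Sweeping along `x` time-averages the
intensity, equivalent to keeping the `k_x = 0` line of the excitation OTF.
By Parseval's theorem the swept cross-section `I(y, z)` equals the
incoherent sum over pupil columns (fixed `k_x`) of their 1D focal
intensities — the field-synthesis identity — which is also how it is
computed: only columns carrying amplitude are transformed, which makes the
y-scans used for length measurement and design loops cheap.  The identity
itself is verified against the direct 2D route (x-average of the full
stationary PSF) to 1e-6 relative in the tests.  Fine axial sampling (e.g.
the 36.7 nm benchmark pixel) is obtained by zero-padding the column spectra
(`n_z_out`), which changes evaluation density, not physics.

**Detection.** The detection OTF is the scalar Debye model: the
autocorrelation of a uniform spherical pupil cap of half-angle
`asin(NA_det/n)` at the emission wavelength.  Its `k_y = 0` slice (the
"bowtie" with the missing cone) is computed by numerically defocusing the
cap, integrating the intensity over the third axis, and transforming; a
Hann window over the finite defocus range suppresses spectral leakage from
the slowly decaying defocus halo (at the cost of smearing DC over ~2 kz
samples and under-reading thresholded support radii by a few percent).
Vectorial (Richards–Wolf) detection is a documented extension point; all
support-geometry metrics used here are apodization-independent.

## Sheet families and their parameters

| family | key parameters | pupil structure |
|---|---|---|
| `gaussian` | waist `w0` (nm), optional line offset | vertical line(s), Gaussian `exp(-(k_z w0)^2/4)` |
| `sinc` | half-bandwidth `NA_sinc` | uniform line(s), rect of half-width `NA_sinc` |
| `bessel` | annulus `NA_min/NA_max` | constant ring |
| `mb` | ring `NA_exc`, annulus, period `T` | `2M+1` uniform lines of period `k_x = 2*pi/T`, annulus-cropped |
| `ac` | `NA_exc`, symmetry, stripe width `sigma_NA` | ideal-lattice points replaced by equal Gaussian stripes |
| `hb` | `NA_exc`, symmetry, `sigma_ref` or target length | Gaussian beamlets, widths/amplitudes balanced (below) |
| `cs` | as `mb` | analytic band sum `cos^2 * sinc^2` (swept profile only) |

`sigma_NA` throughout is the 1/e half-width of the beamlet *field* in NA
units (equivalently the 1/e^2 half-width of pupil intensity).  Lattice
periods follow from ring geometry: square `T = lambda/NA_exc`, hexagonal
`T = (2/sqrt(3)) lambda/NA_exc`; the hexrect pattern adds ring points at
`NA_z = +-NA_exc/4` and `+-3 NA_exc/4`, whose rectangular-lattice
equivalents have periods `(4/sqrt(15))` and `(4/sqrt(7)) lambda/NA_exc`.
MB bands are kept whenever their line still intersects the annulus
(`|m| lambda/T <= NA_max`).

**Harmonic balancing.** Each beamlet `b` of the ideal lattice (direction
cosines `(s_b, c_b)`, `c_b` axial) becomes a 1D Gaussian stripe.  Its
radial NA extent — which sets its propagation length — scales as
`|c_b| * sigma_b`, so equal per-beamlet length requires
`sigma_b = sigma_ref / |c_b|` with the polar beamlet (`|c_b| = 1`) as
reference.  The focal amplitude of a beamlet is the integral of its pupil
field (`~ E_b * sigma_b`), so equal focal amplitudes — and hence equal
swept-OTF harmonic strengths — require `E_b = |c_b| * E_ref`.  With these
two rules the hexagonal `+-k_o NA_exc` and `+-2 k_o NA_exc` harmonics come
out exactly equal (each 1/4 of DC).  `sigma_ref` is initialized from the
thin-annulus estimate `(n^2 - NA^2)/(4 NA) * lambda/y_FWHM` and tuned by
deterministic bisection (bracket `sigma_0/5 .. 5*sigma_0`, tolerance
`0.5 lambda/n`) against the simulated sheet length, since the closed-form
estimate underestimates the measured FWHM by the envelope shape factor.
For the hexrect pattern at practical lengths the `NA_exc/4` beamlets merge
across the equator into quasi-DC bands; this is reported as a warning, not
an error, and the sheet remains usable.

**SLM generation path.** The experimental path is modeled as: focal field
→ normalized real part → phase pattern (`pi*E_norm` grayscale, or binary
{0, pi}), cropped to zero where `|E_norm| <= epsilon` → unit-amplitude
phase screen `exp(i*Phi)` → forward transform → annular mask.  The
incident illumination is a uniform plane wave; SLM pixelation, fill factor
and dispersion are not modeled.  Full-depth phase-only encoding is
nonlinear (the fundamental diffracted order scales like `J1(pi*E)`), so the
realized focal intensity reproduces the designed structure (correlation
> 0.8, band positions to one grid sample, variable band intensities) but
not its exact intensity profile; realized sheets are typically somewhat
longer than their ideal designs.  Cropping adds sinc-like side orders that
partially fill overall-OTF troughs, as intended.

## Resolution metrics

Resolution means reciprocal OTF-support radius (no contrast criterion):
lateral swept `lambda_det/(2 NA_det)`; on-axis axial
`lambda_exc/(2 NA_exc_max)`; maximal axial (at the bowtie offset)
`1/[2 NA_exc_max/lambda_exc + (n - sqrt(n^2 - NA_det^2))/lambda_det]`;
widefield axial `lambda_det/(n - sqrt(n^2 - NA^2))`; SIM lateral
`1/[2 NA_det/lambda_det + q NA_exc/lambda_exc]` with `q = sqrt(3)`
(hexagonal) or 2 (square) — the aperiodic hexrect pattern cannot be used
for coherent SIM and is rejected.  The effective `NA_exc_max` of
Gaussian-beamlet families is `min(NA_exc + sigma_NA, NA_max)`.  The overall
swept OTF for axial-SW/square sheets becomes discontinuous once
`NA_exc > (lambda_exc/lambda_det)(n - sqrt(n^2 - NA_det^2))` (~0.425 for
the reference instrument).  Specimen-frame resolutions are obtained by
scanning the support boundary along axes rotated by the objective tilt
(32.45 degrees by default); for closed-form reports an elliptical proxy
support built from the lateral and maximal-axial radii is used, for OTF
maps the support is measured numerically along the rotated rays.

`y_FWHM` is operationally the interpolated FWHM of `I(y, z=0)`, and
`y_HWHM` the offset where it falls to half.  Excitation confinement is the
cumulative fraction `C(z)` of the swept profile within `+-z`, computed as
centered pixel sums mapped to pixel edges so that `C(0) = 0` and
`C(inf) = 1` exactly.

## Stripe benchmark

The benchmark mirrors a standard resolvability protocol: 28 one-pixel
stripes normal to `z`, separated by 1..25 then 100 and 151 simulation
pixels of 0.10 medium wavelengths (36.7 nm at 488 nm in water), are imaged
by 3D convolution with the overall swept PSF (sheet cross-section times the
scalar detection PSF), binned 3x to an effective 110.1 nm camera pixel
(the integer-factor stand-in for the instrument's 108 nm), normalized so
the 99.9th percentile is 400 counts (shot-noise SNR 20), and corrupted
with variance-matched Gaussian shot noise, `N(0, 4^2)` read noise and a
100-count offset.  Volumes default to 64 x 64 x 833 simulation voxels:
the phantom is laterally uniform, so a reduced transverse extent changes
only the (negligible) stripe-edge spectrum, and the 833-plane z range
holds the full ladder plus 128-pixel margins.  Richardson–Lucy
deconvolution (our implementation; verified against the scikit-image
reference to 1e-8) runs on the offset-subtracted, clamped volume; the
stopping iteration is either fixed or chosen as the count maximizing the
FSC cutoff (threshold 1/7) between two independent noise realizations,
ties toward fewer iterations.

**Resolvability readout.** For each adjacent stripe pair the modulation
depth `(peaks - trough)/(peaks + trough)` is measured on the x,y-averaged
axial linecut, peaks searched within one camera pixel of the known
positions; a pair is resolved at depth >= 0.04.  The threshold
operationalizes the visual "smallest resolvable line pair" judgment and
was calibrated once against the three benchmark spacings the protocol is
known to produce (881/514/404 nm; any value in ~0.006–0.046 reproduces
them, and a 4% dip on the noise-averaged linecut is plainly visible).
RL introduces two artifact classes: isolated ghost-resolved pairs far
below the resolvable band (harmonics of the lattice period) and isolated
contrast-inverted pairs inside deep OTF troughs (for the MB hexagonal
sheet the 734/771 nm pairs invert at every iteration count).  The reported
smallest resolvable spacing is therefore the lower edge of the longest
contiguous band of resolved pairs (ties toward larger spacings), with a
monotonicity flag recording failures above it.

**What the benchmark does and does not show.**  The phantom is noise-free
binary geometry with ideal, known PSFs; real specimens add scattering,
aberrations, PSF mismatch and dense spectra weighted toward DC, all of
which reduce practical resolution.  The Gaussian-approximated Poisson
noise is accurate at these signal levels but not at photon-starved ones.
Results beyond the linear support limit rely on the nonnegativity prior of
RL and are specific to sparse, high-contrast structure.

## Reference configurations

Presets encode the printed parameter sets of the standard nine-sheet
comparison (all of length ~50 lambda/n unless "short"): Gaussian and sinc
with waist/bandwidth solved for the target length; MB square (NA 0.30,
annulus width solved; short variant NA 0.41, annulus 0.60/0.40); MB
hexagonal (NA 0.43, annulus 0.47/0.40, binary cropping 0.080); cosine-sinc
hexagonal (NA 0.40, annulus 0.435/0.365); axially confined SW/square/
hexagonal with stripe width solved for the target length; harmonic-
balanced hexagonal (NA 0.50, annulus 0.60/0.40, cropping 0.010, length
53 lambda/n) and hexrect (length 56 lambda/n).  Where a published
configuration quotes both a beamlet width and a sheet length that the
scalar model cannot produce simultaneously, the solved-for-length variant
is used for length characterization and the quoted-width variant for
benchmark resolvability; both are exposed explicitly.

## Numerical defaults

Pupil grid 1001 x 1001 samples spanning 2.6 NA (focal spacing 187.7 nm;
doubling the sampling changes sheet-length metrics well under 0.5%).  The
grid span is capped at `2n` (beyond which added bandwidth is
evanescent-only).  Benchmark axial sampling 36.70 nm via spectral
padding; detection PSF computed on a 256-wide transverse grid and cropped,
so the detection pupil is sampled by ~18 samples per radius.  OTF maps are
DC-normalized per y plane; only ratios are compared.  All stochastic paths
take explicit seeds; fixed seeds give bit-identical outputs.

## Known limitations

Scalar theory throughout (no polarization; excitation apodization is
uniform); ideal annuli and SLM; no aberrations, scattering or
sample-induced PSF distortion; confocal-slit and incoherent-SIM sweep
modes are out of scope, as is full coherent SIM reconstruction (only SIM
support metrics are computed); the photobleaching analysis is limited to
the excitation-confinement curve.
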