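# llsheet

Design and characterization of light-sheet microscopy illumination.

Light-sheet microscopes image a 3D specimen by sweeping a thin plane of
excitation light (confined along the detection axis `z`, propagating along
`y`, swept along `x`) through the sample.  The sheet's axial profile sets
the axial resolution and optical sectioning; the distance over which it
stays thin sets the usable field of view.  Structured sheets — axial
standing waves, square and hexagonal optical lattices, multi-Bessel (MB)
arrays, axially confined (AC) and harmonic-balanced (HB) lattices — trade
these off very differently from the common Gaussian or sinc sheets, and
comparing them fairly requires simulating the full chain from the rear
pupil of the excitation objective to a deconvolved image.

`llsheet` is aimed at microscope builders and image-analysis researchers
who need that chain in one place:

- **Pupil synthesis** for every family (Gaussian, sinc, Bessel annulus,
  MB lattices, AC lattices, HB lattices, cosine-sinc band profiles), plus
  the spatial-light-modulator generation path (grayscale/binary phase with
  cropping factor, annular mask filtering).
- **Scalar diffraction propagation**: stationary and swept excitation
  PSFs/OTFs versus propagation distance `y`, the scalar detection OTF with
  its missing cone, and the overall swept OTF
  `OTF_overall(k_x, y, k_z) = OTF_det *_kz OTF_exc_swept`.
- **Design**: the harmonic-balancing algorithm — beamlet widths
  `sigma_b = sigma_ref/|c_b|` equalize per-beamlet propagation length
  `(y_FWHM)_b = lambda / {2n [sqrt(1-(NA_b-/n)^2) - sqrt(1-(NA_b+/n)^2)]}`,
  amplitudes `E_b = |c_b| E_ref` equalize the axial OTF harmonics, and
  `sigma_ref` is tuned by bisection to a requested sheet length.
- **Metrics**: closed-form and numerically measured resolution limits
  (lateral `lambda_det/2NA_det`; axial on-axis `lambda_exc/2NA_exc`;
  maximal axial `1/[2NA_exc/lambda_exc + (n - sqrt(n^2-NA_det^2))/
  lambda_det]`; SIM-extended lateral support), the OTF gap/discontinuity
  criterion, and excitation-confinement curves.
- **Benchmarking**: a variable-pitch stripe phantom imaged with the
  overall swept PSF at SNR 20, Richardson–Lucy deconvolved with
  Fourier-shell-correlation-guided stopping, and scored by the smallest
  resolvable line-pair spacing.

See `docs/methods.md` for the model, assumptions and numerical choices.

## Worked example

Characterize the MB hexagonal lattice sheet (ring NA 0.43, annulus
0.47/0.40) and benchmark a sinc sheet of the same ~50-wavelength length:

```python
import numpy as np
from llsheet import (OpticalConfig, SheetSpec, make_grids, mb_pupil,
                     run_stripe_benchmark, swept_sheet, y_fwhm)
from llsheet.presets import preset_pupil

config = OpticalConfig()          # 488/520 nm, water, NA_det 1.0
grids = make_grids(config)

spec = SheetSpec(family="mb", symmetry="hexagonal", na_exc=0.43,
                 na_min=0.40, na_max=0.47)
pupil = mb_pupil(spec, grids, config)
sheet = swept_sheet(pupil.values, grids, config,
                    y_planes_nm=np.linspace(-35000, 35000, 281))
print(f"MB hexagonal y_FWHM = {y_fwhm(sheet)/config.lambda_medium_nm:.1f} "
      "lambda/n")

sinc = preset_pupil("sinc-50", config, grids)
bench = run_stripe_benchmark(sinc.values, grids, config)
print(f"sinc sheet: FSC-optimal {bench.rl_iterations} RL iterations, "
      f"smallest resolved line pair {bench.min_resolved_nm:.0f} nm")
```

Output:

```
MB hexagonal y_FWHM = 49.2 lambda/n
sinc sheet: FSC-optimal 15 RL iterations, smallest resolved line pair 881 nm
```

The hexagonal sheet stays near its minimum thickness for ~49 excitation
wavelengths in the medium (18 um at 488 nm in water), and the sinc sheet
of comparable length resolves stripe pairs down to 881 nm after
deconvolution — well short of what the lattice sheets reach (the HB
hexagonal design resolves below 500 nm in the same benchmark), which is
the central quantitative argument for structured illumination sheets.

A thin CLI wraps the same functions:

```bash
llsheet presets                      # the named reference configurations
llsheet characterize --preset mb-hex-48 --out out/
llsheet design-hb --symmetry hexagonal --na-exc 0.5 --y-fwhm 53 --out out/
llsheet stripe-bench --preset sinc-50 --out out/
```

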