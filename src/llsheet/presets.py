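"""Named light-sheet configurations.

The nine standard sheets compared throughout the package share a propagation
length of ~50 excitation wavelengths in the medium (y_FWHM ~ 50 lambda/n,
the span of a whole cultured cell) unless marked "short".  Parameters that
are printed for a configuration (ring NA, annulus, cropping factor) are
encoded directly; free parameters (Gaussian waist, sinc bandwidth, beamlet
widths, annulus widths) are solved at build time so the *simulated* sheet
reaches the stated length.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .core import GridSet, OpticalConfig, make_grids, pupil_to_focal
from .pupils import (
    PupilField,
    SheetSpec,
    build_pupil,
    hb_design,
    _measure_y_fwhm,
)
from .slm import AnnularMask, apply_slm_and_mask, phase_binary, phase_grayscale

__all__ = ["PRESETS", "preset_names", "preset_pupil", "realize_pupil", "solve_length"]


def _lam_n(config: OpticalConfig) -> float:
    return config.lambda_medium_nm


def solve_length(
    build: Callable[[float], PupilField],
    config: OpticalConfig,
    y_target_nm: float,
    lo: float,
    hi: float,
    tol_nm: float | None = None,
    max_iter: int = 60,
) -> tuple[float, PupilField]:
    """Bisection on a scalar sheet parameter against the simulated y_FWHM.

    ``build(p)`` returns a pupil; the probe range scales with the target.
    Works for either monotone direction.
    """
    if tol_nm is None:
        tol_nm = 0.5 * config.lambda_medium_nm
    probe = 2.5 * y_target_nm

    def measure(p: float) -> float:
        try:
            return _measure_y_fwhm(build(p), config, probe)
        except ValueError:
            return np.inf

    y_lo, y_hi = measure(lo), measure(hi)
    if not (min(y_lo, y_hi) <= y_target_nm <= max(y_lo, y_hi)):
        raise RuntimeError(
            f"target y_FWHM {y_target_nm:.0f} nm not bracketed on [{lo}, {hi}] "
            f"(measured {y_lo:.0f}..{y_hi:.0f} nm)"
        )
    increasing = y_hi > y_lo
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        y_mid = measure(mid)
        if abs(y_mid - y_target_nm) < tol_nm:
            return mid, build(mid)
        if (y_mid < y_target_nm) == increasing:
            lo = mid
        else:
            hi = mid
    raise RuntimeError("length solve did not converge")


def _gaussian_50(config: OpticalConfig, grids: GridSet) -> PupilField:
    target = 50.0 * _lam_n(config)

    def build(w0: float) -> PupilField:
        return build_pupil(SheetSpec(family="gaussian", w0_nm=w0), grids, config)

    _, pupil = solve_length(build, config, target, lo=200.0, hi=3000.0)
    return pupil


def _sinc_50(config: OpticalConfig, grids: GridSet) -> PupilField:
    target = 50.0 * _lam_n(config)

    def build(na_sinc: float) -> PupilField:
        return build_pupil(SheetSpec(family="sinc", na_sinc=na_sinc), grids, config)

    _, pupil = solve_length(build, config, target, lo=0.05, hi=0.59)
    return pupil


def _mb_square_50(config: OpticalConfig, grids: GridSet) -> PupilField:
    target = 50.0 * _lam_n(config)
    na_exc = 0.30

    def build(w: float) -> PupilField:
        return build_pupil(
            SheetSpec(
                family="mb", symmetry="square", na_exc=na_exc,
                na_min=na_exc - w, na_max=na_exc + w,
            ),
            grids, config,
        )

    _, pupil = solve_length(build, config, target, lo=0.005, hi=0.15)
    return pupil


def _ac_solved(symmetry: str, na_exc: float):
    def factory(config: OpticalConfig, grids: GridSet) -> PupilField:
        target = 50.0 * _lam_n(config)

        def build(sigma: float) -> PupilField:
            return build_pupil(
                SheetSpec(family="ac", symmetry=symmetry, na_exc=na_exc,
                          sigma_na=sigma),
                grids, config,
            )

        _, pupil = solve_length(build, config, target, lo=0.003, hi=0.12)
        return pupil

    return factory


def _hb(symmetry: str, y_lam_n: float):
    def factory(config: OpticalConfig, grids: GridSet) -> PupilField:
        _, pupil, _ = hb_design(
            symmetry=symmetry, na_exc=0.50,
            y_fwhm_target_nm=y_lam_n * _lam_n(config),
            config=config, grids=grids,
            epsilon=0.010, na_min=0.40, na_max=0.60,
        )
        return pupil

    return factory


def _fixed(spec_kwargs: dict):
    def factory(config: OpticalConfig, grids: GridSet) -> PupilField:
        return build_pupil(SheetSpec(**spec_kwargs), grids, config)

    return factory


PRESETS: dict[str, dict] = {
    "gaussian-50": {
        "builder": _gaussian_50, "slm_mode": "grayscale",
        "description": "Gaussian sheet, waist solved for y_FWHM = 50 lambda/n",
    },
    "sinc-50": {
        "builder": _sinc_50, "slm_mode": "grayscale",
        "description": "sinc sheet, NA_sinc solved for y_FWHM = 50 lambda/n",
    },
    "mb-square-50": {
        "builder": _mb_square_50, "slm_mode": "binary", "epsilon": 0.080,
        "description": "MB square lattice, NA_exc 0.30, annulus solved for "
                       "y_FWHM = 50 lambda/n",
    },
    "mb-square-16": {
        "builder": _fixed(dict(family="mb", symmetry="square", na_exc=0.41,
                               na_min=0.40, na_max=0.60)),
        "slm_mode": "binary", "epsilon": 0.080,
        "description": "short MB square lattice, NA_exc 0.41, annulus 0.60/0.40",
    },
    "mb-hex-48": {
        "builder": _fixed(dict(family="mb", symmetry="hexagonal", na_exc=0.43,
                               na_min=0.40, na_max=0.47, epsilon=0.080)),
        "slm_mode": "binary", "epsilon": 0.080,
        "description": "MB hexagonal lattice, NA_exc 0.43, annulus 0.47/0.40, "
                       "binary SLM cropping 0.080",
    },
    "cs-hex-54": {
        "builder": _fixed(dict(family="mb", symmetry="hexagonal", na_exc=0.40,
                               na_min=0.365, na_max=0.435)),
        "slm_mode": None,
        "description": "cosine-sinc realization of a hexagonal sheet, NA_exc "
                       "0.40, annulus 0.435/0.365 (swept profile is the "
                       "incoherent band sum of the matching MB pupil)",
    },
    "ac-sw-50": {
        "builder": _ac_solved("axial_sw", 0.30), "slm_mode": "binary",
        "epsilon": 0.080,
        "description": "axially confined axial standing wave, NA_exc 0.30, "
                       "stripe width solved for y_FWHM = 50 lambda/n",
    },
    "ac-square-50": {
        "builder": _ac_solved("square", 0.30), "slm_mode": "binary",
        "epsilon": 0.080,
        "description": "axially confined square lattice, NA_exc 0.30, stripe "
                       "width solved for y_FWHM = 50 lambda/n",
    },
    "ac-hex-50": {
        "builder": _ac_solved("hexagonal", 0.43), "slm_mode": "binary",
        "epsilon": 0.080,
        "description": "axially confined hexagonal lattice, NA_exc 0.43, "
                       "stripe width solved for y_FWHM = 50 lambda/n",
    },
    "hb-hex-53": {
        "builder": _hb("hexagonal", 53.0), "slm_mode": "grayscale",
        "epsilon": 0.010,
        "description": "harmonic-balanced hexagonal lattice, NA_exc 0.50, "
                       "annulus 0.60/0.40, cropping 0.010, y_FWHM = 53 lambda/n",
    },
    "hb-hexrect-56": {
        "builder": _hb("hexrect", 56.0), "slm_mode": "grayscale",
        "epsilon": 0.010,
        "description": "harmonic-balanced hexagonal-rectangular pattern, "
                       "NA_exc 0.50, annulus 0.60/0.40, y_FWHM = 56 lambda/n",
    },
}


def preset_names() -> list[str]:
    return list(PRESETS)


def realize_pupil(
    ideal: PupilField, config: OpticalConfig, mode: str, epsilon: float,
    mask: AnnularMask,
) -> PupilField:
    """Pass an ideal pupil through the SLM generation path: focal field ->
    phase pattern (grayscale or binary, cropped at epsilon) -> diffraction ->
    annular mask."""
    focal = pupil_to_focal(ideal.values, ideal.grids, config, 0.0)
    if mode == "binary":
        pattern = phase_binary(focal.values, epsilon, ideal.grids)
    elif mode == "grayscale":
        pattern = phase_grayscale(focal.values, epsilon, ideal.grids)
    else:
        raise ValueError(f"unknown SLM mode {mode!r}")
    return apply_slm_and_mask(pattern, mask, ideal.grids, spec=ideal.spec)


def preset_pupil(
    name: str,
    config: OpticalConfig | None = None,
    grids: GridSet | None = None,
    realized: bool = False,
) -> PupilField:
    """Build a preset's pupil.  ``realized=True`` routes the ideal design
    through the SLM + annular-mask generation model (binary mode for MB/AC
    sheets, grayscale otherwise) using the preset's cropping factor."""
    if name not in PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(PRESETS)}"
        )
    config = config or OpticalConfig()
    grids = grids or make_grids(config)
    entry = PRESETS[name]
    pupil = entry["builder"](config, grids)
    if realized:
        mode = entry.get("slm_mode")
        if mode is None:
            raise ValueError(f"preset {name!r} has no SLM realization")
        spec = pupil.spec
        if spec.na_max > 0:
            mask = AnnularMask(spec.na_min, spec.na_max)
        else:
            # unrestricted families: transmit everything below the objective NA
            mask = AnnularMask(0.0, config.na_exc_obj)
        pupil = realize_pupil(pupil, config, mode, entry.get("epsilon", 0.0), mask)
    return pupil
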