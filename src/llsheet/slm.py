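"""Experimental generation path: focal field -> SLM phase -> annular mask.

A phase-only spatial light modulator conjugate to the specimen displays the
real part of the desired focal field, renormalized to +-pi and cropped below
a threshold ``epsilon`` to suppress weak sidelobes.  Diffraction from the
unit-amplitude phase screen is filtered by a pupil-conjugate annular mask
(inner/outer NA) that blocks undiffracted DC light and unwanted orders,
yielding the realized pupil.  Cropping adds sinc-like side orders flanking
each pupil band, which help fill troughs of the overall OTF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import GridSet
from .pupils import PupilField, SheetSpec

__all__ = [
    "SLMPattern",
    "AnnularMask",
    "phase_grayscale",
    "phase_binary",
    "apply_slm_and_mask",
]


@dataclass
class SLMPattern:
    """Phase pattern in [-pi, pi] on the focal (z, x) grid."""

    phase: np.ndarray
    mode: str  # "grayscale" | "binary"
    epsilon: float
    grids: GridSet

    def __post_init__(self) -> None:
        if self.mode not in ("grayscale", "binary"):
            raise ValueError(f"unknown SLM mode {self.mode!r}")
        if np.abs(self.phase).max() > np.pi + 1e-12:
            raise ValueError("phase exceeds +-pi")


@dataclass(frozen=True)
class AnnularMask:
    """Transmitting ring between NA_min and NA_max."""

    na_min: float
    na_max: float

    def __post_init__(self) -> None:
        if not (0 <= self.na_min < self.na_max):
            raise ValueError("need 0 <= na_min < na_max")


def _normalized_real(e_focal: np.ndarray) -> np.ndarray:
    re = np.real(e_focal)
    peak = np.abs(re).max()
    if peak == 0:
        raise ValueError("focal field has zero real part everywhere")
    return re / peak


def phase_grayscale(e_focal: np.ndarray, epsilon: float, grids: GridSet) -> SLMPattern:
    """Grayscale phase: pi * E_norm where |E_norm| > epsilon, else 0."""
    e_norm = _normalized_real(e_focal)
    phase = np.where(np.abs(e_norm) > epsilon, np.pi * e_norm, 0.0)
    return SLMPattern(phase=phase, mode="grayscale", epsilon=epsilon, grids=grids)


def phase_binary(e_focal: np.ndarray, epsilon: float, grids: GridSet) -> SLMPattern:
    """Binary phase: pi where E_norm > epsilon, 0 where E_norm < -epsilon,
    0 in the cropped band |E_norm| <= epsilon."""
    e_norm = _normalized_real(e_focal)
    phase = np.where(
        np.abs(e_norm) > epsilon,
        (np.pi / 2.0) * np.sign(e_norm) + np.pi / 2.0,
        0.0,
    )
    return SLMPattern(phase=phase, mode="binary", epsilon=epsilon, grids=grids)


def apply_slm_and_mask(
    pattern: SLMPattern,
    mask: AnnularMask,
    grids: GridSet,
    spec: SheetSpec | None = None,
) -> PupilField:
    """Diffract a unit plane wave off the phase screen and filter at the pupil.

    The diffracted field ``exp(i*Phi)`` is transformed to the pupil and all
    samples outside the [NA_min, NA_max] annulus are zeroed.  An NA_min of 0
    transmits the large undiffracted DC component and triggers a warning.
    """
    if pattern.phase.shape != (grids.n_k, grids.n_k):
        raise ValueError("pattern grid does not match grids")
    if mask.na_min == 0:
        zero_frac = np.mean(pattern.phase == 0)
        if zero_frac > 0.25:
            warnings.warn(
                "mask transmits DC while the pattern is mostly flat: "
                "undiffracted light will dominate the pupil",
                stacklevel=2,
            )
    field = np.exp(1j * pattern.phase)
    pupil = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(field), norm="ortho"))
    na = grids.na_axis
    rho = np.sqrt(na[np.newaxis, :] ** 2 + na[:, np.newaxis] ** 2)
    pupil[(rho < mask.na_min) | (rho > mask.na_max)] = 0.0
    if spec is None:
        spec = SheetSpec(family="bessel", na_min=mask.na_min, na_max=mask.na_max)
    return PupilField(values=pupil, spec=spec, grids=grids)
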