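"""Physical configuration, sampling grids and scalar diffraction transforms.

Coordinate conventions
----------------------
``z`` is the sheet-confinement / detection axis, ``y`` the propagation axis
and ``x`` the sweep axis.  Pupil coordinates are expressed in NA units, so a
pupil sample at ``(NA_x, NA_z)`` corresponds to transverse wave-vector
components ``(k_x, k_z) = k_o * (NA_x, NA_z)`` with ``k_o = 2*pi/lambda_exc``.
A scalar field on the pupil maps to the focal plane through an inverse 2D
Fourier transform (angular-spectrum propagation); the axial wave number of
each plane-wave component is ``k_y = k_o*sqrt(n^2 - NA_x^2 - NA_z^2)``, so
propagating a distance ``y`` multiplies the pupil by ``exp(i*k_y*y)``.

Grids are centered with an odd number of samples per axis so that the zero
frequency / focal origin lies exactly on a sample, and the conjugate focal
spacing satisfies ``dx * dNA * N = lambda_exc`` per axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OpticalConfig",
    "GridSet",
    "FocalField",
    "make_grids",
    "pupil_to_focal",
    "EvanescentPupilError",
]


class EvanescentPupilError(ValueError):
    """Raised when a pupil has amplitude outside the propagating circle NA = n."""


@dataclass(frozen=True)
class OpticalConfig:
    """Global physical frame of the microscope.

    Parameters
    ----------
    lambda_exc_nm : float
        Excitation vacuum wavelength (nm).
    lambda_det_nm : float
        Detection emission wavelength (nm).
    n_medium : float
        Refractive index of the immersion/specimen medium.
    na_det : float
        Detection objective numerical aperture.
    na_exc_obj : float
        Maximum numerical aperture of the excitation objective.
    tilt_alpha_deg : float
        Tilt of the objective pair relative to the specimen substrate, in
        degrees (0 <= alpha < 90).
    """

    lambda_exc_nm: float = 488.0
    lambda_det_nm: float = 520.0
    n_medium: float = 1.33
    na_det: float = 1.0
    na_exc_obj: float = 0.60
    tilt_alpha_deg: float = 32.45

    def __post_init__(self) -> None:
        if self.lambda_exc_nm <= 0 or self.lambda_det_nm <= 0:
            raise ValueError("wavelengths must be positive")
        if not (0 < self.na_det < self.n_medium):
            raise ValueError(
                f"need 0 < na_det < n_medium, got na_det={self.na_det}, "
                f"n_medium={self.n_medium}"
            )
        if not (0 < self.na_exc_obj < self.n_medium):
            raise ValueError(
                f"need 0 < na_exc_obj < n_medium, got na_exc_obj={self.na_exc_obj}"
            )
        if not (0 <= self.tilt_alpha_deg < 90):
            raise ValueError("tilt_alpha_deg must lie in [0, 90)")

    @property
    def k_o(self) -> float:
        """Vacuum excitation wave number 2*pi/lambda_exc (rad/nm)."""
        return 2.0 * np.pi / self.lambda_exc_nm

    @property
    def k(self) -> float:
        """Medium excitation wave number n*k_o (rad/nm)."""
        return self.n_medium * self.k_o

    @property
    def lambda_medium_nm(self) -> float:
        """Excitation wavelength in the medium, lambda_exc/n (nm)."""
        return self.lambda_exc_nm / self.n_medium


@dataclass(frozen=True)
class GridSet:
    """Conjugate pupil/focal sampling grids (one transform pair per axis)."""

    n_k: int
    d_na: float
    lambda_exc_nm: float
    y_planes: np.ndarray = field(default_factory=lambda: np.zeros(1))

    def __post_init__(self) -> None:
        if self.n_k % 2 == 0 or self.n_k < 3:
            raise ValueError(f"n_k must be odd and >= 3, got {self.n_k}")
        if self.d_na <= 0:
            raise ValueError("d_na must be positive")

    @property
    def na_axis(self) -> np.ndarray:
        """Centered pupil coordinate axis in NA units (DC on a sample)."""
        half = self.n_k // 2
        return (np.arange(self.n_k) - half) * self.d_na

    @property
    def na_span(self) -> float:
        return self.n_k * self.d_na

    @property
    def dx_nm(self) -> float:
        """Focal-plane sample spacing; dx * dNA * N = lambda_exc."""
        return self.lambda_exc_nm / (self.n_k * self.d_na)

    @property
    def x_axis_nm(self) -> np.ndarray:
        half = self.n_k // 2
        return (np.arange(self.n_k) - half) * self.dx_nm

    @property
    def kz_cycles_axis(self) -> np.ndarray:
        """Spatial-frequency axis conjugate to x_axis_nm, in cycles/nm."""
        return self.na_axis / self.lambda_exc_nm


@dataclass
class FocalField:
    """Complex scalar amplitude E(x, z) at a stated propagation offset y."""

    values: np.ndarray
    y_offset_nm: float
    grids: GridSet

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.shape != (self.grids.n_k, self.grids.n_k):
            raise ValueError(
                f"field shape {v.shape} does not match grid ({self.grids.n_k},)*2"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("focal field contains non-finite values")

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.values) ** 2


def make_grids(
    config: OpticalConfig,
    na_span: float = 2.6,
    n_k: int = 1001,
    y_extent_nm: float = 0.0,
    n_y: int = 1,
) -> GridSet:
    """Build consistent conjugate pupil/focal grids.

    ``na_span`` must cover at least ``2 * 1.1 * max(na_exc_obj, na_det)`` so
    OTF autocorrelations are not aliased, and may not exceed ``2*n_medium``
    (beyond which only evanescent components exist).  ``y_planes`` are
    ``n_y`` offsets symmetric about 0 spanning ``[-y_extent, +y_extent]``.
    """
    if n_k % 2 == 0:
        raise ValueError(f"n_k must be odd, got {n_k}")
    min_span = 2.0 * 1.1 * max(config.na_exc_obj, config.na_det)
    if na_span < min_span:
        raise ValueError(
            f"na_span={na_span} too small; need >= {min_span:.3f} to hold the OTF"
        )
    if na_span > 2.0 * config.n_medium:
        raise ValueError(
            f"na_span={na_span} exceeds 2*n_medium={2 * config.n_medium}: "
            "the added band is evanescent-only"
        )
    if y_extent_nm < 0 or n_y < 1:
        raise ValueError("y_extent_nm must be >= 0 and n_y >= 1")
    if y_extent_nm == 0 or n_y == 1:
        y_planes = np.zeros(1)
    else:
        y_planes = np.linspace(-y_extent_nm, y_extent_nm, n_y)
    d_na = na_span / n_k
    return GridSet(
        n_k=n_k, d_na=d_na, lambda_exc_nm=config.lambda_exc_nm, y_planes=y_planes
    )


def propagation_phase(
    na_x: np.ndarray, na_z: np.ndarray, config: OpticalConfig, y_nm: float
) -> np.ndarray:
    """exp(i*k_y*y) on the (na_z, na_x) mesh; zero where NA_rho >= n (no
    evanescent propagation is modeled)."""
    na_rho_sq = na_x[np.newaxis, :] ** 2 + na_z[:, np.newaxis] ** 2
    inside = na_rho_sq < config.n_medium**2
    ky = np.zeros_like(na_rho_sq)
    ky[inside] = config.k_o * np.sqrt(config.n_medium**2 - na_rho_sq[inside])
    phase = np.exp(1j * ky * y_nm)
    phase[~inside] = 0.0
    return phase


def _check_propagating(values: np.ndarray, grids: GridSet, config: OpticalConfig) -> None:
    na = grids.na_axis
    na_rho_sq = na[np.newaxis, :] ** 2 + na[:, np.newaxis] ** 2
    peak = np.abs(values).max()
    bad = (na_rho_sq >= config.n_medium**2) & (np.abs(values) > 1e-9 * peak)
    if np.any(bad):
        idx = np.argwhere(bad)
        worst = idx[np.argmax(np.abs(values)[bad])]
        raise EvanescentPupilError(
            f"pupil has {idx.shape[0]} nonzero samples outside the propagating "
            f"circle NA = n = {config.n_medium}; e.g. grid index "
            f"(iz={worst[0]}, ix={worst[1]}) at NA_rho = "
            f"{np.sqrt(na_rho_sq[worst[0], worst[1]]):.3f}"
        )


def pupil_to_focal(
    pupil_values: np.ndarray,
    grids: GridSet,
    config: OpticalConfig,
    y_nm: float = 0.0,
) -> FocalField:
    """Propagate a pupil field to the focal region at offset ``y``.

    Computes ``E(x, z; y) = FT^-1_{kx,kz}[E_pupil(kx,kz) exp(i k_y y)]`` on
    the centered grid, with an orthonormal transform so that total power is
    conserved (sum |E_focal|^2 == sum |E_pupil|^2, exactly at y = 0 and to
    rounding elsewhere).  Rows index z, columns index x.
    """
    v = np.asarray(pupil_values, dtype=complex)
    if v.shape != (grids.n_k, grids.n_k):
        raise ValueError("pupil shape does not match grids")
    _check_propagating(v, grids, config)
    if y_nm != 0.0:
        v = v * propagation_phase(grids.na_axis, grids.na_axis, config, y_nm)
    focal = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(v), norm="ortho"))
    return FocalField(values=focal, y_offset_nm=y_nm, grids=grids)


def focal_to_pupil(
    focal_values: np.ndarray, grids: GridSet
) -> np.ndarray:
    """Forward transform (focal plane -> pupil), inverse of :func:`pupil_to_focal`
    at y = 0, with the same orthonormal scaling."""
    v = np.asarray(focal_values, dtype=complex)
    if v.shape != (grids.n_k, grids.n_k):
        raise ValueError("field shape does not match grids")
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(v), norm="ortho"))
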