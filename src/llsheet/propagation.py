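"""Stationary and swept excitation PSFs/OTFs, the detection OTF and the
overall (excitation x detection) swept transfer function.

Sweeping a structured sheet along ``x`` time-averages its intensity, which is
equivalent to retaining only the ``k_x = 0`` line of the excitation OTF.  The
swept cross-section ``I(y, z)`` is therefore the ``x``-average of the
stationary PSF at each propagation offset ``y``; by Parseval's theorem this
equals the incoherent sum of the 1D focal intensities formed by each pupil
column of fixed ``k_x`` — the field synthesis theorem — which is how it is
computed here (only columns that carry pupil amplitude are transformed).

The detection arm is modeled as a scalar Debye spherical-cap pupil of
half-angle ``asin(NA_det/n)`` at the emission wavelength, without
apodization.  Its ``k_y = 0`` OTF slice shows the classic "bowtie" with the
missing cone around the axial frequency axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FocalField, GridSet, OpticalConfig, propagation_phase, pupil_to_focal

__all__ = [
    "SweptSheet",
    "OTFMap",
    "DetectionOTF",
    "excitation_psf",
    "excitation_otf",
    "swept_sheet",
    "detection_otf",
    "detection_psf_volume",
    "overall_swept_otf",
    "overall_psf",
    "sim_support",
]


@dataclass
class SweptSheet:
    """Swept-sheet intensity I(y, z) and per-y axial excitation OTF."""

    intensity: np.ndarray  # (n_y, n_z), real >= 0
    y_planes_nm: np.ndarray
    z_axis_nm: np.ndarray

    def __post_init__(self) -> None:
        if self.intensity.shape != (len(self.y_planes_nm), len(self.z_axis_nm)):
            raise ValueError("intensity shape does not match axes")

    @property
    def dz_nm(self) -> float:
        return float(self.z_axis_nm[1] - self.z_axis_nm[0])

    @property
    def kz_axis_cycles(self) -> np.ndarray:
        """Centered axial frequency axis (cycles/nm) for :meth:`axial_otf`."""
        n = len(self.z_axis_nm)
        return np.fft.fftshift(np.fft.fftfreq(n, d=self.dz_nm))

    def axial_otf(self, iy: int) -> np.ndarray:
        """DC-normalized axial excitation OTF at y_planes[iy] (centered)."""
        prof = self.intensity[iy]
        otf = np.fft.fftshift(np.fft.fft(np.fft.ifftshift(prof)))
        dc = otf[len(otf) // 2]
        if dc == 0:
            raise ValueError("zero total intensity at this y plane")
        return otf / dc

    def profile_at(self, y_nm: float) -> np.ndarray:
        """Intensity profile I(y, z) at the y plane nearest y_nm."""
        iy = int(np.argmin(np.abs(self.y_planes_nm - y_nm)))
        return self.intensity[iy]


@dataclass
class OTFMap:
    """DC-normalized complex transfer function on a (kz, kx) grid."""

    values: np.ndarray  # (n_kz, n_kx) complex, DC at center, DC == 1
    kx_axis_cycles: np.ndarray
    kz_axis_cycles: np.ndarray
    y_offset_nm: float = 0.0

    def linecut_kx0(self) -> np.ndarray:
        return self.values[:, len(self.kx_axis_cycles) // 2]

    def linecut_kz0(self) -> np.ndarray:
        return self.values[len(self.kz_axis_cycles) // 2, :]


@dataclass
class DetectionOTF:
    """k_y = 0 slice of the 3D scalar detection OTF (bowtie + missing cone)."""

    slice_values: np.ndarray  # (n_kz, n_kx) real-ish, DC at center == 1
    kx_axis_cycles: np.ndarray
    kz_axis_cycles: np.ndarray
    support_mask: np.ndarray
    config: OpticalConfig

    @property
    def lateral_support_cycles(self) -> float:
        """2 NA_det / lambda_det (cycles/nm)."""
        return 2.0 * self.config.na_det / self.config.lambda_det_nm

    @property
    def bowtie_kz_half_support_cycles(self) -> float:
        """Maximum axial half-extent of the bowtie: (n - sqrt(n^2 - NA^2))/lambda."""
        c = self.config
        return (c.n_medium - np.sqrt(c.n_medium**2 - c.na_det**2)) / c.lambda_det_nm


def excitation_psf(
    pupil_values: np.ndarray,
    grids: GridSet,
    config: OpticalConfig,
    y_nm: float = 0.0,
) -> FocalField:
    """Stationary excitation field at plane y; ``.intensity`` is the PSF."""
    return pupil_to_focal(pupil_values, grids, config, y_nm)


def excitation_otf(
    pupil_values: np.ndarray,
    grids: GridSet,
    config: OpticalConfig,
    y_nm: float = 0.0,
) -> OTFMap:
    """Excitation OTF(kx, y, kz): Fourier transform of the stationary PSF.

    At y = 0 this equals the autocorrelation of the pupil field.
    """
    psf = excitation_psf(pupil_values, grids, config, y_nm).intensity
    otf = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(psf)))
    c = grids.n_k // 2
    dc = otf[c, c]
    if dc == 0:
        raise ValueError("empty pupil: OTF has zero DC")
    otf = otf / dc
    freq = np.fft.fftshift(np.fft.fftfreq(grids.n_k, d=grids.dx_nm))
    return OTFMap(values=otf, kx_axis_cycles=freq, kz_axis_cycles=freq.copy(),
                  y_offset_nm=y_nm)


def _active_columns(pupil_values: np.ndarray, rel_tol: float = 1e-12) -> np.ndarray:
    mags = np.abs(pupil_values)
    peak = mags.max()
    if peak == 0:
        raise ValueError("all-zero pupil")
    return np.flatnonzero(mags.max(axis=0) > rel_tol * peak)


def swept_sheet(
    pupil_values: np.ndarray,
    grids: GridSet,
    config: OpticalConfig,
    y_planes_nm: np.ndarray | None = None,
    n_z_out: int | None = None,
) -> SweptSheet:
    """Swept-sheet cross-section I(y, z) from a pupil field.

    ``I(y, z) = <|E(x, z; y)|^2>_x`` evaluated per pupil column (field
    synthesis).  ``n_z_out`` zero-pads the column spectra to sample ``z`` on a
    finer grid of spacing ``lambda_exc / (n_z_out * d_na)`` without changing
    the physics; default keeps the native focal grid.
    """
    v = np.asarray(pupil_values, dtype=complex)
    if y_planes_nm is None:
        y_planes_nm = grids.y_planes
    y_planes_nm = np.atleast_1d(np.asarray(y_planes_nm, dtype=float))
    n = grids.n_k
    n_out = int(n_z_out) if n_z_out else n
    if n_out < n or n_out % 2 == 0:
        raise ValueError("n_z_out must be odd and >= n_k")
    cols = _active_columns(v)
    na = grids.na_axis
    na_z = na
    intensity = np.zeros((len(y_planes_nm), n_out))
    pad_lo = (n_out - n) // 2
    dz = config.lambda_exc_nm / (n_out * grids.d_na)
    half = n_out // 2
    z_axis = (np.arange(n_out) - half) * dz
    # 1D propagator per column sample
    for iy, y in enumerate(y_planes_nm):
        spec = np.zeros((len(cols), n_out), dtype=complex)
        for j, c in enumerate(cols):
            col = v[:, c]
            if y != 0.0:
                ph = propagation_phase(na[c : c + 1], na_z, config, y)[:, 0]
                col = col * ph
            spec[j, pad_lo : pad_lo + n] = col
        fields = np.fft.ifft(np.fft.ifftshift(spec, axes=1), axis=1)
        fields = np.fft.fftshift(fields, axes=1) * (n_out / np.sqrt(n))
        intensity[iy] = (np.abs(fields) ** 2).sum(axis=0) / n
    return SweptSheet(intensity=intensity, y_planes_nm=y_planes_nm, z_axis_nm=z_axis)


def _detection_cap(config: OpticalConfig, n_xy: int, dx_nm: float):
    """Transverse detection pupil cap and axial wave number kz(kx, ky)."""
    fx = np.fft.fftfreq(n_xy, d=dx_nm)  # cycles/nm
    fxx, fyy = np.meshgrid(fx, fx, indexing="ij")
    frho_sq = fxx**2 + fyy**2
    na_cut = config.na_det / config.lambda_det_nm
    cap = frho_sq <= na_cut**2
    n_over_lam = config.n_medium / config.lambda_det_nm
    kz = np.zeros_like(frho_sq)
    inside = frho_sq < n_over_lam**2
    kz[inside] = 2.0 * np.pi * np.sqrt(n_over_lam**2 - frho_sq[inside])
    return cap.astype(complex), kz


def detection_psf_volume(
    config: OpticalConfig,
    shape: tuple[int, int, int],
    dx_nm: float,
    dz_nm: float,
    n_fov: int = 256,
) -> np.ndarray:
    """Scalar detection PSF volume PSF_det(x, y, z), unit sum.

    Computed by angular-spectrum defocus of the spherical-cap pupil on an
    ``n_fov``-wide transverse grid (to sample the pupil finely) and cropped to
    the requested transverse ``shape[:2]``; ``z`` (the detection axis) is
    centered on focus.
    """
    nx, ny, nz = shape
    n_fov = max(n_fov, nx, ny)
    cap, kz = _detection_cap(config, n_fov, dx_nm)
    z_axis = (np.arange(nz) - nz // 2) * dz_nm
    psf = np.empty((nx, ny, nz), dtype=np.float32)
    x0 = 0  # cap grid is in fft order; field comes out centered after shift
    for iz, z in enumerate(z_axis):
        field = np.fft.ifft2(cap * np.exp(1j * kz * z))
        inten = np.abs(np.fft.fftshift(field)) ** 2
        c = n_fov // 2
        crop = inten[c - nx // 2 : c - nx // 2 + nx, c - ny // 2 : c - ny // 2 + ny]
        psf[:, :, iz] = crop
    s = psf.sum()
    if s <= 0:
        raise ValueError("empty detection PSF")
    return psf / s


def detection_otf(
    config: OpticalConfig,
    n_xy: int = 129,
    dx_nm: float = 40.0,
    n_z: int | None = None,
    dz_nm: float | None = None,
    support_rel: float = 1e-3,
    z_window: bool = True,
) -> DetectionOTF:
    """k_y = 0 slice of the 3D scalar detection OTF.

    The slice equals ``FT_{x,z}`` of the y-integrated 3D PSF; it is computed
    by defocusing the cap over ``n_z`` z planes of spacing ``dz_nm`` (defaults
    match the transverse sampling), integrating the intensity over y, and
    transforming.  DC is normalized to 1.
    """
    if n_z is None:
        n_z = n_xy
    if dz_nm is None:
        dz_nm = dx_nm
    if n_xy % 2 == 0 or n_z % 2 == 0:
        raise ValueError("n_xy and n_z must be odd")
    cap, kz = _detection_cap(config, n_xy, dx_nm)
    z_axis = (np.arange(n_z) - n_z // 2) * dz_nm
    d_xz = np.empty((n_z, n_xy))
    for iz, z in enumerate(z_axis):
        field = np.fft.ifft2(cap * np.exp(1j * kz * z))
        d_xz[iz] = (np.abs(field) ** 2).sum(axis=1)  # integrate over y
    if z_window:
        # Hann apodization of the finite defocus range suppresses spectral
        # leakage from the slowly decaying defocus halo
        d_xz *= np.hanning(n_z)[:, np.newaxis]
    d_xz = np.fft.fftshift(d_xz, axes=1)
    otf = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(d_xz)))
    c_z, c_x = n_z // 2, n_xy // 2
    otf = otf / otf[c_z, c_x]
    kx_axis = np.fft.fftshift(np.fft.fftfreq(n_xy, d=dx_nm))
    kz_axis = np.fft.fftshift(np.fft.fftfreq(n_z, d=dz_nm))
    mask = np.abs(otf) > support_rel
    return DetectionOTF(
        slice_values=otf,
        kx_axis_cycles=kx_axis,
        kz_axis_cycles=kz_axis,
        support_mask=mask,
        config=config,
    )


def overall_swept_otf(
    sheet: SweptSheet, det: DetectionOTF, y_nm: float = 0.0
) -> OTFMap:
    """Swept overall OTF: 1D convolution along kz of the detection slice with
    the sheet's axial excitation OTF at offset y; DC normalized to 1."""
    if len(det.kz_axis_cycles) != len(sheet.z_axis_nm):
        raise ValueError("kz grids of detection OTF and sheet do not match")
    dz_det = det.kz_axis_cycles[1] - det.kz_axis_cycles[0]
    dz_sheet = sheet.kz_axis_cycles[1] - sheet.kz_axis_cycles[0]
    if not np.isclose(dz_det, dz_sheet, rtol=1e-9):
        raise ValueError("kz sample spacing mismatch between detection and sheet")
    iy = int(np.argmin(np.abs(sheet.y_planes_nm - y_nm)))
    prof = sheet.intensity[iy]
    prof = prof / prof.sum()  # unit-DC excitation kernel
    det_real = np.fft.ifft(np.fft.ifftshift(det.slice_values, axes=0), axis=0)
    mixed = det_real * np.fft.ifftshift(prof)[:, np.newaxis]
    otf = np.fft.fftshift(np.fft.fft(mixed, axis=0), axes=0)
    c_z = len(sheet.z_axis_nm) // 2
    c_x = len(det.kx_axis_cycles) // 2
    otf = otf / otf[c_z, c_x]
    return OTFMap(
        values=otf,
        kx_axis_cycles=det.kx_axis_cycles,
        kz_axis_cycles=np.asarray(det.kz_axis_cycles),
        y_offset_nm=float(sheet.y_planes_nm[iy]),
    )


def overall_psf(sheet_iyz: np.ndarray, det_psf: np.ndarray) -> np.ndarray:
    """Overall swept PSF: product of the sheet cross-section with the
    detection PSF, normalized to unit sum.

    ``sheet_iyz`` has shape (ny, nz) on the same (y, z) grid as the detection
    volume ``det_psf`` of shape (nx, ny, nz).
    """
    if sheet_iyz.shape != det_psf.shape[1:]:
        raise ValueError(
            f"sheet grid {sheet_iyz.shape} does not match PSF volume "
            f"{det_psf.shape[1:]}"
        )
    psf = det_psf * sheet_iyz[np.newaxis, :, :]
    s = psf.sum()
    if s <= 0:
        raise ValueError("overall PSF has zero power")
    return psf / s


_LATTICE_MAX_KX = {
    "axial_sw": 0.0,
    "square": 2.0,
    "hexagonal": np.sqrt(3.0),
}


def sim_support(symmetry: str, na_exc: float, config: OpticalConfig) -> dict:
    """Support radii of the coherent structured-illumination (SIM) mode.

    Lateral SIM support = detection lateral support + largest lateral lattice
    harmonic (sqrt(3) k_o NA_exc for hexagonal, 2 k_o NA_exc for square);
    axial support equals the swept-mode value.  The aperiodic hexrect pattern
    cannot be used for coherent SIM and is rejected.
    """
    if symmetry == "hexrect":
        raise ValueError(
            "the hexrect pattern is aperiodic and cannot be applied to coherent SIM"
        )
    if symmetry not in _LATTICE_MAX_KX:
        raise ValueError(f"unknown lattice symmetry: {symmetry!r}")
    lateral_det = 2.0 * config.na_det / config.lambda_det_nm
    lateral_harm = _LATTICE_MAX_KX[symmetry] * na_exc / config.lambda_exc_nm
    lateral_support = lateral_det + lateral_harm
    axial_support = 2.0 * na_exc / config.lambda_exc_nm + (
        config.n_medium - np.sqrt(config.n_medium**2 - config.na_det**2)
    ) / config.lambda_det_nm
    return {
        "lateral_support_cycles": lateral_support,
        "lateral_resolution_nm": 1.0 / lateral_support,
        "axial_support_cycles": axial_support,
        "axial_resolution_nm": 1.0 / axial_support,
    }
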