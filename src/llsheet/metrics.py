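"""Quantitative light-sheet characterization.

Closed-form resolution limits (reciprocal OTF support radii), propagation
lengths, the OTF gap/discontinuity criterion, excitation-confinement curves
and OTF linecuts.  Resolution here means the support limit of linear
deconvolution; practical resolvability under noise is measured by the stripe
benchmark in :mod:`llsheet.pipeline`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import OpticalConfig
from .propagation import OTFMap, SweptSheet, sim_support

__all__ = [
    "ResolutionReport",
    "ConfinementCurve",
    "y_fwhm",
    "beamlet_length",
    "resolution_limits",
    "widefield_axial_resolution",
    "gap_criterion",
    "cumulative_intensity",
    "specimen_projection",
    "support_radius_numeric",
    "otf_linecuts",
]


@dataclass
class ResolutionReport:
    """Support-limited resolutions (nm) of one light sheet, optical frame
    plus tilt-projected specimen frame."""

    r_x_swept_nm: float
    r_z_axis_nm: float  # along the detection axis (k_x = 0)
    r_z_max_nm: float  # at the bowtie offset (highest axial resolution)
    na_exc_max: float
    r_x_sim_nm: float | None = None
    r_x_specimen_nm: float | None = None
    r_z_specimen_nm: float | None = None

    def __post_init__(self) -> None:
        if self.r_z_max_nm > self.r_z_axis_nm + 1e-9:
            raise ValueError("r_z_max must not exceed r_z_axis")


@dataclass
class ConfinementCurve:
    """Cumulative excitation fraction within +-z of the sheet center."""

    z_grid_nm: np.ndarray
    cumulative: np.ndarray
    y_offset_nm: float

    def fraction_within(self, z_nm: float) -> float:
        return float(np.interp(z_nm, self.z_grid_nm, self.cumulative))


def y_fwhm(sheet: SweptSheet) -> float:
    """Full width at half maximum of I(y, z=0), by linear interpolation.

    Raises if the on-axis profile never drops below half its maximum within
    the simulated y range.
    """
    prof = sheet.intensity[:, sheet.intensity.shape[1] // 2].astype(float)
    y = sheet.y_planes_nm
    i_pk = int(np.argmax(prof))
    half = 0.5 * prof[i_pk]

    def crossing(idx_range) -> float | None:
        prev = None
        for i in idx_range:
            if prof[i] < half:
                lo, hi = (i, prev) if prev is not None else (i, i)
                frac = (half - prof[lo]) / (prof[hi] - prof[lo])
                return float(y[lo] + frac * (y[hi] - y[lo]))
            prev = i
        return None

    right = crossing(range(i_pk + 1, len(prof)))
    left = crossing(range(i_pk - 1, -1, -1))
    if right is None and left is None:
        raise ValueError(
            "I(y,0) never falls below half maximum in the simulated range "
            "(sheet effectively propagation-invariant here)"
        )
    if right is not None and left is not None:
        return right - left
    if right is not None:
        return 2.0 * (right - float(y[i_pk]))
    return 2.0 * (float(y[i_pk]) - left)


def beamlet_length(na_minus: float, na_plus: float, config: OpticalConfig) -> float:
    """Propagation length (y_FWHM)_b of a pupil beamlet spanning radial NA
    bounds [na_minus, na_plus]:
    ``lambda_exc / (2 n [sqrt(1-(NA-/n)^2) - sqrt(1-(NA+/n)^2)])`` (nm)."""
    n = config.n_medium
    if not (0 <= na_minus < na_plus < n):
        raise ValueError(f"need 0 <= na_minus < na_plus < n={n}")
    f_lo = np.sqrt(1.0 - (na_minus / n) ** 2)
    f_hi = np.sqrt(1.0 - (na_plus / n) ** 2)
    return config.lambda_exc_nm / (2.0 * n * (f_lo - f_hi))


def widefield_axial_resolution(na: float, lambda_det_nm: float, n_medium: float) -> float:
    """Maximum axial resolution of a widefield microscope:
    ``lambda_det / (n - sqrt(n^2 - NA^2))`` (nm)."""
    if not (0 < na < n_medium):
        raise ValueError("need 0 < NA < n")
    return lambda_det_nm / (n_medium - np.sqrt(n_medium**2 - na**2))


def _bowtie_term(config: OpticalConfig) -> float:
    """Maximum axial half-support of the detection bowtie (cycles/nm)."""
    c = config
    return (c.n_medium - np.sqrt(c.n_medium**2 - c.na_det**2)) / c.lambda_det_nm


def resolution_limits(
    na_exc_max: float,
    config: OpticalConfig,
    symmetry: str | None = None,
    project_to_specimen: bool = True,
) -> ResolutionReport:
    """Closed-form support-limited resolutions for a sheet whose excitation
    reaches an effective maximum NA of ``na_exc_max``.

    * lateral swept: ``lambda_det / (2 NA_det)``
    * axial on-axis: ``lambda_exc / (2 NA_exc_max)``
    * axial at the bowtie offset:
      ``1 / (2 NA_exc_max/lambda_exc + (n - sqrt(n^2-NA_det^2))/lambda_det)``
    * lateral SIM (periodic lattices only): via :func:`sim_support`.
    """
    if na_exc_max > config.na_exc_obj + 1e-9:
        raise ValueError("na_exc_max exceeds the excitation objective NA")
    r_x = config.lambda_det_nm / (2.0 * config.na_det)
    r_z_axis = config.lambda_exc_nm / (2.0 * na_exc_max)
    r_z_max = 1.0 / (
        2.0 * na_exc_max / config.lambda_exc_nm + _bowtie_term(config)
    )
    r_x_sim = None
    if symmetry in ("square", "hexagonal"):
        r_x_sim = sim_support(symmetry, na_exc_max, config)["lateral_resolution_nm"]
    report = ResolutionReport(
        r_x_swept_nm=r_x,
        r_z_axis_nm=r_z_axis,
        r_z_max_nm=r_z_max,
        na_exc_max=na_exc_max,
        r_x_sim_nm=r_x_sim,
    )
    if project_to_specimen:
        rx_sp, rz_sp = specimen_projection(report, config.tilt_alpha_deg)
        report.r_x_specimen_nm = rx_sp
        report.r_z_specimen_nm = rz_sp
    return report


def gap_criterion(na_exc: float, config: OpticalConfig) -> tuple[bool, float]:
    """Whether the overall swept OTF of an axial-SW/square sheet at ``na_exc``
    is discontinuous, plus the threshold NA.

    The shifted detection copies at +-2 k_o NA_exc separate from the DC copy
    once the shift exceeds the bowtie's maximum axial width, i.e. for
    ``NA_exc > (lambda_exc/lambda_det)(n - sqrt(n^2 - NA_det^2))``.
    """
    c = config
    threshold = (c.lambda_exc_nm / c.lambda_det_nm) * (
        c.n_medium - np.sqrt(c.n_medium**2 - c.na_det**2)
    )
    return bool(na_exc > threshold), float(threshold)


def cumulative_intensity(sheet: SweptSheet, y_nm: float = 0.0) -> ConfinementCurve:
    """Cumulative excitation fraction C(z) = int_{-z}^{z} I dz' / int I dz'
    at the y plane nearest ``y_nm``."""
    iy = int(np.argmin(np.abs(sheet.y_planes_nm - y_nm)))
    prof = sheet.intensity[iy]
    total = prof.sum()
    if total <= 0:
        raise ValueError("zero total intensity at this y plane")
    n = len(prof)
    center = n // 2
    half_extent = min(center, n - 1 - center)
    # pixel sums reach the pixel edge at (j + 1/2) dz; C(0) = 0
    z = np.concatenate([[0.0], (np.arange(half_extent + 1) + 0.5) * sheet.dz_nm])
    cum = np.empty(half_extent + 2)
    cum[0] = 0.0
    cum[1] = prof[center]
    for j in range(1, half_extent + 1):
        cum[j + 1] = cum[j] + prof[center - j] + prof[center + j]
    return ConfinementCurve(
        z_grid_nm=z, cumulative=cum / total, y_offset_nm=float(sheet.y_planes_nm[iy])
    )


def support_radius_numeric(
    otf: OTFMap, direction_deg: float, threshold: float = 1e-3
) -> float:
    """Support radius of |OTF| along a direction in the (k_x, k_z) plane
    (degrees from +k_x toward +k_z), by dense sampling along the ray."""
    th = np.deg2rad(direction_deg)
    kx_max = otf.kx_axis_cycles[-1]
    kz_max = otf.kz_axis_cycles[-1]
    r_max = min(
        kx_max / abs(np.cos(th)) if abs(np.cos(th)) > 1e-12 else np.inf,
        kz_max / abs(np.sin(th)) if abs(np.sin(th)) > 1e-12 else np.inf,
    )
    r = np.linspace(0.0, r_max, 2048)
    kx = r * np.cos(th)
    kz = r * np.sin(th)
    mag = np.abs(otf.values)
    # bilinear sample
    fx = np.interp(kx, otf.kx_axis_cycles, np.arange(len(otf.kx_axis_cycles)))
    fz = np.interp(kz, otf.kz_axis_cycles, np.arange(len(otf.kz_axis_cycles)))
    ix, iz = np.floor(fx).astype(int), np.floor(fz).astype(int)
    ix1 = np.minimum(ix + 1, len(otf.kx_axis_cycles) - 1)
    iz1 = np.minimum(iz + 1, len(otf.kz_axis_cycles) - 1)
    wx, wz = fx - ix, fz - iz
    vals = (
        mag[iz, ix] * (1 - wx) * (1 - wz)
        + mag[iz, ix1] * wx * (1 - wz)
        + mag[iz1, ix] * (1 - wx) * wz
        + mag[iz1, ix1] * wx * wz
    )
    above = np.flatnonzero(vals > threshold)
    if above.size == 0:
        return 0.0
    return float(r[above[-1]])


def specimen_projection(
    report_or_support, tilt_alpha_deg: float, threshold: float = 1e-3
):
    """Resolutions along the specimen-frame x/z axes for objectives tilted by
    ``alpha`` in the xz plane.

    Accepts either a :class:`ResolutionReport` (an elliptical proxy support
    built from its lateral/axial radii is scanned) or an :class:`OTFMap`
    (support measured numerically).  Returns ``(R_x_specimen, R_z_specimen)``
    in nm: the reciprocal support radii along the rotated axes.
    """
    if isinstance(report_or_support, OTFMap):
        rx = support_radius_numeric(report_or_support, tilt_alpha_deg, threshold)
        rz = support_radius_numeric(report_or_support, 90.0 + tilt_alpha_deg, threshold)
        return 1.0 / rx, 1.0 / rz
    report = report_or_support
    a = 1.0 / report.r_x_swept_nm  # lateral support radius (cycles/nm)
    b = 1.0 / report.r_z_max_nm  # maximal axial support radius
    th = np.deg2rad(tilt_alpha_deg)

    def ellipse_radius(angle: float) -> float:
        return 1.0 / np.sqrt(
            (np.cos(angle) / a) ** 2 + (np.sin(angle) / b) ** 2
        )

    return 1.0 / ellipse_radius(th), 1.0 / ellipse_radius(th + np.pi / 2.0)


def otf_linecuts(otf: OTFMap, config: OpticalConfig) -> dict[str, np.ndarray]:
    """|OTF| along k_x = 0, along k_z = 0, and along the line
    ``k_x = NA_det/lambda_det`` (half the maximal lateral support), the axis
    where the widefield microscope has its highest axial resolution."""
    mag = np.abs(otf.values)
    kx_half = config.na_det / config.lambda_det_nm
    i_half = int(np.argmin(np.abs(otf.kx_axis_cycles - kx_half)))
    return {
        "kx0": mag[:, len(otf.kx_axis_cycles) // 2],
        "kz0": mag[len(otf.kz_axis_cycles) // 2, :],
        "kx_half_support": mag[:, i_half],
        "kz_axis_cycles": otf.kz_axis_cycles,
        "kx_axis_cycles": otf.kx_axis_cycles,
    }
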