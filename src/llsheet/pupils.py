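"""Ideal pupil fields for every light-sheet family.

Families
--------
``gaussian``
    One or two vertical pupil lines with a Gaussian ``k_z`` profile; the
    two-line variant realizes the sheet as a lateral standing wave that the
    annular mask does not clip.
``sinc``
    Uniform (rect) ``k_z`` profile of half-width ``NA_sinc``; the swept focal
    intensity is ``sinc^2(k_o NA_sinc z)`` and the axial OTF a triangle.
``bessel``
    Constant annulus between ``NA_min`` and ``NA_max``.
``mb`` (multi-Bessel)
    A coherent periodic array of annulus-bound Bessel beams: ``2M + 1``
    uniform vertical lines of period ``k_x = 2*pi/T`` cropped by the annulus.
    At special periods the array equals a bound 2D optical lattice.
``ac`` (axially confined)
    An ideal lattice whose discrete pupil points are replaced by identical
    Gaussian stripes along ``k_z`` (equal bounding of every plane wave).
``hb`` (harmonic balanced)
    Gaussian beamlets whose widths equalize per-beamlet propagation length
    (``sigma_b = sigma_ref / |c_b|``) and whose amplitudes equalize the focal
    beam amplitudes (``E_b = |c_b| * E_ref``), so that all nonzero axial OTF
    harmonics are equally strong and stay so along the propagation range.
``cs`` (cosine-sinc)
    The field-synthesis realization of an MB sheet: the swept axial profile
    is the incoherent band sum of ``cos^2 * sinc^2`` terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import GridSet, OpticalConfig
from .propagation import SweptSheet, swept_sheet

__all__ = [
    "SheetSpec",
    "Beamlet",
    "PupilField",
    "lattice_wavevectors",
    "gaussian_pupil",
    "sinc_pupil",
    "bessel_pupil",
    "mb_pupil",
    "mb_period",
    "ac_pupil",
    "hb_design",
    "cs_bands",
    "cs_axial_profile",
    "build_pupil",
]

FAMILIES = ("gaussian", "sinc", "bessel", "mb", "ac", "hb", "cs")
SYMMETRIES = ("axial_sw", "square", "hexagonal", "hexrect", "none")


@dataclass(frozen=True)
class SheetSpec:
    """Parameters selecting and sizing one light-sheet family."""

    family: str
    symmetry: str = "none"
    na_exc: float = 0.0  # lattice ring NA
    na_min: float = 0.0  # annulus inner bound (NA units)
    na_max: float = 0.0  # annulus outer bound
    w0_nm: float = 0.0  # Gaussian waist (gaussian family)
    na_sinc: float = 0.0  # sinc half-bandwidth
    sigma_na: float = 0.0  # reference beamlet 1/e field half-width (ac/hb)
    epsilon: float = 0.0  # SLM cropping factor
    x_offset_na: float = 0.0  # lateral pupil offset (standing-wave lines)
    T_override_nm: float = 0.0  # explicit MB period

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.symmetry not in SYMMETRIES:
            raise ValueError(f"unknown symmetry {self.symmetry!r}")
        if not (0 <= self.epsilon < 1):
            raise ValueError("epsilon must lie in [0, 1)")
        if self.na_min < 0 or (self.na_max and self.na_max <= self.na_min):
            raise ValueError("need 0 <= na_min < na_max")
        if self.family in ("ac", "hb") and self.sigma_na <= 0:
            raise ValueError(f"{self.family} family requires sigma_na > 0")
        if self.family in ("mb", "ac", "hb", "cs") and self.symmetry == "none":
            if not (self.family == "mb" and self.T_override_nm > 0):
                raise ValueError(f"{self.family} family requires a lattice symmetry")


@dataclass(frozen=True)
class Beamlet:
    """One vertical pupil stripe tied to a plane wave of the ideal lattice."""

    s_b: float  # lateral direction cosine (k_x component / k_o NA_exc)
    c_b: float  # axial direction cosine (signed)
    center_na: tuple[float, float]  # (NA_x, NA_z)
    sigma_b: float = 0.0  # 1/e field half-width in the pupil (NA units)
    amplitude: float = 1.0
    na_minus: float = 0.0  # effective radial NA bounds (Eq.-15 inputs)
    na_plus: float = 0.0


@dataclass
class PupilField:
    """Complex pupil amplitude plus its provenance."""

    values: np.ndarray
    spec: SheetSpec
    grids: GridSet
    beamlets: list[Beamlet] = field(default_factory=list)


def lattice_wavevectors(symmetry: str, na_exc: float) -> np.ndarray:
    """Unit direction cosines (s_b, c_b) of the ideal-lattice plane waves.

    All points lie on the pupil ring of radius ``na_exc``; the returned array
    has shape (B, 2) and actual pupil positions are ``na_exc * (s_b, c_b)``.
    axial_sw -> 2 polar points; square -> polar + equatorial pairs;
    hexagonal -> 6 points (polar pair + 4 at c = +-1/2); hexrect ->
    hexagonal + 8 points at c = +-1/4 and +-3/4.
    """
    if na_exc <= 0:
        raise ValueError("na_exc must be positive")
    if symmetry == "axial_sw":
        cz = [1.0, -1.0]
        dirs = [(0.0, c) for c in cz]
    elif symmetry == "square":
        dirs = [(0.0, 1.0), (0.0, -1.0), (1.0, 0.0), (-1.0, 0.0)]
    elif symmetry in ("hexagonal", "hexrect"):
        dirs = [(0.0, 1.0), (0.0, -1.0)]
        for cz in (0.5, -0.5):
            s = np.sqrt(1.0 - cz**2)
            dirs += [(s, cz), (-s, cz)]
        if symmetry == "hexrect":
            for cz_mag in (0.25, 0.75):
                s = np.sqrt(1.0 - cz_mag**2)
                for cz in (cz_mag, -cz_mag):
                    dirs += [(s, cz), (-s, cz)]
    else:
        raise ValueError(f"unknown lattice symmetry {symmetry!r}")
    return np.array(dirs, dtype=float)


def _nearest_col(grids: GridSet, na_x: float) -> int:
    return int(np.argmin(np.abs(grids.na_axis - na_x)))


def _line_columns(spec: SheetSpec, grids: GridSet) -> list[int]:
    """Column indices of the one or two vertical excitation lines."""
    if spec.x_offset_na == 0.0:
        if spec.na_min > 0:
            warnings.warn(
                "centered excitation line is clipped by the annulus "
                "(x_offset_na <= na_min)",
                stacklevel=3,
            )
        return [_nearest_col(grids, 0.0)]
    if spec.x_offset_na <= spec.na_min:
        warnings.warn(
            "x_offset_na <= na_min: the offset lines are clipped by the annulus",
            stacklevel=3,
        )
    return [_nearest_col(grids, +spec.x_offset_na), _nearest_col(grids, -spec.x_offset_na)]


def gaussian_pupil(spec: SheetSpec, grids: GridSet, config: OpticalConfig) -> PupilField:
    """Gaussian-sheet pupil: vertical line(s) with profile exp(-(k_z w0)^2/4).

    With ``x_offset_na = 0`` this is the single ideal line; a nonzero offset
    places two lines at +-x_offset_na, realizing the sheet as a standing wave
    whose swept profile is identical to the 1D sheet's.
    """
    if spec.family != "gaussian":
        raise ValueError("spec.family must be 'gaussian'")
    if spec.w0_nm <= 0:
        raise ValueError("gaussian family requires w0_nm > 0")
    na = grids.na_axis
    kz = config.k_o * na  # rad/nm
    profile = np.exp(-0.25 * (kz * spec.w0_nm) ** 2)
    values = np.zeros((grids.n_k, grids.n_k), dtype=complex)
    for c in _line_columns(spec, grids):
        col_profile = profile.copy()
        # truncate the (negligible) tail beyond the propagating circle
        col_profile[np.hypot(na[c], na) >= config.n_medium] = 0.0
        values[:, c] += col_profile
    return PupilField(values=values, spec=spec, grids=grids)


def sinc_pupil(spec: SheetSpec, grids: GridSet, config: OpticalConfig) -> PupilField:
    """Sinc-sheet pupil: uniform line(s) over |NA_z| <= NA_sinc."""
    if spec.family != "sinc":
        raise ValueError("spec.family must be 'sinc'")
    if not (0 < spec.na_sinc <= config.na_exc_obj):
        raise ValueError(
            f"na_sinc must lie in (0, na_exc_obj={config.na_exc_obj}]"
        )
    na = grids.na_axis
    profile = (np.abs(na) <= spec.na_sinc).astype(complex)
    values = np.zeros((grids.n_k, grids.n_k), dtype=complex)
    for c in _line_columns(spec, grids):
        values[:, c] += profile
    return PupilField(values=values, spec=spec, grids=grids)


def bessel_pupil(spec: SheetSpec, grids: GridSet, config: OpticalConfig) -> PupilField:
    """Annular pupil of constant amplitude between NA_min and NA_max."""
    if spec.family != "bessel":
        raise ValueError("spec.family must be 'bessel'")
    na = grids.na_axis
    rho = np.sqrt(na[np.newaxis, :] ** 2 + na[:, np.newaxis] ** 2)
    mask = (rho >= spec.na_min) & (rho <= spec.na_max)
    if not mask.any():
        raise ValueError("empty annulus on this grid")
    return PupilField(values=mask.astype(complex), spec=spec, grids=grids)


def mb_period(symmetry: str, na_exc: float, lambda_exc_nm: float) -> float:
    """Lattice-equivalent MB period T for a given symmetry.

    axial_sw uses any sub-diffractive period (T < lambda/NA_exc; half of it is
    returned so only the m = 0 band survives); square uses T = lambda/NA_exc;
    hexagonal T = (2/sqrt(3)) lambda/NA_exc (ring geometry: the flanking
    lattice points sit at k_x = +-(sqrt(3)/2) k_o NA_exc).
    """
    base = lambda_exc_nm / na_exc
    if symmetry == "axial_sw":
        return 0.5 * base
    if symmetry == "square":
        return base
    if symmetry == "hexagonal":
        return 2.0 / np.sqrt(3.0) * base
    raise ValueError(f"no MB period for symmetry {symmetry!r}")


def mb_pupil(
    spec: SheetSpec,
    grids: GridSet,
    config: OpticalConfig,
    max_bands: int = 25,
) -> PupilField:
    """Multi-Bessel pupil: uniform vertical lines of period k_x = 2*pi/T
    cropped by the [NA_min, NA_max] annulus.

    Bands are placed at NA_x = m*lambda/T for every integer m whose line
    still intersects the annulus (|m| lambda/T <= NA_max).
    """
    if spec.family != "mb":
        raise ValueError("spec.family must be 'mb'")
    if spec.na_max <= 0:
        raise ValueError("mb family requires an annulus")
    T = spec.T_override_nm or mb_period(spec.symmetry, spec.na_exc, config.lambda_exc_nm)
    band_step = config.lambda_exc_nm / T  # NA units between bands
    m_max = int(np.floor(spec.na_max / band_step))
    if m_max > max_bands:
        raise ValueError(
            f"period T={T:.1f} nm yields {2 * m_max + 1} bands "
            f"(> cap {2 * max_bands + 1}); raise max_bands or shrink T"
        )
    na = grids.na_axis
    values = np.zeros((grids.n_k, grids.n_k), dtype=complex)
    beamlets: list[Beamlet] = []
    for m in range(-m_max, m_max + 1):
        na_x = m * band_step
        col = _nearest_col(grids, na_x)
        na_x_snap = na[col]
        rho = np.sqrt(na_x_snap**2 + na**2)
        seg = (rho >= spec.na_min) & (rho <= spec.na_max)
        if not seg.any():
            continue
        values[seg, col] = 1.0
        # one Beamlet record per contiguous kz segment
        edges = np.flatnonzero(np.diff(seg.astype(int)))
        bounds = np.concatenate([[0], edges + 1, [grids.n_k]])
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            if not seg[lo]:
                continue
            z_lo, z_hi = na[lo], na[hi - 1]
            crosses_equator = z_lo <= 0 <= z_hi
            na_minus = abs(na_x_snap) if crosses_equator else float(
                np.sqrt(na_x_snap**2 + min(abs(z_lo), abs(z_hi)) ** 2)
            )
            na_minus = max(na_minus, spec.na_min) if not crosses_equator else na_minus
            na_plus = float(np.sqrt(na_x_snap**2 + max(abs(z_lo), abs(z_hi)) ** 2))
            zc = 0.5 * (z_lo + z_hi)
            r = np.hypot(na_x_snap, zc) or 1.0
            beamlets.append(
                Beamlet(
                    s_b=na_x_snap / r,
                    c_b=zc / r,
                    center_na=(float(na_x_snap), float(zc)),
                    amplitude=1.0,
                    na_minus=na_minus,
                    na_plus=na_plus,
                )
            )
    if not np.any(values):
        raise ValueError("no MB band intersects the annulus")
    return PupilField(values=values, spec=spec, grids=grids, beamlets=beamlets)


def ac_pupil(spec: SheetSpec, grids: GridSet, config: OpticalConfig) -> PupilField:
    """Axially confined lattice pupil: each ideal-lattice point becomes a
    Gaussian stripe exp(-(dNA_z/sigma_na)^2) of identical width and amplitude
    (equal bounding of every plane wave)."""
    if spec.family != "ac":
        raise ValueError("spec.family must be 'ac'")
    dirs = lattice_wavevectors(spec.symmetry, spec.na_exc)
    na = grids.na_axis
    values = np.zeros((grids.n_k, grids.n_k), dtype=complex)
    beamlets: list[Beamlet] = []
    for s, c in dirs:
        na_x, na_z = s * spec.na_exc, c * spec.na_exc
        outer = np.hypot(na_x, abs(na_z) + 3.0 * spec.sigma_na)
        if outer >= config.n_medium:
            raise ValueError(
                f"stripe at ({na_x:.3f}, {na_z:.3f}) extends past the "
                f"propagating circle NA = n = {config.n_medium}"
            )
        col = _nearest_col(grids, na_x)
        profile = np.exp(-((na - na_z) / spec.sigma_na) ** 2)
        values[:, col] += profile
        if c == 0.0:
            # equatorial stripe crosses NA_z = 0: the inner bound is the NA
            # at the crossing point
            na_minus = spec.na_exc
            na_plus = float(np.hypot(spec.na_exc, spec.sigma_na))
        else:
            na_minus = _beamlet_na_bound(spec.na_exc, abs(c), spec.sigma_na, -1)
            na_plus = _beamlet_na_bound(spec.na_exc, abs(c), spec.sigma_na, +1)
        beamlets.append(
            Beamlet(
                s_b=float(s),
                c_b=float(c),
                center_na=(float(na[col]), float(na_z)),
                sigma_b=spec.sigma_na,
                amplitude=1.0,
                na_minus=na_minus,
                na_plus=na_plus,
            )
        )
    return PupilField(values=values, spec=spec, grids=grids, beamlets=beamlets)


def _beamlet_na_bound(na_exc: float, c_abs: float, sigma_b: float, sign: int) -> float:
    """Radial NA at the 1/e field points of a Gaussian beamlet on the ring."""
    val = na_exc**2 + sign * 2.0 * na_exc * c_abs * sigma_b + sigma_b**2
    return float(np.sqrt(max(val, 0.0)))


def _hb_beamlets(
    symmetry: str, na_exc: float, sigma_ref: float
) -> list[Beamlet]:
    dirs = lattice_wavevectors(symmetry, na_exc)
    out = []
    for s, c in dirs:
        c_abs = abs(c)
        if c_abs == 0:
            raise ValueError("harmonic balancing excludes equatorial beamlets")
        sigma_b = sigma_ref / c_abs
        if c_abs * na_exc <= 0.5 * sigma_b:
            raise ValueError(
                f"beamlet at c_b={c:+.2f} (sigma_b={sigma_b:.3f}) is centered "
                "essentially on the equatorial line NA_z = 0; shorten y_FWHM "
                "or lower NA_exc"
            )
        if c_abs * na_exc <= 2.0 * sigma_b:
            warnings.warn(
                f"beamlets at c_b=+-{c_abs:.2f} merge across NA_z = 0 into "
                "longer quasi-DC bands (width within 2 sigma of the equator)",
                stacklevel=3,
            )
        out.append(
            Beamlet(
                s_b=float(s),
                c_b=float(c),
                center_na=(float(s * na_exc), float(c * na_exc)),
                sigma_b=sigma_b,
                amplitude=c_abs,
                na_minus=_beamlet_na_bound(na_exc, c_abs, sigma_b, -1),
                na_plus=_beamlet_na_bound(na_exc, c_abs, sigma_b, +1),
            )
        )
    return out


def _beamlets_to_pupil(
    beamlets: list[Beamlet], spec: SheetSpec, grids: GridSet
) -> PupilField:
    na = grids.na_axis
    values = np.zeros((grids.n_k, grids.n_k), dtype=complex)
    for b in beamlets:
        col = _nearest_col(grids, b.center_na[0])
        values[:, col] += b.amplitude * np.exp(
            -(((na - b.center_na[1]) / b.sigma_b) ** 2)
        )
    if spec.na_max > 0:
        rho = np.sqrt(na[np.newaxis, :] ** 2 + na[:, np.newaxis] ** 2)
        values[(rho < spec.na_min) | (rho > spec.na_max)] = 0.0
    return PupilField(values=values, spec=spec, grids=grids, beamlets=beamlets)


def _measure_y_fwhm(
    pupil: PupilField, config: OpticalConfig, y_probe_nm: float
) -> float:
    """FWHM along y of I(y, z=0), scanning out to +-y_probe_nm."""
    y = np.linspace(0.0, y_probe_nm, 161)
    sheet = swept_sheet(pupil.values, pupil.grids, config, y_planes_nm=y)
    prof = sheet.intensity[:, sheet.intensity.shape[1] // 2]
    prof = prof / prof[0]
    below = np.flatnonzero(prof < 0.5)
    if below.size == 0:
        raise ValueError("I(y,0) does not fall below half within the probe range")
    j = below[0]
    # linear interpolation of the half crossing; symmetric sheet -> FWHM = 2y
    y_half = np.interp(0.5, prof[j : j - 2 : -1], y[j : j - 2 : -1])
    return 2.0 * float(y_half)


def hb_design(
    symmetry: str,
    na_exc: float,
    y_fwhm_target_nm: float,
    config: OpticalConfig,
    grids: GridSet,
    epsilon: float = 0.0,
    na_min: float = 0.0,
    na_max: float = 0.0,
    tol_nm: float | None = None,
    max_iter: int = 60,
) -> tuple[SheetSpec, PupilField, list[Beamlet]]:
    """Design a harmonic-balanced lattice sheet of a requested length.

    Beamlet widths are slaved to a polar reference (``sigma_b =
    sigma_ref/|c_b|``, equal propagation length) and amplitudes to the focal
    field (``E_b = |c_b| E_ref``, equal harmonic strength); ``sigma_ref`` is
    initialized from the thin-annulus estimate
    ``(n^2 - NA^2)/(4 NA) * lambda/y_FWHM`` and then tuned by deterministic
    bisection against the simulated sheet length until the measured
    ``y_FWHM`` is within ``tol_nm`` (default 0.5 lambda_exc/n) of the target.
    """
    if symmetry not in ("axial_sw", "hexagonal", "hexrect"):
        raise ValueError(
            "harmonic balancing applies to axial_sw, hexagonal or hexrect "
            "lattices (the square lattice is excluded)"
        )
    if tol_nm is None:
        tol_nm = 0.5 * config.lambda_medium_nm
    n, lam = config.n_medium, config.lambda_exc_nm
    sigma0 = (n**2 - na_exc**2) / (4.0 * na_exc) * lam / y_fwhm_target_nm
    lo, hi = sigma0 / 5.0, sigma0 * 5.0
    y_probe = 2.5 * y_fwhm_target_nm

    def measure(sig: float) -> float:
        spec = SheetSpec(
            family="hb", symmetry=symmetry, na_exc=na_exc, sigma_na=sig,
            epsilon=epsilon, na_min=na_min, na_max=na_max,
        )
        pupil = _beamlets_to_pupil(_hb_beamlets(symmetry, na_exc, sig), spec, grids)
        return _measure_y_fwhm(pupil, config, y_probe)

    def measure_or_inf(sig: float) -> float:
        try:
            return measure(sig)
        except ValueError:
            return np.inf  # sheet longer than the probe range

    # y_FWHM is monotone decreasing in sigma_ref
    y_lo, y_hi = measure_or_inf(lo), measure_or_inf(hi)
    if not (y_hi <= y_fwhm_target_nm <= y_lo):
        raise RuntimeError(
            f"target y_FWHM={y_fwhm_target_nm:.0f} nm not bracketed by "
            f"sigma in [{lo:.4f}, {hi:.4f}] (y in [{y_hi:.0f}, {y_lo:.0f}] nm)"
        )
    sig = sigma0
    for _ in range(max_iter):
        y_mid = measure(sig)
        if abs(y_mid - y_fwhm_target_nm) < tol_nm:
            break
        if y_mid > y_fwhm_target_nm:
            lo = sig
        else:
            hi = sig
        sig = 0.5 * (lo + hi)
    else:
        raise RuntimeError(
            f"harmonic-balance tuning did not converge in {max_iter} iterations"
        )
    spec = SheetSpec(
        family="hb", symmetry=symmetry, na_exc=na_exc, sigma_na=sig,
        epsilon=epsilon, na_min=na_min, na_max=na_max,
    )
    beamlets = _hb_beamlets(symmetry, na_exc, sig)
    pupil = _beamlets_to_pupil(beamlets, spec, grids)
    return spec, pupil, beamlets


def cs_bands(
    spec: SheetSpec, config: OpticalConfig, grids: GridSet | None = None
) -> list[dict]:
    """Annulus-cropped band extents for the cosine-sinc profile.

    For each surviving band m the record holds the NA_z midpoint and range of
    its segments plus the relative weight of its swept contribution.  With
    ``grids`` given, the extents are quantized to the pupil sample edges of
    the matching multi-Bessel pupil, so the analytic profile matches the
    numerically swept discrete pupil to high accuracy.
    """
    if spec.family != "cs":
        raise ValueError("spec.family must be 'cs'")
    if spec.na_max <= 0:
        raise ValueError("cs family requires an annulus")
    if grids is not None:
        return _cs_bands_snapped(spec, config, grids)
    T = spec.T_override_nm or mb_period(spec.symmetry, spec.na_exc, config.lambda_exc_nm)
    band_step = config.lambda_exc_nm / T
    m_max = int(np.floor(spec.na_max / band_step))
    bands = []
    for m in range(-m_max, m_max + 1):
        na_x = m * band_step
        if abs(na_x) > spec.na_max:
            raise ValueError(f"band m={m} lies entirely outside the annulus")
        z_max = np.sqrt(spec.na_max**2 - na_x**2)
        if abs(na_x) >= spec.na_min:
            bands.append(
                {"m": m, "kz_mid_na": 0.0, "kz_range_na": 2.0 * z_max, "segments": 1}
            )
        else:
            z_min = np.sqrt(spec.na_min**2 - na_x**2)
            bands.append(
                {
                    "m": m,
                    "kz_mid_na": 0.5 * (z_max + z_min),
                    "kz_range_na": z_max - z_min,
                    "segments": 2,
                }
            )
    return bands


def _cs_bands_snapped(
    spec: SheetSpec, config: OpticalConfig, grids: GridSet
) -> list[dict]:
    """Band extents read off the discrete MB pupil (sample-edge quantized)."""
    mb_spec = SheetSpec(
        family="mb", symmetry=spec.symmetry, na_exc=spec.na_exc,
        na_min=spec.na_min, na_max=spec.na_max,
        T_override_nm=spec.T_override_nm,
    )
    pupil = mb_pupil(mb_spec, grids, config)
    na, half_step = grids.na_axis, grids.d_na / 2.0
    bands: list[dict] = []
    for m, col in enumerate(np.flatnonzero(np.abs(pupil.values).max(axis=0) > 0)):
        seg = np.flatnonzero(np.abs(pupil.values[:, col]) > 0)
        splits = np.flatnonzero(np.diff(seg) > 1)
        groups = np.split(seg, splits + 1)
        if len(groups) == 2:
            g_hi = groups[1]
            lo = na[g_hi[0]] - half_step
            hi = na[g_hi[-1]] + half_step
            bands.append(
                {"m": m, "kz_mid_na": 0.5 * (hi + lo), "kz_range_na": hi - lo,
                 "segments": 2}
            )
        else:
            g0 = groups[0]
            lo = na[g0[0]] - half_step
            hi = na[g0[-1]] + half_step
            bands.append(
                {"m": m, "kz_mid_na": 0.0, "kz_range_na": hi - lo, "segments": 1}
            )
    return bands


def cs_axial_profile(
    spec: SheetSpec,
    config: OpticalConfig,
    z_axis_nm: np.ndarray,
    grids: GridSet | None = None,
) -> np.ndarray:
    """Swept axial intensity of a cosine-sinc sheet (analytic band sum).

    ``I(z) = sum_m w_m cos^2(k_o kz_mid,m z) sinc^2(k_o kz_range,m z / 2)``
    with the band extents read off the annulus; a single centered band
    degenerates to a pure sinc^2 and a vanishing range to an undamped cos^2.
    """
    z = np.asarray(z_axis_nm, dtype=float)
    out = np.zeros_like(z)
    for band in cs_bands(spec, config, grids):
        mid = config.k_o * band["kz_mid_na"]
        rng = config.k_o * band["kz_range_na"]
        sinc = np.sinc(rng * z / (2.0 * np.pi))  # sin(rng z/2)/(rng z/2)
        term = (band["kz_range_na"] ** 2) * np.cos(mid * z) ** 2 * sinc**2
        if band["segments"] == 2:
            term = term * 4.0
        out += term
    return out


def build_pupil(
    spec: SheetSpec, grids: GridSet, config: OpticalConfig
) -> PupilField:
    """Dispatch a SheetSpec to its pupil constructor (hb uses the stored
    sigma_na directly, without re-running the design loop)."""
    if spec.family == "gaussian":
        return gaussian_pupil(spec, grids, config)
    if spec.family == "sinc":
        return sinc_pupil(spec, grids, config)
    if spec.family == "bessel":
        return bessel_pupil(spec, grids, config)
    if spec.family == "mb":
        return mb_pupil(spec, grids, config)
    if spec.family == "ac":
        return ac_pupil(spec, grids, config)
    if spec.family == "hb":
        return _beamlets_to_pupil(
            _hb_beamlets(spec.symmetry, spec.na_exc, spec.sigma_na), spec, grids
        )
    raise ValueError(f"family {spec.family!r} has no direct pupil (use cs_axial_profile)")
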