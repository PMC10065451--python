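"""Pupil synthesis for every sheet family."""

import warnings

import numpy as np
import pytest

from llsheet import (
    SheetSpec,
    ac_pupil,
    bessel_pupil,
    build_pupil,
    cs_axial_profile,
    gaussian_pupil,
    hb_design,
    lattice_wavevectors,
    mb_period,
    mb_pupil,
    sinc_pupil,
    swept_sheet,
    y_fwhm,
)
from llsheet.metrics import beamlet_length


def focal_swept_profile(pupil, grids, config, y=0.0, n_z_out=None):
    sheet = swept_sheet(pupil.values, grids, config, y_planes_nm=[y],
                        n_z_out=n_z_out)
    return sheet.z_axis_nm, sheet.intensity[0]


class TestLatticeWavevectors:
    @pytest.mark.parametrize(
        "symmetry,count", [("axial_sw", 2), ("square", 4), ("hexagonal", 6),
                           ("hexrect", 14)]
    )
    def test_counts_and_ring_constraint(self, symmetry, count):
        dirs = lattice_wavevectors(symmetry, 0.50)
        assert len(dirs) == count
        radii = np.hypot(dirs[:, 0], dirs[:, 1])
        assert np.allclose(radii, 1.0, atol=1e-14)

    def test_hexagonal_swept_harmonics(self):
        """Pairwise kz differences within each kx column give the swept
        harmonic set {0, +-1, +-2} * k_o NA_exc."""
        dirs = lattice_wavevectors("hexagonal", 1.0)
        harmonics = set()
        for s, c in dirs:
            for s2, c2 in dirs:
                if abs(s - s2) < 1e-12:
                    harmonics.add(round(c - c2, 9))
        assert harmonics == {0.0, 1.0, -1.0, 2.0, -2.0}

    def test_hexrect_swept_harmonics_nine_copies(self):
        dirs = lattice_wavevectors("hexrect", 1.0)
        harmonics = set()
        for s, c in dirs:
            for s2, c2 in dirs:
                if abs(s - s2) < 1e-12:
                    harmonics.add(round(c - c2, 9))
        assert harmonics == {0.0, 0.5, -0.5, 1.0, -1.0, 1.5, -1.5, 2.0, -2.0}

    def test_unknown_symmetry(self):
        with pytest.raises(ValueError, match="symmetry"):
            lattice_wavevectors("cubic", 0.5)


class TestGaussianPupil:
    def test_peak_at_equator_and_gaussian_profile(self, config, grids_small):
        spec = SheetSpec(family="gaussian", w0_nm=800.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pupil = gaussian_pupil(spec, grids_small, config)
        col = np.abs(pupil.values).max(axis=1)
        assert np.argmax(col) == grids_small.n_k // 2

    def test_swept_profile_matches_1d_transform(self, config, grids):
        """Swept focal intensity equals exp(-2 z^2 / w0^2) (1D transform of
        the pupil line profile) to machine precision."""
        w0 = 800.0
        spec = SheetSpec(family="gaussian", w0_nm=w0)
        pupil = gaussian_pupil(spec, grids, config)
        z, prof = focal_swept_profile(pupil, grids, config, n_z_out=4433)
        prof = prof / prof.max()
        assert np.allclose(prof, np.exp(-2 * z**2 / w0**2), atol=1e-12)

    def test_standing_wave_swept_equals_single_line(self, config, grids):
        """The two-line standing-wave realization has the same swept profile
        as the ideal single line."""
        single = gaussian_pupil(SheetSpec(family="gaussian", w0_nm=800.0),
                                grids, config)
        double = gaussian_pupil(
            SheetSpec(family="gaussian", w0_nm=800.0, x_offset_na=0.3),
            grids, config,
        )
        _, p1 = focal_swept_profile(single, grids, config)
        _, p2 = focal_swept_profile(double, grids, config)
        assert np.allclose(p1 / p1.max(), p2 / p2.max(), atol=1e-9)

    def test_clipping_warning(self, config, grids_small):
        spec = SheetSpec(family="gaussian", w0_nm=800.0, na_min=0.3, na_max=0.5,
                         x_offset_na=0.2)
        with pytest.warns(UserWarning, match="clip"):
            gaussian_pupil(spec, grids_small, config)


class TestSincPupil:
    def test_axial_otf_is_triangle(self, config, grids):
        """Swept axial OTF at focus equals tri(kz / (2 k_o NA_sinc))."""
        na_sinc = 0.25
        pupil = sinc_pupil(SheetSpec(family="sinc", na_sinc=na_sinc), grids,
                           config)
        c = grids.n_k // 2
        # effective half-bandwidth of the sampled rect (half-sample edges)
        na_eff = (np.abs(pupil.values[:, c]) > 0).sum() * grids.d_na / 2
        sheet = swept_sheet(pupil.values, grids, config, y_planes_nm=[0.0])
        otf = np.abs(sheet.axial_otf(0))
        kz = sheet.kz_axis_cycles
        u = np.abs(kz) / (2 * na_eff / config.lambda_exc_nm)
        tri = np.where(u < 1, 1 - u, 0.0)
        assert np.max(np.abs(otf - tri)[u < 0.98]) < 1e-3
        # half value at kz = k_o NA_sinc (to within half-sample quantization)
        i = np.argmin(np.abs(kz - na_eff / config.lambda_exc_nm))
        assert otf[i] == pytest.approx(tri[i], abs=1e-3)
        assert tri[i] == pytest.approx(0.5, abs=0.01)

    def test_first_intensity_zero(self, config, grids):
        """First zero of sinc^2(k_o NA_sinc z) at z = lambda/(2 NA_sinc)."""
        na_sinc = 0.25
        pupil = sinc_pupil(SheetSpec(family="sinc", na_sinc=na_sinc), grids,
                           config)
        z, prof = focal_swept_profile(pupil, grids, config, n_z_out=4433)
        z_zero = config.lambda_exc_nm / (2 * na_sinc)
        i = np.argmin(np.abs(z - z_zero))
        assert prof[i] / prof.max() < 1e-4

    def test_na_sinc_beyond_objective_rejected(self, config, grids_small):
        with pytest.raises(ValueError):
            sinc_pupil(SheetSpec(family="sinc", na_sinc=0.8), grids_small,
                       config)


class TestBesselPupil:
    def test_constant_ring(self, config, grids_small):
        spec = SheetSpec(family="bessel", na_min=0.40, na_max=0.47)
        pupil = bessel_pupil(spec, grids_small, config).values
        na = grids_small.na_axis
        rho = np.hypot(na[None, :], na[:, None])
        inside = (rho >= 0.41) & (rho <= 0.46)
        assert np.all(pupil[inside] == 1.0)
        assert np.all(pupil[rho > 0.48] == 0.0)

    def test_empty_annulus(self, config):
        from llsheet import make_grids

        g = make_grids(config, n_k=51, na_span=2.55)
        with pytest.raises(ValueError, match="empty"):
            bessel_pupil(SheetSpec(family="bessel", na_min=0.400, na_max=0.401),
                         g, config)

    def test_swept_otf_nonzero_with_secondary_maximum(self, config, grids):
        """The swept Bessel axial OTF stays nonzero across |kz| < 2 k_o NA_max
        and rises to a secondary maximum near the support edge."""
        spec = SheetSpec(family="bessel", na_min=0.40, na_max=0.47)
        pupil = bessel_pupil(spec, grids, config)
        sheet = swept_sheet(pupil.values, grids, config, y_planes_nm=[0.0])
        otf = np.abs(sheet.axial_otf(0))
        kz = sheet.kz_axis_cycles
        support = 2 * 0.47 / config.lambda_exc_nm
        inside = (kz > 0.02 * support) & (kz < 0.97 * support)
        assert otf[inside].min() > 1e-3
        # secondary maximum near the support edge
        near = (kz > 0.75 * support) & (kz < 0.99 * support)
        mid = (kz > 0.3 * support) & (kz < 0.6 * support)
        assert otf[near].max() > otf[mid].min()


class TestMBPupil:
    def test_hexagonal_period_and_bands(self, config, grids):
        """Reference hexagonal parameters: T = (2/sqrt(3)) lambda/NA, bands m in
        {-1, 0, 1} at kx = m (sqrt(3)/2) NA_exc."""
        na_exc = 0.43
        T = mb_period("hexagonal", na_exc, config.lambda_exc_nm)
        assert T == pytest.approx(2 / np.sqrt(3) * 488 / 0.43, rel=1e-12)
        spec = SheetSpec(family="mb", symmetry="hexagonal", na_exc=na_exc,
                         na_min=0.40, na_max=0.47)
        pupil = mb_pupil(spec, grids, config)
        cols = np.flatnonzero(np.abs(pupil.values).max(axis=0) > 0)
        na_cols = grids.na_axis[cols]
        expected = np.array([-1, 0, 1]) * np.sqrt(3) / 2 * na_exc
        assert len(na_cols) == 3
        assert np.allclose(np.sort(na_cols), np.sort(expected),
                           atol=grids.d_na)

    def test_square_keeps_polar_and_equatorial_stripes(self, config, grids):
        spec = SheetSpec(family="mb", symmetry="square", na_exc=0.41,
                         na_min=0.40, na_max=0.60)
        pupil = mb_pupil(spec, grids, config)
        cols = grids.na_axis[np.flatnonzero(np.abs(pupil.values).max(axis=0) > 0)]
        assert np.allclose(np.sort(cols), [-0.41, 0.0, 0.41], atol=grids.d_na)
        # m=0 band: two polar segments (annulus excludes the center)
        c = grids.n_k // 2
        col0 = np.abs(pupil.values[:, c]) > 0
        assert not col0[c]  # equator of the polar band is blocked
        assert col0.sum() > 0

    def test_subdiffractive_period_leaves_axial_sw(self, config, grids):
        spec = SheetSpec(family="mb", symmetry="axial_sw", na_exc=0.43,
                         na_min=0.40, na_max=0.47)
        pupil = mb_pupil(spec, grids, config)
        cols = np.flatnonzero(np.abs(pupil.values).max(axis=0) > 0)
        assert np.allclose(grids.na_axis[cols], 0.0, atol=grids.d_na / 2)

    def test_annulus_sharing_beamlets_have_equal_lengths(self, config, grids):
        """All beamlets with |kx| < NA_min span the full annulus and share one
        propagation length."""
        spec = SheetSpec(family="mb", symmetry="hexagonal", na_exc=0.43,
                         na_min=0.40, na_max=0.47)
        pupil = mb_pupil(spec, grids, config)
        lengths = [
            beamlet_length(b.na_minus, b.na_plus, config)
            for b in pupil.beamlets
            if abs(b.center_na[0]) < spec.na_min
        ]
        assert len(lengths) >= 2
        assert np.ptp(lengths) / np.mean(lengths) < 0.05

    def test_band_cap(self, config, grids):
        spec = SheetSpec(family="mb", symmetry="none", na_exc=0.43,
                         na_min=0.40, na_max=0.47, T_override_nm=1e6)
        with pytest.raises(ValueError, match="cap"):
            mb_pupil(spec, grids, config, max_bands=10)


class TestACPupil:
    def test_equal_bounding(self, config, grids_small):
        """All stripes have identical integrated |E|^2."""
        spec = SheetSpec(family="ac", symmetry="hexagonal", na_exc=0.43,
                         sigma_na=0.05)
        pupil = ac_pupil(spec, grids_small, config)
        na = grids_small.na_axis
        energies = []
        for b in pupil.beamlets:
            col = np.argmin(np.abs(na - b.center_na[0]))
            profile = np.exp(-(((na - b.center_na[1]) / spec.sigma_na) ** 2))
            energies.append(np.sum(np.abs(profile) ** 2))
        assert np.ptp(energies) / np.mean(energies) < 1e-9

    def test_narrow_stripe_recovers_ideal_lattice_positions(
        self, config, grids_small
    ):
        spec = SheetSpec(family="ac", symmetry="hexagonal", na_exc=0.43,
                         sigma_na=0.01)
        pupil = ac_pupil(spec, grids_small, config)
        na = grids_small.na_axis
        for b in pupil.beamlets:
            col = np.argmin(np.abs(na - b.center_na[0]))
            peak = na[np.argmax(np.abs(pupil.values[:, col]))]
            assert abs(abs(peak) - abs(b.c_b) * 0.43) <= grids_small.d_na

    def test_ac_square_equatorial_beamlets_much_longer(self, config, grids_small):
        """Equal-width stripes give the equatorial beamlets of an AC square
        lattice a propagation length many times the polar one."""
        spec = SheetSpec(family="ac", symmetry="square", na_exc=0.30,
                         sigma_na=0.05)
        pupil = ac_pupil(spec, grids_small, config)
        pol = [beamlet_length(b.na_minus, b.na_plus, config)
               for b in pupil.beamlets if b.s_b == 0.0]
        eq = [beamlet_length(b.na_minus, b.na_plus, config)
              for b in pupil.beamlets if b.c_b == 0.0]
        assert min(eq) / max(pol) > 8.0

    def test_stripe_past_propagating_circle_rejected(self, config, grids_small):
        spec = SheetSpec(family="ac", symmetry="hexagonal", na_exc=1.2,
                         sigma_na=0.1)
        with pytest.raises(ValueError, match="propagating circle"):
            ac_pupil(spec, grids_small, config)


class TestHBDesign:
    def test_width_and_amplitude_rules(self, config, grids):
        """Hexagonal side beamlets: sigma_b = 2 sigma_ref, amplitude 1/2;
        hexrect NA/4 beamlets: sigma_b = 4 sigma_ref."""
        from llsheet.pupils import _hb_beamlets

        beams = _hb_beamlets("hexagonal", 0.50, 0.02)
        for b in beams:
            if abs(b.c_b) == 1.0:
                assert b.sigma_b == pytest.approx(0.02)
                assert b.amplitude == pytest.approx(1.0)
            else:
                assert b.sigma_b == pytest.approx(0.04)
                assert b.amplitude == pytest.approx(0.5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            beams = _hb_beamlets("hexrect", 0.50, 0.012)
        widths = {round(abs(b.c_b), 2): b.sigma_b for b in beams}
        assert widths[0.25] == pytest.approx(4 * 0.012)
        assert widths[0.75] == pytest.approx(0.012 / 0.75)

    def test_design_hits_target_length(self, config, grids):
        target = 53.0 * config.lambda_medium_nm
        spec, pupil, beams = hb_design("hexagonal", 0.50, target, config, grids,
                                       na_min=0.40, na_max=0.60)
        sheet = swept_sheet(pupil.values, grids, config,
                            y_planes_nm=np.linspace(-30000, 30000, 241))
        assert y_fwhm(sheet) == pytest.approx(target, rel=0.02)

    def test_per_beamlet_lengths_agree(self, config, grids):
        """Balanced widths equalize the per-beamlet propagation lengths."""
        spec, pupil, beams = hb_design(
            "hexagonal", 0.50, 50.0 * config.lambda_medium_nm, config, grids,
            na_min=0.40, na_max=0.60,
        )
        lengths = [beamlet_length(b.na_minus, b.na_plus, config) for b in beams]
        assert np.ptp(lengths) / np.mean(lengths) < 0.20

    def test_square_excluded(self, config, grids_small):
        with pytest.raises(ValueError, match="square"):
            hb_design("square", 0.5, 10000.0, config, grids_small)


class TestCosineSinc:
    def test_single_centered_band_is_pure_sinc_squared(self, config):
        # na_min = 0: the m = 0 band spans the full -NA_max..NA_max range
        spec = SheetSpec(family="cs", symmetry="axial_sw", na_exc=0.3,
                         na_min=0.0, na_max=0.3)
        z = np.linspace(-5000, 5000, 2001)
        prof = cs_axial_profile(spec, config, z)
        rng_na = 0.6  # single band spans -0.3..0.3
        u = config.k_o * rng_na * z / 2
        expected = np.sinc(u / np.pi) ** 2
        assert np.allclose(prof / prof.max(), expected, atol=1e-12)

    def test_vanishing_range_tends_to_cosine_squared(self, config):
        spec = SheetSpec(family="cs", symmetry="axial_sw", na_exc=0.43,
                         na_min=0.4295, na_max=0.4305)
        z = np.linspace(-2000, 2000, 1001)
        prof = cs_axial_profile(spec, config, z)
        mid = (0.4295 + 0.4305) / 2
        expected = np.cos(config.k_o * mid * z) ** 2
        assert np.max(np.abs(prof / prof.max() - expected)) < 1e-3

    def test_cs_equals_swept_mb_profile(self, config, grids):
        """Field synthesis: the analytic cosine-sinc band sum equals the
        numerically swept multi-Bessel profile for matched band extents."""
        kwargs = dict(symmetry="hexagonal", na_exc=0.40, na_min=0.365,
                      na_max=0.435)
        mb = mb_pupil(SheetSpec(family="mb", **kwargs), grids, config)
        sheet = swept_sheet(mb.values, grids, config, y_planes_nm=[0.0],
                            n_z_out=4433)
        cs = cs_axial_profile(SheetSpec(family="cs", **kwargs), config,
                              sheet.z_axis_nm, grids=grids)
        a = sheet.intensity[0] / sheet.intensity[0].max()
        b = cs / cs.max()
        assert np.linalg.norm(a - b) / np.linalg.norm(a) < 1e-3


class TestBuildPupil:
    @pytest.mark.parametrize(
        "spec",
        [
            SheetSpec(family="gaussian", w0_nm=800.0),
            SheetSpec(family="sinc", na_sinc=0.25),
            SheetSpec(family="bessel", na_min=0.4, na_max=0.47),
            SheetSpec(family="mb", symmetry="hexagonal", na_exc=0.43,
                      na_min=0.4, na_max=0.47),
            SheetSpec(family="ac", symmetry="axial_sw", na_exc=0.3,
                      sigma_na=0.05),
            SheetSpec(family="hb", symmetry="hexagonal", na_exc=0.5,
                      sigma_na=0.075, na_min=0.4, na_max=0.6),
        ],
    )
    def test_dispatch(self, config, grids_small, spec):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pupil = build_pupil(spec, grids_small, config)
        assert np.abs(pupil.values).max() > 0

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            SheetSpec(family="unknown")
        with pytest.raises(ValueError):
            SheetSpec(family="ac", symmetry="hexagonal", na_exc=0.4)
        with pytest.raises(ValueError):
            SheetSpec(family="mb")
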