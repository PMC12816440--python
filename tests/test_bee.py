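import math

import numpy as np
import pytest

from chromacomm.bee import (bee_color_category, bee_excitation, brightness_bee,
                            chromatic_contrast_hu, dominant_wavelength,
                            green_contrast, hexagon_locus, hue_angle,
                            spectral_purity_bee)
from chromacomm.spectra import Spectrum
from chromacomm.vision import stimulus_catches


class TestExcitation:
    @pytest.mark.parametrize("q,expected", [(1.0, 0.5), (3.0, 0.75), (0.0, 0.0)])
    def test_closed_form(self, q, expected):
        assert bee_excitation(q) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            bee_excitation(-0.1)


class TestHexagonGeometry:
    def test_background_at_origin(self):
        assert hexagon_locus(0.5, 0.5, 0.5) == pytest.approx((0.0, 0.0))

    def test_blue_corner(self):
        x, y = hexagon_locus(0.0, 1.0, 0.0)
        assert (x, y) == pytest.approx((0.0, 1.0))

    def test_green_corner(self):
        x, y = hexagon_locus(0.0, 0.0, 1.0)
        assert x == pytest.approx(math.sqrt(3) / 2)
        assert y == pytest.approx(-0.5)

    def test_all_pure_corners_at_unit_radius(self):
        # 3 vertices + 3 midpoint corners of the hexagon
        corners = [(1, 0, 0), (0, 1, 0), (0, 0, 1),
                   (1, 1, 0), (0, 1, 1), (1, 0, 1)]
        for e in corners:
            x, y = hexagon_locus(*e)
            assert math.hypot(x, y) == pytest.approx(1.0, abs=1e-12)

    def test_contrast_unit_and_symmetry(self):
        assert chromatic_contrast_hu((0, 0), (0, 1)) == pytest.approx(1.0)
        a, b = (0.3, -0.2), (-0.1, 0.4)
        assert chromatic_contrast_hu(a, b) == chromatic_contrast_hu(b, a)

    def test_triangle_inequality_on_random_loci(self):
        rng = np.random.default_rng(11)
        pts = rng.uniform(-1, 1, size=(200, 3, 2))
        for a, b, c in pts:
            assert (chromatic_contrast_hu(a, c)
                    <= chromatic_contrast_hu(a, b)
                    + chromatic_contrast_hu(b, c) + 1e-12)


class TestGreenContrastAndBrightness:
    @pytest.mark.parametrize("eg,expected", [(0.5, 0.0), (0.8, 0.3), (0.2, 0.3)])
    def test_green_contrast(self, eg, expected):
        assert green_contrast(eg) == pytest.approx(expected)

    def test_brightness_background_is_three(self):
        assert brightness_bee([1.0, 1.0, 1.0]) == pytest.approx(3.0)

    def test_brightness_zero_reflectance(self):
        assert brightness_bee([0.0, 0.0, 0.0]) == 0.0


class TestCategories:
    def test_vertex_and_midline_sectors(self):
        assert bee_color_category((0.0, 1.0)) == "blue"
        # angle exactly between blue (0 deg) and green (120 deg) vertices
        ang = math.radians(60.0)
        assert bee_color_category((math.sin(ang), math.cos(ang))) == "blue-green"

    def test_boundary_goes_counter_clockwise(self):
        # boundary at +30 deg between blue and blue-green -> blue
        ang = math.radians(30.0)
        assert bee_color_category((math.sin(ang), math.cos(ang))) == "blue"

    def test_achromatic_label_near_origin(self):
        assert bee_color_category((0.01, 0.01)) == "achromatic"

    def test_all_six_sectors_hit(self):
        got = {bee_color_category((math.sin(math.radians(a)),
                                   math.cos(math.radians(a))))
               for a in (0, 60, 120, 180, 240, 300)}
        assert got == {"blue", "blue-green", "green", "uv-green", "uv", "uv-blue"}


def _narrowband(grid, wl, fwhm=10.0):
    sigma = fwhm / (2 * math.sqrt(2 * math.log(2)))
    return Spectrum(grid, np.exp(-((grid - wl) ** 2) / (2 * sigma ** 2)))


def _locus_of(refl, background, bee_rec, illuminant):
    qc = stimulus_catches(refl, background, bee_rec, illuminant)
    e = bee_excitation(qc.relative)
    return hexagon_locus(*e)


class TestDominantWavelengthAndPurity:
    def test_monochromatic_self_consistency(self, grid, background, bee_rec,
                                            illuminant, locus_table):
        for wl in (350.0, 440.0, 520.0):
            loc = _locus_of(_narrowband(grid, wl), background, bee_rec, illuminant)
            got, flag = dominant_wavelength(loc, locus_table)
            assert flag is None
            assert abs(got - wl) <= 1.0

    def test_achromatic_flagged(self, locus_table):
        wl, flag = dominant_wavelength((0.0, 0.0), locus_table)
        assert wl is None and flag == "achromatic"

    def test_uv_green_mixture_hits_purple_line(self, grid, background, bee_rec,
                                               illuminant, locus_table):
        # mixture of the two spectrum-locus endpoints: hue falls in the gap
        mix = Spectrum(grid, np.clip(_narrowband(grid, 300.0).values
                                     + _narrowband(grid, 550.0).values, 0, 1))
        loc = _locus_of(mix, background, bee_rec, illuminant)
        ang = hue_angle(loc)
        lo, hi = locus_table.angles[0], locus_table.angles[-1]
        # oracle: the gap arc runs from the 550-endpoint through 180 deg
        assert ang > hi or ang < lo
        wl, flag = dominant_wavelength(loc, locus_table)
        assert flag == "purple-line"

    def test_monochromatic_purity_is_one(self, grid, background, bee_rec,
                                         illuminant, locus_table):
        loc = _locus_of(_narrowband(grid, 440.0), background, bee_rec, illuminant)
        purity, flag = spectral_purity_bee(loc, locus_table)
        assert flag is None
        assert purity == pytest.approx(1.0, abs=1e-6)

    def test_background_purity_undefined(self, locus_table):
        purity, flag = spectral_purity_bee((0.0, 0.0), locus_table)
        assert purity is None and flag == "achromatic"

    def test_mixture_purity_matches_radius_ratio_oracle(
            self, grid, background, bee_rec, illuminant, locus_table):
        # 50/50 mix of a narrowband and a flat spectrum
        mix = Spectrum(grid, 0.5 * _narrowband(grid, 440.0).values
                       + 0.5 * np.full_like(grid, 0.5))
        loc = _locus_of(mix, background, bee_rec, illuminant)
        purity, flag = spectral_purity_bee(loc, locus_table)
        assert flag is None
        wl, _ = dominant_wavelength(loc, locus_table)
        mono_loc = _locus_of(_narrowband(grid, wl), background, bee_rec,
                             illuminant)
        oracle = (math.hypot(*loc) / math.hypot(*mono_loc))
        assert 0.0 < purity < 1.0
        assert purity == pytest.approx(oracle, abs=0.02)

    def test_purity_never_exceeds_one_on_random_spectra(
            self, grid, background, bee_rec, illuminant, locus_table):
        rng = np.random.default_rng(23)
        for _ in range(200):
            # smooth random flower-like spectrum
            edge = rng.uniform(350, 650)
            v = (rng.uniform(0, 0.2)
                 + rng.uniform(0.2, 0.8) / (1 + np.exp(-(grid - edge) / 15))
                 + rng.uniform(0, 0.4) * np.exp(
                     -((grid - rng.uniform(320, 680)) ** 2) / (2 * 40.0 ** 2)))
            loc = _locus_of(Spectrum(grid, np.clip(v, 0, 1)),
                            background, bee_rec, illuminant)
            purity, flag = spectral_purity_bee(loc, locus_table)
            if flag is None:
                assert purity <= 1.0 + 1e-12
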