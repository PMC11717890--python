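"""Synthetic phantom generator: extinction curves, Beer-Lambert rendering,
FIT simulation, study fixtures."""

import dataclasses

import numpy as np
import pytest
from scipy.signal import argrelmax

import hsifob as h

WL = h.DEFAULT_WAVELENGTHS


class TestExtinctionTable:
    def test_soret_and_q_band_structure(self):
        t = h.hb_extinction_table()
        soret = WL[np.argmax(t.oxy)]
        assert 410 <= soret <= 420
        qwin = (WL >= 530) & (WL <= 590)
        local_max = argrelmax(t.oxy)[0]
        q_peaks = [i for i in local_max if qwin[i]]
        assert len(q_peaks) == 2

    def test_positive_and_smooth(self):
        t = h.hb_extinction_table()
        for curve in (t.oxy, t.deoxy):
            assert np.all(curve > 0)
            ratio = curve[1:] / curve[:-1]
            assert ratio.max() < 10 and ratio.min() > 0.1

    def test_mixture_endpoints_and_midpoint(self):
        t = h.hb_extinction_table()
        np.testing.assert_array_equal(h.hb_extinction_spectrum(t, 1.0), t.oxy)
        np.testing.assert_array_equal(h.hb_extinction_spectrum(t, 0.0),
                                      t.deoxy)
        np.testing.assert_allclose(h.hb_extinction_spectrum(t, 0.5),
                                   (t.oxy + t.deoxy) / 2)

    @pytest.mark.parametrize("frac", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_mixture_keeps_soret_peak(self, frac):
        t = h.hb_extinction_table()
        mix = h.hb_extinction_spectrum(t, frac)
        assert 405 <= WL[np.argmax(mix)] <= 435

    def test_fraction_out_of_range(self):
        with pytest.raises(ValueError):
            h.hb_extinction_spectrum(h.hb_extinction_table(), 1.2)


class TestStoolPhantom:
    def clean_spec(self, **kw):
        defaults = dict(scatter_sd=0.0, noise_sd=0.0,
                        background_variation=0.0, seed=3)
        defaults.update(kw)
        return h.PhantomSpec(**defaults)

    def test_no_blood_no_noise_recovers_background(self):
        spec = self.clean_spec()
        raw, white, dark, stool, truth = h.generate_stool_phantom(spec)
        refl = h.calibrate_reflectance(raw, white, dark)
        bg = h.phantom.background_reflectance("stool", WL)
        inside = refl.data[stool.pixels]
        np.testing.assert_allclose(inside, np.broadcast_to(bg, inside.shape),
                                   rtol=1e-9)
        assert truth.max() == 0.0

    def test_beer_lambert_absorbance_proportional_to_load(self):
        load = 0.37
        spec = self.clean_spec(
            blood_regions=(h.BloodRegion((24, 24), 6, load),))
        raw, white, dark, stool, truth = h.generate_stool_phantom(spec)
        refl = h.calibrate_reflectance(raw, white)
        bg = h.phantom.background_reflectance("stool", WL)
        eps = h.hb_extinction_spectrum(h.hb_extinction_table(),
                                       spec.oxy_fraction)
        absorbance = -np.log10(refl.data[24, 24] / bg)
        np.testing.assert_allclose(absorbance, load * eps, atol=1e-9)

    def test_q_band_dips_at_table_peaks(self):
        spec = self.clean_spec(
            blood_regions=(h.BloodRegion((24, 24), 6, 0.5),))
        raw, white, dark, stool, truth = h.generate_stool_phantom(spec)
        refl = h.calibrate_reflectance(raw, white)
        bg = h.phantom.background_reflectance("stool", WL)
        ratio = refl.data[24, 24] / bg
        qwin = (WL >= 520) & (WL <= 600)
        dip = WL[qwin][np.argmin(ratio[qwin])]
        t = h.hb_extinction_table()
        q_peak = WL[qwin][np.argmax(t.oxy[qwin])]
        assert abs(dip - q_peak) <= 5.0

    def test_subsurface_blood_is_optically_hidden(self):
        surf = self.clean_spec(
            blood_regions=(h.BloodRegion((24, 24), 6, 0.5, "surface"),))
        sub = self.clean_spec(
            blood_regions=(h.BloodRegion((24, 24), 6, 0.5, "subsurface"),))
        r_surf = h.calibrate_reflectance(
            *h.generate_stool_phantom(surf)[:2])
        r_sub = h.calibrate_reflectance(*h.generate_stool_phantom(sub)[:2])
        bg = h.phantom.background_reflectance("stool", WL)
        a_surf = -np.log10(r_surf.data[24, 24] / bg).max()
        a_sub = -np.log10(r_sub.data[24, 24] / bg).max()
        assert a_sub <= a_surf / 99.0
        # but the truth map still records the nominal load
        assert h.generate_stool_phantom(sub)[4][24, 24] == 0.5

    def test_seed_determinism(self):
        spec = h.PhantomSpec(seed=9,
                             blood_regions=(h.BloodRegion((20, 20), 5, 0.3),))
        a = h.generate_stool_phantom(spec)
        b = h.generate_stool_phantom(spec)
        np.testing.assert_array_equal(a[0].data, b[0].data)
        c = h.generate_stool_phantom(dataclasses.replace(spec, seed=10))
        assert not np.array_equal(a[0].data, c[0].data)


class TestLiquidPhantom:
    def test_blood_spot_confined_q_dips(self):
        spec = h.PhantomSpec(background="milk", scatter_sd=0.0, noise_sd=0.0,
                             background_variation=0.0,
                             blood_regions=(h.BloodRegion((24, 24), 5, 0.4),),
                             seed=1)
        raw, white, dark, vessel, truth = h.generate_liquid_phantom(spec)
        refl = h.calibrate_reflectance(raw, white)
        bg = h.phantom.background_reflectance("milk", WL)
        qwin = (WL >= 520) & (WL <= 600)
        spot = refl.data[24, 24] / bg
        away = refl.data[5, 24] / bg
        assert (1 - spot[qwin].min()) > 0.2
        np.testing.assert_allclose(away[qwin], 1.0, atol=1e-9)

    def test_backgrounds_are_distinct(self):
        curves = {bg: h.phantom.background_reflectance(bg, WL)
                  for bg in h.phantom.LIQUID_BACKGROUNDS}
        names = list(curves)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                assert np.abs(curves[a] - curves[b]).max() > 0.05

    def test_water_round_trips_through_calibration(self):
        spec = h.PhantomSpec(background="water", scatter_sd=0.0,
                             noise_sd=0.0, background_variation=0.0, seed=2)
        raw, white, dark, vessel, truth = h.generate_liquid_phantom(spec)
        refl = h.calibrate_reflectance(raw, white)
        bg = h.phantom.background_reflectance("water", WL)
        inside = refl.data[vessel.pixels]
        np.testing.assert_allclose(inside, np.broadcast_to(bg, inside.shape),
                                   rtol=1e-9)

    def test_stool_background_rejected(self):
        with pytest.raises(ValueError, match="liquid"):
            h.generate_liquid_phantom(h.PhantomSpec(background="stool"))


class TestSimulateFit:
    def disc(self, center, radius, shape=(48, 48)):
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        return h.RoiMask((rr - center[0]) ** 2 + (cc - center[1]) ** 2
                         <= radius ** 2)

    def test_zero_load_zero_noise_gives_zero(self):
        truth = np.zeros((48, 48))
        out = h.simulate_fit_values(truth, [self.disc((10, 10), 4)],
                                    noise_cv=0.0)
        assert out[0] == 0.0

    def test_linear_in_load_without_noise(self):
        truth = np.full((48, 48), 0.1)
        m = [self.disc((10, 10), 4)]
        a = h.simulate_fit_values(truth, m, gain=2000.0, noise_cv=0.0)
        b = h.simulate_fit_values(2 * truth, m, gain=2000.0, noise_cv=0.0)
        assert b[0] == pytest.approx(2 * a[0])
        assert a[0] == pytest.approx(2000.0 * 0.1)

    def test_noise_is_mean_one_multiplicative(self):
        truth = np.full((48, 48), 0.2)
        masks = [self.disc((24, 24), 10)] * 4000
        vals = h.simulate_fit_values(truth, masks, gain=1000.0,
                                     noise_cv=0.15, seed=5)
        assert vals.mean() == pytest.approx(200.0, rel=0.02)
        assert vals.std() / vals.mean() == pytest.approx(0.15, rel=0.1)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            h.simulate_fit_values(np.zeros((4, 4)), [np.zeros((4, 4), bool)])


class TestGenerateStudy:
    def test_training_style_counts(self, small_study):
        assert len(small_study.cases) == 16
        areas = list(small_study.areas())
        assert len(areas) == 32

    def test_fifty_case_study_has_100_areas(self):
        fix = h.generate_study(n_cases=50, areas_per_case=2, seed=0)
        assert len(list(fix.areas())) == 100

    def test_positive_fraction_near_design_value(self):
        fix = h.generate_study(n_cases=50, areas_per_case=2, seed=0)
        fits = np.array([f for _, _, _, f in fix.areas()])
        assert 0.2 <= (fits >= 400.0).mean() <= 0.5

    def test_composition_batch(self):
        fix = h.generate_study(n_cases=10, composition=(2, 3, 5), seed=4)
        patterns = [c.pattern_truth for c in fix.cases]
        assert patterns.count("whole_positive") == 2
        assert patterns.count("partial_positive") == 3
        assert patterns.count("whole_negative") == 5
        for c in fix.cases:
            if c.pattern_truth == "whole_negative":
                assert c.truth_map.max() == 0.0
            else:
                assert c.truth_map.max() > 0.0

    def test_seed_reproducibility(self):
        a = h.generate_study(n_cases=4, seed=12)
        b = h.generate_study(n_cases=4, seed=12)
        for ca, cb in zip(a.cases, b.cases):
            np.testing.assert_array_equal(ca.raw.data, cb.raw.data)
            np.testing.assert_array_equal(ca.fit_values, cb.fit_values)

    def test_bad_composition_rejected(self):
        with pytest.raises(ValueError, match="composition"):
            h.generate_study(n_cases=5, composition=(1, 1, 1), seed=0)
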