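"""Synthetic season generator: traits, closure curve, spectra, images."""

import numpy as np
import pandas as pd
import pytest

from canospec import (
    CanopyScenario,
    DateSpec,
    Endmembers,
    TraitRange,
    TraitRecord,
    fractional_cover,
    generate_image,
    generate_spectra,
    generate_spectrum,
    generate_traits,
    ndsi,
    scenario_2014,
    scenario_2016,
    segment_green,
)
from canospec.synthetic import chlorophyll_proxy


def season_frame(traits):
    return pd.DataFrame(
        [(t.date_id, t.bbch, t.fresh_weight, t.dry_weight, t.n_conc, t.n_uptake) for t in traits],
        columns=["date_id", "bbch", "fresh", "dry", "n_conc", "n_uptake"],
    )


class TestTraits:
    def test_ranges_respected_per_date(self, season):
        sc, traits, _ = season
        df = season_frame(traits)
        for ds in sc.dates:
            sub = df[df["date_id"] == ds.date_id]
            assert sub["dry"].between(ds.dry_weight.lo, ds.dry_weight.hi).all()
            assert sub["fresh"].between(ds.fresh_weight.lo, ds.fresh_weight.hi).all()
            assert sub["n_conc"].between(ds.n_conc.lo, ds.n_conc.hi).all()

    def test_uptake_identity_exact(self, season):
        _, traits, _ = season
        for t in traits:
            assert t.n_uptake == t.dry_weight * t.n_conc / 100.0

    def test_dry_never_exceeds_fresh(self, season):
        _, traits, _ = season
        assert all(t.dry_weight <= t.fresh_weight for t in traits)

    def test_dilution_effect_across_stages(self, season):
        """Mean dry weight rises and mean N% falls across BBCH 19 -> 30."""
        _, traits, _ = season
        m = season_frame(traits).groupby("bbch")[["dry", "n_conc"]].mean().sort_index()
        assert m["dry"].is_monotonic_increasing
        assert m["n_conc"].is_monotonic_decreasing

    def test_2016_preset_reverses_n_trend(self):
        traits = generate_traits(scenario_2016(seed=3))
        m = season_frame(traits).groupby("bbch")[["dry", "n_conc"]].mean().sort_index()
        assert m["n_conc"].is_monotonic_increasing  # fertilization between dates

    def test_seed_determinism(self):
        a = generate_traits(scenario_2014(n_plots=8, seed=5))
        b = generate_traits(scenario_2014(n_plots=8, seed=5))
        assert [(t.dry_weight, t.n_conc) for t in a] == [(t.dry_weight, t.n_conc) for t in b]
        c = generate_traits(scenario_2014(n_plots=8, seed=6))
        assert [t.dry_weight for t in a] != [t.dry_weight for t in c]

    def test_point_mass_distributions_give_identical_plots(self):
        dates = (DateSpec("d1", 19, TraitRange(1000, 1000, 1000),
                          TraitRange(300, 300, 300), TraitRange(3.0, 3.0, 3.0)),)
        sc = CanopyScenario(name="pm", n_plots=6, dates=dates, noise_sd_trait=0.0)
        traits = generate_traits(sc)
        assert len({(t.fresh_weight, t.dry_weight, t.n_conc) for t in traits}) == 1

    def test_infeasible_targets_rejected(self):
        with pytest.raises(ValueError):
            TraitRange(10, 5, 1)  # min > max
        with pytest.raises(ValueError):
            TraitRange(1, 5, 4)   # mean above max

    def test_trait_record_invariants(self):
        with pytest.raises(ValueError):
            TraitRecord("p", "d", 19, 100.0, 200.0, 3.0, 6.0)  # dry > fresh
        with pytest.raises(ValueError):
            TraitRecord("p", "d", 19, 200.0, 100.0, 0.0, 0.0)  # n_conc <= 0


class TestFractionalCover:
    def test_boundary_and_closed_form(self):
        assert fractional_cover(0.0, 1e-3) == 0.0
        assert fractional_cover(2206.0, 1e-3) == pytest.approx(1 - np.exp(-2.206), abs=1e-15)

    def test_strictly_increasing_concave_below_one(self):
        w = np.linspace(0, 10_000, 200)
        f = fractional_cover(w, 5e-4)
        assert np.all(np.diff(f) > 0)
        assert np.all(np.diff(f, 2) < 0)  # concave
        assert f.max() < 1.0
        # concavity in the spec's increment form: f(2w) - f(w) < f(w) - f(0)
        for wi in [100.0, 1000.0, 4000.0]:
            k = 5e-4
            assert (fractional_cover(2 * wi, k) - fractional_cover(wi, k)
                    < fractional_cover(wi, k) - 0.0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            fractional_cover(-1.0, 1e-3)
        with pytest.raises(ValueError):
            fractional_cover(10.0, 0.0)


class TestEndmembers:
    def test_vegetation_nir_above_red(self, grid):
        em = Endmembers.default(grid)
        for chl in [0.0, 0.5, 1.0]:
            veg = em.vegetation_reflectance(chl)
            assert veg[grid >= 760].min() > veg[np.abs(grid - 670) <= 10].max()

    def test_soil_monotone_on_400_1000(self, grid):
        em = Endmembers.default(grid)
        sel = (grid >= 400) & (grid <= 1000)
        assert np.all(np.diff(em.soil_reflectance[sel]) >= 0)

    def test_higher_chl_deepens_red_and_shifts_red_edge(self, grid):
        em = Endmembers.default(grid)
        lo, hi = em.vegetation_reflectance(0.1), em.vegetation_reflectance(0.9)
        i670 = int(np.argmin(np.abs(grid - 670)))
        assert hi[i670] < lo[i670]
        i730 = int(np.argmin(np.abs(grid - 730)))
        assert hi[i730] < lo[i730]  # red edge pushed right -> lower shoulder


class TestSpectra:
    def _noiseless(self, **kw):
        return scenario_2014(n_plots=4, seed=0, noise_sd_spectral=0.0, **kw)

    def test_zero_cover_returns_soil_exactly(self, grid):
        sc = self._noiseless()
        em = Endmembers.default(grid)
        t = TraitRecord.from_biomass("p1", "d1", 19, 0.0, 0.0, 3.0)
        s = generate_spectrum(t, em, sc)
        np.testing.assert_array_equal(s.reflectance, em.soil_reflectance)

    def test_full_cover_limit_returns_vegetation(self, grid):
        sc = self._noiseless(cover_saturation_k=10.0)  # f -> 1
        em = Endmembers.default(grid)
        t = TraitRecord.from_biomass("p1", "d1", 19, 9000.0, 9000.0, 3.0)
        s = generate_spectrum(t, em, sc)
        np.testing.assert_allclose(
            s.reflectance, em.vegetation_reflectance(chlorophyll_proxy(3.0)), atol=1e-12
        )

    def test_ndvi_strictly_increasing_in_dry_weight(self, grid):
        sc = self._noiseless()
        em = Endmembers.default(grid)
        vals = []
        for dw in [200.0, 800.0, 2000.0, 4000.0]:
            t = TraitRecord.from_biomass("p1", "d1", 19, dw * 5, dw, 2.5)
            vals.append(ndsi(generate_spectrum(t, em, sc), 780, 670))
        assert np.all(np.diff(vals) > 0)

    def test_grid_mismatch_rejected(self, grid):
        sc = self._noiseless()
        em = Endmembers.default(grid[:-10])
        t = TraitRecord.from_biomass("p1", "d1", 19, 500.0, 100.0, 3.0)
        with pytest.raises(ValueError):
            generate_spectrum(t, em, sc)

    def test_spectra_deterministic_given_seed(self):
        sc = scenario_2014(n_plots=3, seed=4)
        traits = generate_traits(sc)
        a = generate_spectra(traits, sc)
        b = generate_spectra(traits, sc)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.reflectance, y.reflectance)


class TestImages:
    def test_target_zero_and_hundred(self):
        img0, n0 = generate_image(0.0, 16, 16, seed=1)
        assert n0 == 0 and segment_green(img0).green_count == 0
        img1, n1 = generate_image(100.0, 16, 16, seed=1)
        assert n1 == 256 and segment_green(img1).green_count == 256

    def test_exact_pixel_arithmetic(self):
        _, n = generate_image(25.0, 128, 128, seed=2)
        assert n == 4096

    def test_round_trip_within_one_pixel(self):
        img, n = generate_image(61.9, 64, 64, seed=3)
        res = segment_green(img)
        assert res.green_count == n
        assert abs(res.green_pct - 61.9) <= 100.0 / (64 * 64)

    def test_winter_stressed_background_still_excluded(self):
        img, n = generate_image(30.0, 64, 64, style="winter_stressed", seed=4)
        assert segment_green(img).green_count == n

    def test_bad_target_rejected(self):
        with pytest.raises(ValueError):
            generate_image(101.0, 8, 8, seed=0)
        with pytest.raises(ValueError):
            generate_image(-0.1, 8, 8, seed=0)

    def test_image_determinism(self):
        a, _ = generate_image(40.0, 32, 32, seed=7)
        b, _ = generate_image(40.0, 32, 32, seed=7)
        np.testing.assert_array_equal(a, b)


def test_scenario_json_round_trip():
    sc = scenario_2014(n_plots=5, seed=9)
    back = CanopyScenario.from_json(sc.to_json())
    assert back == sc
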