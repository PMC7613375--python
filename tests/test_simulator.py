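"""Tests of the surrogate simulator: sampling, leaf/canopy optics, derived
traits, library generation, non-vegetated archetypes, synthetic cubes."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

import hytrait as ht
from hytrait.errors import ConfigurationError, ValidationError
from hytrait.simulator import (DEFAULT_OPTICS, INPUT_NAMES, TABLE_DISTRIBUTIONS,
                               DistributionSpec, TraitSample, generate_nonveg_cube,
                               sample_inputs_frame, _simulate_frame)


def _specs_with(**overrides):
    return [overrides.get(s.name, s) for s in TABLE_DISTRIBUTIONS]


def _mid_sample(**overrides) -> TraitSample:
    vals = {}
    for s in TABLE_DISTRIBUTIONS:
        vals[s.name] = s.mean if s.mean is not None else 0.5 * (s.min + s.max)
    vals.update(overrides)
    return TraitSample(**vals)


class TestSampling:
    def test_uniform_draws_stay_in_range(self):
        rng = np.random.default_rng(0)
        spec = DistributionSpec("LAI", "uniform", 0.1, 8.0)
        draws = spec.draw(1000, rng)
        assert draws.min() >= 0.1 and draws.max() <= 8.0

    def test_fixed_spec_is_degenerate(self):
        rng = np.random.default_rng(0)
        spec = DistributionSpec("Cant", "fixed", 0.0, 0.0)
        assert np.all(spec.draw(50, rng) == 0.0)

    def test_truncated_gaussian_mean_matches_quadrature(self):
        # Independent oracle: mean of the analytically truncated normal by
        # numerical integration of x f(x) / Z over [0, 80].
        mean, sd, lo, hi = 45.0, 35.0, 0.0, 80.0
        pdf = lambda x: stats.norm.pdf(x, mean, sd)
        z, _ = integrate.quad(pdf, lo, hi)
        m1, _ = integrate.quad(lambda x: x * pdf(x), lo, hi)
        expected = m1 / z
        rng = np.random.default_rng(7)
        draws = DistributionSpec("Cab", "truncated-gaussian", lo, hi, mean, sd).draw(10_000, rng)
        assert abs(draws.mean() - expected) < 2.0
        assert draws.min() >= lo and draws.max() <= hi

    def test_uniform_draws_pass_ks(self):
        # Seeded fixture: KS against the uniform CDF at alpha=0.01, n=1e4.
        rng = np.random.default_rng(42)
        draws = DistributionSpec("LAI", "uniform", 0.1, 8.0).draw(10_000, rng)
        u = (draws - 0.1) / 7.9
        assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_missing_spec_is_configuration_error(self):
        specs = [s for s in TABLE_DISTRIBUTIONS if s.name != "LAI"]
        with pytest.raises(ConfigurationError, match="LAI"):
            ht.sample_inputs(specs, 3, seed=0)

    def test_bad_sd_rejected(self):
        with pytest.raises(ValidationError):
            DistributionSpec("x", "truncated-gaussian", 0, 1, 0.5, 0.0)

    def test_yaml_config_overrides_defaults(self, tmp_path):
        cfg = tmp_path / "dist.yml"
        cfg.write_text("- {name: LAI, kind: uniform, min: 1.0, max: 3.0}\n")
        specs = ht.load_distribution_config(cfg)
        by_name = {s.name: s for s in specs}
        assert by_name["LAI"].min == 1.0 and by_name["LAI"].max == 3.0
        assert by_name["Cab"] == dict((s.name, s) for s in TABLE_DISTRIBUTIONS)["Cab"]
        with pytest.raises(ConfigurationError):
            cfg.write_text("- {kind: uniform, min: 0, max: 1}\n")
            ht.load_distribution_config(cfg)

    def test_sample_inputs_reproducible(self):
        a = ht.sample_inputs(TABLE_DISTRIBUTIONS, 5, seed=9)
        b = ht.sample_inputs(TABLE_DISTRIBUTIONS, 5, seed=9)
        for sa, sb in zip(a, b):
            assert sa.as_dict() == sb.as_dict()


class TestLeafOptics:
    wl = np.arange(400.0, 2501.0, 10.0)

    def test_zero_contents_zero_absorptance(self):
        s = _mid_sample(Cab=0.0, Cxc=0.0, Cw=0.0, Cm=0.0)
        rho, ab = ht.simulate_leaf(s, self.wl)
        assert np.all(ab == 0.0)
        s_n = DEFAULT_OPTICS.s0 + DEFAULT_OPTICS.s1 * (s.N - 1.5)
        assert np.allclose(rho, DEFAULT_OPTICS.rho0 + s_n)

    def test_doubling_water_raises_1450_absorptance(self):
        lo = ht.simulate_leaf(_mid_sample(Cw=0.015), self.wl)[1]
        hi = ht.simulate_leaf(_mid_sample(Cw=0.030), self.wl)[1]
        i = np.argmin(np.abs(self.wl - 1450))
        assert hi[i] > lo[i]

    def test_matches_scalar_closed_form(self):
        # Brute-force per-band evaluation of the stated closed form.
        s = _mid_sample(Cab=45.0, Cw=0.015, Cm=0.0075, Cxc=10.0, N=1.5)
        rho, ab = ht.simulate_leaf(s, self.wl)
        o = DEFAULT_OPTICS
        for i, w in enumerate(self.wl[::25]):
            wl1 = np.array([w])
            a = (45.0 * o.k_ab(wl1) + 10.0 * o.k_xc(wl1)
                 + 0.015 * o.k_w(wl1) + 0.0075 * o.k_m(wl1)) / 1.5
            a_expect = 1.0 - np.exp(-a[0])
            j = i * 25
            assert ab[j] == pytest.approx(a_expect, abs=1e-12)
            assert rho[j] == pytest.approx(o.rho0 + o.s0 * (1 - a_expect), abs=1e-12)

    def test_negative_content_rejected(self):
        with pytest.raises(ValidationError):
            ht.simulate_leaf(_mid_sample(Cab=-1.0), self.wl)

    def test_outputs_bounded(self):
        rho, ab = ht.simulate_leaf(_mid_sample(Cw=0.035, Cm=0.02, Cab=80), self.wl)
        assert np.all((rho >= 0) & (rho <= 1)) and np.all((ab >= 0) & (ab <= 1))


class TestCanopy:
    wl = np.arange(400.0, 2501.0, 10.0)

    def _soil(self):
        return 0.2 * np.ones_like(self.wl)

    def test_bare_soil_limit(self):
        s = _mid_sample(LAI=0.0, SZA=30.0, OZA=10.0, RAA=90.0)
        leaf = ht.simulate_leaf(s, self.wl)
        refl, gap = ht.simulate_canopy(s, leaf, self._soil())
        assert gap == pytest.approx(1.0)
        g = (1.0 + 0.05 * (np.cos(np.deg2rad(10)) - 1)
             + 0.02 * np.cos(np.deg2rad(90)) * np.sin(np.deg2rad(30)) * np.sin(np.deg2rad(10)))
        assert np.allclose(refl, g * self._soil(), atol=1e-12)

    def test_closed_canopy_limit(self):
        s = _mid_sample(LAI=50.0, OZA=0.0, SZA=0.0, RAA=0.0)
        leaf = ht.simulate_leaf(s, self.wl)
        refl, gap = ht.simulate_canopy(s, leaf, self._soil())
        rho, ab = leaf
        expected = np.clip(rho * (1 + DEFAULT_OPTICS.q_multi * (1 - ab)), 0, 1)
        assert np.allclose(refl, expected, atol=1e-6)

    def test_gap_fraction_arithmetic(self):
        # k_ext = 0.5 at LIDF = 0; LAI = 2 -> P = exp(-1).
        s = _mid_sample(LAI=2.0, LIDF=0.0)
        leaf = ht.simulate_leaf(s, self.wl)
        _, gap = ht.simulate_canopy(s, leaf, self._soil())
        assert gap == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_negative_lai_rejected(self):
        s = _mid_sample(LAI=-1.0)
        leaf = ht.simulate_leaf(_mid_sample(), self.wl)
        with pytest.raises(ValidationError):
            ht.simulate_canopy(s, leaf, self._soil())

    @pytest.mark.parametrize("var,wl_probe,lo,hi", [
        ("Cab", 660.0, 20.0, 60.0),   # red absorption deepens with chlorophyll
        ("Cw", 1450.0, 0.008, 0.030),  # SWIR water feature deepens with water
    ])
    def test_reflectance_decreases_with_absorber(self, var, wl_probe, lo, hi):
        i = np.argmin(np.abs(self.wl - wl_probe))
        vals = []
        for v in (lo, hi):
            s = _mid_sample(LAI=4.0, **{var: v})
            leaf = ht.simulate_leaf(s, self.wl)
            refl, _ = ht.simulate_canopy(s, leaf, self._soil())
            vals.append(refl[i])
        assert vals[1] < vals[0]


class TestDerivedTraits:
    wl = np.arange(400.0, 2501.0, 10.0)

    def test_ccc_cwc_unit_arithmetic(self):
        s = _mid_sample(LAI=2.0, Cab=45.0, Cw=0.015)
        leaf = ht.simulate_leaf(s, self.wl)
        _, gap = ht.simulate_canopy(s, leaf, 0.2 * np.ones_like(self.wl))
        s = ht.derive_traits(s, leaf[1], gap, self.wl)
        assert s.CCC == pytest.approx(0.9)      # 2 x 45 x 1e-2 g/m^2
        assert s.CWC == pytest.approx(300.0)    # 2 x 0.015 x 1e4 g/m^2
        assert s.SLA == pytest.approx(1.0 / s.Cm)
        assert s.FVC == pytest.approx(1.0 - gap)

    def test_zero_lai_gives_zero_cover_and_fapar(self):
        s = _mid_sample(LAI=0.0)
        leaf = ht.simulate_leaf(s, self.wl)
        _, gap = ht.simulate_canopy(s, leaf, 0.2 * np.ones_like(self.wl))
        s = ht.derive_traits(s, leaf[1], gap, self.wl)
        assert s.FVC == 0.0 and s.FAPAR == 0.0

    def test_zero_cm_rejected(self):
        s = _mid_sample(Cm=0.0)
        with pytest.raises(ValidationError):
            ht.derive_traits(s, np.zeros_like(self.wl), 0.5, self.wl)

    def test_randomized_trait_arithmetic(self, rng):
        # CCC/CWC/SLA/FVC formulas against direct arithmetic on random inputs.
        params = sample_inputs_frame(TABLE_DISTRIBUTIONS, 200, rng)
        wl = self.wl
        refl, traits = _simulate_frame(params, wl, DEFAULT_OPTICS)
        lai = params["LAI"].to_numpy()
        kext = 0.5 * (1 + 0.3 * params["LIDF"].to_numpy())
        np.testing.assert_allclose(traits["CCC"], lai * params["Cab"] * 1e-2, rtol=1e-12)
        np.testing.assert_allclose(traits["CWC"], lai * params["Cw"] * 1e4, rtol=1e-12)
        np.testing.assert_allclose(traits["SLA"], 1.0 / params["Cm"], rtol=1e-12)
        np.testing.assert_allclose(traits["FVC"], 1.0 - np.exp(-kext * lai), rtol=1e-12)
        assert np.all(traits["FAPAR"] <= traits["FVC"] + 1e-15)


class TestLibrary:
    def test_library_shape_and_invariants(self, default_library):
        lib = default_library
        assert lib.n_samples == 200
        assert np.all((lib.reflectance >= 0) & (lib.reflectance <= 1))
        assert np.all(np.diff(lib.wavelengths) > 0)
        for name, lo, hi in [("LAI", 0.1, 8), ("FVC", 0, 1), ("FAPAR", 0, 1)]:
            v = lib.targets(name)
            assert v.min() >= lo and v.max() <= hi

    def test_determinism(self):
        a = ht.generate_library(n=5, seed=77)
        b = ht.generate_library(n=5, seed=77)
        assert np.array_equal(a.reflectance, b.reflectance)
        pd.testing.assert_frame_equal(a.traits, b.traits)

    def test_lai_fvc_monte_carlo_correlation(self):
        lib = ht.generate_library(n=5000, seed=5)
        r = np.corrcoef(lib.targets("LAI"), lib.targets("FVC"))[0, 1]
        assert r > 0.5


class TestNonVegetated:
    def test_counts_and_zero_traits(self):
        nv = ht.generate_nonvegetated(26, seed=1)
        assert nv.n_samples == 26
        for t in ("SLA", "LAI", "CCC", "CWC", "FAPAR", "FVC"):
            assert np.all(nv.targets(t) == 0.0)

    def test_water_is_dark_in_swir(self):
        nv = ht.generate_nonvegetated(40, seed=2,
                                      class_probs={"water": 1.0})
        wl = nv.wavelengths
        swir = nv.reflectance[:, (wl >= 1500) & (wl <= 2300)].mean()
        vis = nv.reflectance[:, (wl >= 400) & (wl <= 700)].mean()
        assert swir < vis

    def test_zero_jitter_reproduces_template(self):
        from hytrait.simulator import _archetype_spectrum

        nv = ht.generate_nonvegetated(3, seed=3, jitter=0.0,
                                      class_probs={"bright_soil": 1.0})
        template = _archetype_spectrum("bright_soil", nv.wavelengths)
        assert np.allclose(nv.reflectance, template[None, :])


class TestSyntheticCube:
    def test_fixed_sample_pixel_matches_library_path(self, coarse_grid):
        s = _mid_sample(LAI=3.0)
        cube, truth, cmap = ht.generate_synthetic_cube(
            1, 1, grid=coarse_grid, seed=0, fixed_sample=s)
        frame = pd.DataFrame([{k: getattr(s, k) for k in INPUT_NAMES}])
        refl, traits = _simulate_frame(frame, coarse_grid.centers, DEFAULT_OPTICS)
        assert np.allclose(cube[0, 0], refl[0])
        assert truth["LAI"][0, 0] == pytest.approx(3.0)

    def test_all_water_truth_is_zero(self, coarse_grid):
        cube, truth, cmap = generate_nonveg_cube(8, 8, "water", grid=coarse_grid, seed=1)
        assert all(np.all(truth[t] == 0) for t in truth)
        assert np.all(cmap == "water")

    def test_cube_determinism(self, coarse_grid):
        a = ht.generate_synthetic_cube(20, 20, grid=coarse_grid, seed=13)[0]
        b = ht.generate_synthetic_cube(20, 20, grid=coarse_grid, seed=13)[0]
        assert np.array_equal(a, b)

    def test_trait_fields_within_ranges(self, coarse_grid):
        cube, truth, cmap = ht.generate_synthetic_cube(15, 15, grid=coarse_grid, seed=2)
        veg = cmap == "vegetated"
        assert truth["LAI"][veg].max() <= 8.0 and truth["LAI"][veg].min() >= 0.1
        assert np.all((cube >= 0) & (cube <= 1))
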