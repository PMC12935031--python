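"""Synthetic-world generators: determinism, built-in contrasts, recovery."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.integrate import quad

from terracarbon.config import BiasParams, DeltaSocModel, WorldConfig
from terracarbon.synthetic import (
    DEFAULT_PEAKS,
    generate_gridded_estimates,
    generate_phenology,
    generate_profiles,
    generate_sites,
    generate_spectra,
    generate_synthesis_records,
    generate_world,
    soc_depth_function,
    write_world,
)
from terracarbon.productivity import filter_synthesis


class TestConfigValidation:
    def test_layer_thickness_must_divide_depth(self):
        with pytest.raises(ValueError, match="divide"):
            WorldConfig(depth_max=100.0, layer_thickness=7.0)

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError, match="n_sites"):
            WorldConfig(n_sites=2)

    def test_extreme_arid_range_rejected(self):
        with pytest.raises(ValueError, match="arid"):
            WorldConfig(ai_range=(0.1, 2.0))

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            WorldConfig(soc_noise_sd=-0.1)


class TestSites:
    def test_seed_determinism(self):
        cfg = WorldConfig(n_sites=14, seed=1)
        pd.testing.assert_frame_equal(generate_sites(cfg), generate_sites(cfg))

    def test_ai_spans_configured_range(self):
        sites = generate_sites(WorldConfig(seed=3))
        assert sites["ai"].min() == pytest.approx(0.32)
        assert sites["ai"].max() == pytest.approx(2.17)
        assert np.allclose(sites["ai"], sites["map"] / sites["pet"], atol=1e-9)

    def test_noise_free_monotonicity(self):
        cfg = WorldConfig(seed=5, delta_soc_model=DeltaSocModel(
            slope=40.0, intercept=-10.0, site_sd=0.0))
        sites = generate_sites(cfg)
        assert (np.diff(sites["true_delta_soc"]) > 0).all()

    def test_regression_recovery_oracle(self):
        # OLS on 500 sites recovers the generating slope within 3 SE
        slope, sd = 57.0, 18.0
        cfg = WorldConfig(n_sites=500, seed=9, delta_soc_model=DeltaSocModel(
            slope=slope, intercept=-38.0, site_sd=sd))
        sites = generate_sites(cfg)
        fit = sps.linregress(sites["ai"], sites["true_delta_soc"])
        assert abs(fit.slope - slope) < 3 * fit.stderr


class TestProfiles:
    def test_climate_contrast_in_geochemistry(self, noise_free_config):
        cfg = noise_free_config
        rng = np.random.default_rng(0)
        humid = generate_profiles({"site_id": "H", "ai": 2.0, "true_delta_soc": 0.0}, cfg, rng)
        arid = generate_profiles({"site_id": "A", "ai": 0.4, "true_delta_soc": 0.0}, cfg, rng)
        assert humid["Fe_o"].mean() > arid["Fe_o"].mean()
        assert humid["Ca_ex"].mean() < arid["Ca_ex"].mean()
        assert humid["pH"].mean() < arid["pH"].mean()

    def test_monotone_decay_in_controls(self, noise_free_config):
        prof = generate_profiles({"site_id": "S", "ai": 1.0, "true_delta_soc": 0.0},
                                 noise_free_config, np.random.default_rng(1))
        for _, grp in prof[prof["position"] == "control"].groupby("profile_id"):
            grp = grp.sort_values("depth_top")
            assert grp["soc"].iloc[0] >= grp["soc"].iloc[-1]

    def test_fill_bump_integral_oracle(self, noise_free_config):
        # integral of (fill - control) SOC equals the configured burial bump
        cfg = noise_free_config
        site = {"site_id": "S", "ai": 1.0, "true_delta_soc": 0.0}
        prof = generate_profiles(site, cfg, np.random.default_rng(2))
        fill = prof[prof["position"] == "fill"].sort_values("depth_top")
        ctrl = prof[prof["position"] == "control"].sort_values("depth_top")
        thick = (fill["depth_bottom"] - fill["depth_top"]).to_numpy()
        diff_integral = float(((fill["soc"].to_numpy() - ctrl["soc"].to_numpy()) * thick).sum())
        soc0 = cfg.soc_surface_base + cfg.soc_surface_per_ai * 1.0
        amp = cfg.fill_bump_rel * soc0
        bump = quad(lambda z: amp * np.exp(-0.5 * ((z - cfg.fill_bump_center)
                                                   / cfg.fill_bump_width) ** 2),
                    0, cfg.depth_max)[0]
        assert diff_integral == pytest.approx(bump, rel=0.02)

    def test_invalid_depth_rejected(self):
        with pytest.raises(ValueError):
            WorldConfig(depth_max=-10.0)

    def test_texture_sums_to_100(self, demo_world):
        total = demo_world.horizons[["clay", "silt", "sand"]].sum(axis=1)
        assert np.allclose(total, 100.0, atol=0.5)

    def test_nonnegative_responses(self, demo_world):
        assert (demo_world.horizons["soc"] >= 0).all()
        assert (demo_world.horizons["spr"] >= 0).all()


class TestGridded:
    def test_identity_bias_reproduces_truth(self):
        truth = np.array([10.0, 30.0, 50.0])
        est = generate_gridded_estimates(truth, BiasParams(0.0, 1.0, 0.0),
                                         n_pixels=5, seed=0, pixel_sd=0.0)
        assert np.allclose(est.deltas["delta_mean"], truth)
        assert np.allclose(est.deltas["delta_se"], 0.0)

    def test_layer_conservation(self):
        est = generate_gridded_estimates([20.0, 40.0], BiasParams(), 5, seed=1)
        for (_, schema), grp in est.layers.groupby(["site_id", "schema"]):
            assert grp["stock"].sum() == pytest.approx(
                grp["total_stock"].iloc[0], abs=1e-9)

    def test_calibration_recovery_oracle(self):
        # regressing field truth on generated gridded means recovers the bias
        bias = BiasParams(alpha=5.0, beta=0.8, sigma=10.0)
        rng = np.random.default_rng(21)
        truth = rng.uniform(-20, 80, 1000)
        est = generate_gridded_estimates(truth, bias, n_pixels=10, seed=3,
                                         pixel_sd=0.0)
        g = est.deltas["delta_mean"].to_numpy()
        fit = sps.linregress(g, truth)
        n = len(truth)
        resid = truth - (fit.intercept + fit.slope * g)
        sigma_hat = np.sqrt(np.sum(resid**2) / (n - 2))
        assert abs(fit.slope - bias.beta) < 3 * fit.stderr
        assert abs(fit.intercept - bias.alpha) < 3 * fit.intercept_stderr
        assert abs(sigma_hat - bias.sigma) < 3 * bias.sigma / np.sqrt(2 * (n - 2))

    def test_pixel_count_validated(self):
        with pytest.raises(ValueError):
            generate_gridded_estimates([1.0], BiasParams(), n_pixels=1, seed=0)


class TestSpectra:
    def test_zero_amplitudes_flat_zero_baseline(self):
        spectra, truth = generate_spectra([{}], baseline_params=(0.0,), seed=0)
        assert np.allclose(-np.log10(spectra[0].values), 0.0)
        assert (truth.filter(like="true_height") == 0).all().all()

    def test_single_peak_max_equals_amplitude(self):
        spectra, _ = generate_spectra([{"arom": 0.4}], baseline_params=(0.0,), seed=0)
        absorb = -np.log10(spectra[0].values)
        assert absorb.max() == pytest.approx(0.4, rel=5e-3)  # grid discretization

    def test_truth_matches_analytic_gaussian_sum(self):
        amps = {"arom": 0.3, "acid": 0.5}
        _, truth = generate_spectra([amps], baseline_params=(0.05, 0.01), seed=0)
        for band, amp in amps.items():
            c_b, _ = DEFAULT_PEAKS[band]
            expected = sum(a * np.exp(-0.5 * ((c_b - DEFAULT_PEAKS[b][0])
                                              / DEFAULT_PEAKS[b][1]) ** 2)
                           for b, a in amps.items())
            assert truth[f"true_height_{band}"].iloc[0] == pytest.approx(expected)

    def test_nonmonotone_grid_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            generate_spectra([{}], wavenumbers=np.array([500.0, 499.0, 600.0]))


class TestPhenology:
    def test_constant_index_integral(self):
        series, truth = generate_phenology(season=(100, 200), amplitude=0.0,
                                           base=0.3, seed=0)
        assert truth == pytest.approx(0.3 * 101)  # inclusive day count

    def test_scaled_series_gives_31_percent(self):
        _, tpp_c = generate_phenology(season=(100, 280), seed=0, scale=1.0)
        _, tpp_t = generate_phenology(season=(100, 280), seed=0, scale=1.31)
        assert 100 * (tpp_t - tpp_c) / tpp_c == pytest.approx(31.0)

    def test_stored_integral_matches_quadrature(self):
        start, end, amp, base = 100, 280, 0.8, 0.05
        _, truth = generate_phenology(season=(start, end), amplitude=amp,
                                      base=base, seed=0)
        integral, _ = quad(
            lambda d: base + amp * np.sin(np.pi * (d - start) / (end - start)) ** 2,
            start, end, limit=200)
        # daily rectangle sum vs continuous integral: within 1%
        assert truth == pytest.approx(integral, rel=0.01)

    def test_invalid_season_rejected(self):
        with pytest.raises(ValueError):
            generate_phenology(season=(250, 100))


class TestSynthesisRecords:
    def test_clean_records_all_pass(self):
        rec = generate_synthesis_records(100, seed=0)
        included, excluded = filter_synthesis(rec)
        assert len(included) == 100 and excluded.empty

    def test_young_terrace_excluded(self):
        rec = generate_synthesis_records(10, seed=0)
        rec.loc[4, "terrace_age"] = 0.5
        included, excluded = filter_synthesis(rec)
        assert len(included) == 9
        assert excluded["study_id"].tolist() == [rec.loc[4, "study_id"]]

    def test_binomial_pass_rate_oracle(self):
        probs = {"missing_control": 0.1, "young": 0.05, "paddy": 0.1,
                 "fluvial_gravel": 0.05, "desert": 0.05}
        n = 2000
        rec = generate_synthesis_records(n, seed=42, flag_probs=probs)
        included, _ = filter_synthesis(rec)
        p_pass = np.prod([1 - p for p in probs.values()])
        se = np.sqrt(n * p_pass * (1 - p_pass))
        assert abs(len(included) - n * p_pass) < 3 * se


class TestWorld:
    def test_world_determinism(self):
        cfg = WorldConfig(n_sites=5, seed=7)
        w1, w2 = generate_world(cfg), generate_world(cfg)
        pd.testing.assert_frame_equal(w1.sites, w2.sites)
        pd.testing.assert_frame_equal(w1.horizons, w2.horizons)
        pd.testing.assert_frame_equal(w1.gridded.deltas, w2.gridded.deltas)
        pd.testing.assert_frame_equal(w1.phenology, w2.phenology)
        for s1, s2 in zip(w1.spectra, w2.spectra):
            assert np.array_equal(s1.values, s2.values)

    def test_expected_climate_contrast_in_large_world(self):
        # the humid-oxide / arid-cation contrast holds in expectation
        cfg = WorldConfig(n_sites=40, seed=13)
        world = generate_world(cfg)
        hz = world.horizons
        humid = hz[hz["ai"] >= 1.0]
        arid = hz[hz["ai"] < 1.0]
        assert humid["Fe_o"].mean() > arid["Fe_o"].mean()
        assert arid["Ca_ex"].mean() > humid["Ca_ex"].mean()

    def test_write_world_outputs(self, tmp_path, demo_world):
        paths = write_world(demo_world, tmp_path)
        for name in ("sites", "horizons", "gridded", "gridded_layers", "spectra",
                     "phenology", "synthesis", "truth"):
            assert paths[name].exists()

    def test_with_seed_returns_new_config(self):
        cfg = WorldConfig(seed=1)
        assert cfg.with_seed(2).seed == 2
        assert dataclasses.replace(cfg).seed == 1
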