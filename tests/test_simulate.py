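"""Synthetic vineyard generator: design structure, variance ground truth,
forward-modelled spectra."""

import numpy as np
import pandas as pd
import pytest

from vitespec.modeling import PLSTraitModel, SplitSpec, split_data
from vitespec.simulate import (
    SimConfig,
    SpectralLink,
    TraitSpec,
    analytic_baseline,
    baseline_template,
    default_config,
    generate_spectra,
    generate_traits,
)


class TestConfig:
    def test_proportions_over_one_rejected(self):
        with pytest.raises(ValueError, match="sum to <= 1"):
            TraitSpec(0, 1, {"cultivar": 0.7, "origin": 0.5})

    def test_link_bounds(self):
        with pytest.raises(ValueError):
            SpectralLink("N", 300, 10, 0.1)
        with pytest.raises(ValueError):
            SpectralLink("N", 700, 0, 0.1)

    def test_default_config_design(self):
        cfg = default_config()
        assert cfg.n_cultivars == 12
        assert cfg.n_varieties == 7
        assert cfg.n_leaves == 180
        assert len(cfg.trait_specs) == 12


class TestGenerateTraits:
    def test_leaf_count_and_metadata(self):
        cfg = default_config(seed=0)
        t = generate_traits(cfg)
        assert len(t) == 180
        assert t["leaf_id"].is_unique
        assert t.groupby("cultivar").size().eq(15).all()
        assert t["variety"].nunique() == 7
        # origin and colour constant within variety
        assert (t.groupby("variety")["origin"].nunique() == 1).all()
        assert (t.groupby("variety")["colour"].nunique() == 1).all()

    def test_bit_reproducible(self):
        cfg = default_config(seed=42)
        pd.testing.assert_frame_equal(generate_traits(cfg), generate_traits(cfg))

    def test_pure_residual_no_cultivar_structure(self):
        """All variance residual: cultivar means vary only by sampling noise,
        var of cultivar means ~ total_sd^2 / leaves_per_cultivar."""
        var_means = []
        for seed in range(100):
            cfg = SimConfig(
                trait_specs={"T": TraitSpec(0, 1, {})}, missing_rate=0, seed=seed
            )
            t = generate_traits(cfg)
            var_means.append(t.groupby("cultivar")["T"].mean().var(ddof=1))
        assert np.mean(var_means) == pytest.approx(1 / 15, rel=0.25)

    def test_pure_cultivar_degenerate_variance(self):
        cfg = SimConfig(
            trait_specs={"T": TraitSpec(5, 2, {"cultivar": 1.0})}, missing_rate=0, seed=1
        )
        t = generate_traits(cfg)
        assert (t.groupby("cultivar")["T"].nunique() == 1).all()
        assert t["T"].nunique() > 1

    def test_moment_recovery_of_cultivar_variance(self):
        """One-way ANOVA expected-mean-squares estimate of the cultivar
        variance averages to the configured 0.5 over replicates."""
        est = []
        for seed in range(200):
            cfg = SimConfig(
                trait_specs={"T": TraitSpec(0, 1, {"cultivar": 0.5})},
                missing_rate=0,
                seed=seed,
            )
            t = generate_traits(cfg)
            g = t.groupby("cultivar")["T"]
            k, n = 12, 15
            msb = n * g.mean().var(ddof=1)
            msw = (g.var(ddof=1) * (n - 1)).sum() / (k * (n - 1))
            est.append((msb - msw) / n)
        assert np.mean(est) == pytest.approx(0.5, abs=0.05)

    def test_missingness_rate(self):
        cfg = SimConfig(
            trait_specs={"T": TraitSpec(0, 1, {})}, missing_rate=0.1, seed=8
        )
        frac = generate_traits(cfg)["T"].isna().mean()
        assert 0.03 < frac < 0.2

    def test_empirical_proportions_converge(self):
        """Across replicates, REML-estimated proportions land within 0.1 of the
        configured values for a balanced design."""
        from vitespec.variation import fit_variance_components

        target = {"origin": 0.3, "cultivar": 0.4}
        sums = {"origin": 0.0, "cultivar": 0.0, "residual": 0.0}
        reps = 50
        for seed in range(reps):
            cfg = SimConfig(
                trait_specs={"T": TraitSpec(0, 1, dict(target))},
                missing_rate=0,
                seed=seed,
            )
            t = generate_traits(cfg)
            vc = fit_variance_components(t, "T", nesting=("origin", "cultivar"))
            sums["origin"] += vc.proportions["origin"]
            sums["cultivar"] += vc.proportions["cultivar"]
            sums["residual"] += vc.residual
        assert sums["cultivar"] / reps == pytest.approx(0.4, abs=0.1)
        assert sums["residual"] / reps == pytest.approx(0.3, abs=0.1)


class TestGenerateSpectra:
    def test_reflectance_bounds_and_grid(self, small_vineyard):
        _, table, spectra = small_vineyard
        assert spectra.wavelengths[0] == 400 and spectra.wavelengths[-1] == 2400
        assert spectra.n_bands == 2001
        assert spectra.reflectance.min() >= 0 and spectra.reflectance.max() <= 1

    def test_bit_reproducible(self, small_vineyard):
        cfg, table, spectra = small_vineyard
        again = generate_spectra(table, cfg)
        assert np.array_equal(spectra.reflectance, again.reflectance)

    def test_zero_strength_gives_baseline(self):
        cfg = SimConfig(
            trait_specs={"T": TraitSpec(0, 1, {})},
            links=[SpectralLink("T", 700, 30, 0.0)],
            missing_rate=0,
            spectral_noise_sd=0,
            seed=2,
        )
        sp = generate_spectra(generate_traits(cfg), cfg)
        assert np.all(sp.reflectance == sp.reflectance[0])

    def test_unknown_trait_link_rejected(self):
        cfg = SimConfig(
            trait_specs={"T": TraitSpec(0, 1, {})},
            links=[SpectralLink("missing", 700, 30, 0.1)],
            missing_rate=0,
            seed=2,
        )
        with pytest.raises(KeyError, match="missing"):
            generate_spectra(generate_traits(cfg), cfg)

    def test_noiseless_single_link_one_component_calibration(self, one_link_noiseless):
        """Noiseless single-factor spectra: one component nearly saturates
        the calibration fit."""
        from vitespec.plsr import fit_plsr

        _, table, spectra = one_link_noiseless
        y = table["N"].to_numpy()
        m = fit_plsr(spectra.reflectance[:100], y[:100], 1)
        pred = m.predict(spectra.reflectance[:100])
        ss_res = np.sum((y[:100] - pred) ** 2)
        ss_tot = np.sum((y[:100] - y[:100].mean()) ** 2)
        assert 1 - ss_res / ss_tot >= 0.99

    def test_noise_degrades_validation_r2(self):
        """Tenfold more band noise strictly lowers validation R2, seed by seed."""
        def val_r2(noise, seed):
            cfg = SimConfig(
                trait_specs={"N": TraitSpec(2.75, 0.35, {"cultivar": 0.5})},
                links=[SpectralLink("N", 1510, 40, 0.05)],
                missing_rate=0,
                spectral_noise_sd=noise,
                seed=seed,
            )
            t = generate_traits(cfg)
            sp = generate_spectra(t, cfg)
            cal, val = split_data(t, SplitSpec(seed=2))
            res = PLSTraitModel.from_dataframes(sp, t, "N", leaf_ids=cal).fit()
            yv = t.set_index("leaf_id").loc[val, "N"].to_numpy()
            return res.evaluate(sp.select(val).reflectance, yv).r2

        for seed in (1, 2, 3):
            assert val_r2(0.02, seed) < val_r2(0.002, seed)


class TestBaseline:
    def test_packaged_template_matches_analytic_recipe(self):
        wl, refl = baseline_template()
        assert wl.size == 2001
        assert np.allclose(refl, analytic_baseline(wl), atol=1e-6)

    def test_template_shape_is_leaf_like(self):
        wl, refl = baseline_template()
        vis = refl[(wl >= 400) & (wl <= 680)].mean()
        nir = refl[(wl >= 800) & (wl <= 1300)].mean()
        dip_1940 = refl[np.argmin(np.abs(wl - 1940))]
        assert vis < 0.15 < nir
        assert dip_1940 < nir * 0.75
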