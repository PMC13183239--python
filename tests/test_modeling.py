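"""Split rules, PRESS selection, metrics, jackknife, VIP summaries,
CV-R2 correlation, and the model/results wrapper."""

import numpy as np
import pandas as pd
import pytest

from vitespec.modeling import (
    STATUS_NO_COMPONENT,
    CVResult,
    PLSTraitModel,
    SplitSpec,
    correlate_r2_cv,
    evaluate,
    jackknife_uncertainty,
    loo_press,
    split_data,
    vip_region_summary,
)
from vitespec.plsr import fit_plsr


def _ids(n):
    return pd.DataFrame({"leaf_id": [f"L{i:03d}" for i in range(n)]})


class TestSplitData:
    @pytest.mark.parametrize(
        "n,n_cal,n_val",
        [(173, 138, 35), (172, 137, 35), (163, 130, 33), (160, 128, 32)],
    )
    def test_random_split_uses_floor_rule(self, n, n_cal, n_val):
        cal, val = split_data(_ids(n), SplitSpec(seed=0))
        assert (len(cal), len(val)) == (n_cal, n_val)

    def test_group_balanced_ceil_rule(self):
        # 12 cultivars of 14-15 leaves summing to 173 -> 3 validation each
        sizes = [15] * 5 + [14] * 7
        t = _ids(173)
        t["cultivar"] = np.repeat([f"c{j:02d}" for j in range(12)], sizes)
        cal, val = split_data(t, SplitSpec(strategy="group_balanced", seed=0))
        assert len(val) == 36
        per_group = t.set_index("leaf_id").loc[val, "cultivar"].value_counts()
        assert (per_group == 3).all()

    def test_partition_properties(self):
        t = _ids(57)
        t["cultivar"] = [f"c{i % 5}" for i in range(57)]
        for spec in (SplitSpec(seed=3), SplitSpec(strategy="group_balanced", seed=3)):
            cal, val = split_data(t, spec)
            assert set(cal) | set(val) == set(t["leaf_id"])
            assert not set(cal) & set(val)

    def test_group_balanced_every_group_in_validation(self):
        t = _ids(60)
        t["cultivar"] = [f"c{i % 6}" for i in range(60)]
        _, val = split_data(t, SplitSpec(strategy="group_balanced", seed=1))
        assert t.set_index("leaf_id").loc[val, "cultivar"].nunique() == 6

    def test_singleton_group_rejected_by_name(self):
        t = _ids(12)
        t["cultivar"] = ["solo"] + ["c"] * 11
        with pytest.raises(ValueError, match="solo"):
            split_data(t, SplitSpec(strategy="group_balanced", seed=0))

    def test_seeded_reproducibility(self):
        t = _ids(50)
        assert split_data(t, SplitSpec(seed=9)) == split_data(t, SplitSpec(seed=9))


class TestLooPress:
    def test_selection_is_argmin(self):
        cv = CVResult(press=np.array([5.0, 3.0, 4.0]), selected=1, a_max=2)
        assert cv.selected == 1 and not cv.failed

    def test_tie_selects_fewest_and_flags_failure_at_zero(self, rng):
        X, y = rng.normal(size=(12, 5)), rng.normal(size=12)
        cv = loo_press(X, y, 3)
        # contract checks on a real run plus the documented tie rule
        assert cv.press.shape == (4,)
        assert np.all(cv.press >= 0)
        tied = CVResult(press=np.array([3.0, 3.0, 4.0]), selected=0, a_max=2)
        assert tied.failed

    def test_matches_brute_force_refits(self, rng):
        """PRESS(a) equals an explicit refit-per-left-out-sample loop."""
        for _ in range(20):
            X, y = rng.normal(size=(10, 6)), rng.normal(size=10)
            cv = loo_press(X, y, 3)
            brute = np.zeros(4)
            for i in range(10):
                keep = np.arange(10) != i
                brute[0] += (y[i] - y[keep].mean()) ** 2
                for a in range(1, 4):
                    m = fit_plsr(X[keep], y[keep], a)
                    brute[a] += (y[i] - m.predict(X[i])[0]) ** 2
            assert np.max(np.abs(cv.press - brute)) < 1e-10

    def test_small_calibration_rejected(self, rng):
        with pytest.raises(ValueError, match="too small"):
            loo_press(rng.normal(size=(4, 3)), rng.normal(size=4), 3)


class TestEvaluate:
    def test_perfect_predictions(self):
        m = evaluate([1, 2, 3], [1, 2, 3])
        assert (m.r2, m.rmse, m.pct_rmse) == (1.0, 0.0, 0.0)

    def test_mean_prediction_gives_zero_r2(self):
        m = evaluate([1, 2, 3], [2, 2, 2])
        assert m.r2 == pytest.approx(0.0)
        assert m.rmse == pytest.approx(0.8165, abs=1e-4)
        assert m.pct_rmse == pytest.approx(40.82, abs=0.01)

    def test_negative_out_of_sample_r2(self):
        """Worse-than-mean predictions give negative R2 = 1 - SSres/SStot."""
        assert evaluate([1, 2, 3], [3, 1, 2]).r2 == pytest.approx(-2.0)

    def test_constant_observed_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            evaluate([2, 2, 2], [1, 2, 3])


class TestJackknife:
    def test_zero_noise_rank_one_gives_degenerate_ci(self, rng):
        """No sampling variability in a noiseless rank-1 problem: CI width ~ 0."""
        z = rng.normal(size=40)
        load = rng.normal(size=25)
        X = np.outer(z, load)
        y = 2.0 + 3.0 * z
        jk = jackknife_uncertainty(X[:30], y[:30], 1, X[30:], B=100, seed=0)
        width = jk["ci_hi"] - jk["ci_lo"]
        assert np.max(width) < 1e-6

    def test_prediction_interval_contains_confidence_interval(self, small_vineyard):
        _, table, spectra = small_vineyard
        obs = table.dropna(subset=["N"])
        cal, val = split_data(obs, SplitSpec(seed=4))
        res = PLSTraitModel.from_dataframes(spectra, obs, "N", leaf_ids=cal).fit(ncomp=3)
        jk = res.jackknife(spectra.select(val).reflectance, B=100, seed=5)
        assert np.all(jk["pi_lo"] <= jk["ci_lo"]) and np.all(jk["ci_hi"] <= jk["pi_hi"])
        assert jk["sigma_resid"] > 0

    def test_delete_one_mode_refit_count(self, rng):
        X, y = rng.normal(size=(15, 6)), rng.normal(size=15)
        jk = jackknife_uncertainty(X, y, 2, X[:3], mode="delete-one", seed=0)
        assert jk["n_refits"] == 15

    def test_more_calibration_data_shrinks_ci(self):
        """Doubling calibration size does not widen the median CI."""
        from vitespec.simulate import SimConfig, SpectralLink, TraitSpec
        from vitespec.simulate import generate_spectra, generate_traits

        widths = {}
        for rows, key in ((3, "small"), (6, "large")):
            per_seed = []
            for seed in (21, 22, 23):
                cfg = SimConfig(
                    rows_per_cultivar=rows,
                    trait_specs={"N": TraitSpec(2.75, 0.35, {"cultivar": 0.5})},
                    links=[SpectralLink("N", 1510, 40, 0.05)],
                    missing_rate=0,
                    spectral_noise_sd=0.02,
                    seed=seed,
                )
                t = generate_traits(cfg)
                sp = generate_spectra(t, cfg)
                cal, val = split_data(t, SplitSpec(seed=2))
                res = PLSTraitModel.from_dataframes(sp, t, "N", leaf_ids=cal).fit(ncomp=2)
                jk = res.jackknife(sp.select(val).reflectance, B=150, seed=3)
                per_seed.append(np.median(jk["ci_hi"] - jk["ci_lo"]))
            widths[key] = np.median(per_seed)
        assert widths["large"] <= widths["small"]


class TestVIPRegions:
    def test_uniform_vip(self):
        wl = np.arange(400.0, 2401.0)
        out = vip_region_summary(np.ones(wl.size), wl)
        assert set(out["region"]) == {"VIS", "RED_EDGE", "NIR", "SWIR1", "SWIR2"}
        assert (out["mean_vip"] == 1.0).all()
        assert (out["frac_ge_0.8"] == 1.0).all()

    def test_link_at_700nm_peaks_in_red_edge(self, rng):
        """A synthetic absorption feature at 700 nm makes RED_EDGE the
        top-VIP region."""
        from vitespec.simulate import SimConfig, SpectralLink, TraitSpec
        from vitespec.simulate import generate_spectra, generate_traits

        cfg = SimConfig(
            trait_specs={"T": TraitSpec(0, 1, {"cultivar": 0.5})},
            links=[SpectralLink("T", 700, 20, 0.06)],
            missing_rate=0,
            spectral_noise_sd=0.002,
            seed=6,
        )
        t = generate_traits(cfg)
        sp = generate_spectra(t, cfg)
        res = PLSTraitModel(sp.reflectance, t["T"].to_numpy(), wavelengths=sp.wavelengths).fit(ncomp=2)
        out = res.vip_regions().set_index("region")
        # VIS contains the same band (regions overlap), so assert the
        # red-edge max equals the global max rather than a unique winner
        assert out.loc["RED_EDGE", "max_vip"] == pytest.approx(
            out["max_vip"].max(), rel=1e-12
        )
        assert out.loc["RED_EDGE", "max_vip"] > out.loc["SWIR1", "max_vip"]

    def test_no_overlap_region_omitted(self):
        wl = np.arange(400.0, 700.0)  # no SWIR coverage
        out = vip_region_summary(np.ones(wl.size), wl)
        assert "SWIR1" not in set(out["region"])


class TestCorrelation:
    def test_exact_collinearity(self):
        r, _ = correlate_r2_cv([10, 20, 30], [0.5, 0.3, 0.1])
        assert r == pytest.approx(-1.0)

    def test_missing_pairs_dropped(self):
        r, _ = correlate_r2_cv([10, 20, 30, 40], [0.5, np.nan, 0.3, 0.1])
        assert -1 <= r <= 0

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            correlate_r2_cv([1, 2], [0.1, 0.2])

    def test_published_tables_negative_and_ordered(self):
        """Printed per-trait CVs vs validation R2: both split strategies
        correlate negatively, more strongly for the cultivar split."""
        import importlib.resources as resources

        with resources.files("vitespec.data").joinpath("reference_model_fits.csv").open() as fh:
            ref = pd.read_csv(fh)
        r_cult, _ = correlate_r2_cv(ref["cv"], ref["r2_cultivar"])
        r_rand, _ = correlate_r2_cv(ref["cv"], ref["r2_random"])
        assert r_cult < 0 and r_rand < 0
        assert r_cult < r_rand


class TestModelResults:
    def test_fit_select_evaluate_reproducible(self, small_vineyard):
        _, table, spectra = small_vineyard
        obs = table.dropna(subset=["E"])

        def run():
            cal, val = split_data(obs, SplitSpec(seed=7))
            res = PLSTraitModel.from_dataframes(spectra, obs, "E", leaf_ids=cal).fit()
            yv = obs.set_index("leaf_id").loc[val, "E"].to_numpy()
            met = res.evaluate(spectra.select(val).reflectance, yv)
            return res.ncomp, met.r2, met.rmse

        assert run() == run()

    def test_zero_variance_trait_reports_no_component(self, small_vineyard):
        _, table, spectra = small_vineyard
        t = table.copy()
        t["flat"] = 1.0
        res = PLSTraitModel.from_dataframes(spectra, t, "flat").fit(ncomp=2)
        assert res.status == STATUS_NO_COMPONENT
        assert res.ncomp == 0
        with pytest.raises(ValueError):
            res.vip()

    def test_summary_mentions_trait_and_ncomp(self, one_link_noiseless):
        _, table, spectra = one_link_noiseless
        res = PLSTraitModel.from_dataframes(spectra, table, "N").fit(ncomp=2)
        s = res.summary()
        assert "N" in s and "Components" in s and "ok" in s
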