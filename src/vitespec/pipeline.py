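"""End-to-end orchestration: data -> screening -> variance partitioning ->
per-trait PLSR under both splitting strategies -> report bundle.

Stage order: derive -> transform + normality screen -> cell-wise IQR
outlier masking -> split -> LOO-PRESS component selection -> final
calibration fit -> validation metrics -> jackknife intervals. Outliers are
masked before splitting. Every output is a CSV (plus a JSON manifest), and
for a fixed configuration the whole bundle is byte-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .modeling import (
    STATUS_OK,
    PLSTraitModel,
    SplitSpec,
    correlate_r2_cv,
    split_data,
)
from .simulate import SimConfig, default_config, generate_spectra, generate_traits
from .spectra import SpectraSet, read_spectra, region_of, trim_and_resample
from .traits import (
    DEFAULT_TRANSFORMS,
    METADATA_COLUMNS,
    apply_transforms,
    iqr_outlier_filter,
    summary_table,
)
from .variation import anova_tukey, cultivar_means, fit_variance_components

__all__ = ["PipelineConfig", "run_pipeline"]


class PipelineError(RuntimeError):
    """Raised with the failing stage's name prefixed."""


@dataclass
class PipelineConfig:
    """Everything one analysis run needs. Exactly one input source:
    ``simulate`` (a SimConfig) or ``files`` (paths to trait + spectra CSVs)."""

    simulate: SimConfig | None = None
    traits_path: str | None = None
    spectra_path: str | None = None
    spectra_layout: str = "wide"
    window: tuple[float, float, float] = (400.0, 2400.0, 1.0)
    outlier_factor: float = 2.0
    transforms: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_TRANSFORMS))
    split_seeds: dict[str, int] = field(default_factory=lambda: {"random": 11, "cultivar": 12})
    a_max: int = 15
    scale: bool = False
    jackknife_B: int = 200
    jackknife_leave_frac: float = 0.2
    jackknife_seed: int = 13
    run_jackknife: bool = True
    traits: list[str] | None = None      # None = every trait column present
    output_dir: str = "vitespec_out"

    def __post_init__(self) -> None:
        has_sim = self.simulate is not None
        has_files = self.traits_path is not None or self.spectra_path is not None
        if has_sim == has_files:
            raise ValueError("configure exactly one input source: simulate or files")
        if has_files and (self.traits_path is None or self.spectra_path is None):
            raise ValueError("file input needs both traits_path and spectra_path")

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        src = raw.get("input", {})
        sim = None
        traits_path = spectra_path = None
        layout = "wide"
        if "simulate" in src:
            sim_raw = src["simulate"] or {}
            sim = default_config(seed=sim_raw.get("seed", 0))
            if seed is not None:
                sim = type(sim)(**{**sim.__dict__, "seed": seed})
        elif "files" in src:
            traits_path = src["files"]["traits"]
            spectra_path = src["files"]["spectra"]
            layout = src["files"].get("layout", "wide")
        win = raw.get("window", {})
        jk = raw.get("jackknife", {})
        pl = raw.get("plsr", {})
        transforms = raw.get("transforms", "default")
        if transforms == "default":
            transforms = dict(DEFAULT_TRANSFORMS)
        return cls(
            simulate=sim,
            traits_path=traits_path,
            spectra_path=spectra_path,
            spectra_layout=layout,
            window=(win.get("lower", 400.0), win.get("upper", 2400.0), win.get("step", 1.0)),
            outlier_factor=raw.get("outlier_factor", 2.0),
            transforms=transforms,
            split_seeds=raw.get("splits", {"random": 11, "cultivar": 12}),
            a_max=pl.get("a_max", 15),
            scale=pl.get("scale", False),
            jackknife_B=jk.get("B", 200),
            jackknife_leave_frac=jk.get("leave_frac", 0.2),
            jackknife_seed=jk.get("seed", 13),
            run_jackknife=jk.get("enabled", True),
            traits=raw.get("traits"),
            output_dir=raw.get("output_dir", "vitespec_out"),
        )


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"[stage: {name}] {exc}") from exc
        return wrapped
    return deco


@_stage("load")
def _load_inputs(config: PipelineConfig, log) -> tuple[pd.DataFrame, SpectraSet]:
    if config.simulate is not None:
        log(f"simulating vineyard (seed={config.simulate.seed})")
        table = generate_traits(config.simulate)
        spectra = generate_spectra(table, config.simulate)
    else:
        log(f"reading traits from {config.traits_path}")
        table = pd.read_csv(config.traits_path)
        log(f"reading spectra from {config.spectra_path}")
        spectra = read_spectra(config.spectra_path, layout=config.spectra_layout)
    lower, upper, step = config.window
    spectra = trim_and_resample(spectra, lower, upper, step)
    log(f"{len(table)} leaves, {spectra.n_bands} bands ({lower:g}-{upper:g} nm)")
    return table, spectra


def run_pipeline(config: PipelineConfig, log=None) -> dict:
    """Run the full analysis; write the report bundle under ``output_dir``.

    Returns a dict with the in-memory tables (summary, variance components,
    ANOVA, model fits, VIP, intervals) plus the manifest.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def _log(msg: str) -> None:
        log_lines.append(msg)
        if log is not None:
            log(msg)

    table, spectra = _load_inputs(config, _log)

    # ---- screen: transforms + summary statistics ----------------------
    try:
        table = apply_transforms(table, config.transforms)
        trait_cols = config.traits or [
            c for c in table.columns if c not in METADATA_COLUMNS
        ]
        summary = summary_table(table, trait_cols)
    except Exception as exc:
        raise PipelineError(f"[stage: screen] {exc}") from exc

    # ---- outlier masking (cells only, before splitting) ---------------
    outlier_counts: dict[str, int] = {}
    try:
        for t in trait_cols:
            keep = iqr_outlier_filter(table[t], factor=config.outlier_factor)
            removed = int((~keep).sum())
            outlier_counts[t] = removed
            if removed:
                table.loc[~keep, t] = np.nan
                _log(f"outliers removed for {t}: {removed}")
    except Exception as exc:
        raise PipelineError(f"[stage: outliers] {exc}") from exc

    # ---- variance partitioning + ANOVA --------------------------------
    vc_rows, anova_rows, tukey_frames = [], [], []
    try:
        for t in trait_cols:
            vc = fit_variance_components(table, t)
            vc_rows.append({"trait": t, **vc.as_dict(), "method": vc.method})
            ar = anova_tukey(table, t)
            anova_rows.append(
                {
                    "trait": t,
                    "F": ar.f_statistic,
                    "p": ar.p_value,
                    "n_groups": len(ar.group_means),
                    "degenerate": ar.degenerate,
                }
            )
            tk = ar.pairwise.copy()
            tk.insert(0, "trait", t)
            tukey_frames.append(tk)
        means = cultivar_means(table, trait_cols)
    except Exception as exc:
        raise PipelineError(f"[stage: variation] {exc}") from exc

    # ---- PLSR per trait x split ---------------------------------------
    fit_rows, vip_frames, interval_frames = [], [], []
    try:
        for t in trait_cols:
            obs = table.dropna(subset=[t])
            for strategy, key in (("random", "random"), ("cultivar", "cultivar")):
                spec = SplitSpec(
                    strategy="random" if strategy == "random" else "group_balanced",
                    seed=config.split_seeds.get(key, 0),
                )
                cal_ids, val_ids = split_data(obs, spec)
                model = PLSTraitModel.from_dataframes(
                    spectra, obs, t, leaf_ids=cal_ids, scale=config.scale,
                    a_max=min(config.a_max, len(cal_ids) - 2),
                )
                res = model.fit()
                Xv = spectra.select(val_ids).reflectance
                yv = obs.set_index("leaf_id").loc[val_ids, t].to_numpy(dtype=float)
                row = {
                    "trait": t,
                    "split": strategy,
                    "n_obs": len(obs),
                    "n_cal": len(cal_ids),
                    "n_val": len(val_ids),
                    "n_comp": res.ncomp,
                    "status": res.status,
                }
                if res.status == STATUS_OK:
                    met = res.evaluate(Xv, yv)
                    row.update(
                        RMSE=met.rmse, R2=met.r2, pct_RMSE=met.pct_rmse, bias=met.bias
                    )
                    vip = res.vip()
                    vf = pd.DataFrame(
                        {
                            "trait": t,
                            "split": strategy,
                            "wavelength_nm": model.wavelengths,
                            "vip": vip,
                        }
                    )
                    vf["regions"] = [
                        "|".join(sorted(region_of(w))) for w in model.wavelengths
                    ]
                    vip_frames.append(vf)
                    if config.run_jackknife:
                        jk = res.jackknife(
                            Xv,
                            B=config.jackknife_B,
                            leave_frac=config.jackknife_leave_frac,
                            seed=config.jackknife_seed,
                        )
                        interval_frames.append(
                            pd.DataFrame(
                                {
                                    "trait": t,
                                    "split": strategy,
                                    "leaf_id": val_ids,
                                    "observed": yv,
                                    "predicted_mean": jk["pred_mean"],
                                    "ci_lo": jk["ci_lo"],
                                    "ci_hi": jk["ci_hi"],
                                    "pi_lo": jk["pi_lo"],
                                    "pi_hi": jk["pi_hi"],
                                }
                            )
                        )
                else:
                    row.update(RMSE=np.nan, R2=np.nan, pct_RMSE=np.nan, bias=np.nan)
                    _log(f"{t} [{strategy}]: {res.status}")
                fit_rows.append(row)
                _log(
                    f"fit {t} [{strategy}]: n_cal={len(cal_ids)} n_val={len(val_ids)} "
                    f"ncomp={res.ncomp}"
                )
    except Exception as exc:
        raise PipelineError(f"[stage: plsr] {exc}") from exc

    # ---- assemble + write --------------------------------------------
    fits = pd.DataFrame(fit_rows)
    vc_table = pd.DataFrame(vc_rows)
    anova_table = pd.DataFrame(anova_rows)
    tukey_table = (
        pd.concat(tukey_frames, ignore_index=True) if tukey_frames else pd.DataFrame()
    )
    vip_table = (
        pd.concat(vip_frames, ignore_index=True) if vip_frames else pd.DataFrame()
    )
    intervals = (
        pd.concat(interval_frames, ignore_index=True)
        if interval_frames
        else pd.DataFrame()
    )

    corr = {}
    for strategy in ("random", "cultivar"):
        sub = fits[(fits["split"] == strategy) & (fits["status"] == STATUS_OK)]
        merged = sub.merge(summary[["trait", "cv"]], on="trait")
        if len(merged) >= 3:
            r, p = correlate_r2_cv(merged["cv"], merged["R2"])
            corr[strategy] = {"r": r, "p": p, "n_traits": int(len(merged))}

    manifest = {
        "package_version": __version__,
        "seeds": {
            "simulate": config.simulate.seed if config.simulate else None,
            "splits": config.split_seeds,
            "jackknife": config.jackknife_seed,
        },
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "n_leaves": int(len(table)),
        "n_bands": int(spectra.n_bands),
        "outliers_removed": outlier_counts,
        "traits": trait_cols,
        "cv_r2_correlation": corr,
        "rows": {
            "model_fits": int(len(fits)),
            "summary_stats": int(len(summary)),
            "variance_components": int(len(vc_table)),
        },
    }

    float_fmt = "%.10g"
    summary.to_csv(out / "summary_stats.csv", index=False, float_format=float_fmt)
    vc_table.to_csv(out / "variance_components.csv", index=False, float_format=float_fmt)
    anova_table.to_csv(out / "anova.csv", index=False, float_format=float_fmt)
    tukey_table.to_csv(out / "tukey_pairwise.csv", index=False, float_format=float_fmt)
    means.to_csv(out / "cultivar_means.csv", index=False, float_format=float_fmt)
    fits.to_csv(out / "model_fits.csv", index=False, float_format=float_fmt)
    vip_table.to_csv(out / "vip_scores.csv", index=False, float_format=float_fmt)
    intervals.to_csv(out / "intervals.csv", index=False, float_format=float_fmt)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    (out / "run.log").write_text("\n".join(log_lines) + "\n")

    return {
        "summary": summary,
        "variance_components": vc_table,
        "anova": anova_table,
        "tukey": tukey_table,
        "cultivar_means": means,
        "model_fits": fits,
        "vip": vip_table,
        "intervals": intervals,
        "manifest": manifest,
    }
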