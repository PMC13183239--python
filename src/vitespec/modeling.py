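"""The spectra-to-trait modelling protocol around the PLS1 core.

Provides the calibration/validation split rules, leave-one-out PRESS
component selection, validation metrics, repeated-subsample ("jackknife")
uncertainty, VIP region summaries and the CV-vs-R2 correlation — and wraps
them in a statsmodels-style pair of objects:

    model = PLSTraitModel.from_dataframes(spectra, trait_table, trait="N")
    res = model.fit()          # LOO-PRESS component selection
    print(res.summary())
    metrics = res.evaluate(X_val, y_val)

A selected component count of 0 is a *model outcome* ("no latent component
explains the covariance"), carried as a status flag, never an exception.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .plsr import PLSRModel, fit_plsr
from .spectra import REGIONS, SpectraSet, SpectralRegion

__all__ = [
    "SplitSpec",
    "CVResult",
    "Metrics",
    "split_data",
    "loo_press",
    "evaluate",
    "jackknife_uncertainty",
    "vip_region_summary",
    "correlate_r2_cv",
    "PLSTraitModel",
    "PLSTraitResults",
]

STATUS_OK = "ok"
STATUS_NO_COMPONENT = "no latent component"

#: Hard cap on the component search; the search never exceeds n_cal - 2.
DEFAULT_A_MAX = 15


@dataclass(frozen=True)
class SplitSpec:
    """Calibration/validation split specification.

    ``random``: calibration = floor(cal_fraction * n) leaves sampled without
    replacement. ``group_balanced``: every group (cultivar) contributes
    ceil((1 - cal_fraction) * n_k) leaves to validation, so each group is
    represented in both halves.
    """

    strategy: str = "random"
    cal_fraction: float = 0.8
    group_key: str = "cultivar"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in ("random", "group_balanced"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if not 0 < self.cal_fraction < 1:
            raise ValueError("cal_fraction must be in (0, 1)")


def split_data(
    table: pd.DataFrame, spec: SplitSpec, id_column: str = "leaf_id"
) -> tuple[list[str], list[str]]:
    """Partition leaf ids into (calibration, validation) under ``spec``."""
    n = len(table)
    if n < 10:
        raise ValueError("need at least 10 rows to split")
    rng = np.random.default_rng(spec.seed)
    ids = table[id_column].astype(str).to_numpy()

    if spec.strategy == "random":
        n_cal = math.floor(spec.cal_fraction * n)
        perm = rng.permutation(n)
        cal = sorted(ids[perm[:n_cal]].tolist())
        val = sorted(ids[perm[n_cal:]].tolist())
        return cal, val

    val: list[str] = []
    cal: list[str] = []
    for group, g in table.groupby(spec.group_key, sort=True):
        gids = g[id_column].astype(str).to_numpy()
        if gids.size < 2:
            raise ValueError(f"group {group!r} has a single member; cannot split")
        n_val = math.ceil((1.0 - spec.cal_fraction) * gids.size)
        perm = rng.permutation(gids.size)
        val.extend(gids[perm[:n_val]].tolist())
        cal.extend(gids[perm[n_val:]].tolist())
    return sorted(cal), sorted(val)


@dataclass
class CVResult:
    """PRESS per candidate component count 0..A_max and the selected count.

    The selection is argmin with ties broken toward fewer components; two
    PRESS values are treated as tied when they differ by less than the
    double-precision resolution of the baseline PRESS (1e-8 * PRESS(0)),
    so numerically indistinguishable minima never inflate the component
    count. selected == 0 means the leave-one-out mean outpredicts every
    latent component ("no latent component explains the covariance").
    """

    press: np.ndarray          # length A_max + 1, index = component count
    selected: int
    a_max: int

    @property
    def failed(self) -> bool:
        return self.selected == 0


def _loo_predictions(X: np.ndarray, y: np.ndarray, a_max: int,
                     scale: bool = False) -> np.ndarray:
    """Leave-one-out predictions, shape (n, a_max + 1); column a uses a
    components (column 0 is the leave-one-out mean)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    preds = np.empty((n, a_max + 1))
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        yi = y[keep]
        preds[i, 0] = yi.mean()
        m = fit_plsr(X[keep], yi, a_max, scale=scale)
        for a in range(1, a_max + 1):
            preds[i, a] = m.predict(X[i], ncomp=a)[0]
    return preds


def loo_press(X_cal: np.ndarray, y_cal: np.ndarray, a_max: int,
              scale: bool = False) -> CVResult:
    """Leave-one-out PRESS over component counts 0..a_max.

    PRESS(a) = sum_i (y_i - yhat_{-i, a})^2, one refit per left-out leaf
    (n_cal fits in total).
    """
    y = np.asarray(y_cal, dtype=float).ravel()
    n = y.size
    if n < a_max + 2:
        raise ValueError(f"n_cal={n} too small for a_max={a_max} (need n >= a_max + 2)")
    preds = _loo_predictions(X_cal, y, a_max, scale=scale)
    press = ((preds - y[:, None]) ** 2).sum(axis=0)
    # smallest component count whose PRESS is within floating-point
    # resolution of the minimum (ties break toward fewer components)
    tol = 1e-8 * press[0]
    selected = int(np.flatnonzero(press <= press.min() + tol)[0])
    return CVResult(press=press, selected=selected, a_max=a_max)


@dataclass
class Metrics:
    """Validation-set performance: R2 (1 - SSres/SStot, may be negative),
    RMSE in trait units, %RMSE relative to the observed range, and bias."""

    r2: float
    rmse: float
    pct_rmse: float
    bias: float
    n: int


def evaluate(observed, predicted, trait: str = "") -> Metrics:
    o = np.asarray(observed, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if o.size != p.size or o.size < 2:
        raise ValueError("observed and predicted must have equal length >= 2")
    ss_tot = float(((o - o.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError(f"constant observed values for {trait or 'trait'}; R2 undefined")
    ss_res = float(((o - p) ** 2).sum())
    rmse = math.sqrt(ss_res / o.size)
    rng = float(o.max() - o.min())
    return Metrics(
        r2=1.0 - ss_res / ss_tot,
        rmse=rmse,
        pct_rmse=100.0 * rmse / rng,
        bias=float((p - o).mean()),
        n=int(o.size),
    )


def jackknife_uncertainty(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    ncomp: int,
    X_val: np.ndarray,
    B: int = 500,
    leave_frac: float = 0.2,
    seed: int = 0,
    scale: bool = False,
    mode: str = "subsample",
) -> dict:
    """Model uncertainty by repeated refitting on perturbed calibration sets.

    ``subsample`` mode refits B times, each on a random (1 - leave_frac)
    fraction of the calibration leaves; ``delete-one`` is the classical
    jackknife (B then equals n_cal). Returns per-band coefficient percentile
    envelopes, and per-validation-leaf mean prediction with 95% confidence
    intervals (percentiles of the B predictions) and prediction intervals
    (CI widened by +-1.96 * sigma_resid, the LOO residual SD at ``ncomp``).
    """
    X_cal = np.atleast_2d(np.asarray(X_cal, dtype=float))
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    X_val = np.atleast_2d(np.asarray(X_val, dtype=float))
    n = y_cal.size
    if ncomp < 1:
        raise ValueError("jackknife requires a model with >= 1 component")
    rng = np.random.default_rng(seed)

    if mode == "delete-one":
        subsets = [np.delete(np.arange(n), i) for i in range(n)]
    elif mode == "subsample":
        keep = max(int(round((1.0 - leave_frac) * n)), ncomp + 2)
        if B < 1 or keep < 1:
            raise ValueError("need B >= 1 and a non-empty retained subsample")
        subsets = [rng.permutation(n)[:keep] for _ in range(B)]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    coefs = np.empty((len(subsets), X_cal.shape[1]))
    preds = np.empty((len(subsets), X_val.shape[0]))
    for b, rows in enumerate(subsets):
        m = fit_plsr(X_cal[rows], y_cal[rows], ncomp, scale=scale)
        coefs[b] = m.coefficients()
        preds[b] = m.predict(X_val)

    loo = _loo_predictions(X_cal, y_cal, ncomp, scale=scale)[:, ncomp]
    sigma_resid = float(np.std(y_cal - loo, ddof=1))

    ci_lo, ci_hi = np.percentile(preds, [2.5, 97.5], axis=0)
    return {
        "coef_mean": coefs.mean(axis=0),
        "coef_lo": np.percentile(coefs, 2.5, axis=0),
        "coef_hi": np.percentile(coefs, 97.5, axis=0),
        "pred_mean": preds.mean(axis=0),
        "ci_lo": ci_lo,
        "ci_hi": ci_hi,
        "pi_lo": ci_lo - 1.96 * sigma_resid,
        "pi_hi": ci_hi + 1.96 * sigma_resid,
        "sigma_resid": sigma_resid,
        "n_refits": len(subsets),
    }


def vip_region_summary(
    vip_scores: np.ndarray,
    wavelengths: np.ndarray,
    regions: tuple[SpectralRegion, ...] = REGIONS,
    thresholds: tuple[float, ...] = (0.8, 1.0),
) -> pd.DataFrame:
    """Mean/max VIP and fraction of bands above each threshold, per region.

    Regions with no band on the model grid are omitted.
    """
    vip_scores = np.asarray(vip_scores, dtype=float)
    wavelengths = np.asarray(wavelengths, dtype=float)
    if vip_scores.shape != wavelengths.shape:
        raise ValueError("vip_scores and wavelengths must align")
    rows = []
    for r in regions:
        inside = (wavelengths >= r.lower) & (wavelengths <= r.upper)
        if not inside.any():
            continue
        v = vip_scores[inside]
        row = {
            "region": r.name,
            "n_bands": int(inside.sum()),
            "mean_vip": float(v.mean()),
            "max_vip": float(v.max()),
        }
        for t in thresholds:
            row[f"frac_ge_{t:g}"] = float((v >= t).mean())
        rows.append(row)
    return pd.DataFrame(rows)


def correlate_r2_cv(cv_values, r2_values) -> tuple[float, float]:
    """Pearson correlation between trait CVs and validation R2 values.

    Pairs with a missing member are dropped; needs >= 3 complete pairs.
    Returns (r, p).
    """
    cv = np.asarray(cv_values, dtype=float)
    r2 = np.asarray(r2_values, dtype=float)
    ok = np.isfinite(cv) & np.isfinite(r2)
    if ok.sum() < 3:
        raise ValueError("need >= 3 complete (CV, R2) pairs")
    r, p = stats.pearsonr(cv[ok], r2[ok])
    return float(r), float(p)


# --------------------------------------------------------------------------
# model / results objects


class PLSTraitModel:
    """Spectra -> single-trait PLS regression model (unfitted).

    Parameters
    ----------
    X : (n, p) calibration reflectance matrix
    y : (n,) calibration trait values (no missing)
    wavelengths : optional band grid, used for VIP region summaries
    leaf_ids : optional row identifiers
    scale : unit-variance scale the bands (default False: reflectance bands
        share units, so only centring is applied)
    a_max : cap on the component search (default min(15, n - 2))
    trait : display name
    """

    def __init__(self, X, y, wavelengths=None, leaf_ids=None, scale: bool = False,
                 a_max: int | None = None, trait: str = ""):
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.y = np.asarray(y, dtype=float).ravel()
        if self.X.shape[0] != self.y.size:
            raise ValueError("X and y disagree on sample count")
        if np.isnan(self.y).any() or np.isnan(self.X).any():
            raise ValueError("missing values must be dropped before modelling")
        self.wavelengths = (
            None if wavelengths is None else np.asarray(wavelengths, dtype=float)
        )
        self.leaf_ids = list(leaf_ids) if leaf_ids is not None else None
        self.scale = scale
        self.a_max = a_max if a_max is not None else min(DEFAULT_A_MAX, self.y.size - 2)
        self.trait = trait

    @classmethod
    def from_dataframes(
        cls,
        spectra: SpectraSet,
        trait_table: pd.DataFrame,
        trait: str,
        leaf_ids: list[str] | None = None,
        scale: bool = False,
        a_max: int | None = None,
    ) -> "PLSTraitModel":
        """Align a SpectraSet with a trait table on leaf_id, dropping leaves
        whose trait cell is missing."""
        tab = trait_table.set_index("leaf_id")[trait]
        ids = [lid for lid in (leaf_ids or spectra.leaf_ids)
               if lid in tab.index and pd.notna(tab.loc[lid])]
        sub = spectra.select(ids)
        return cls(
            sub.reflectance,
            tab.loc[ids].to_numpy(dtype=float),
            wavelengths=sub.wavelengths,
            leaf_ids=ids,
            scale=scale,
            a_max=a_max,
            trait=trait,
        )

    def fit(self, ncomp: int | None = None) -> "PLSTraitResults":
        """Fit; when ``ncomp`` is None, select it by leave-one-out PRESS."""
        cv = None
        if ncomp is None:
            cv = loo_press(self.X, self.y, self.a_max, scale=self.scale)
            ncomp = cv.selected
        if ncomp == 0:
            return PLSTraitResults(self, None, cv, 0, STATUS_NO_COMPONENT)
        plsr = fit_plsr(self.X, self.y, ncomp, scale=self.scale)
        status = STATUS_NO_COMPONENT if plsr.zero_variance_y else STATUS_OK
        return PLSTraitResults(self, plsr, cv, plsr.ncomp if status == STATUS_OK else 0,
                               status)


class PLSTraitResults:
    """Fitted spectra->trait model: estimates, uncertainty and diagnostics."""

    def __init__(self, model: PLSTraitModel, plsr: PLSRModel | None,
                 cv: CVResult | None, ncomp: int, status: str):
        self.model = model
        self.plsr = plsr
        self.cv = cv
        self.ncomp = ncomp
        self.status = status

    # -- estimates -----------------------------------------------------

    @property
    def params(self) -> np.ndarray:
        """Regression coefficients on the (centred/scaled) band grid."""
        if self.plsr is None:
            return np.zeros(self.model.X.shape[1])
        return self.plsr.coefficients(self.ncomp)

    def predict(self, X_new) -> np.ndarray:
        if self.plsr is None:
            return np.full(np.atleast_2d(X_new).shape[0], float(self.model.y.mean()))
        return self.plsr.predict(X_new, ncomp=self.ncomp)

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.X)

    def vip(self) -> np.ndarray:
        if self.plsr is None or self.ncomp == 0:
            raise ValueError(f"model status {self.status!r}: VIP undefined")
        return self.plsr.vip(self.ncomp)

    def vip_regions(self, thresholds=(0.8, 1.0)) -> pd.DataFrame:
        if self.model.wavelengths is None:
            raise ValueError("model was built without a wavelength grid")
        return vip_region_summary(self.vip(), self.model.wavelengths,
                                  thresholds=thresholds)

    # -- diagnostics ---------------------------------------------------

    def calibration_metrics(self) -> Metrics:
        return evaluate(self.model.y, self.fittedvalues, self.model.trait)

    def evaluate(self, X_val, y_val) -> Metrics:
        return evaluate(y_val, self.predict(X_val), self.model.trait)

    def jackknife(self, X_val, B: int = 500, leave_frac: float = 0.2,
                  seed: int = 0, mode: str = "subsample") -> dict:
        if self.ncomp == 0:
            raise ValueError(f"model status {self.status!r}: no jackknife")
        return jackknife_uncertainty(
            self.model.X, self.model.y, self.ncomp, X_val,
            B=B, leave_frac=leave_frac, seed=seed, scale=self.model.scale,
            mode=mode,
        )

    def summary(self) -> str:
        m = self.model
        lines = [
            "PLS trait regression results".center(58),
            "=" * 58,
            f"{'Trait:':<18}{m.trait or '-':<12}{'n_cal:':<12}{m.y.size}",
            f"{'Components:':<18}{self.ncomp:<12}{'A_max:':<12}{m.a_max}",
            f"{'Status:':<18}{self.status:<24}",
        ]
        if self.cv is not None:
            lines.append(
                f"{'PRESS (selected):':<18}{self.cv.press[self.cv.selected]:<12.4g}"
                f"{'PRESS (mean):':<14}{self.cv.press.mean():.4g}"
            )
        if self.status == STATUS_OK:
            cal = self.calibration_metrics()
            lines.append(
                f"{'Calibration R2:':<18}{cal.r2:<12.4f}{'RMSE:':<12}{cal.rmse:.4g}"
            )
        lines.append("=" * 58)
        return "\n".join(lines)

    def plot_observed_vs_predicted(self, X_val, y_val, ax=None):
        """Validation scatter with the 1:1 line, annotated with R2 and %RMSE."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        pred = self.predict(X_val)
        met = evaluate(y_val, pred, self.model.trait)
        ax.scatter(y_val, pred, s=18, alpha=0.7)
        lo = min(np.min(y_val), np.min(pred))
        hi = max(np.max(y_val), np.max(pred))
        ax.plot([lo, hi], [lo, hi], ls=":", c="grey")
        ax.set_xlabel(f"observed {self.model.trait}")
        ax.set_ylabel(f"predicted {self.model.trait}")
        ax.annotate(
            f"$R^2$ = {met.r2:.2f}\n%RMSE = {met.pct_rmse:.1f}",
            xy=(0.05, 0.85), xycoords="axes fraction", fontsize=9,
        )
        return ax
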