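"""Leaf trait table construction and screening.

Derived traits (water-use efficiencies, LMA, LDMC), per-trait summary
statistics with Shapiro-Wilk normality screening, an explicit log-transform
registry, and cell-wise IQR outlier masking. Only individual trait cells are
ever masked, never whole leaves, so per-trait sample sizes may differ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TRAIT_UNITS",
    "METADATA_COLUMNS",
    "SummaryStats",
    "derive_wue",
    "derive_morphology",
    "summarize_trait",
    "summary_table",
    "iqr_outlier_filter",
    "apply_transforms",
    "DEFAULT_TRANSFORMS",
]

#: Measurement units per trait column.
TRAIT_UNITS: dict[str, str] = {
    "E": "mmol H2O m-2 s-1",
    "A_max": "umol CO2 m-2 s-1",
    "g_s": "mol m-2 s-1",
    "N": "% dry mass",
    "C": "% dry mass",
    "d13C": "permil",
    "Psi_pd": "MPa",
    "WUE_intr": "umol CO2 mol-1 H2O",
    "WUE_inst": "umol CO2 mmol-1 H2O",
    "Area": "cm2",
    "LDMC": "mg g-1",
    "LMA": "g m-2",
}

METADATA_COLUMNS = ("leaf_id", "cultivar", "variety", "origin", "colour", "row", "vine")

#: Traits modelled on the natural-log scale by default. The choice is an
#: explicit registry because normality screening alone does not fully
#: determine it; callers may pass their own mapping.
DEFAULT_TRANSFORMS: dict[str, str] = {
    "WUE_inst": "log",
    "WUE_intr": "log",
    "Area": "log",
    "LDMC": "log",
    "LMA": "log",
}


def derive_wue(table: pd.DataFrame) -> pd.DataFrame:
    """Add intrinsic (A_max/g_s) and instantaneous (A_max/E) water-use efficiency.

    Missing inputs propagate; zero denominators give a missing cell with a
    warning (the ratio is undefined, not infinite for our purposes).
    """
    for col in ("A_max", "g_s", "E"):
        if col not in table.columns:
            raise KeyError(f"derive_wue requires column {col!r}")
    out = table.copy()
    for name, denom in (("WUE_intr", "g_s"), ("WUE_inst", "E")):
        d = out[denom].astype(float)
        zero = d == 0
        if zero.any():
            warnings.warn(
                f"{int(zero.sum())} leaf(s) with {denom}=0; {name} set missing",
                stacklevel=2,
            )
        out[name] = out["A_max"].astype(float) / d.where(~zero)
    return out


def derive_morphology(
    dry_mass_g: float, fresh_mass_g: float, area_cm2: float
) -> tuple[float, float]:
    """Return (LMA in g m-2, LDMC in mg g-1) from leaf masses and area.

    LMA = dry mass / area; LDMC = dry mass / water-saturated fresh mass.
    """
    if dry_mass_g <= 0 or fresh_mass_g <= 0 or area_cm2 <= 0:
        raise ValueError("masses and area must be positive")
    if dry_mass_g > fresh_mass_g:
        raise ValueError("dry mass cannot exceed fresh (saturated) mass")
    lma = dry_mass_g / (area_cm2 * 1e-4)
    ldmc = dry_mass_g * 1000.0 / fresh_mass_g
    return lma, ldmc


@dataclass
class SummaryStats:
    """Descriptive statistics for one trait.

    ``mad`` is the raw median absolute deviation (no 1.4826 consistency
    scaling); ``cv`` is 100*sd/|mean| so that negative-valued traits
    (Psi_pd, d13C) report a positive coefficient of variation.
    """

    n: int
    mean: float
    sd: float
    median: float
    mad: float
    min: float
    max: float
    cv: float
    shapiro_w: float = float("nan")
    shapiro_p: float = float("nan")


def cv_percent(mean: float, sd: float) -> float:
    """Coefficient of variation, percent: 100*sd/|mean|."""
    if mean == 0:
        return float("nan")
    return 100.0 * sd / abs(mean)


def summarize_trait(values) -> SummaryStats:
    x = np.asarray(pd.Series(values).dropna(), dtype=float)
    if x.size == 0:
        raise ValueError("all values missing")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1)) if x.size >= 2 else float("nan")
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    w = p = float("nan")
    # skip the normality test for (numerically) constant samples, where W
    # is undefined; the relative guard avoids spurious near-zero ranges
    if x.size >= 3 and np.ptp(x) > 1e-12 * max(1.0, float(np.max(np.abs(x)))):
        w, p = stats.shapiro(x)
    return SummaryStats(
        n=int(x.size),
        mean=mean,
        sd=sd,
        median=med,
        mad=mad,
        min=float(np.min(x)),
        max=float(np.max(x)),
        cv=cv_percent(mean, sd),
        shapiro_w=float(w),
        shapiro_p=float(p),
    )


def summary_table(table: pd.DataFrame, traits: list[str] | None = None) -> pd.DataFrame:
    """Descriptive-statistics table, one row per trait column."""
    if traits is None:
        traits = [c for c in table.columns if c not in METADATA_COLUMNS]
    rows = []
    for t in traits:
        s = summarize_trait(table[t])
        rows.append({"trait": t, **s.__dict__})
    return pd.DataFrame(rows)


def iqr_outlier_filter(values, factor: float = 2.0) -> np.ndarray:
    """Keep-mask for the interquartile-range outlier rule.

    A value is an outlier when it lies below Q1 - factor*IQR or above
    Q3 + factor*IQR, with quartiles by type-7 (linear) interpolation.
    Missing cells are kept (they are already absent). Returns a boolean
    array aligned with ``values``: True = keep.
    """
    x = np.asarray(pd.Series(values), dtype=float)
    obs = x[~np.isnan(x)]
    if obs.size < 4:
        raise ValueError("need at least 4 observed values for the IQR rule")
    if not np.isfinite(factor):
        return np.ones_like(x, dtype=bool)
    q1, q3 = np.quantile(obs, [0.25, 0.75], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - factor * iqr, q3 + factor * iqr
    keep = np.isnan(x) | ((x >= lo) & (x <= hi))
    return keep


def apply_transforms(
    table: pd.DataFrame, registry: dict[str, str] | None = None
) -> pd.DataFrame:
    """Apply per-trait transforms; 'log' columns are renamed with a ``log-`` prefix.

    ``registry`` maps trait -> {'identity', 'log'}; traits not listed are
    left untouched. Natural log; non-positive values become missing with a
    warning.
    """
    if registry is None:
        registry = DEFAULT_TRANSFORMS
    out = table.copy()
    for trait, kind in registry.items():
        if trait not in out.columns:
            continue
        if kind == "identity":
            continue
        if kind != "log":
            raise ValueError(f"unknown transform {kind!r} for trait {trait!r}")
        x = out[trait].astype(float)
        bad = x <= 0
        if bad.fillna(False).any():
            warnings.warn(
                f"{int(bad.sum())} non-positive value(s) in {trait}; set missing under log",
                stacklevel=2,
            )
        out[f"log-{trait}"] = np.log(x.where(~bad.fillna(False)))
        out = out.drop(columns=[trait])
    return out
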