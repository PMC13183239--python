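"""Containers, I/O and summaries for leaf reflectance spectra.

The interchange formats are plain CSV: a *wide* layout (one row per leaf,
columns ``leaf_id, wl_0400, wl_0401, ...``) and a *long* layout
(``leaf_id, wavelength_nm, reflectance``). Reflectance is stored as a
fraction; values slightly above 1 (up to 1.2) can occur with leaf-clip
white-reference calibration and are accepted with a warning, anything
outside [0, 1.2] is rejected.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpectraSet",
    "SpectralRegion",
    "REGIONS",
    "region_of",
    "read_spectra",
    "trim_and_resample",
    "quantile_summary",
]

WIDE_PREFIX = "wl_"

#: Accept measured reflectance up to this value; flag anything in (1, _SOFT_MAX].
_SOFT_MAX = 1.2


@dataclass(frozen=True)
class SpectralRegion:
    """Named wavelength window, inclusive at both ends (nm)."""

    name: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"region {self.name}: lower must be < upper")

    def __contains__(self, wavelength: float) -> bool:
        return self.lower <= wavelength <= self.upper


#: Conventional optical regions for leaf spectra. RED_EDGE deliberately
#: overlaps VIS, so region lookups return a set rather than one label.
REGIONS: tuple[SpectralRegion, ...] = (
    SpectralRegion("VIS", 380.0, 780.0),
    SpectralRegion("RED_EDGE", 680.0, 750.0),
    SpectralRegion("NIR", 780.0, 1400.0),
    SpectralRegion("SWIR1", 1550.0, 1750.0),
    SpectralRegion("SWIR2", 2000.0, 2300.0),
)


def region_of(wavelength: float, regions: tuple[SpectralRegion, ...] = REGIONS) -> set[str]:
    """Return the set of region names covering ``wavelength`` (possibly empty)."""
    return {r.name for r in regions if wavelength in r}


@dataclass
class SpectraSet:
    """Aligned reflectance spectra for a set of leaves.

    Parameters
    ----------
    wavelengths : array, nm, strictly increasing
    reflectance : array, shape (n_leaves, n_bands), fraction
    leaf_ids : unique identifiers, one per row
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    leaf_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.atleast_2d(np.asarray(self.reflectance, dtype=float))
        self.leaf_ids = [str(i) for i in self.leaf_ids]
        self._validate()

    def _validate(self) -> None:
        wl, refl = self.wavelengths, self.reflectance
        if wl.ndim != 1 or wl.size == 0:
            raise ValueError("wavelengths must be a non-empty 1-D array")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing with no duplicates")
        if refl.shape != (len(self.leaf_ids), wl.size):
            raise ValueError(
                f"reflectance shape {refl.shape} does not match "
                f"{len(self.leaf_ids)} leaves x {wl.size} bands"
            )
        if len(set(self.leaf_ids)) != len(self.leaf_ids):
            raise ValueError("leaf_ids must be unique")
        if not np.all(np.isfinite(refl)):
            i, j = np.argwhere(~np.isfinite(refl))[0]
            raise ValueError(
                f"non-finite reflectance for leaf {self.leaf_ids[i]} at {wl[j]:g} nm"
            )
        bad = (refl < 0) | (refl > _SOFT_MAX)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"reflectance {refl[i, j]:g} out of [0, {_SOFT_MAX}] "
                f"for leaf {self.leaf_ids[i]} at {wl[j]:g} nm"
            )
        high = refl > 1.0
        if high.any():
            i, j = np.argwhere(high)[0]
            warnings.warn(
                f"{int(high.sum())} reflectance value(s) in (1, {_SOFT_MAX}], e.g. leaf "
                f"{self.leaf_ids[i]} at {wl[j]:g} nm; check white-reference calibration",
                stacklevel=3,
            )

    @property
    def n_leaves(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_bands(self) -> int:
        return self.wavelengths.size

    def select(self, leaf_ids: list[str]) -> "SpectraSet":
        """Subset rows by leaf id, preserving the requested order."""
        index = {lid: k for k, lid in enumerate(self.leaf_ids)}
        missing = [lid for lid in leaf_ids if lid not in index]
        if missing:
            raise KeyError(f"leaf ids not in SpectraSet: {missing[:5]}")
        rows = [index[lid] for lid in leaf_ids]
        return SpectraSet(self.wavelengths.copy(), self.reflectance[rows], list(leaf_ids))

    def to_wide_frame(self) -> pd.DataFrame:
        cols = [f"{WIDE_PREFIX}{int(round(w)):04d}" if float(w).is_integer()
                else f"{WIDE_PREFIX}{w:g}" for w in self.wavelengths]
        df = pd.DataFrame(self.reflectance, columns=cols)
        df.insert(0, "leaf_id", self.leaf_ids)
        return df

    def to_long_frame(self) -> pd.DataFrame:
        n, p = self.reflectance.shape
        return pd.DataFrame(
            {
                "leaf_id": np.repeat(self.leaf_ids, p),
                "wavelength_nm": np.tile(self.wavelengths, n),
                "reflectance": self.reflectance.ravel(),
            }
        )

    def write(self, path, layout: str = "wide") -> None:
        if layout == "wide":
            self.to_wide_frame().to_csv(path, index=False)
        elif layout == "long":
            self.to_long_frame().to_csv(path, index=False)
        else:
            raise ValueError(f"unknown layout {layout!r}")


def _parse_wide_column(name: str) -> float:
    m = re.fullmatch(rf"{WIDE_PREFIX}0*([0-9]+(?:\.[0-9]+)?)", name)
    if not m:
        raise ValueError(f"cannot parse wavelength from column {name!r}")
    return float(m.group(1))


def read_spectra(path, layout: str = "wide") -> SpectraSet:
    """Read spectra from CSV in the wide or long layout.

    Raises on duplicate (leaf, wavelength) pairs, non-numeric reflectance,
    or (long layout) leaves measured on inconsistent wavelength grids.
    """
    if layout == "wide":
        df = pd.read_csv(path, float_precision="round_trip")
        if df.columns[0] != "leaf_id":
            raise ValueError("wide layout requires first column 'leaf_id'")
        wl = np.array([_parse_wide_column(c) for c in df.columns[1:]])
        order = np.argsort(wl)
        refl = df.iloc[:, 1:].to_numpy(dtype=float)[:, order]
        return SpectraSet(wl[order], refl, df["leaf_id"].astype(str).tolist())
    if layout == "long":
        df = pd.read_csv(path, float_precision="round_trip")
        required = {"leaf_id", "wavelength_nm", "reflectance"}
        if not required.issubset(df.columns):
            raise ValueError(f"long layout requires columns {sorted(required)}")
        df = df.assign(leaf_id=df["leaf_id"].astype(str))
        if df.duplicated(["leaf_id", "wavelength_nm"]).any():
            raise ValueError("duplicate (leaf_id, wavelength) pairs in long CSV")
        wide = df.pivot(index="leaf_id", columns="wavelength_nm", values="reflectance")
        if wide.isna().any().any():
            raise ValueError("inconsistent wavelength grids across leaves in long CSV")
        # preserve file order of leaves, not pivot's lexical order
        ids = df["leaf_id"].drop_duplicates().tolist()
        wide = wide.loc[ids]
        wl = wide.columns.to_numpy(dtype=float)
        order = np.argsort(wl)
        return SpectraSet(wl[order], wide.to_numpy(dtype=float)[:, order], ids)
    raise ValueError(f"unknown layout {layout!r}")


def trim_and_resample(
    s: SpectraSet, lower: float = 400.0, upper: float = 2400.0, step: float = 1.0
) -> SpectraSet:
    """Trim to [lower, upper] and linearly resample onto a uniform grid.

    The default window and step give the 2001-band 400-2400 nm grid used
    throughout the trait models. Idempotent when the input already lies on
    the target grid.
    """
    wl = s.wavelengths
    if wl[0] > lower or wl[-1] < upper:
        raise ValueError(
            f"input grid [{wl[0]:g}, {wl[-1]:g}] nm does not cover [{lower:g}, {upper:g}] nm"
        )
    n_out = int(round((upper - lower) / step)) + 1
    grid = lower + step * np.arange(n_out)
    refl = np.vstack([np.interp(grid, wl, row) for row in s.reflectance])
    return SpectraSet(grid, refl, list(s.leaf_ids))


def quantile_summary(
    s: SpectraSet, probs: tuple[float, ...] = (0.025, 0.25, 0.5, 0.75, 0.975)
) -> pd.DataFrame:
    """Per-band reflectance quantiles across leaves (type-7 interpolation).

    Returns a frame with a ``wavelength_nm`` column and one ``q<prob>``
    column per requested probability.
    """
    if s.n_leaves == 0:
        raise ValueError("empty SpectraSet")
    probs = tuple(probs)
    q = np.quantile(s.reflectance, probs, axis=0, method="linear")
    out = pd.DataFrame({"wavelength_nm": s.wavelengths})
    for pr, row in zip(probs, q):
        out[f"q{pr:g}"] = row
    return out


def plot_quantiles(s: SpectraSet, probs=(0.025, 0.25, 0.5, 0.75, 0.975), ax=None):
    """Plot the quantile envelope of a spectra set, shading the named regions."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    qs = quantile_summary(s, probs)
    wl = qs["wavelength_nm"]
    cols = [c for c in qs.columns if c.startswith("q")]
    if len(cols) >= 2:
        ax.fill_between(wl, qs[cols[0]], qs[cols[-1]], alpha=0.2, label=f"{cols[0]}-{cols[-1]}")
    mid = cols[len(cols) // 2]
    ax.plot(wl, qs[mid], lw=1.5, label=mid)
    for r in REGIONS:
        if r.name != "RED_EDGE":
            ax.axvspan(r.lower, r.upper, color="grey", alpha=0.08)
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel("reflectance")
    ax.legend(loc="upper right", fontsize=8)
    return ax
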