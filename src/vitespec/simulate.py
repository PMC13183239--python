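"""Synthetic vineyard generator: cultivar-structured traits and linked spectra.

Emulates a single-vineyard cultivar panel: 12 cultivars in 7 varieties
(two clones for most varieties), each sampled on 5 vines in each of 3
planting rows. Trait values follow a nested random-effects model — for each
trait, value = mean + origin effect + red/white effect + cultivar effect +
row effect + leaf residual, every effect drawn once per grouping unit from
a zero-mean normal whose variance is the configured proportion of the total
variance. Reflectance spectra are produced by a forward model: a fixed
smooth leaf-reflectance baseline multiplied by Gaussian absorption features
whose depths track trait z-scores, plus band noise.

This is deliberately *not* a radiative-transfer model; it provides known
ground truth (which traits are spectrally encoded, and where) so that the
retrieval machinery can be tested end to end.
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .spectra import SpectraSet

__all__ = [
    "TraitSpec",
    "SpectralLink",
    "SimConfig",
    "default_config",
    "generate_traits",
    "generate_spectra",
    "baseline_template",
    "analytic_baseline",
]

LEVELS = ("origin", "red_white", "cultivar", "row")

#: The default cultivar panel: (cultivar, variety, colour). Origin
#: (warm/cool growing region of the variety's provenance) is an arbitrary
#: binary label fixed per variety — the class membership is not part of the
#: emulated dataset's public record.
CULTIVAR_PANEL: tuple[tuple[str, str, str], ...] = (
    ("CF314", "Cabernet franc", "red"),
    ("CF327", "Cabernet franc", "red"),
    ("CS29", "Cabernet sauvignon", "red"),
    ("CS412", "Cabernet sauvignon", "red"),
    ("M181", "Merlot", "red"),
    ("M348", "Merlot", "red"),
    ("PN828", "Pinot noir", "red"),
    ("PN89", "Pinot noir", "red"),
    ("R171", "Riesling", "white"),
    ("R23", "Riesling", "white"),
    ("SB906", "Sauvignon blanc", "white"),
    ("V642", "Viognier", "white"),
)

VARIETY_ORIGIN: dict[str, str] = {
    "Cabernet franc": "warm",
    "Cabernet sauvignon": "warm",
    "Merlot": "warm",
    "Pinot noir": "cool",
    "Riesling": "cool",
    "Sauvignon blanc": "cool",
    "Viognier": "warm",
}


@dataclass(frozen=True)
class TraitSpec:
    """Population mean, total SD and hierarchical variance proportions for one trait.

    ``proportions`` maps level name (origin, red_white, cultivar, row) to the
    share of total variance; any shortfall from 1 is the leaf-level residual.
    """

    mean: float
    total_sd: float
    proportions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.total_sd < 0:
            raise ValueError("total_sd must be >= 0")
        bad = set(self.proportions) - set(LEVELS) - {"residual"}
        if bad:
            raise ValueError(f"unknown variance levels: {sorted(bad)}")
        if any(v < 0 for v in self.proportions.values()):
            raise ValueError("variance proportions must be >= 0")
        if sum(self.proportions.values()) > 1 + 1e-9:
            raise ValueError("variance proportions must sum to <= 1")

    @property
    def residual(self) -> float:
        explicit = self.proportions.get("residual")
        if explicit is not None:
            return explicit
        return 1.0 - sum(self.proportions.values())


@dataclass(frozen=True)
class SpectralLink:
    """Gaussian absorption feature tying one trait to the spectrum.

    Depth (in absorbance units) = strength * trait z-score; centred at
    ``center`` nm with Gaussian sd ``width`` nm.
    """

    trait: str
    center: float
    width: float
    strength: float

    def __post_init__(self) -> None:
        if not 400.0 <= self.center <= 2400.0:
            raise ValueError("link center must lie within 400-2400 nm")
        if self.width <= 0:
            raise ValueError("link width must be > 0")


@dataclass
class SimConfig:
    """Full specification of one synthetic vineyard draw."""

    n_cultivars: int = 12
    n_varieties: int = 7
    rows_per_cultivar: int = 3
    vines_per_row: int = 5
    trait_specs: dict[str, TraitSpec] = field(default_factory=dict)
    links: list[SpectralLink] = field(default_factory=list)
    missing_rate: float = 0.03
    spectral_noise_sd: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.spectral_noise_sd < 0:
            raise ValueError("spectral_noise_sd must be >= 0")

    @property
    def leaves_per_cultivar(self) -> int:
        return self.rows_per_cultivar * self.vines_per_row

    @property
    def n_leaves(self) -> int:
        return self.n_cultivars * self.leaves_per_cultivar


def _load_yaml_config(path_or_stream) -> SimConfig:
    raw = yaml.safe_load(path_or_stream)
    specs = {
        t: TraitSpec(d["mean"], d["total_sd"], d.get("proportions", {}))
        for t, d in raw.get("traits", {}).items()
    }
    links = [
        SpectralLink(d["trait"], d["center"], d["width"], d["strength"])
        for d in raw.get("links", [])
    ]
    design = raw.get("design", {})
    return SimConfig(
        n_cultivars=design.get("n_cultivars", 12),
        n_varieties=design.get("n_varieties", 7),
        rows_per_cultivar=design.get("rows_per_cultivar", 3),
        vines_per_row=design.get("vines_per_row", 5),
        trait_specs=specs,
        links=links,
        missing_rate=raw.get("missing_rate", 0.03),
        spectral_noise_sd=raw.get("spectral_noise_sd", 0.002),
        seed=raw.get("seed", 0),
    )


def load_config(path) -> SimConfig:
    """Load a :class:`SimConfig` from YAML."""
    with open(path) as fh:
        return _load_yaml_config(fh)


def default_config(seed: int = 0) -> SimConfig:
    """The packaged default vineyard: 12 traits with published-style means,
    SDs and variance partitioning, plus the default spectral links."""
    with resources.files("vitespec.data").joinpath("default_vineyard.yaml").open() as fh:
        cfg = _load_yaml_config(fh)
    return replace(cfg, seed=seed)


def _cultivar_table(config: SimConfig) -> pd.DataFrame:
    """Cultivar -> variety/colour/origin map for the configured panel size."""
    if (config.n_cultivars, config.n_varieties) == (12, 7):
        rows = [
            {
                "cultivar": c,
                "variety": v,
                "colour": col,
                "origin": VARIETY_ORIGIN[v],
            }
            for c, v, col in CULTIVAR_PANEL
        ]
        return pd.DataFrame(rows)
    # generic panel: varieties round-robin over cultivars; colour and origin
    # assigned at the variety level, alternating
    rows = []
    for i in range(config.n_cultivars):
        vi = i % config.n_varieties
        rows.append(
            {
                "cultivar": f"C{i + 1:02d}",
                "variety": f"V{vi + 1:02d}",
                "colour": "red" if vi % 2 == 0 else "white",
                "origin": "warm" if (vi // 2) % 2 == 0 else "cool",
            }
        )
    return pd.DataFrame(rows)


def generate_traits(config: SimConfig) -> pd.DataFrame:
    """Draw one vineyard's leaf trait table under the nested effects model.

    Returns a frame with metadata columns (leaf_id, cultivar, variety,
    origin, colour, row, vine) and one column per configured trait. Missing
    cells are inserted completely at random per trait cell at
    ``missing_rate``.
    """
    rng = np.random.default_rng(config.seed)
    panel = _cultivar_table(config)

    meta_rows = []
    for _, c in panel.iterrows():
        for r in range(1, config.rows_per_cultivar + 1):
            for v in range(1, config.vines_per_row + 1):
                meta_rows.append(
                    {
                        "leaf_id": f"{c.cultivar}-R{r}-V{v}",
                        "cultivar": c.cultivar,
                        "variety": c.variety,
                        "origin": c.origin,
                        "colour": c.colour,
                        "row": f"R{r}",
                        "vine": v,
                    }
                )
    table = pd.DataFrame(meta_rows)

    unit_keys = {
        "origin": table["origin"],
        "red_white": table["origin"] + "/" + table["colour"],
        "cultivar": table["cultivar"],
        "row": table["cultivar"] + "/" + table["row"],
    }

    for trait, spec in config.trait_specs.items():
        total_var = spec.total_sd**2
        value = np.full(len(table), spec.mean, dtype=float)
        for level in LEVELS:
            p = spec.proportions.get(level, 0.0)
            if p == 0.0:
                continue
            units = unit_keys[level]
            uniq = units.unique()
            effects = dict(zip(uniq, rng.normal(0.0, np.sqrt(p * total_var), uniq.size)))
            value += units.map(effects).to_numpy()
        resid = spec.residual
        if resid > 0:
            value += rng.normal(0.0, np.sqrt(resid * total_var), len(table))
        if config.missing_rate > 0:
            mask = rng.random(len(table)) < config.missing_rate
            value = np.where(mask, np.nan, value)
        table[trait] = value
    return table


# --------------------------------------------------------------------------
# spectra forward model


def analytic_baseline(wavelengths: np.ndarray) -> np.ndarray:
    """Smooth healthy-leaf reflectance template on an arbitrary grid.

    Low visible reflectance with a green bump near 550 nm, a red-edge rise
    to a NIR plateau around 0.45, water absorption dips near 1450 and
    1940 nm and a gentle SWIR roll-off. This analytic recipe generated the
    packaged 2001-point template (data/baseline_reflectance.csv).
    """
    lam = np.asarray(wavelengths, dtype=float)
    sig = lambda x: 1.0 / (1.0 + np.exp(-x))
    gauss = lambda c, w: np.exp(-0.5 * ((lam - c) / w) ** 2)
    base = 0.05 + 0.055 * gauss(550.0, 35.0)
    base += 0.45 * sig((lam - 710.0) / 17.0) * (1.0 - 0.30 * sig((lam - 1650.0) / 250.0))
    absorb = (
        0.35 * gauss(1450.0, 40.0)
        + 0.55 * gauss(1940.0, 55.0)
        + 0.08 * gauss(1200.0, 35.0)
        + 0.25 * gauss(2500.0, 220.0)
    )
    return np.clip(base * np.exp(-absorb), 0.0, 1.0)


def baseline_template() -> tuple[np.ndarray, np.ndarray]:
    """The packaged baseline: (wavelengths 400..2400 nm at 1 nm, reflectance)."""
    path = resources.files("vitespec.data").joinpath("baseline_reflectance.csv")
    with path.open() as fh:
        df = pd.read_csv(fh)
    return df["wavelength_nm"].to_numpy(dtype=float), df["reflectance"].to_numpy(dtype=float)


def generate_spectra(traits: pd.DataFrame, config: SimConfig) -> SpectraSet:
    """Forward-model reflectance spectra for a generated trait table.

    reflectance(lambda) = baseline(lambda) * exp(-sum_links strength * z *
    gauss(lambda)) + noise, clipped to [0, 1], on the 400-2400 nm 1 nm grid.
    Trait z-scores use the configured mean/SD; a missing trait cell
    contributes no absorption (z treated as 0).
    """
    for link in config.links:
        if link.trait not in traits.columns:
            raise KeyError(f"spectral link references unknown trait {link.trait!r}")

    # independent stream so trait and spectral noise draws never interleave
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    wl, base = baseline_template()
    n = len(traits)
    absorb = np.zeros((n, wl.size))
    for link in config.links:
        spec = config.trait_specs[link.trait]
        sd = spec.total_sd if spec.total_sd > 0 else 1.0
        z = ((traits[link.trait].to_numpy(dtype=float) - spec.mean) / sd)
        z = np.nan_to_num(z, nan=0.0)
        shape = np.exp(-0.5 * ((wl - link.center) / link.width) ** 2)
        absorb += np.outer(z * link.strength, shape)
    refl = base[None, :] * np.exp(-absorb)
    if config.spectral_noise_sd > 0:
        refl = refl + rng.normal(0.0, config.spectral_noise_sd, refl.shape)
    refl = np.clip(refl, 0.0, 1.0)
    return SpectraSet(wl, refl, traits["leaf_id"].tolist())
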