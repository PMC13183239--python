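import numpy as np
import pytest

from vitespec.simulate import SimConfig, SpectralLink, TraitSpec, generate_spectra, generate_traits


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def one_link_noiseless():
    """Single weak-absorbance link, no noise: ground truth for retrieval tests."""
    cfg = SimConfig(
        trait_specs={"N": TraitSpec(2.75, 0.35, {"cultivar": 0.5})},
        links=[SpectralLink("N", 1510, 40, 0.02)],
        missing_rate=0.0,
        spectral_noise_sd=0.0,
        seed=7,
    )
    table = generate_traits(cfg)
    spectra = generate_spectra(table, cfg)
    return cfg, table, spectra


@pytest.fixture(scope="session")
def small_vineyard():
    """A compact noisy vineyard (4 traits) reused across tests."""
    cfg = SimConfig(
        trait_specs={
            "N": TraitSpec(2.75, 0.35, {"red_white": 0.12, "row": 0.05}),
            "E": TraitSpec(3.24, 1.13, {"origin": 0.42, "cultivar": 0.38, "row": 0.08}),
            "g_s": TraitSpec(0.26, 0.08, {"cultivar": 0.54, "row": 0.15}),
            "LDMC": TraitSpec(255.69, 21.98, {"red_white": 0.09, "cultivar": 0.05}),
        },
        links=[
            SpectralLink("N", 1510, 40, 0.05),
            SpectralLink("E", 1450, 45, 0.08),
            SpectralLink("g_s", 715, 35, 0.06),
            SpectralLink("LDMC", 2100, 80, 0.08),
        ],
        missing_rate=0.03,
        spectral_noise_sd=0.002,
        seed=11,
    )
    table = generate_traits(cfg)
    spectra = generate_spectra(table, cfg)
    return cfg, table, spectra
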