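import pytest

from isopair import PeptideSpecies, SimConfig


@pytest.fixture(scope="session")
def hai_light() -> PeptideSpecies:
    """The parent shuttle peptide Ac-HAIYPRH-NH2, light acetyl."""
    return PeptideSpecies("HAIYPRH", "acetyl_light", "amide", name="1L")


@pytest.fixture(scope="session")
def hai_heavy(hai_light) -> PeptideSpecies:
    return hai_light.with_n_terminus("acetyl_heavy")


@pytest.fixture
def clean_config() -> SimConfig:
    """Noiseless, protonated-adduct-only acquisition around the HAI pair."""
    return SimConfig(mz_range=(920.0, 960.0), adduct_abundances={"H": 1.0}, seed=11)
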