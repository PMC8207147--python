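import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from cepaea import (
    CANONICAL_GRID,
    ObserverModel,
    ReflectanceSpectrum,
    ShellRecord,
    ValleyScenario,
    generate_spectra,
    generate_survey,
    preprocess_spectra,
    site_frequencies,
    tristimulus,
)


@pytest.fixture(scope="session")
def observer():
    return ObserverModel.default()


@pytest.fixture(scope="session")
def white_spectrum():
    return ReflectanceSpectrum("white", 0, CANONICAL_GRID, np.full(401, 100.0))


@pytest.fixture(scope="session")
def two_morph_coords(observer):
    """CIE coordinates + labels for 60 yellow and 60 pink synthetic shells."""
    records = [
        ShellRecord(f"Y{i:03d}", "yellow", "unbanded", "pale") for i in range(60)
    ] + [ShellRecord(f"P{i:03d}", "pink", "banded", "other") for i in range(60)]
    specs = generate_spectra(records, seed=5)
    coords = [tristimulus(s, observer) for s in preprocess_spectra(specs)]
    labels = ["yellow" if c.shell_id.startswith("Y") else "pink" for c in coords]
    return coords, labels


@pytest.fixture(scope="session")
def default_survey():
    """One seeded two-era survey of the default valley plus its frequency table."""
    past, present = generate_survey(ValleyScenario(seed=3))
    freq = site_frequencies(past + present)
    return past, present, freq
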