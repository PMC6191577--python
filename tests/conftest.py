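import numpy as np
import pytest

from canospec import Spectrum, default_grid, generate_spectra, generate_traits, scenario_2014


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def season():
    """One seeded default four-date season: (scenario, traits, spectra)."""
    sc = scenario_2014(seed=11)
    traits = generate_traits(sc)
    spectra = generate_spectra(traits, sc)
    return sc, traits, spectra


def random_spectrum(rng, grid, plot_id="p", date_id="d"):
    return Spectrum(grid, rng.uniform(0.01, 1.0, grid.size), plot_id=plot_id, date_id=date_id)
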