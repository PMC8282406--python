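import dataclasses

import pytest

from iemv import IemvModel, SynthConfig, synth_world


SMALL_CONFIG = SynthConfig(seed=202, n_countries_per_group=4, n_aux_countries=3)


@pytest.fixture(scope="session")
def small_world():
    """A compact but complete synthetic panel (4 countries/group + 3 reference)."""
    return synth_world(SMALL_CONFIG)


@pytest.fixture(scope="session")
def noiseless_world():
    """Same panel with all planted relationships exact (no log-scale noise)."""
    return synth_world(dataclasses.replace(SMALL_CONFIG, noise_sd=0.0))


@pytest.fixture(scope="session")
def fitted(small_world):
    surface, gni, population, _ = small_world
    return IemvModel(surface, gni, population).fit()
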