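import numpy as np
import pytest

from deswax import HansenTriplet, default_group_table
from deswax.io import load_packaged_components, load_packaged_mixtures, load_reported_screen


@pytest.fixture(scope="session")
def group_table():
    return default_group_table()


@pytest.fixture(scope="session")
def components():
    return load_packaged_components()


@pytest.fixture(scope="session")
def mixtures():
    return load_packaged_mixtures()


@pytest.fixture(scope="session")
def reported_panel():
    """Published Hansen/Teas/RED table for the twelve formulations."""
    return load_reported_screen()


@pytest.fixture(scope="session")
def reported_triplets(reported_panel):
    return [
        (str(r.des_name), HansenTriplet(r.delta_d, r.delta_p, r.delta_h))
        for r in reported_panel.itertuples(index=False)
    ]
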