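import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from embryosim import mechanics as mech
from embryosim import synthetic_data as synth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def four_generation_tree():
    return synth.synth_lineage(synth.SynthSpec(generations=4, division_interval=15))


@pytest.fixture
def default_shell():
    return mech.EggshellEllipsoid()


def random_network(rng, n=10, box=10.0, radius_range=(0.8, 1.5)):
    """A contact network of n random cells in a cube (shared test helper)."""
    cells = [
        mech.Cell(
            f"c{k}",
            rng.uniform(-box / 2, box / 2, size=3),
            rng.uniform(*radius_range),
        )
        for k in range(n)
    ]
    return mech.build_neighbor_graph(cells, contact_factor=1.2)
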