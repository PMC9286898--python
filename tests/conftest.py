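import numpy as np
import pytest

from cdrscreen.dataset import SplitSpec, complement_pool, make_ratio_datasets
from cdrscreen.model import TrainConfig, build_network, train
from cdrscreen.pipeline import images_and_labels, normalize_world
from cdrscreen.synthetic_data import SimConfig, simulate


@pytest.fixture(scope="session")
def small_world():
    """A compact synthetic world shared by fast tests (60 x 12 grid)."""
    return simulate(
        SimConfig(n_compounds=60, n_diseases=12, d_compound=16, d_disease=8, seed=42)
    )


@pytest.fixture(scope="session")
def small_trained(small_world):
    """A tiny CNN trained briefly on the small world (for contract tests)."""
    world = small_world
    pos = world.positive_pairs
    pool = complement_pool(world.compounds.ids, world.diseases.ids, pos)
    spec = SplitSpec(ratio_neg_per_pos=1, sample_size=160, repeats=1, seed=7)
    split = make_ratio_datasets(pos, pool, spec)[0]
    compounds, diseases = normalize_world(world)
    x, y = images_and_labels(split.train, compounds, diseases)
    model = build_network("tiny", x.shape[1:], seed=7)
    config = TrainConfig.desk_scale(seed=7, max_epochs=3)
    return train(model, x, y, config), compounds, diseases


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
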