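import numpy as np
import pytest

from hcscreen import synthgen


@pytest.fixture(scope="session")
def small_layout():
    return synthgen.make_screen_layout(6, markers=("LC3B",), seed=11)


@pytest.fixture(scope="session")
def small_model():
    return synthgen.EffectModel(
        gene_effects={"GENE001": (3.0, 3.0), "GENE002": (0.4, 0.4)},
        toxic_sirnas={"GENE003_pool": synthgen.ToxicEffect()},
        seed=11,
    )


@pytest.fixture(scope="session")
def small_wells(small_layout, small_model):
    return synthgen.simulate_well_table(small_layout, small_model)


@pytest.fixture(scope="session")
def demo_image():
    """Clean rendered field: 10 cells, 5 spots each."""
    img, truth = synthgen.render_well_image(
        n_cells=10, spots_per_cell=5, size=320, seed=7, noise_sd=0.01)
    return img, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
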