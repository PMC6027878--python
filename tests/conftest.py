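import numpy as np
import pytest

from wingmorph import simulate as sim


@pytest.fixture(scope="session")
def templates():
    return sim.default_templates()


@pytest.fixture(scope="session")
def small_config():
    """Balanced 6-per-group dataset: fast but exercises every group."""
    cfg = sim.SimulationConfig(seed=11)
    cfg.n_per_group = {k: 6 for k in cfg.n_per_group}
    return cfg


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return sim.generate_dataset(small_config)


@pytest.fixture(scope="session")
def aligned_small(small_dataset):
    from wingmorph import superimposition

    return superimposition.align(small_dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_specimens(n, rng, stage="adult", genotype="yw"):
    """Valid random specimens for I/O round-trip tests."""
    from wingmorph.io import Specimen

    out = []
    for i in range(n):
        coords = rng.uniform(-2.0, 2.0, size=(17, 2))
        out.append(
            Specimen(
                id=f"rt_{i}",
                stage=stage,
                genotype=genotype,
                sex="F" if i % 2 else "M",
                landmarks=coords,
            )
        )
    return out
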