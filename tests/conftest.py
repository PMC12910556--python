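import numpy as np
import pytest

import zipo


@pytest.fixture(scope="session")
def small_counts():
    """A small deterministic synthetic dataset shared across tests."""
    cm, truth = zipo.simulate(zipo.SimSpec(n_cells=120, n_genes=40, seed=11))
    return cm, truth


@pytest.fixture(scope="session")
def tiny_trained_model(small_counts):
    """A briefly trained small network (shared, read-only for most tests)."""
    cm, _ = small_counts
    spec = zipo.ModelSpec(encoder_sizes=[16, 8, 4], n_genes=cm.n_genes,
                          residuals="full")
    model = zipo.build_model(spec, seed=1)
    result = zipo.train(
        model, cm,
        cfg=zipo.TrainConfig(max_epochs=8, batch_size=32, seed=1),
        preprocess_spec=zipo.PreprocessSpec(log_transform=True),
    )
    return model, result, cm


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
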