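import numpy as np
import pytest
from hypothesis import settings

from scdiffvae import preprocess, synthetic

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """120 cells x 60 genes, 3 well-separated clusters."""
    spec = synthetic.SyntheticSpec(
        n_cells=120, n_genes=60, n_clusters=3, markers_per_cluster=5,
        marker_effect=3.0, noise_sd=0.5, seed=42,
    )
    return synthetic.generate_expression(spec)


@pytest.fixture(scope="session")
def small_unit(small_dataset):
    return preprocess.minmax_scale(small_dataset.expression)


@pytest.fixture(scope="session")
def tiny_config():
    from scdiffvae.diffvae import DiffVAEConfig

    return DiffVAEConfig(h1=16, m=8, epochs=5, batch_size=32, seed=3)


@pytest.fixture(scope="session")
def tiny_model(small_unit, tiny_config):
    from scdiffvae.diffvae import train_diffvae

    model, history = train_diffvae(small_unit, tiny_config)
    return model, history


def zero_model(n_genes=4, **kwargs):
    """A DiffVAE with every weight and bias set to zero (batch norm off)."""
    from scdiffvae.diffvae import DiffVAEConfig, DiffVAEModel
    from scdiffvae.nn import Dense

    cfg = DiffVAEConfig(h1=3, h2=5, m=2, batchnorm=False, **kwargs)
    model = DiffVAEModel(n_genes, cfg)
    for chain in (model.encoder, model.head_mu, model.head_logvar, model.decoder):
        for layer in chain.layers:
            if isinstance(layer, Dense):
                layer.W.value[...] = 0.0
                layer.b.value[...] = 0.0
    return model


def unit_toy_model(head_activation="relu"):
    """1-gene toy: k = h1 = h2 = m = 1, all weights 1, biases 0, no batch norm."""
    from scdiffvae.diffvae import DiffVAEConfig, DiffVAEModel
    from scdiffvae.nn import Dense

    cfg = DiffVAEConfig(h1=1, h2=1, m=1, batchnorm=False, head_activation=head_activation)
    model = DiffVAEModel(1, cfg)
    for chain in (model.encoder, model.head_mu, model.head_logvar, model.decoder):
        for layer in chain.layers:
            if isinstance(layer, Dense):
                layer.W.value[...] = 1.0
                layer.b.value[...] = 0.0
    return model


@pytest.fixture
def rng():
    return np.random.default_rng(0)
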