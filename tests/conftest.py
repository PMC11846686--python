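import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cellforge as cf

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def tiny_matrix() -> cf.ExpressionMatrix:
    """Hand-built 3 cells x 2 genes matrix with one label attribute."""
    counts = np.array([[10.0, 0.0], [0.0, 0.0], [3.0, 7.0]])
    return cf.ExpressionMatrix(counts, ["c1", "c2", "c3"], ["gene_a", "gene_b"],
                               {"cell_type": np.array(["T", "T", "B"])})


@pytest.fixture(scope="session")
def toy_dataset() -> cf.ExpressionMatrix:
    """Small 3-type NB dataset (60 cells x 40 genes), low noise."""
    return cf.make_dataset(cf.SyntheticConfig(
        n_genes=40, cells_per_group=20, seed=3,
        attributes=[("cell_type", ["a", "b", "c"])],
        dispersion=5.0, baseline_mean=0.5))


@pytest.fixture(scope="session")
def toy_ae(toy_dataset):
    """Trained toy autoencoder + its normalized training data."""
    norm = cf.normalize(toy_dataset)
    cfg = cf.AEConfig(latent_dim=8, encoder_hidden=[64],
                      decoder_hidden=[64, 64], epochs=800, seed=0)
    params, trace = cf.train_autoencoder(cfg, norm)
    return params, trace, norm


@pytest.fixture
def tiny_backbone():
    """Randomly initialized small backbone (latent 4, depth 2)."""
    cfg = cf.BackboneConfig(latent_dim=4, n_classes=4, depth=2,
                            chunk_widths=[6, 5, 5], embed_dim=8,
                            time_dim=8, seed=1)
    return cf.init_backbone(cfg)
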