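import numpy as np
import pytest

from tofrank import SimConfig, TrainingSet, simulate_sources


@pytest.fixture(scope="session")
def planted():
    """Planted-signal simulation: 1000 genes, 3 sources, 20 training genes,
    enrichment 3, fixed seed."""
    cfg = SimConfig(n_genes=1000, n_sources=3, n_features_per_source=50,
                    enrichment=3.0, noise_sd=1.0, seed=11)
    sources = simulate_sources(cfg)
    training = TrainingSet("planted", frozenset(cfg.resolved_training_genes()))
    return cfg, sources, training


@pytest.fixture()
def toy_source():
    """5 genes x 3 features, hand-checkable."""
    from tofrank import FeatureSource

    rng = np.random.default_rng(7)
    return FeatureSource(
        name="toy",
        genes=["g1", "g2", "g3", "g4", "g5"],
        matrix=rng.normal(size=(5, 3)),
    )
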