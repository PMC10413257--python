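import pytest

from luxuptake import SyntheticConfig, generate_bundle


@pytest.fixture(scope="session")
def bundle():
    """Full-size synthetic bundle at the study's default conditions."""
    return generate_bundle(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def small_bundle():
    """Small bundle for cheap structural tests."""
    return generate_bundle(SyntheticConfig(n_genes=300, seed=5))
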