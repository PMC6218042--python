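import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_panel():
    """A 60 x 200 panel with 3 founder clusters, a drifted ring and
    sprinkled missing genotypes."""
    from trcmgene import PanelSpec, generate_panel

    spec = PanelSpec(n_individuals=60, n_markers=200, n_clusters=3,
                     mu_in=0.02, rho=0.2, mu_ring=0.3, missing_rate=0.02,
                     seed=42)
    matrix, labels = generate_panel(spec)
    return matrix, labels
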