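import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid256():
    from nusclust import Grid

    return Grid((256,))


@pytest.fixture(scope="session")
def clustered_signal():
    """Noiseless clustered five-component benchmark signal on n=256."""
    from nusclust import make_scenario, synth_fid

    return synth_fid(make_scenario("clustered_sparse", 256), 256)


def complex_allclose(a, b, tol=1e-9):
    return np.linalg.norm(np.asarray(a) - np.asarray(b)) <= tol * max(
        1.0, np.linalg.norm(np.asarray(b))
    )
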