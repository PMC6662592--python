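import numpy as np
import pytest

from wfpgl.core import build_weight_matrix, compute_sample_covariance
from wfpgl.simulate import ScenarioConfig, make_scenario


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scenario():
    """A 40-gene two-state dataset with overlapping pathways and a prior."""
    cfg = ScenarioConfig(p=40, K=2, n=100, J=3, n_ol=4, r=0.3, eta=0.8, seed=7)
    data, truth = make_scenario(cfg)
    S = [compute_sample_covariance(X) for X in data.matrices]
    W = build_weight_matrix(truth.G, 0.3)
    return {"cfg": cfg, "data": data, "truth": truth, "S": S, "W": W}
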