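import numpy as np
import pytest
from hypothesis import settings

import otudelim as od

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def random_distance_matrix(rng, n, scale=0.2):
    """Random symmetric matrix with zero diagonal (not necessarily metric)."""
    d = rng.uniform(0, scale, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    ids = [f"t{k}" for k in range(n)]
    return od.DistanceMatrix(ids, d, np.full((n, n), 100))


@pytest.fixture(scope="session")
def small_regime_dataset():
    """One small set-3 regime dataset shared by fast tests."""
    cfg = od.SynthConfig.set3_regime(seed=11, K=6, samples_per_species=4)
    aln, truth, chrono = od.make_dataset(cfg)
    return cfg, aln, truth, chrono
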