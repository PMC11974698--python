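import numpy as np
import pytest
from hypothesis import settings

from confusenn.io import pad_to_width
from confusenn.synthetic import (
    simulate_ld_mosaic,
    simulate_neutral,
    simulate_sweep_like,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_mixed_matrices(n, master_seed=0, max_hap=32, max_sites=128):
    """Random matrices cycling through the three generators, half padded."""
    rng = np.random.default_rng(master_seed)
    out = []
    for i in range(n):
        n_hap = int(rng.integers(4, max_hap + 1))
        n_sites = int(rng.integers(8, max_sites + 1))
        seed = np.random.SeedSequence([master_seed, i])
        kind = i % 3
        if kind == 0:
            m = simulate_neutral(n_hap, n_sites, seed)
        elif kind == 1:
            n_f = int(rng.integers(2, min(6, n_hap) + 1))
            m = simulate_ld_mosaic(n_hap, n_sites, n_f, 0.05, seed)
        else:
            m = simulate_sweep_like(n_hap, n_sites, 0.8, seed)
        if i % 2 == 0:
            m = pad_to_width(m, m.n_col + int(rng.integers(1, 17)))
        out.append(m)
    return out


@pytest.fixture(scope="session")
def mixed_matrices():
    """Factory for mixed-generator matrix collections."""
    return make_mixed_matrices
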