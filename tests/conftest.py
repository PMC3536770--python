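import numpy as np
import pandas as pd
import pytest

from andropipe import SignalMatrix, simulate_experiment


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_signal():
    """Four clones x four samples, two groups, hand-checkable numbers."""
    clones = ["c1", "c2", "c3", "c4"]
    samples = ["a1", "a2", "a3", "a4"]
    S = pd.DataFrame(
        [[100.0, 200.0, 150.0, 120.0],
         [80.0, 90.0, 85.0, 95.0],
         [400.0, 380.0, 420.0, 410.0],
         [10.0, 12.0, 11.0, 9.0]],
        index=clones, columns=samples,
    )
    V = pd.DataFrame(
        [[4.0, 2.0, 3.0, 3.0],
         [5.0, 5.0, 5.0, 5.0],
         [6.0, 7.0, 8.0, 9.0],
         [2.0, 2.0, 3.0, 2.0]],
        index=clones, columns=samples,
    )
    B = pd.Series([1.0, 1.0, 1.0, 1.0], index=samples)
    groups = pd.Series(["g1", "g1", "g2", "g2"], index=samples)
    return SignalMatrix(S=S, V=V, B=B, groups=groups)


@pytest.fixture(scope="session")
def small_experiment():
    """A small but realistic synthetic experiment shared across tests."""
    return simulate_experiment(n_clones=800, frac_de=0.1, seed=42)
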