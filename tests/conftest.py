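import numpy as np
import pandas as pd
import pytest

from ubisite.aaindex import build_aa_pcp_matrix, parse_aaindex1
from ubisite.features import average_pcp_features, discretize_equal_interval
from ubisite.synth import SignalSpec, generate_aaindex, generate_labeled_segments


@pytest.fixture(scope="session")
def aa_pcp():
    """36 complete synthetic properties (40 generated, 4 with an NA)."""
    text, _ = generate_aaindex(40, na_fraction=0.1, seed=3)
    return build_aa_pcp_matrix(parse_aaindex1(text))


@pytest.fixture(scope="session")
def signal_dataset(aa_pcp):
    """Planted-signal segments (delta 0.8, 3 informative properties)."""
    spec = SignalSpec(n_segments=300, delta=0.8, n_informative=3, seed=11)
    segments, informative = generate_labeled_segments(spec, aa_pcp)
    cont = average_pcp_features(segments, aa_pcp)
    disc = discretize_equal_interval(cont)
    return {"segments": segments, "informative": informative,
            "continuous": cont, "discretized": disc}


@pytest.fixture(scope="session")
def null_dataset(aa_pcp):
    """No-signal segments: labels independent of sequence content."""
    spec = SignalSpec(n_segments=300, delta=0.0, n_informative=0, seed=7)
    segments, _ = generate_labeled_segments(spec, aa_pcp)
    cont = average_pcp_features(segments, aa_pcp)
    disc = discretize_equal_interval(cont)
    return {"segments": segments, "continuous": cont, "discretized": disc}


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_disc():
    """Tiny 3-feature discrete dataset with one informative feature."""
    r = np.random.default_rng(17)
    n = 80
    X = pd.DataFrame(r.integers(0, 3, size=(n, 3)), columns=["a", "b", "c"])
    y = np.where(r.random(n) < 0.85, X["a"] % 2, r.integers(0, 2, size=n))
    return X, np.asarray(y, dtype=int)
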