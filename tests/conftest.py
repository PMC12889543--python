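import numpy as np
import pytest

from chiarep import Config, Sample, SyntheticSpec, make_pair
from chiarep.simulate import write_library

# Scoring geometry used throughout the suite: 1 Mb windows at 10 kb bins on
# the 3 Mb synthetic chromosome (5 windows of 100 bins each).
DESK_CONFIG = dict(window_size_bp=1_000_000, bin_size_bp=10_000)


@pytest.fixture
def desk_config():
    return Config(**DESK_CONFIG)


@pytest.fixture
def replicate_pair():
    spec = SyntheticSpec(seed=7)
    return make_pair(spec, "replicate")


@pytest.fixture
def replicate_samples(replicate_pair):
    (A1, b1), (A2, b2) = replicate_pair
    return (Sample.from_arrays("rep1", A1.values, b1.values),
            Sample.from_arrays("rep2", A2.values, b2.values))


@pytest.fixture
def fixture_library_dir(tmp_path):
    """A small simulated library written as BEDPE + bedGraph + chrom.sizes."""
    spec = SyntheticSpec(n_bins=60, seed=11)
    (A, b), _ = make_pair(spec, "replicate")
    paths = write_library(A, b, tmp_path / "lib", prefix="s1")
    paths["matrix"] = A
    paths["signal_vec"] = b
    return paths


def toy_loop_window(n_bins=20, loop=(3, 16), loop_strength=50.0):
    """Near-diagonal banded matrix plus one long-range loop."""
    idx = np.arange(n_bins)
    A = 10.0 * (np.abs(idx[:, None] - idx[None, :]) <= 1)
    np.fill_diagonal(A, 0.0)
    i, j = loop
    A[i, j] = A[j, i] = loop_strength
    return A
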