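import numpy as np
import pytest

from transcomp import SequenceRecord
from transcomp.synthetic import (BenchmarkConfig, MarkovModel,
                                 balanced_signal_set, generate_benchmark)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[c] for c in rng.integers(0, 4, size=length))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def random_records(rng):
    """100 unlabelled random sequences of length 50..5000."""
    out = []
    for i in range(100):
        L = int(rng.integers(50, 5001))
        out.append(SequenceRecord(f"r{i:03d}", random_dna(rng, L)))
    return out


@pytest.fixture(scope="session")
def null_benchmark():
    """Two groups from the same background model (no planted signal)."""
    cfg = BenchmarkConfig(n_pos=50, n_neg=50, length_median=2000,
                          length_log_sd=0.3, min_length=800, signal={},
                          seed=424242)
    records, truth = generate_benchmark(cfg)
    return records, truth


@pytest.fixture(scope="session")
def shifted_benchmark():
    """Balanced order-5 signal pairs planted as a global shift."""
    bg = MarkovModel.skewed()
    signal = balanced_signal_set(n_pairs=6, delta=0.22, core_length=4,
                                 background=bg, seed=7)
    cfg = BenchmarkConfig(n_pos=60, n_neg=60, length_median=4000,
                          length_log_sd=0.35, min_length=1500,
                          background=bg, signal=signal, seed=99)
    records, truth = generate_benchmark(cfg)
    return records, truth
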