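import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

import hgtlink as hl


@pytest.fixture(scope="session")
def benchmark():
    """The default synthetic benchmark instance (seeded)."""
    return hl.generate(hl.SynthSpec(rng_seed=20))


@pytest.fixture(scope="session")
def tiny_graph():
    """A 50-node instance for smoke tests."""
    return hl.generate(hl.SynthSpec(n_drugs=15, n_diseases=10, n_proteins=25,
                                    n_blocks=2, rng_seed=3))


@pytest.fixture(scope="session")
def trained_benchmark(benchmark):
    """Benchmark model trained once and shared across evaluation tests."""
    from hgtlink.benchmark import benchmark_config, run_benchmark
    rec, eq_report, out = run_benchmark(benchmark, rng_seed=7)
    return {"config": benchmark_config(), "recovery": rec, "eq_report": eq_report,
            "output": out, "data": benchmark}


@pytest.fixture()
def rng():
    return np.random.Generator(np.random.PCG64(0))
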