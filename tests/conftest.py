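import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from ssrscape.benchmarks import scaled_config
from ssrscape.detect import find_ssrs_genome
from ssrscape.simulate import simulate_genome


@pytest.fixture(scope="session")
def small_sim():
    """One 1 Mb synthetic genome with its truth and detected SSRs,
    shared across tests (seed-fixed, read-only)."""
    cfg = scaled_config(seed=42, genome_length=1_000_000)
    sequences, truth = simulate_genome(cfg)
    records = find_ssrs_genome(sequences)
    return {"cfg": cfg, "sequences": sequences, "truth": truth,
            "records": records}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
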