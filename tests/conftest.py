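import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

import mitokit as mk


@pytest.fixture(scope="session")
def default_config():
    return mk.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def ancestor(default_config):
    return mk.build_ancestor(default_config)


@pytest.fixture(scope="session")
def clade(default_config, ancestor):
    """Default 7-tip simulated clade (outgroup + 6 ingroup tips)."""
    chron = mk.default_chronogram()
    tips, truth = mk.evolve_clade(ancestor, chron, default_config)
    return tips, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_alignment(rng, n_rows, n_cols, missing_rate=0.05):
    """Random small alignment over A,C,G,T with sprinkled N/-."""
    alphabet = np.array(list("ACGT"))
    rows = []
    for i in range(n_rows):
        chars = alphabet[rng.integers(0, 4, size=n_cols)]
        miss = rng.random(n_cols) < missing_rate
        sym = np.where(rng.random(n_cols) < 0.5, "N", "-")
        chars = np.where(miss, sym, chars)
        rows.append((f"t{i}", "".join(chars)))
    return rows
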