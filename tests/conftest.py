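import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import treegenval as tg

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


def random_pedigree(rng, n, n_founders=None, groups=("g1", "g2")):
    """Random acyclic pedigree with labelled founders (topological by build)."""
    n_founders = n_founders or max(4, n // 5)
    sire = np.full(n, -1, dtype=np.int64)
    dam = np.full(n, -1, dtype=np.int64)
    for i in range(n_founders, n):
        s, d = rng.choice(i, size=2, replace=False)
        sire[i], dam[i] = s, d
    glabels = np.asarray(
        [groups[k % len(groups)] if sire[k] < 0 else "" for k in range(n)], dtype=object
    )
    ids = np.asarray([f"i{k:04d}" for k in range(n)], dtype=object)
    return tg.Pedigree(ids, sire, dam, glabels)


@pytest.fixture
def rng():
    return np.random.default_rng(20250923)


@pytest.fixture(scope="session")
def tiny_pop():
    """Small simulated population shared by read-only tests."""
    cfg = tg.paper_like_config(scale=0.05, n_markers=600, n_qtl=80)
    return tg.simulate_population(cfg, seed=42)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_pop):
    return tiny_pop.to_dataset()


@pytest.fixture
def trio():
    df = pd.DataFrame({
        "id": ["A", "B", "C"],
        "sire": [tg.UNKNOWN, tg.UNKNOWN, "A"],
        "dam": [tg.UNKNOWN, tg.UNKNOWN, "B"],
        "group": ["g1", "g1", ""],
    })
    return tg.RawPedigreeTable(df)
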