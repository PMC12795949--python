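import numpy as np
import pandas as pd
import pytest

import pondiv as pv


@pytest.fixture(scope="session")
def default_dataset():
    """One default-config synthetic metacommunity (two contrasting regions)."""
    return pv.generate_metacommunity(pv.GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def aligned(default_dataset):
    cm, tm, _ = default_dataset
    return pv.align(cm, tm)


@pytest.fixture
def toy_cm():
    """2 ponds x 2 species toy community."""
    counts = pd.DataFrame(
        [[5, 0], [2, 3]], index=["p1", "p2"], columns=["s1", "s2"]
    )
    return pv.CommunityMatrix(counts, {"p1": "A", "p2": "B"})


def small_community(counts, regions=None):
    counts = np.asarray(counts)
    ponds = [f"p{i+1}" for i in range(counts.shape[0])]
    species = [f"s{j+1}" for j in range(counts.shape[1])]
    regions = regions or {p: "A" for p in ponds}
    if not isinstance(regions, dict):
        regions = dict(zip(ponds, regions))
    return pv.CommunityMatrix(
        pd.DataFrame(counts, index=ponds, columns=species), regions
    )
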