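import numpy as np
import pandas as pd
import pytest

from pathblend import (
    OmicsBlock,
    OutcomeVector,
    PathwayCollection,
    PathwayDef,
    SyntheticBaseConfig,
    apply_standardizer,
    fit_standardizer,
    generate_base,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_block(rng):
    """50 samples x 12 molecules of standardizable Gaussian data."""
    data = pd.DataFrame(
        rng.standard_normal((50, 12)),
        index=[f"s{i:02d}" for i in range(50)],
        columns=[f"m{i}" for i in range(12)],
    )
    return OmicsBlock(data=data, omics_label="metabolomics", is_log_scale=True)


@pytest.fixture
def std_block(small_block):
    return apply_standardizer(fit_standardizer(small_block), small_block)


@pytest.fixture
def small_pathways():
    return PathwayCollection(
        pathways=[
            PathwayDef("P1", "four-member", frozenset(["m0", "m1", "m2", "m3"])),
            PathwayDef("P2", "three-member", frozenset(["m4", "m5", "m6"])),
            PathwayDef("P3", "two-member", frozenset(["m7", "m8"])),
        ]
    )


@pytest.fixture
def binary_y(small_block, rng):
    vals = np.zeros(50, dtype=int)
    vals[:25] = 1
    return OutcomeVector(
        values=pd.Series(rng.permutation(vals), index=small_block.sample_ids),
        binary=True,
    )


@pytest.fixture(scope="session")
def synthetic_base():
    """Default-condition synthetic base dataset, shared across tests."""
    config = SyntheticBaseConfig(seed=20240101)
    return generate_base(config)
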