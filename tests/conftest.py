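import numpy as np
import pandas as pd
import pytest

from medipdmr import normalize, regions, synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_regionset():
    return regions.RegionSet(
        pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr2"],
                "start": [100, 500, 50],
                "end": [200, 900, 150],
                "region_id": ["r1", "r2", "r3"],
            }
        )
    )


@pytest.fixture
def small_count_matrix(rng):
    R, S = 50, 12
    vals = pd.DataFrame(
        rng.poisson(100, size=(R, S)).astype(float),
        index=[f"r{i}" for i in range(R)],
        columns=[f"s{i}" for i in range(S)],
    )
    return normalize.CountMatrix(
        values=vals,
        lengths=pd.Series(rng.integers(300, 1000, R).astype(float), index=vals.index),
        totals=vals.sum(axis=0),
        state="raw",
    )


@pytest.fixture
def dev_design():
    return synthetic.developmental_design()


def random_intervals(rng, n, chrom="chr1", lo=0, hi=10000, min_len=5, max_len=200):
    starts = rng.integers(lo, hi - max_len, n)
    lens = rng.integers(min_len, max_len, n)
    return pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": starts + lens,
         "region_id": [f"iv{i}" for i in range(n)]}
    )
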