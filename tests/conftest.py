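import numpy as np
import pandas as pd
import pytest

from cryptomap.markers import MarkerMap


def tiny_map(positions, chrom_length=None, name="chr1"):
    """A single-chromosome MarkerMap at explicit positions."""
    positions = list(positions)
    length = chrom_length or positions[-1] + 1000
    table = pd.DataFrame(
        {
            "chrom": [name] * len(positions),
            "pos": positions,
            "allele_p1": ["A"] * len(positions),
            "allele_p2": ["C"] * len(positions),
            "marker_id": [f"{name}_{p}" for p in positions],
        }
    )
    return MarkerMap(chromosomes=((name, length),), table=table)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
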