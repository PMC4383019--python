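import numpy as np
import pandas as pd
import pytest

from papevo import simdata
from papevo.variant_filters import SomaticVariant


@pytest.fixture
def small_tree():
    return simdata.simulate_clone_tree(4, 3, (0.5, 0.9), seed=11)


@pytest.fixture
def passing_variant():
    """A variant that passes every rule of every filter set."""
    def make(**overrides):
        base = dict(
            chrom="chr1", pos=100, ref="A", alt="G", variant_class="SNV",
            tumour_depth=100, tumour_alt=30, normal_depth=60, normal_alt=0,
            region_depths={"R1": 100}, region_alts={"R1": 30},
            mappability=1.0, segdup=False,
            pop_freq={"EVS": 0.0, "1000G": 0.0, "CG69": 0.0, "local": 0.0},
            dbsnp132=False, base_quality=35.0, unique_mapping=True,
            sift=0.0, polyphen=1.0, effect="non-synonymous SNV",
        )
        base.update(overrides)
        return SomaticVariant(**base)
    return make


@pytest.fixture
def presence_matrix():
    """3 regions x 6 mutations: 3 truncal, 2 in a (R1,R2) clade, 1 private."""
    data = {
        "M1": [1, 1, 1], "M2": [1, 1, 1], "M3": [1, 1, 1],
        "M4": [1, 1, 0], "M5": [1, 1, 0], "M6": [0, 0, 1],
    }
    return pd.DataFrame(data, index=["R1", "R2", "R3"], dtype=float)


def rng(seed=0):
    return np.random.default_rng(seed)
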