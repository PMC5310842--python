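import numpy as np
import pandas as pd
import pytest

from tethermap import simulate
from tethermap.fragments import ChromSizes, FragmentSet


@pytest.fixture(scope="session")
def small_sim():
    """One modest simulation shared by read-only tests."""
    cfg = simulate.default_config(seed=11, genome_length=160_000, n_chroms=2,
                                  n_direct_sites=40, n_indirect_sites=10,
                                  n_centromere_sites=4, frags_per_site=50)
    genome, truth, cs, spike_cs = simulate.make_genome(cfg)
    prim, spk = simulate.simulate_fragments(cfg, truth, cs, spike_cs, time_index=0)
    return dict(cfg=cfg, genome=genome, truth=truth, cs=cs, spike_cs=spike_cs,
                primary=prim, spike=spk)


@pytest.fixture
def tiny_cs():
    return ChromSizes({"chr1": 1000, "chr2": 500})


def make_fragset(records, genome="primary", **meta):
    df = pd.DataFrame(records, columns=["chrom", "start", "end"])
    return FragmentSet(df=df, genome=genome, meta=meta)


@pytest.fixture
def fragset_factory():
    return make_fragset
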