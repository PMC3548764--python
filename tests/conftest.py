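import numpy as np
import pytest

from svfuse import synthdata
from svfuse.model import LibrarySpec, ReferenceGenome


@pytest.fixture(scope="session")
def small_ref():
    return synthdata.generate_reference(2, [120_000, 80_000], gc=0.41, seed=11)


@pytest.fixture()
def pe_lib():
    return LibrarySpec("pe500", 36, 504, 404, 619, n_pairs=5_000)


@pytest.fixture()
def lib_specs(pe_lib):
    mp = LibrarySpec("mp3k", 36, 3_000, 2_500, 3_600, n_pairs=2_000)
    return {pe_lib.name: pe_lib, mp.name: mp}


@pytest.fixture(scope="session")
def demo_scenario():
    from svfuse import demo
    return demo.build_demo(seed=0)


def make_pair(pair_id="p1", library="pe500", chrom1="chr1", pos1=1_000,
              strand1="+", mapq1=60, chrom2="chr1", pos2=1_503, strand2="-",
              mapq2=60, **extra):
    row = {"pair_id": pair_id, "library": library,
           "chrom1": chrom1, "pos1": pos1, "strand1": strand1, "mapq1": mapq1,
           "chrom2": chrom2, "pos2": pos2, "strand2": strand2, "mapq2": mapq2}
    row.update(extra)
    return row


@pytest.fixture()
def pair_factory():
    import pandas as pd

    def factory(rows):
        return pd.DataFrame([make_pair(**r) for r in rows])

    return factory
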