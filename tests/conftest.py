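import numpy as np
import pandas as pd
import pytest

from mirtriad.io import MirnaLocus

# mature miR-34c-5p sequence; its positions 2-8 are the canonical
# miR-449/34-family seed GGCAGTG
MIR34C_MATURE = "AGGCAGTGTAGTTAGCTGATTGC"


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def plus_locus():
    return MirnaLocus(
        name="mirA", chrom="chr1", start=100, end=122, strand="+",
        mature_sequence="A" * 22,
    )


def make_reads(rows):
    """BED6+sequence frame from (chrom, start, end, sample, strand) tuples."""
    return pd.DataFrame(
        [(c, s, e, name, 0, st, "A" * (e - s)) for c, s, e, name, st in rows],
        columns=["chrom", "start", "end", "name", "score", "strand", "sequence"],
    )
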