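"""Count reads at a miRNA locus and group them into 5' isomiRs.

Simulates 2000 reads at one locus with a 70/20/10 mixture of 5' start
offsets, counts them, and shows the isomiR table plus log2-RPM
normalization of the resulting counts.
"""

import pandas as pd

from mirtriad import (
    CountMatrix,
    count_reads_per_mirna,
    group_isomirs,
    rpm_normalize,
    simulate_reads_at_locus,
)
from mirtriad.io import MirnaLocus
from mirtriad.synthdata import random_genome

genome = random_genome(600, seed=3)
locus = MirnaLocus(name="mir-x", chrom="chr1", start=300, end=322, strand="+",
                   mature_sequence=genome["chr1"][300:322])

reads = simulate_reads_at_locus(
    locus, {0: 0.7, -1: 0.2, 1: 0.1}, n_reads=2000, genome=genome, seed=4
)
counts = count_reads_per_mirna(reads, [locus])
print("locus counts per sample:")
print(counts.values)
print()
print("isomiR records (5' offset -> reads):")
for rec in group_isomirs(reads, locus):
    print(f"  offset {rec.offset5:+d}: {rec.total} reads")
print()
norm = rpm_normalize(counts)
print("log2 RPM of the locus:", norm.values.iloc[0, 0].round(3))
# Offsets near the specified 70/20/10 mixture confirm strand-aware 5'-start
# grouping; counts across offsets always sum to the locus total.
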