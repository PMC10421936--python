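"""File-format bindings shared by the analysis stages.

All tabular data travel as TSV with features in rows and samples in columns
(header row of sample ids).  Aligned small-RNA reads are BED6 plus a seventh
column holding the read sequence; miRNA loci are GFF3 with feature type
``miRNA``.  Genomic coordinates are 0-based half-open internally; GFF3
(1-based, closed) is converted on read and write.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BED_READ_COLUMNS = ["chrom", "start", "end", "name", "score", "strand", "sequence"]


@dataclass(frozen=True)
class MirnaLocus:
    """A mature miRNA locus with its genomic window and mature sequence.

    ``start``/``end`` are 0-based half-open; ``mature_sequence`` is the
    5'->3' mature sequence, whose length must equal ``end - start``.
    """

    name: str
    chrom: str
    start: int
    end: int
    strand: str
    mature_sequence: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"locus {self.name}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"locus {self.name}: strand must be '+' or '-'")
        if len(self.mature_sequence) != self.end - self.start:
            raise ValueError(
                f"locus {self.name}: sequence length {len(self.mature_sequence)} "
                f"!= interval length {self.end - self.start}"
            )


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a feature x sample TSV matrix (first column = feature ids)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t")


def read_reads_bed(path: str | Path) -> pd.DataFrame:
    """Read aligned reads as BED6+sequence.

    Returns a DataFrame with columns chrom/start/end/name/score/strand/sequence;
    the ``name`` column carries the sample id of each read.
    """
    reads = pd.read_csv(path, sep="\t", header=None, names=BED_READ_COLUMNS)
    bad = reads["end"] <= reads["start"]
    if bad.any():
        row = reads.index[bad][0]
        raise ValueError(f"malformed interval at row {row}: end <= start")
    return reads


def write_reads_bed(reads: pd.DataFrame, path: str | Path) -> None:
    reads.loc[:, BED_READ_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_loci_gff3(path: str | Path) -> list[MirnaLocus]:
    """Read miRNA loci from GFF3 (feature type ``miRNA``).

    GFF3 coordinates (1-based closed) are converted to 0-based half-open.
    The mature sequence is taken from the ``sequence`` attribute.
    """
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    loci = []
    for feat in db.features_of_type("miRNA"):
        if feat.end < feat.start:
            raise ValueError(f"GFF3 feature {feat.id}: end < start")
        loci.append(
            MirnaLocus(
                name=feat.attributes.get("Name", [feat.id])[0],
                chrom=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand,
                mature_sequence=feat.attributes["sequence"][0],
            )
        )
    return loci


def write_loci_gff3(loci: Iterable[MirnaLocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for loc in loci:
            attrs = f"ID={loc.name};Name={loc.name};sequence={loc.mature_sequence}"
            fh.write(
                f"{loc.chrom}\tmirtriad\tmiRNA\t{loc.start + 1}\t{loc.end}\t.\t"
                f"{loc.strand}\t.\t{attrs}\n"
            )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence dict (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_genotypes(path: str | Path) -> pd.DataFrame:
    """Read a SNP x sample genotype matrix coded 0/1/2 (NA allowed)."""
    geno = pd.read_csv(path, sep="\t", index_col=0)
    values = geno.to_numpy(dtype=float)
    valid = np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0))
    if not valid.all():
        raise ValueError("genotype matrix contains entries outside {0,1,2,NA}")
    return geno
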