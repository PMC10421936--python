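"""Turn aligned small-RNA reads into QC'd, normalized miRNA expression.

Counting follows the simplest faithful interval rule: a read increments a
locus if it overlaps it by at least one base on the same strand, and a read
overlapping k loci increments all k (multi-counted, documented).  Per-sample
totals are the number of reads assigned to at least one locus, which is what
the RPM denominator uses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MirnaLocus

logger = logging.getLogger(__name__)

QC_LENGTH_BINS = np.arange(15, 37)  # 15..36 nt inclusive


@dataclass
class CountMatrix:
    """Integer miRNA x sample counts plus per-sample locus-aligned totals."""

    values: pd.DataFrame
    sample_totals: pd.Series
    batch: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        self.sample_totals = self.sample_totals.reindex(self.values.columns)


@dataclass
class NormalizedMatrix:
    """log2 RPM expression (pseudocount 1), optionally batch-adjusted."""

    values: pd.DataFrame
    pseudocount: float = 1.0
    batch_adjusted: bool = False


def count_reads_per_mirna(reads: pd.DataFrame, loci: list[MirnaLocus]) -> CountMatrix:
    """Count reads overlapping each mature miRNA locus, per sample.

    ``reads`` is a BED6+sequence frame whose ``name`` column is the sample id.
    Overlap = >=1 shared base, same strand, same chromosome.  A read hitting
    several loci is counted toward each; ``sample_totals`` count each read
    once if it hit any locus.
    """
    if (reads["end"] <= reads["start"]).any():
        raise ValueError("malformed read interval: end <= start")
    samples = list(pd.unique(reads["name"]))
    sample_idx = {s: j for j, s in enumerate(samples)}
    counts = np.zeros((len(loci), len(samples)), dtype=int)
    assigned = np.zeros(len(reads), dtype=bool)

    starts = reads["start"].to_numpy()
    ends = reads["end"].to_numpy()
    chroms = reads["chrom"].to_numpy()
    strands = reads["strand"].to_numpy()
    cols = reads["name"].map(sample_idx).to_numpy()
    for i, locus in enumerate(loci):
        hit = (
            (chroms == locus.chrom)
            & (strands == locus.strand)
            & (starts < locus.end)
            & (ends > locus.start)
        )
        assigned |= hit
        if hit.any():
            counts[i] = np.bincount(cols[hit], minlength=len(samples))
    totals = pd.Series(
        np.bincount(cols[assigned], minlength=len(samples)), index=samples, dtype=int
    )
    values = pd.DataFrame(counts, index=[l.name for l in loci], columns=samples)
    return CountMatrix(values=values, sample_totals=totals)


def read_length_qc(
    read_lengths: dict[str, np.ndarray], outlier_threshold: float = 5.0
) -> pd.DataFrame:
    """Flag samples whose read-length profile is an outlier.

    Builds each sample's length histogram over 15-36 nt (proportions), then
    computes the Euclidean distance of each profile to the per-bin median
    profile; samples farther than ``outlier_threshold`` times the median
    absolute deviation of the distances (above the median distance) fail.
    Empty samples fail automatically.

    Returns a per-sample frame with columns ``distance``, ``pass``, ``reason``.
    """
    if len(read_lengths) < 3:
        raise ValueError("need >=3 samples for a robust median profile")
    bins = np.append(QC_LENGTH_BINS, QC_LENGTH_BINS[-1] + 1)
    profiles, empties = {}, []
    for sample, lengths in read_lengths.items():
        lengths = np.asarray(lengths)
        if lengths.size == 0:
            empties.append(sample)
            continue
        hist, _ = np.histogram(np.clip(lengths, bins[0], bins[-2]), bins=bins)
        profiles[sample] = hist / hist.sum()
    if len(profiles) < 3:
        raise ValueError("need >=3 non-empty samples for a robust median profile")
    mat = pd.DataFrame(profiles).T
    median_profile = mat.median(axis=0)
    dist = np.sqrt(((mat - median_profile) ** 2).sum(axis=1))
    mad = np.median(np.abs(dist - dist.median()))
    cutoff = dist.median() + outlier_threshold * mad
    report = pd.DataFrame({"distance": dist})
    # zero MAD (identical profiles): nothing can be an outlier
    report["pass"] = dist <= cutoff if mad > 0 else True
    report["reason"] = np.where(report["pass"], "", "length-profile outlier")
    for sample in empties:
        report.loc[sample] = [np.nan, False, "empty sample"]
    return report.reindex(read_lengths.keys())


def rpm_normalize(counts: CountMatrix) -> NormalizedMatrix:
    """log2 reads-per-million with a pseudocount of one.

    value = log2((count + 1) / sample_total * 1e6); the totals are the raw
    locus-aligned read counts (not pseudocount-inflated).
    """
    totals = counts.sample_totals
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero locus-aligned total for sample(s): {list(zero.index)}")
    rpm = (counts.values + 1).div(totals, axis=1) * 1e6
    return NormalizedMatrix(values=np.log2(rpm))


def detection_filter(
    counts: CountMatrix | pd.DataFrame, min_count: int = 2, min_fraction: float = 0.5
) -> list[str]:
    """miRNAs detected with >= ``min_count`` reads in >= ``min_fraction`` of samples."""
    values = counts.values if isinstance(counts, CountMatrix) else counts
    frac = (values >= min_count).mean(axis=1)
    return list(values.index[frac >= min_fraction])


@dataclass
class IsomiRRecord:
    """A 5'-start variant at a locus: signed offset, per-sample counts."""

    locus: str
    offset5: int
    counts: pd.Series = field(repr=False)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def group_isomirs(reads: pd.DataFrame, locus: MirnaLocus) -> list[IsomiRRecord]:
    """Group a locus's reads by 5' start position into isomiR records.

    The offset is computed from coordinates, strand-aware: on the plus strand
    ``offset5 = read.start - locus.start``; on the minus strand the 5' end is
    the interval end, so ``offset5 = locus.end - read.end`` (negative =
    upstream of the canonical 5' end in transcript orientation).  Reads on
    the wrong strand are ignored and logged.
    """
    on_locus = reads[
        (reads["chrom"] == locus.chrom)
        & (reads["start"] < locus.end)
        & (reads["end"] > locus.start)
    ]
    wrong = on_locus[on_locus["strand"] != locus.strand]
    if len(wrong):
        logger.warning("%d reads on wrong strand at %s ignored", len(wrong), locus.name)
    good = on_locus[on_locus["strand"] == locus.strand]
    if locus.strand == "+":
        offsets = good["start"] - locus.start
    else:
        offsets = locus.end - good["end"]
    samples = list(pd.unique(reads["name"]))
    records = []
    for off, grp in good.groupby(offsets):
        per_sample = grp["name"].value_counts().reindex(samples, fill_value=0)
        records.append(IsomiRRecord(locus=locus.name, offset5=int(off), counts=per_sample))
    records.sort(key=lambda r: r.offset5)
    return records


def batch_adjust(
    matrix: NormalizedMatrix,
    batch: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> NormalizedMatrix:
    """Remove batch (sequencing-protocol) effects by parametric empirical
    Bayes location/scale adjustment (ComBat), preserving covariate signal.

    With a single batch the input is returned unchanged; a singleton batch is
    an error (its variance is not estimable).
    """
    import anndata
    import scanpy as sc

    batch = batch.reindex(matrix.values.columns)
    if batch.isna().any():
        raise ValueError("batch labels missing for some samples")
    sizes = batch.value_counts()
    if len(sizes) == 1:
        return NormalizedMatrix(values=matrix.values.copy(), batch_adjusted=True)
    if (sizes < 2).any():
        raise ValueError(f"singleton batch(es): {list(sizes.index[sizes < 2])}")

    obs = pd.DataFrame({"batch": batch.astype(str)})
    cov_keys = []
    if covariates is not None:
        covariates = covariates.reindex(matrix.values.columns)
        for col in covariates.columns:
            obs[col] = covariates[col].to_numpy()
            cov_keys.append(col)
    adata = anndata.AnnData(
        X=matrix.values.to_numpy(dtype=float).T.copy(), obs=obs
    )
    sc.pp.combat(adata, key="batch", covariates=cov_keys or None)
    adjusted = pd.DataFrame(
        adata.X.T, index=matrix.values.index, columns=matrix.values.columns
    )
    return NormalizedMatrix(values=adjusted, batch_adjusted=True)
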