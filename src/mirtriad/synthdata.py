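"""Synthetic cohorts with the statistical structure the analysis assumes.

Every downstream stage of the pipeline is exercised against data generated
here, with full ground truth: Hardy-Weinberg genotypes, planted
SNP->miRNA->mRNA mediation triplets of four generative classes, negative
binomial read counts with library-size and batch effects, 5'-offset isomiR
reads at synthetic loci, and clinical phenotypes with cluster structure.

Triplet classes (L = genotype, G = miRNA, T = gene; noise standard normal,
effects are standardized slopes on a unit-variance genotype score):

* ``causal``       G = a*L + e1,  T = b*G + e2         (L -> G -> T)
* ``reactive``     T = c*L + e3,  G = d*T + e4         (L -> T -> G)
* ``independent``  G = a*L + e1,  T = c*L + e3         (common driver, no G-T path)
* ``null``         G, T pure noise

All generators take an explicit seed and are bit-reproducible; there is no
hidden global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio

TRIPLET_CLASSES = ("causal", "reactive", "independent", "null")

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class TripletSpec:
    """Generative class and standardized effect sizes for one planted triplet.

    ``effect_snp_mirna`` is the slope on the first generated arrow
    (L->G for causal/independent, L->T for reactive); ``effect_mirna_gene``
    the slope on the second (G->T for causal, T->G for reactive, L->T for
    independent).
    """

    klass: str
    effect_snp_mirna: float = 0.8
    effect_mirna_gene: float = 0.8

    def __post_init__(self) -> None:
        if self.klass not in TRIPLET_CLASSES:
            raise ValueError(f"unknown triplet class {self.klass!r}")
        if not (np.isfinite(self.effect_snp_mirna) and np.isfinite(self.effect_mirna_gene)):
            raise ValueError("triplet effects must be finite")


@dataclass
class SimConfig:
    """Parameters of a simulated cohort."""

    n_subjects: int = 200
    n_snps: int = 50
    maf_range: tuple[float, float] = (0.2, 0.5)
    n_mirna: int = 50
    n_gene: int = 50
    triplet_spec: list[TripletSpec] = field(default_factory=list)
    nb_dispersion: float = 2.0
    lib_size_range: tuple[int, int] = (500_000, 2_000_000)
    batch_labels: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if min(self.lib_size_range) < 1:
            raise ValueError("library sizes must be >= 1")
        n_triplets = len(self.triplet_spec)
        if n_triplets > min(self.n_snps, self.n_mirna, self.n_gene):
            raise ValueError("more planted triplets than available feature ids")


def simulate_genotypes(
    n_subjects: int,
    n_snps: int,
    maf_range: tuple[float, float] = (0.2, 0.5),
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a SNP x sample genotype matrix under Hardy-Weinberg equilibrium.

    Each SNP's minor-allele frequency is drawn uniformly from ``maf_range``
    and genotypes are Binomial(2, maf), i.e. HWE with independent SNPs.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(lo, hi, size=n_snps)
    geno = rng.binomial(2, mafs[:, None], size=(n_snps, n_subjects))
    return pd.DataFrame(
        geno,
        index=[f"snp{i}" for i in range(n_snps)],
        columns=[f"s{i}" for i in range(n_subjects)],
    )


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return x - x.mean()
    return (x - x.mean()) / sd


def simulate_triplets(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate genotypes plus miRNA/gene expression with planted triplets.

    Returns ``(genotypes, mirna_expression, gene_expression, truth)``.
    Triplet ``i`` uses snp ``snp{i}``, miRNA ``mir{i}`` and gene ``gene{i}``;
    features beyond the planted triplets are pure standard-normal noise.
    ``truth`` records class and the realized slopes per triplet.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    geno = simulate_genotypes(n, config.n_snps, config.maf_range, seed=int(rng.integers(2**31)))

    mirna = rng.standard_normal((config.n_mirna, n))
    gene = rng.standard_normal((config.n_gene, n))
    rows = []
    for i, spec in enumerate(config.triplet_spec):
        L = _standardize(geno.iloc[i].to_numpy(dtype=float))
        a, b = spec.effect_snp_mirna, spec.effect_mirna_gene
        if spec.klass == "causal":
            G = a * L + rng.standard_normal(n)
            T = b * G + rng.standard_normal(n)
        elif spec.klass == "reactive":
            T = a * L + rng.standard_normal(n)
            G = b * T + rng.standard_normal(n)
        elif spec.klass == "independent":
            G = a * L + rng.standard_normal(n)
            T = b * L + rng.standard_normal(n)
        else:  # null
            G = rng.standard_normal(n)
            T = rng.standard_normal(n)
        mirna[i] = G
        gene[i] = T
        rows.append(
            {
                "triplet": i,
                "class": spec.klass,
                "snp_id": geno.index[i],
                "mirna_id": f"mir{i}",
                "gene_id": f"gene{i}",
                "effect_snp_mirna": a,
                "effect_mirna_gene": b,
            }
        )
    samples = geno.columns
    mirna_df = pd.DataFrame(mirna, index=[f"mir{i}" for i in range(config.n_mirna)], columns=samples)
    gene_df = pd.DataFrame(gene, index=[f"gene{i}" for i in range(config.n_gene)], columns=samples)
    truth = pd.DataFrame(rows)
    return geno, mirna_df, gene_df, truth


def simulate_counts(
    log_means: np.ndarray,
    dispersion: float,
    lib_sizes: np.ndarray,
    batch_shifts: np.ndarray | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a miRNA x sample negative binomial count matrix.

    The mean of feature i in sample j is
    ``exp(log_means[i] + log(lib_sizes[j] / median lib size) + batch_shifts[j])``
    and the NB size (theta) is ``dispersion``, so Var = mu + mu^2 / theta.
    The library-size term enters the log-mean as a covariate-style offset
    around the median depth, mirroring depth-as-predictor modelling.
    """
    log_means = np.asarray(log_means, dtype=float)
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    if dispersion <= 0:
        raise ValueError("dispersion (NB size theta) must be positive")
    if np.any(lib_sizes < 1):
        raise ValueError("library sizes must be >= 1")
    if not np.all(np.isfinite(log_means)):
        raise ValueError("log_means must be finite")
    if batch_shifts is None:
        batch_shifts = np.zeros(lib_sizes.shape[0])
    batch_shifts = np.asarray(batch_shifts, dtype=float)
    rng = np.random.default_rng(seed)
    depth_term = np.log(lib_sizes / np.median(lib_sizes))
    mu = np.exp(log_means[:, None] + depth_term[None, :] + batch_shifts[None, :])
    # NB(mean mu, size theta) == Gamma-Poisson mixture
    lam = rng.gamma(shape=dispersion, scale=mu / dispersion)
    counts = rng.poisson(lam)
    return pd.DataFrame(
        counts,
        index=[f"mir{i}" for i in range(log_means.shape[0])],
        columns=[f"s{j}" for j in range(lib_sizes.shape[0])],
    )


def random_genome(length: int, seed: int = 0, chrom: str = "chr1") -> dict[str, str]:
    """A single random chromosome of uniform base composition."""
    rng = np.random.default_rng(seed)
    return {chrom: "".join(_BASES[rng.integers(0, 4, size=length)])}


def simulate_reads_at_locus(
    locus: mio.MirnaLocus,
    offset_distribution: dict[int, float],
    n_reads: int,
    genome: dict[str, str],
    seed: int = 0,
    sample: str = "s0",
) -> pd.DataFrame:
    """Draw reads at a locus with multinomial 5' offsets.

    Each read is an interval of the locus length starting at
    ``locus.start + offset`` (on the minus strand the 5' end is the interval
    end, so the window shifts by ``-offset``), with sequence equal to the
    genomic sequence of that window.  Returns a BED6+sequence DataFrame.
    """
    offsets = np.array(sorted(offset_distribution), dtype=int)
    probs = np.array([offset_distribution[o] for o in offsets], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("offset probabilities must sum to 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_reads, probs)
    chrom_seq = genome[locus.chrom]
    length = locus.end - locus.start
    rows = []
    for off, cnt in zip(offsets, counts):
        if cnt == 0:
            continue
        if locus.strand == "+":
            start = locus.start + int(off)
        else:
            # 5' end of a minus-strand read is the interval end
            start = locus.start - int(off)
        end = start + length
        seq = chrom_seq[start:end]
        for k in range(cnt):
            rows.append((locus.chrom, start, end, sample, 0, locus.strand, seq))
    return pd.DataFrame(rows, columns=mio.BED_READ_COLUMNS)


@dataclass
class SyntheticCohort:
    """Bundle of every input the pipeline consumes, plus ground truth."""

    loci: list[mio.MirnaLocus]
    genome: dict[str, str]
    reads: pd.DataFrame
    counts: pd.DataFrame
    genotypes: pd.DataFrame
    mirna_expression: pd.DataFrame
    gene_expression: pd.DataFrame
    covariates: pd.DataFrame
    utr_sequences: dict[str, str]
    snp_positions: pd.DataFrame
    feature_positions: pd.DataFrame
    truth_triplets: pd.DataFrame
    truth_samples: pd.DataFrame


def simulate_cohort(config: SimConfig, n_clusters: int = 3, cluster_effect: float = 1.5) -> SyntheticCohort:
    """Generate a full end-to-end cohort.

    Layers, in order: HWE genotypes and planted mediation triplets on the
    continuous scale; sample cluster labels shifting disjoint miRNA modules
    by ``cluster_effect`` standard deviations; disease labels (control/COPD/ILD)
    with cluster-dependent enrichment; clinical covariates (age, gender,
    smoking) and two sequencing-protocol batches; NB counts whose log-means
    track the continuous miRNA signal; reads with 5' isomiR offsets at a few
    loci; synthetic 3'UTRs seeded with target sites for the first miRNA.
    """
    rng = np.random.default_rng(config.seed)
    geno, mirna, gene, truth = simulate_triplets(config)
    n = config.n_subjects
    samples = list(mirna.columns)

    # sample-level structure
    cluster = rng.integers(0, n_clusters, size=n)
    module = rng.integers(0, n_clusters, size=config.n_mirna)
    n_triplets = len(config.triplet_spec)
    for c in range(n_clusters):
        members = (module == c) & (np.arange(config.n_mirna) >= n_triplets)
        mirna.loc[mirna.index[members], :] += cluster_effect * (cluster == c)[None, :]

    disease_probs = np.full((n_clusters, 3), 1 / 3)
    disease_probs[0] = [0.6, 0.2, 0.2]          # control-enriched baseline cluster
    if n_clusters > 1:
        disease_probs[1] = [0.15, 0.65, 0.20]   # COPD-enriched
    if n_clusters > 2:
        disease_probs[2] = [0.15, 0.20, 0.65]   # ILD-enriched
    disease = np.array(
        [rng.choice(["Control", "COPD", "ILD"], p=disease_probs[c]) for c in cluster]
    )
    age = rng.normal(63, 10, size=n).round(1)
    gender = rng.choice(["M", "F"], size=n)
    smoking = rng.choice(["never", "former", "current"], p=[0.3, 0.6, 0.1], size=n)
    batch = np.where(np.arange(n) % 2 == 0, "protocolA", "protocolB")
    lib_sizes = rng.integers(config.lib_size_range[0], config.lib_size_range[1] + 1, size=n)

    # NB counts tracking the continuous miRNA signal, with a batch shift
    base = rng.uniform(2.0, 6.0, size=config.n_mirna)
    disease_shift = np.zeros((config.n_mirna, n))
    de_idx = np.arange(config.n_mirna) % 3 == 0   # every third miRNA disease-responsive
    disease_shift[np.ix_(de_idx, disease != "Control")] = 0.5
    log_means = base[:, None] + 0.3 * mirna.to_numpy() + disease_shift
    batch_shift = np.where(batch == "protocolB", 0.4, 0.0)
    depth_term = np.log(lib_sizes / np.median(lib_sizes))
    mu = np.exp(log_means + depth_term[None, :] + batch_shift[None, :])
    lam = rng.gamma(shape=config.nb_dispersion, scale=mu / config.nb_dispersion)
    counts = pd.DataFrame(rng.poisson(lam), index=mirna.index, columns=samples)

    covariates = pd.DataFrame(
        {
            "age": age,
            "gender": gender,
            "smoking": smoking,
            "protocol": batch,
            "disease": disease,
            "lib_size": lib_sizes,
        },
        index=samples,
    )

    # genome, loci and isomiR reads for the first few miRNAs of sample s0
    spacing, mirna_len = 200, 22
    genome = random_genome(spacing * (config.n_mirna + 2), seed=int(rng.integers(2**31)))
    chrom_seq = genome["chr1"]
    loci = []
    for i in range(config.n_mirna):
        start = spacing * (i + 1)
        loci.append(
            mio.MirnaLocus(
                name=f"mir{i}", chrom="chr1", start=start, end=start + mirna_len,
                strand="+" if i % 2 == 0 else "-",
                mature_sequence=chrom_seq[start:start + mirna_len],
            )
        )
    read_frames = []
    offsets = {0: 0.7, -1: 0.2, 1: 0.1}
    for j, s in enumerate(samples):
        for i in range(min(5, config.n_mirna)):
            n_reads = int(counts.iloc[i, j] % 200) + 20  # keep read files small
            read_frames.append(
                simulate_reads_at_locus(
                    loci[i], offsets, n_reads, genome,
                    seed=int(rng.integers(2**31)), sample=s,
                )
            )
    reads = pd.concat(read_frames, ignore_index=True)

    # positions: SNPs along chr1, features colocated (cis) or far (trans)
    snp_pos = pd.DataFrame(
        {"chrom": "chr1", "pos": np.arange(config.n_snps) * 10_000},
        index=geno.index,
    )
    feat_ids = list(mirna.index) + list(gene.index)
    feat_chrom = np.where(rng.random(len(feat_ids)) < 0.5, "chr1", "chr2")
    feature_pos = pd.DataFrame(
        {"chrom": feat_chrom, "pos": rng.integers(0, 5_000_000, size=len(feat_ids))},
        index=feat_ids,
    )

    # synthetic 3'UTRs; plant the reverse-complement seed site of mir0 in the
    # UTRs of the first half of genes
    from .targets import reverse_complement

    utrs = {}
    seed0 = loci[0].mature_sequence[1:8]
    site = reverse_complement(seed0) + "A"  # 8mer site
    for gi, gid in enumerate(gene.index):
        u = "".join(_BASES[rng.integers(0, 4, size=120)])
        if gi < config.n_gene // 2:
            u = u[:50] + site + u[50 + len(site):]
        utrs[gid] = u

    truth_samples = pd.DataFrame(
        {"cluster": cluster, "disease": disease, "batch": batch},
        index=samples,
    )
    return SyntheticCohort(
        loci=loci, genome=genome, reads=reads, counts=counts, genotypes=geno,
        mirna_expression=mirna, gene_expression=gene, covariates=covariates,
        utr_sequences=utrs, snp_positions=snp_pos, feature_positions=feature_pos,
        truth_triplets=truth, truth_samples=truth_samples,
    )


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write every pipeline input of a cohort as plain-text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mio.write_reads_bed(cohort.reads, outdir / "reads.bed")
    mio.write_loci_gff3(cohort.loci, outdir / "loci.gff3")
    mio.write_fasta(cohort.genome, outdir / "genome.fa")
    mio.write_fasta(cohort.utr_sequences, outdir / "utrs.fa")
    mio.write_matrix_tsv(cohort.counts, outdir / "counts.tsv")
    mio.write_matrix_tsv(cohort.genotypes, outdir / "genotypes.tsv")
    mio.write_matrix_tsv(cohort.mirna_expression, outdir / "mirna_expression.tsv")
    mio.write_matrix_tsv(cohort.gene_expression, outdir / "gene_expression.tsv")
    cohort.covariates.to_csv(outdir / "covariates.tsv", sep="\t")
    cohort.snp_positions.to_csv(outdir / "snp_positions.tsv", sep="\t")
    cohort.feature_positions.to_csv(outdir / "feature_positions.tsv", sep="\t")
    cohort.truth_triplets.to_csv(outdir / "truth_triplets.tsv", sep="\t", index=False)
    cohort.truth_samples.to_csv(outdir / "truth_samples.tsv", sep="\t")
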