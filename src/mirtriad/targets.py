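"""Seed-based target prediction for canonical miRNAs and 5' isomiRs.

The seed is the heptamer at mature positions 2-8; a 5' isomiR shifts the
mature start and therefore the seed.  Target sites in a 3'UTR are the seed's
reverse complement: 7mer-m8 (positions 2-8), 7mer-A1 (positions 2-7 followed
by an A in the UTR) and 8mer (both).  Downstream utilities compare canonical
and isomiR target sets (four-way gene partition, Spearman correlation with
rank-sum tests, percent-distinct/Jaccard overlap), run preranked GSEA, and
cluster miRNA modules by Jaccard distance of their gene sets.

U and T are treated as equivalent; all matching is in the DNA alphabet and
ambiguous bases (N) never match.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .diffexpr import bh_fdr

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1")


def _dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    return _dna(seq).translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Seed:
    """A 7-mer seed (mature positions 2-8) at a given 5' offset."""

    mirna: str
    offset5: int
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != 7:
            raise ValueError("seed must be exactly 7 nt")
        if set(_dna(self.sequence)) - set("ACGT"):
            raise ValueError(f"seed alphabet invalid: {self.sequence}")


def extract_seed(
    mature_sequence: str,
    offset5: int = 0,
    extended_sequence: str | None = None,
    mature_start: int = 0,
    mirna: str = "mirna",
) -> Seed:
    """Seed of the (possibly 5'-shifted) mature sequence.

    Positions 2-8 (1-based) of the shifted mature sequence; a negative
    ``offset5`` starts upstream of the canonical 5' end, drawing on
    ``extended_sequence`` (a window containing the mature sequence starting
    at ``mature_start``) when the shifted window leaves the mature sequence.
    """
    if extended_sequence is None:
        extended_sequence, mature_start = mature_sequence, 0
    start = mature_start + offset5 + 1  # position 2 of the shifted sequence
    end = start + 7
    if start < 0 or end > len(extended_sequence):
        raise ValueError(
            f"seed window [{start}, {end}) outside available sequence "
            f"(length {len(extended_sequence)})"
        )
    return Seed(mirna=mirna, offset5=offset5, sequence=_dna(extended_sequence[start:end]))


@dataclass(frozen=True)
class TargetSite:
    """One seed-match site in a gene's 3'UTR (0-based position)."""

    gene: str
    site_type: str
    position: int


def scan_target_sites(seed: Seed | str, utr: str, gene: str = "gene") -> list[TargetSite]:
    """All seed-match sites in a 3'UTR.

    The 7-mer reverse complement of the seed is a 7mer-m8 site; the reverse
    complement of seed positions 1-6 (miRNA positions 2-7) followed by A is
    a 7mer-A1 site; a 7mer-m8 followed by A is an 8mer, which suppresses the
    two 7mer calls it contains at the same position.  Overlapping
    occurrences are all reported.
    """
    s = _dna(seed.sequence if isinstance(seed, Seed) else seed)
    if len(s) != 7:
        raise ValueError("seed must be 7 nt")
    utr = _dna(utr)
    m8_site = reverse_complement(s)            # 7 nt, pairs miRNA 2-8
    a1_site = reverse_complement(s[:6]) + "A"  # 7 nt, pairs miRNA 2-7 + A
    sites: list[TargetSite] = []
    eightmer_at: set[int] = set()
    for i in range(len(utr) - 6):
        if utr[i:i + 7] == m8_site:
            if i + 7 < len(utr) and utr[i + 7] == "A":
                sites.append(TargetSite(gene, "8mer", i))
                eightmer_at.add(i)
            else:
                sites.append(TargetSite(gene, "7mer-m8", i))
    for i in range(len(utr) - 6):
        if utr[i:i + 7] == a1_site and (i - 1) not in eightmer_at:
            sites.append(TargetSite(gene, "7mer-A1", i))
    sites.sort(key=lambda t: (t.position, t.site_type))
    return sites


def predict_targets(seed: Seed | str, utrs: dict[str, str]) -> set[str]:
    """Genes whose 3'UTR carries at least one seed-match site."""
    return {g for g, u in utrs.items() if scan_target_sites(seed, u, g)}


@dataclass
class TargetGroups:
    """Disjoint partition of the gene universe by predicted targeting."""

    canonical_only: set[str]
    isomir_only: set[str]
    both: set[str]
    neither: set[str]


def categorize_genes(
    canonical: set[str], isomir: set[str], universe: set[str]
) -> TargetGroups:
    """Partition the universe into canonical-only / isomiR-only / both / neither."""
    outside = (canonical | isomir) - universe
    if outside:
        raise ValueError(f"targets outside universe: {sorted(outside)[:5]}")
    return TargetGroups(
        canonical_only=canonical - isomir,
        isomir_only=isomir - canonical,
        both=canonical & isomir,
        neither=universe - canonical - isomir,
    )


def spearman_profile(
    mirna_expression: pd.Series, gene_expression: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene Spearman correlation (and p) with one miRNA's expression.

    Constant gene profiles have no defined coefficient and are excluded
    with a log entry.
    """
    if len(mirna_expression) < 3:
        raise ValueError("need >=3 samples")
    x = mirna_expression.to_numpy(dtype=float)
    rows = []
    for gene, prof in gene_expression.iterrows():
        y = prof.to_numpy(dtype=float)
        if np.ptp(y) == 0:
            logger.info("gene %s constant; Spearman undefined, excluded", gene)
            continue
        rho, p = stats.spearmanr(x, y)
        rows.append({"gene": gene, "rho": rho, "p": p})
    return pd.DataFrame(rows).set_index("gene")


def correlate_targets(
    mirna_expression: pd.Series,
    gene_expression: pd.DataFrame,
    groups: TargetGroups,
) -> pd.DataFrame:
    """Spearman coefficients per target group, tested against the neither group.

    Returns one row per non-empty group with the group's median coefficient
    and the two-sided Wilcoxon rank-sum p of its coefficients versus the
    neither group's.
    """
    profile = spearman_profile(mirna_expression, gene_expression)
    neither = profile.loc[profile.index.intersection(groups.neither), "rho"]
    rows = []
    for name in ("canonical_only", "isomir_only", "both"):
        members = getattr(groups, name)
        rho = profile.loc[profile.index.intersection(members), "rho"]
        if len(rho) == 0:
            continue
        if len(neither) == 0:
            p = np.nan
        else:
            p = stats.mannwhitneyu(rho, neither, alternative="two-sided").pvalue
        rows.append({"group": name, "n": len(rho),
                     "median_rho": float(rho.median()), "p_vs_neither": float(p)})
    rows.append({"group": "neither", "n": len(neither),
                 "median_rho": float(neither.median()) if len(neither) else np.nan,
                 "p_vs_neither": np.nan})
    return pd.DataFrame(rows).set_index("group")


def anticorrelated_set(
    profile: pd.DataFrame, candidates: set[str], q_thresh: float = 0.25
) -> set[str]:
    """Candidate genes negatively correlated at BH q < ``q_thresh``.

    BH adjustment is over the whole tested gene universe in ``profile``.
    """
    q = bh_fdr(profile["p"])
    hits = profile.index[(profile["rho"] < 0) & (q < q_thresh)]
    return set(hits) & candidates


def anticorrelated_overlap(set_a: set[str], set_b: set[str]) -> dict[str, float]:
    """Percent-distinct of each set versus the other, plus their Jaccard index.

    percent distinct of S vs R = |S \\ R| / |S| * 100 (NaN for empty S);
    Jaccard of two empty sets is 0.
    """
    union = set_a | set_b
    inter = set_a & set_b
    return {
        "percent_distinct_a": 100.0 * len(set_a - set_b) / len(set_a) if set_a else np.nan,
        "percent_distinct_b": 100.0 * len(set_b - set_a) / len(set_b) if set_b else np.nan,
        "jaccard": len(inter) / len(union) if union else 0.0,
    }


def gsea_preranked(
    scores: pd.Series,
    gene_set: set[str],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict[str, float]:
    """Preranked GSEA: weighted running-sum enrichment with a gene-label null.

    Genes are ranked by decreasing score; hits increment by
    |score|^weight (normalized over the set), misses decrement by
    1/(N - set size); ES is the maximum-magnitude deviation.  Significance
    comes from ``n_perm`` random same-size gene sets (seeded); NES divides
    ES by the mean permuted |ES| of the same sign.  Returns ES, NES, p, q
    (q = p here, a single set being tested).
    """
    missing = gene_set - set(scores.index)
    if missing:
        raise ValueError(f"gene set members missing from ranking: {sorted(missing)[:5]}")
    if len(gene_set) == 0:
        raise ValueError("empty gene set")
    if len(gene_set) >= len(scores):
        raise ValueError("gene set must be a proper subset of the ranked universe")
    order = scores.sort_values(ascending=False, kind="mergesort")
    ranked_genes = np.array(order.index)
    ranked_scores = order.to_numpy(dtype=float)
    hit = np.isin(ranked_genes, list(gene_set))

    def es(hit_mask: np.ndarray) -> float:
        w = np.abs(ranked_scores) ** weight
        hit_w = np.where(hit_mask, w, 0.0)
        total = hit_w.sum()
        if total == 0:  # all-zero scores in the set: fall back to unweighted hits
            hit_w = hit_mask.astype(float)
            total = hit_w.sum()
        miss = (~hit_mask) / (len(ranked_genes) - hit_mask.sum())
        running = np.cumsum(hit_w / total - miss)
        return float(running[np.argmax(np.abs(running))])

    observed = es(hit)
    rng = np.random.default_rng(seed)
    perm = np.empty(n_perm)
    k = int(hit.sum())
    for j in range(n_perm):
        mask = np.zeros(len(ranked_genes), dtype=bool)
        mask[rng.choice(len(ranked_genes), size=k, replace=False)] = True
        perm[j] = es(mask)
    same_sign = perm[np.sign(perm) == np.sign(observed)] if observed != 0 else perm
    if len(same_sign) == 0:
        p, nes = 1.0 / (n_perm + 1), np.nan
    else:
        p = (1 + np.sum(np.abs(same_sign) >= abs(observed))) / (1 + len(same_sign))
        nes = observed / np.mean(np.abs(same_sign))
    return {"es": observed, "nes": float(nes), "p": float(p), "q": float(p)}


def jaccard_module_cluster(
    gene_sets: dict[str, set[str]],
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Average-linkage clustering of miRNA modules on 1 - Jaccard distance.

    Returns the dissimilarity matrix reordered by the deterministic leaf
    order, the scipy linkage matrix, and the leaf order itself.  Two empty
    sets get Jaccard 0 (dissimilarity 1), logged.
    """
    names = list(gene_sets)
    if len(names) < 2:
        raise ValueError("need >=2 gene sets")
    n = len(names)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = gene_sets[names[i]], gene_sets[names[j]]
            union = a | b
            if not union:
                logger.info("both %s and %s empty; Jaccard defined as 0",
                            names[i], names[j])
                jac = 0.0
            else:
                jac = len(a & b) / len(union)
            D[i, j] = D[j, i] = 1.0 - jac
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    order = [names[i] for i in hierarchy.leaves_list(Z)]
    frame = pd.DataFrame(D, index=names, columns=names).loc[order, order]
    return frame, Z, order


def tabulate_eqtl_summary(
    records_per_condition: dict[str, pd.DataFrame],
    feature_types: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Condition x feature-type x cis/trans eQTL tabulation with ratios.

    ``records_per_condition`` maps condition to a classified record frame
    (columns snp/feature/relationship); ``feature_types`` maps feature id to
    ``gene`` or ``mirna``.  Returns (summary, ratios): the summary counts
    eQTL pairs and unique features per stratum, the ratios frame holds the
    cross-condition unique-feature ratios rounded to 2 decimals.
    """
    rows = []
    uniques: dict[tuple[str, str, str], int] = {}
    for cond, rec in records_per_condition.items():
        ftype = rec["feature"].map(feature_types)
        for kind in ("gene", "mirna"):
            for rel in ("cis", "trans"):
                sub = rec[(ftype == kind) & (rec["relationship"] == rel)]
                n_unique = sub["feature"].nunique()
                uniques[(cond, kind, rel)] = n_unique
                rows.append({"condition": cond, "feature_type": kind,
                             "relationship": rel, "n_pairs": len(sub),
                             "n_unique_features": n_unique})
    summary = pd.DataFrame(rows)
    conds = list(records_per_condition)
    ratio_rows = []
    for i, ca in enumerate(conds):
        for cb in conds:
            if ca == cb:
                continue
            for kind in ("gene", "mirna"):
                for rel in ("cis", "trans"):
                    denom = uniques[(cb, kind, rel)]
                    num = uniques[(ca, kind, rel)]
                    ratio = round(num / denom, 2) if denom else np.nan
                    ratio_rows.append({
                        "numerator": ca, "denominator": cb,
                        "feature_type": kind, "relationship": rel,
                        "unique_ratio": ratio,
                    })
    return summary, pd.DataFrame(ratio_rows)
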