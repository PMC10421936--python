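"""Causality inference test (CIT) and condition-specific miRNA networks.

A SNP-miRNA-mRNA triplet (L, M, T) is called causal for the mediation chain
L -> M -> T when four component conditions all hold: (1) T is associated
with L; (2) M is associated with L given T; (3) T is associated with M
given L; and (4) L is conditionally independent of T given M.  Condition 4
is an equivalence-type test: the observed conditional F statistic for L in
T ~ M + L is compared against a reference distribution computed with the
mediator permuted within genotype strata — permutation preserves the L-M
association while destroying the mediated path, so the reference represents
the no-mediation alternative, and the p-value is the fraction of permuted
statistics at or below the observed one.  The omnibus p is the maximum of
the four component p-values; the reactive direction swaps M and T.

Calls at alpha = 0.05: causal (p_causal < alpha <= p_reactive), reactive
(mirror), independent (both >= alpha), non-inferable (both < alpha).
Networks keep one edge miRNA -> gene per condition for every causal-called
triplet whose SNP-miRNA pair passed the eQTL screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_fdr
from .eqtl import residualize

logger = logging.getLogger(__name__)

CIT_CALLS = ("causal", "reactive", "independent", "non_inferable")


@dataclass
class CitResult:
    """Directional omnibus p-values and component p-values for one triplet."""

    p_causal: float
    p_reactive: float
    components_causal: tuple[float, float, float, float]
    components_reactive: tuple[float, float, float, float]
    call: str
    alpha: float = 0.05


def _f_add(y: np.ndarray, base: np.ndarray, x: np.ndarray, extra_df: int = 0) -> float:
    """p-value for adding column x to the regression of y on base columns."""
    n = y.shape[0]
    Q, _ = np.linalg.qr(base)
    ry = y - Q @ (Q.T @ y)
    rx = x - Q @ (Q.T @ x)
    rss0 = ry @ ry
    denom = rx @ rx
    if denom <= 1e-300:
        return 1.0
    b = (rx @ ry) / denom
    rss1 = rss0 - b * (rx @ ry)
    df2 = n - base.shape[1] - 1 - extra_df
    if rss1 <= 1e-300:
        return 0.0
    F = (rss0 - rss1) / (rss1 / df2)
    return float(stats.f.sf(F, 1, df2))


def _directional_p(
    L: np.ndarray, M: np.ndarray, T: np.ndarray,
    n_perm: int, seed: int, extra_df: int,
) -> tuple[float, float, float, float]:
    """Component p-values for the direction L -> M -> T."""
    n = L.shape[0]
    ones = np.ones((n, 1))
    p1 = _f_add(T, ones, L, extra_df)
    p2 = _f_add(M, np.column_stack([ones, T]), L, extra_df)
    p3 = _f_add(T, np.column_stack([ones, L]), M, extra_df)

    # test 4: conditional F for L given M, referenced against within-stratum
    # mediator permutations (no-mediation alternative)
    Lc = L - L.mean()
    Mc = M - M.mean()
    Tc = T - T.mean()
    nL, nM, nT = np.linalg.norm(Lc), np.linalg.norm(Mc), np.linalg.norm(Tc)
    if min(nL, nM, nT) <= 1e-300:
        raise ValueError("constant variable in CIT component test")
    r_tl = float(Tc @ Lc) / (nT * nL)
    r_lm = float(Lc @ Mc) / (nL * nM)
    df4 = n - 3 - extra_df

    def partial_f(r_tm: np.ndarray) -> np.ndarray:
        num = r_tl - r_tm * r_lm
        den = np.sqrt(np.maximum((1 - r_tm**2) * (1 - r_lm**2), 1e-300))
        r = np.clip(num / den, -1 + 1e-15, 1 - 1e-15)
        return df4 * r * r / (1 - r * r)

    f_obs = float(partial_f(np.array([float(Tc @ Mc) / (nT * nM)]))[0])
    rng = np.random.default_rng(seed)
    strata = [np.flatnonzero(L == v) for v in np.unique(L)]
    M_perm = np.empty((n, n_perm))
    for j in range(n_perm):
        col = np.empty(n)
        for idx in strata:
            col[idx] = M[rng.permutation(idx)]
        M_perm[:, j] = col
    Mp = M_perm - M.mean()
    r_tm_perm = (Tc @ Mp) / (nT * nM)  # permutation preserves the norm of M
    f_perm = partial_f(r_tm_perm)
    p4 = (1 + np.sum(f_perm <= f_obs)) / (n_perm + 1)
    return p1, p2, p3, float(p4)


def cit_test(
    L: np.ndarray | pd.Series,
    M: np.ndarray | pd.Series,
    T: np.ndarray | pd.Series,
    covariates: pd.DataFrame | None = None,
    n_perm: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
) -> CitResult:
    """Run the causality inference test on one (genotype, mediator, outcome).

    Covariates are residualized out of M and T first; the genotype is left
    raw (it defines the permutation strata).  The reactive direction reuses
    the same seed, so ``cit_test(L, M, T).p_reactive`` equals
    ``cit_test(L, T, M).p_causal`` exactly.
    """
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    T = np.asarray(T, dtype=float)
    n = L.shape[0]
    if n < 30:
        raise ValueError("CIT needs n >= 30")
    if len(np.unique(L)) < 2:
        raise ValueError("genotype is monomorphic")
    if np.ptp(M) == 0 or np.ptp(T) == 0:
        raise ValueError("constant mediator or outcome")
    if n_perm < 20:
        logger.warning("n_perm=%d is low; test-4 p-values are coarse", n_perm)
    extra_df = 0
    if covariates is not None:
        frame = pd.DataFrame({"M": M, "T": T}).T
        frame.columns = covariates.index
        resid = residualize(frame, covariates)
        M = resid.loc["M"].to_numpy()
        T = resid.loc["T"].to_numpy()
        extra_df = covariates.shape[1]

    comp_c = _directional_p(L, M, T, n_perm, seed, extra_df)
    comp_r = _directional_p(L, T, M, n_perm, seed, extra_df)
    p_causal = max(comp_c)
    p_reactive = max(comp_r)
    return CitResult(
        p_causal=p_causal, p_reactive=p_reactive,
        components_causal=comp_c, components_reactive=comp_r,
        call=classify_triplet(p_causal, p_reactive, alpha), alpha=alpha,
    )


def classify_triplet(p_causal: float, p_reactive: float, alpha: float = 0.05) -> str:
    """Map the two directional omnibus p-values to the four CIT calls."""
    if not (0 <= p_causal <= 1 and 0 <= p_reactive <= 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p_causal < alpha <= p_reactive:
        return "causal"
    if p_reactive < alpha <= p_causal:
        return "reactive"
    if p_causal >= alpha and p_reactive >= alpha:
        return "independent"
    return "non_inferable"


def cit_scan(
    triplets: pd.DataFrame,
    genotypes: pd.DataFrame,
    mirna_expression: pd.DataFrame,
    gene_expression: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    n_perm: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run ``cit_test`` over a candidate triplet table (snp/mirna/gene columns)."""
    rng = np.random.default_rng(seed)
    rows = []
    for _, t in triplets.iterrows():
        res = cit_test(
            genotypes.loc[t["snp"]].to_numpy(dtype=float),
            mirna_expression.loc[t["mirna"]].to_numpy(dtype=float),
            gene_expression.loc[t["gene"]].to_numpy(dtype=float),
            covariates=covariates, n_perm=n_perm,
            seed=int(rng.integers(2**31)), alpha=alpha,
        )
        rows.append(
            {
                "snp": t["snp"], "mirna": t["mirna"], "gene": t["gene"],
                "p_causal": res.p_causal, "p_reactive": res.p_reactive,
                "call": res.call,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class MirnaNetwork:
    """Per-condition miRNA -> gene adjacency with triplet provenance."""

    condition: str
    adjacency: dict[str, set[str]] = field(default_factory=dict)
    provenance: dict[tuple[str, str], list[str]] = field(default_factory=dict)

    def degree(self, mirna: str) -> int:
        return len(self.adjacency.get(mirna, ()))

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for g in self.adjacency.values():
            out |= g
        return out


def build_network(
    cit_results: pd.DataFrame,
    eqtl_records: pd.DataFrame,
    condition: str,
) -> MirnaNetwork:
    """Edges miRNA -> gene from causal-called triplets with an eQTL-backed SNP.

    Only triplets whose (snp, mirna) pair is present in ``eqtl_records``
    (columns snp/feature) contribute; independent and non-inferable calls
    never do.
    """
    allowed = set(zip(eqtl_records["snp"], eqtl_records["feature"]))
    net = MirnaNetwork(condition=condition)
    causal = cit_results[cit_results["call"] == "causal"]
    for _, row in causal.iterrows():
        if (row["snp"], row["mirna"]) not in allowed:
            continue
        net.adjacency.setdefault(row["mirna"], set()).add(row["gene"])
        net.provenance.setdefault((row["mirna"], row["gene"]), []).append(row["snp"])
    return net


def scale_free_fit(network: MirnaNetwork | dict[int, int]) -> tuple[float, float]:
    """log-log fit of degree frequency on degree: returns (slope, r).

    Accepts a network (miRNA degrees are tallied) or a precomputed
    ``{degree: frequency}`` mapping.  Requires >=3 distinct positive degrees.
    """
    if isinstance(network, MirnaNetwork):
        degrees = [network.degree(m) for m in network.adjacency]
        values, counts = np.unique([d for d in degrees if d > 0], return_counts=True)
        freq = dict(zip(values, counts))
    else:
        freq = {d: f for d, f in network.items() if d > 0 and f > 0}
    if len(freq) < 3:
        raise ValueError("need >=3 distinct positive degrees for a log-log fit")
    d = np.log10(np.array(sorted(freq)))
    f = np.log10(np.array([freq[k] for k in sorted(freq)], dtype=float))
    fit = stats.linregress(d, f)
    return float(fit.slope), float(fit.rvalue)


def fisher_exact(table: np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2x2 table of nonnegative integers."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("table entries must be nonnegative")
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return float(p)


def differential_connectivity(
    network_a: MirnaNetwork,
    network_b: MirnaNetwork,
    universe_a: set[str] | None = None,
    universe_b: set[str] | None = None,
    q_thresh: float = 0.2,
) -> pd.DataFrame:
    """Per-miRNA Fisher test of connected vs non-connected genes across two
    condition networks.

    Both columns share the union gene universe (genes tested in either
    condition); a miRNA absent from one network counts with degree 0 there.
    Returns degree_a/degree_b, two-sided p, BH q and the q < ``q_thresh``
    flag, sorted by p.
    """
    universe = (universe_a or network_a.genes) | (universe_b or network_b.genes)
    n_genes = len(universe)
    mirnas = sorted(set(network_a.adjacency) | set(network_b.adjacency))
    rows = []
    for m in mirnas:
        ka, kb = network_a.degree(m), network_b.degree(m)
        if m not in network_a.adjacency or m not in network_b.adjacency:
            logger.info("miRNA %s absent from one network; degree 0 there", m)
        p = fisher_exact([[ka, n_genes - ka], [kb, n_genes - kb]])
        rows.append({"mirna": m, "degree_a": ka, "degree_b": kb, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_fdr(out["p"])
        out["differentially_connected"] = out["q"] < q_thresh
        out = out.sort_values("p", kind="mergesort").reset_index(drop=True)
    return out
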