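"""Consensus clustering of samples/miRNAs and cluster-phenotype models.

Expression subtypes are found by resampled PAM clustering on Euclidean
distances: items are subsampled (fraction 0.8 by default), clustered, and
the fraction of runs in which two items co-cluster among runs where both
were drawn forms the consensus matrix.  The number of clusters is chosen by
a composite of the cophenetic score and average item consensus with a
drop-off bonus.  Sample clusters are then related to disease status
(logistic) and clinical severity (linear) with covariate adjustment,
against a stated baseline cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)


def pam(dissimilarity: np.ndarray, k: int, seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Partitioning around medoids (BUILD + SWAP) on a dissimilarity matrix.

    Returns ``(assignments, medoid_indices)``; assignments are medoid ranks
    0..k-1.  Tiny instances (few candidate medoid sets) are solved exactly by
    exhaustive search; larger ones with BUILD + best-improvement SWAP, run to
    a local optimum: no single medoid/non-medoid exchange lowers the total
    dissimilarity to the nearest medoid.  ``seed`` is accepted for interface
    stability; the procedure is deterministic.
    """
    D = np.asarray(dissimilarity, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("dissimilarity must be square")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("dissimilarity must be symmetric")
    if (D < 0).any():
        raise ValueError("dissimilarity must be nonnegative")
    if not 1 <= k < n or k == n:
        if k == n:
            return np.arange(n), np.arange(n)
        raise ValueError(f"k={k} must satisfy 1 <= k <= n={n}")

    import itertools
    from math import comb

    if comb(n, k) <= 2000:  # exact solution is affordable: use it
        best_set, best_cost = None, np.inf
        for meds in itertools.combinations(range(n), k):
            cost = D[:, meds].min(axis=1).sum()
            if cost < best_cost - 1e-12:
                best_set, best_cost = meds, cost
        medoids = sorted(best_set)
        assignments = np.argmin(D[:, medoids], axis=1)
        return assignments, np.array(medoids)

    # BUILD: greedy cost minimization
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        current = D[:, medoids].min(axis=1)
        gains = np.maximum(current[None, :] - D, 0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))

    def objective(meds: list[int]) -> float:
        return float(D[:, meds].min(axis=1).sum())

    best = objective(medoids)
    improved = True
    while improved:
        improved = False
        non_medoids = [i for i in range(n) if i not in medoids]
        best_swap, best_cost = None, best
        for mi in range(len(medoids)):
            for h in non_medoids:
                trial = list(medoids)
                trial[mi] = h
                cost = objective(trial)
                if cost < best_cost - 1e-12:
                    best_swap, best_cost = trial, cost
        if best_swap is not None:
            medoids, best = best_swap, best_cost
            improved = True
    medoids = sorted(medoids)
    assignments = np.argmin(D[:, medoids], axis=1)
    return assignments, np.array(medoids)


@dataclass
class ConsensusResult:
    """Per-k consensus matrices, assignments and selection scores."""

    items: list[str]
    consensus: dict[int, np.ndarray] = field(default_factory=dict)
    assignments: dict[int, np.ndarray] = field(default_factory=dict)
    cophenetic: dict[int, float] = field(default_factory=dict)
    avg_item_consensus: dict[int, float] = field(default_factory=dict)


def _euclidean(data: np.ndarray) -> np.ndarray:
    sq = (data ** 2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2 * data @ data.T
    np.fill_diagonal(d2, 0)
    return np.sqrt(np.maximum(d2, 0))


def consensus_cluster(
    data: pd.DataFrame,
    k_range: range | list[int],
    n_resamples: int = 1000,
    item_fraction: float = 0.8,
    seed: int = 0,
) -> ConsensusResult:
    """Resampled PAM consensus clustering of the rows of ``data``.

    For each resample, ``item_fraction`` of items are drawn without
    replacement and PAM-clustered on Euclidean distances; co-clustering
    counts are normalized by co-sampling counts.  The final assignment at
    each k cuts an average-linkage tree built on 1 - consensus.
    """
    X = data.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items")
    n_sub = int(np.floor(item_fraction * n))
    if max(k_range) >= n_sub:
        raise ValueError("max k must be below n * item_fraction")
    rng = np.random.default_rng(seed)
    subsets = [rng.choice(n, size=n_sub, replace=False) for _ in range(n_resamples)]
    co_sampled = np.zeros((n, n))
    for idx in subsets:
        co_sampled[np.ix_(idx, idx)] += 1

    result = ConsensusResult(items=list(data.index))
    for k in k_range:
        together = np.zeros((n, n))
        for idx in subsets:
            D = _euclidean(X[idx])
            labels, _ = pam(D, k)
            same = labels[:, None] == labels[None, :]
            together[np.ix_(idx, idx)] += same
        with np.errstate(invalid="ignore", divide="ignore"):
            consensus = np.where(co_sampled > 0, together / co_sampled, 0.0)
        np.fill_diagonal(consensus, np.where(co_sampled.diagonal() > 0, 1.0, 0.0))
        consensus = (consensus + consensus.T) / 2

        dist = 1.0 - consensus
        np.fill_diagonal(dist, 0.0)
        condensed = squareform(dist, checks=False)
        Z = hierarchy.linkage(condensed, method="average")
        labels = hierarchy.fcluster(Z, t=k, criterion="maxclust") - 1
        coph_dist = hierarchy.cophenet(Z)
        if condensed.std() > 0 and coph_dist.std() > 0:
            coph = float(np.corrcoef(condensed, coph_dist)[0, 1])
        else:
            coph = 1.0

        item_cons = np.empty(n)
        for i in range(n):
            mates = (labels == labels[i]) & (np.arange(n) != i)
            item_cons[i] = consensus[i, mates].mean() if mates.any() else 1.0

        result.consensus[k] = consensus
        result.assignments[k] = labels
        result.cophenetic[k] = coph
        result.avg_item_consensus[k] = float(item_cons.mean())
    return result


def select_k(
    result: ConsensusResult,
    min_cluster_size: int = 2,
    min_cluster_frac: float = 0.5,
    score_tol: float = 1e-6,
) -> int:
    """Choose k by combined cophenetic + average-item-consensus score.

    The base score of candidate k is the mean of its cophenetic and
    average-item-consensus scores; the candidate with the highest base score
    wins.  Candidates tied on the base score (within ``score_tol``) are
    ranked by the drop of the base score at the next k ("large drop off"),
    and remaining ties go to the smallest k (logged).  Candidates producing
    small clusters are excluded: the smallest cluster must reach
    ``min_cluster_size`` items and ``min_cluster_frac`` of the balanced
    size n/k.
    """
    ks = sorted(result.consensus)
    if len(ks) < 2:
        if len(ks) == 1:
            return ks[0]
        raise ValueError("need at least one candidate k")
    base = {
        k: 0.5 * (result.cophenetic[k] + result.avg_item_consensus[k]) for k in ks
    }
    n_items = len(result.items)
    eligible = [
        k for k in ks
        if np.bincount(result.assignments[k]).min()
        >= max(min_cluster_size, min_cluster_frac * n_items / k)
    ]
    if not eligible:
        eligible = ks

    def drop(k: int) -> float:
        nxt = [kk for kk in ks if kk > k]
        return max(base[k] - base[nxt[0]], 0.0) if nxt else 0.0

    best_base = max(base[k] for k in eligible)
    tied = [k for k in eligible if base[k] >= best_base - score_tol]
    best_drop = max(drop(k) for k in tied)
    winners = [k for k in tied if drop(k) >= best_drop - score_tol]
    if len(winners) > 1:
        logger.info("select_k tie among %s; choosing smallest", winners)
    return min(winners)


@dataclass
class ModuleScore:
    """First-principal-component meta-score of a miRNA module over samples."""

    module: str
    score: pd.Series
    sign_flipped: bool = False


def module_meta_score(matrix: pd.DataFrame, members: list[str], module: str = "module") -> ModuleScore:
    """PC1 over samples of the z-scored member miRNAs.

    Members are rows of ``matrix``; each is z-scored across samples,
    zero-variance members are dropped with a warning, and the leading
    right-singular vector gives the per-sample score.  The sign is fixed so
    the score correlates positively with the module mean profile; the score
    has zero mean over samples.
    """
    if len(members) < 2:
        raise ValueError("module needs >=2 members")
    sub = matrix.loc[members]
    sd = sub.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.all():
        logger.warning("dropping zero-variance members: %s", list(sub.index[~keep]))
        sub, sd = sub[keep], sd[keep]
    if len(sub) == 0:
        raise ValueError("no members with nonzero variance")
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    u, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
    score = vt[0] * s[0]
    mean_profile = z.mean(axis=0).to_numpy()
    flipped = False
    r = np.corrcoef(score, mean_profile)[0, 1] if mean_profile.std() > 0 else 1.0
    if r < 0:
        score, flipped = -score, True
    return ModuleScore(module=module, score=pd.Series(score, index=matrix.columns),
                       sign_flipped=flipped)


def associate_cluster(
    outcome: pd.Series,
    cluster_labels: pd.Series,
    covariates: pd.DataFrame | None,
    family: str = "linear",
    baseline: int | str = 0,
) -> pd.DataFrame:
    """Per-cluster coefficient and Wald p against a baseline cluster.

    Fits ``outcome ~ cluster indicators + covariates`` with OLS (``linear``)
    or logistic regression; the baseline cluster (conventionally the
    control-enriched one) carries no indicator.  On logistic separation the
    fit falls back to an L2-penalized likelihood and the rows are flagged.
    """
    if family not in {"linear", "logistic"}:
        raise ValueError("family must be 'linear' or 'logistic'")
    labels = cluster_labels.reindex(outcome.index)
    if baseline not in set(labels):
        raise ValueError(f"baseline cluster {baseline!r} not present")
    dummies = pd.get_dummies(labels, prefix="cluster").astype(float)
    base_col = f"cluster_{baseline}"
    dummies = dummies.drop(columns=base_col)
    X = dummies.copy()
    if covariates is not None:
        X = pd.concat([X, covariates.reindex(outcome.index).astype(float)], axis=1)
    X = sm.add_constant(X)
    y = outcome.astype(float)
    penalized = False
    if family == "linear":
        fit = sm.OLS(y, X).fit()
        params, pvals = fit.params, fit.pvalues
    else:
        try:
            with np.errstate(all="ignore"):
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            if not fit.mle_retvals.get("converged", True) or np.any(
                np.abs(fit.params[dummies.columns]) > 15
            ):
                raise np.linalg.LinAlgError("separation suspected")
            params, pvals = fit.params, fit.pvalues
        except Exception:
            penalized = True
            fit = sm.Logit(y, X).fit_regularized(alpha=1.0, L1_wt=0.0, disp=0)
            params = fit.params
            pvals = pd.Series(np.nan, index=params.index)
            logger.warning("logistic separation: penalized fallback, Wald p unavailable")
    rows = []
    for col in dummies.columns:
        rows.append(
            {
                "cluster": col.removeprefix("cluster_"),
                "coef": float(params[col]),
                "p": float(pvals[col]) if np.isfinite(pvals[col]) else np.nan,
                "penalized": penalized,
            }
        )
    return pd.DataFrame(rows).set_index("cluster")
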