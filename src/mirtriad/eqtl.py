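"""Covariate-adjusted SNP-expression association scan with cis/trans calls.

The scan residualizes expression (age, gender, smoking, population-structure
PCs as supplied) and tests every SNP-feature pair, either additively
(correlation of residualized genotype and expression, t-test) or with the
genotype as a 3-level factor (ANOVA F-test) — the whole grid computed with
matrix products, MatrixEQTL-style.  Pairs below the p threshold are kept
and labelled cis (same chromosome, within a window of the feature start,
inclusive) or trans.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CIS_WINDOW = 1_000_000  # conventional 1 Mb cis definition, boundary inclusive


def _covariate_design(covariates: pd.DataFrame | None, n: int) -> np.ndarray:
    if covariates is None or covariates.shape[1] == 0:
        return np.ones((n, 1))
    C = np.column_stack([np.ones(n), covariates.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(C)
    if rank < C.shape[1]:
        # name the offending columns by greedy rank check
        bad = []
        kept = np.ones((n, 1))
        for j, col in enumerate(covariates.columns):
            trial = np.column_stack([kept, covariates.iloc[:, j]])
            if np.linalg.matrix_rank(trial) == trial.shape[1]:
                kept = trial
            else:
                bad.append(col)
        raise ValueError(f"rank-deficient covariates; collinear columns: {bad}")
    return C


def residualize(matrix: pd.DataFrame, covariates: pd.DataFrame | None) -> pd.DataFrame:
    """Project the covariate space (plus intercept) out of every feature row."""
    X = matrix.to_numpy(dtype=float)
    C = _covariate_design(covariates, X.shape[1])
    Q, _ = np.linalg.qr(C)
    resid = X - (X @ Q) @ Q.T
    return pd.DataFrame(resid, index=matrix.index, columns=matrix.columns)


def eqtl_scan(
    genotypes: pd.DataFrame,
    expression: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    p_threshold: float = 5e-4,
    mode: str = "additive",
) -> pd.DataFrame:
    """Scan all SNP x feature pairs; keep records with p below threshold.

    ``additive`` correlates residualized genotype dosage with residualized
    expression (t, df = n - c - 2 with c covariate columns); ``anova``
    treats the genotype as a 3-level factor on residualized expression
    (F, df = (g-1, n - c - g)).  Monomorphic SNPs are skipped and logged.
    Returns a frame with columns snp/feature/statistic/p sorted by p.
    """
    if mode not in {"additive", "anova"}:
        raise ValueError("mode must be 'additive' or 'anova'")
    samples = list(expression.columns)
    if list(genotypes.columns) != samples:
        genotypes = genotypes.reindex(columns=samples)
        if genotypes.isna().all(axis=None):
            raise ValueError("genotype and expression samples do not match")
    n = len(samples)
    c = 0 if covariates is None else covariates.shape[1]
    E = residualize(expression, covariates).to_numpy()
    G = genotypes.to_numpy(dtype=float)

    poly = np.array([len(np.unique(g[~np.isnan(g)])) > 1 for g in G])
    if (~poly).any():
        logger.info("skipping %d monomorphic SNP(s)", int((~poly).sum()))

    records = []
    if mode == "additive":
        df = n - c - 2
        Gr = residualize(genotypes, covariates).to_numpy()
        Ec = E - E.mean(axis=1, keepdims=True)
        Gc = Gr - Gr.mean(axis=1, keepdims=True)
        En = Ec / np.maximum(np.linalg.norm(Ec, axis=1, keepdims=True), 1e-300)
        Gn = Gc / np.maximum(np.linalg.norm(Gc, axis=1, keepdims=True), 1e-300)
        R = Gn @ En.T  # SNPs x features
        R = np.clip(R, -1 + 1e-15, 1 - 1e-15)
        T = R * np.sqrt(df / (1 - R * R))
        P = 2 * stats.t.sf(np.abs(T), df)
        snp_idx, feat_idx = np.nonzero((P < p_threshold) & poly[:, None])
        for si, fi in zip(snp_idx, feat_idx):
            records.append((genotypes.index[si], expression.index[fi],
                            float(T[si, fi]), float(P[si, fi])))
    else:
        Ec = E - E.mean(axis=1, keepdims=True)
        sst = (Ec ** 2).sum(axis=1)
        for si in range(G.shape[0]):
            if not poly[si]:
                continue
            g = G[si]
            ok = ~np.isnan(g)
            levels = np.unique(g[ok])
            n_ok = int(ok.sum())
            k = len(levels)
            df2 = n_ok - c - k
            if df2 <= 0:
                continue
            Z = (g[ok, None] == levels[None, :]).astype(float)
            counts = Z.sum(axis=0)
            Eo = E[:, ok]
            mean_all = Eo.mean(axis=1, keepdims=True)
            M = (Eo @ Z) / counts  # features x levels
            ssb = ((M - mean_all) ** 2 * counts).sum(axis=1)
            sst_ok = ((Eo - mean_all) ** 2).sum(axis=1)
            ssw = np.maximum(sst_ok - ssb, 1e-300)
            F = (ssb / (k - 1)) / (ssw / df2)
            P = stats.f.sf(F, k - 1, df2)
            for fi in np.nonzero(P < p_threshold)[0]:
                records.append((genotypes.index[si], expression.index[fi],
                                float(F[fi]), float(P[fi])))
    out = pd.DataFrame(records, columns=["snp", "feature", "statistic", "p"])
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)


def classify_cis_trans(
    records: pd.DataFrame,
    snp_positions: pd.DataFrame,
    feature_positions: pd.DataFrame,
    window: int = CIS_WINDOW,
) -> pd.DataFrame:
    """Label records cis/trans by SNP-to-feature-start distance.

    cis iff same chromosome and |SNP pos - feature start| <= window
    (boundary inclusive); records with a missing position are dropped with
    a warning.  Position frames need columns ``chrom`` and ``pos`` indexed
    by id.
    """
    out = records.copy()
    known = out["snp"].isin(snp_positions.index) & out["feature"].isin(
        feature_positions.index
    )
    if (~known).any():
        logger.warning("dropping %d record(s) with missing positions", int((~known).sum()))
        out = out[known].copy()
    schrom = snp_positions.loc[out["snp"], "chrom"].to_numpy()
    spos = snp_positions.loc[out["snp"], "pos"].to_numpy()
    fchrom = feature_positions.loc[out["feature"], "chrom"].to_numpy()
    fpos = feature_positions.loc[out["feature"], "pos"].to_numpy()
    cis = (schrom == fchrom) & (np.abs(spos - fpos) <= window)
    out["relationship"] = np.where(cis, "cis", "trans")
    return out.reset_index(drop=True)
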