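"""End-to-end orchestration: quantify -> diffexpr -> cluster -> eqtl ->
citnet -> targets, with configuration, validation, logging and a manifest.

Each stage writes TSV outputs into the run directory and records row counts,
seeds and thresholds in ``manifest.json``; re-running with the same
configuration reproduces identical outputs.  Stages can be toggled off, in
which case dependent outputs are absent and the manifest notes the skip.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import citnet, cluster, diffexpr, eqtl, quantify, targets
from . import io as mio
from . import synthdata

logger = logging.getLogger(__name__)

STAGES = ("quantify", "diffexpr", "cluster", "eqtl", "citnet", "targets")


@dataclass
class PipelineConfig:
    """All thresholds, stage toggles, seeds and file paths of one run."""

    input_dir: str = "."
    output_dir: str = "run"
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})
    detection_min_count: int = 2
    detection_min_fraction: float = 0.5
    de_q_thresh: float = 0.1
    de_coef_thresh: float = 0.22
    eqtl_p_thresh: float = 5e-4
    eqtl_mode: str = "additive"
    cis_window: int = eqtl.CIS_WINDOW
    cit_alpha: float = 0.05
    cit_n_perm: int = 100
    connectivity_q_thresh: float = 0.2
    anticorrelation_q_thresh: float = 0.25
    consensus_k_range: tuple[int, int] = (2, 5)
    consensus_resamples: int = 100
    max_triplets: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        for name, val, lo, hi in (
            ("detection_min_fraction", self.detection_min_fraction, 0, 1),
            ("de_q_thresh", self.de_q_thresh, 0, 1),
            ("eqtl_p_thresh", self.eqtl_p_thresh, 0, 1),
            ("cit_alpha", self.cit_alpha, 0, 1),
            ("connectivity_q_thresh", self.connectivity_q_thresh, 0, 1),
            ("anticorrelation_q_thresh", self.anticorrelation_q_thresh, 0, 1),
        ):
            if not lo <= val <= hi:
                raise ValueError(f"{name}={val} outside [{lo}, {hi}]")
        for s in self.stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "consensus_k_range" in raw:
            raw["consensus_k_range"] = tuple(raw["consensus_k_range"])
        return cls(**raw)


def encode_covariates(
    covariates: pd.DataFrame,
    columns: tuple[str, ...] = ("age", "gender", "smoking"),
) -> pd.DataFrame:
    """Numeric design (dummy-coded categoricals) from a covariate table."""
    parts = {}
    for col in columns:
        if col not in covariates:
            continue
        series = covariates[col]
        if series.dtype.kind in "ifu":
            parts[col] = series.astype(float)
        else:
            dummies = pd.get_dummies(series, prefix=col, drop_first=True)
            for c in dummies.columns:
                parts[c] = dummies[c].astype(float)
    return pd.DataFrame(parts, index=covariates.index)


def validate_inputs(input_dir: str | Path, config: PipelineConfig | None = None) -> list[str]:
    """Sanity checks on the pipeline inputs; returns the list of failures."""
    indir = Path(input_dir)
    failures: list[str] = []
    matrices = {}
    for name in ("counts", "genotypes", "mirna_expression", "gene_expression"):
        path = indir / f"{name}.tsv"
        if path.exists():
            matrices[name] = mio.read_matrix_tsv(path)
        else:
            failures.append(f"missing input: {path.name}")
    cov_path = indir / "covariates.tsv"
    if cov_path.exists():
        cov = pd.read_csv(cov_path, sep="\t", index_col=0)
        for name, mat in matrices.items():
            diff = set(mat.columns) ^ set(cov.index)
            if diff:
                failures.append(
                    f"sample ids of {name} and covariates differ: {sorted(diff)[:5]}"
                )
    else:
        failures.append("missing input: covariates.tsv")
    if "genotypes" in matrices:
        vals = matrices["genotypes"].to_numpy(dtype=float)
        if not (np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))).all():
            failures.append("genotype entries outside {0,1,2,NA}")
    gff = indir / "loci.gff3"
    if gff.exists():
        with open(gff) as fh:
            for ln, line in enumerate(fh, start=1):
                if line.startswith("#") or not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) < 9:
                    failures.append(f"loci.gff3 line {ln}: fewer than 9 columns")
                elif int(parts[4]) < int(parts[3]):
                    failures.append(f"loci.gff3 line {ln}: end < start")
    for fa in ("genome.fa", "utrs.fa"):
        path = indir / fa
        if path.exists():
            try:
                mio.read_fasta(path)
            except Exception as exc:  # parse validity only
                failures.append(f"{fa}: unparseable ({exc})")
    return failures


def _stage_quantify(data: dict, cfg: PipelineConfig, outdir: Path, manifest: dict) -> None:
    counts_df = data["counts"]
    cm = quantify.CountMatrix(values=counts_df, sample_totals=counts_df.sum(axis=0))
    retained = quantify.detection_filter(
        cm, min_count=cfg.detection_min_count, min_fraction=cfg.detection_min_fraction
    )
    normalized = quantify.rpm_normalize(cm)
    adjusted = quantify.batch_adjust(
        normalized,
        batch=data["covariates"]["protocol"],
        covariates=encode_covariates(data["covariates"]),
    )
    isomir_rows = []
    if data.get("reads") is not None and data.get("loci"):
        read_counts = quantify.count_reads_per_mirna(data["reads"], data["loci"])
        mio.write_matrix_tsv(read_counts.values, outdir / "read_counts.tsv")
        lengths = {
            s: (grp["end"] - grp["start"]).to_numpy()
            for s, grp in data["reads"].groupby("name")
        }
        if len(lengths) >= 3:
            quantify.read_length_qc(lengths).to_csv(outdir / "qc_report.tsv", sep="\t")
        for locus in data["loci"]:
            for rec in quantify.group_isomirs(data["reads"], locus):
                isomir_rows.append(
                    {"locus": rec.locus, "offset5": rec.offset5, "count": rec.total}
                )
    isomirs = pd.DataFrame(isomir_rows)
    isomirs.to_csv(outdir / "isomirs.tsv", sep="\t", index=False)
    pd.Series(retained, name="mirna").to_csv(outdir / "retained_mirnas.tsv",
                                             sep="\t", index=False)
    mio.write_matrix_tsv(adjusted.values, outdir / "normalized_adjusted.tsv")
    data["retained"] = retained
    data["normalized"] = adjusted.values
    data["isomirs"] = isomirs
    manifest["stages"]["quantify"] = {
        "n_mirnas": int(len(counts_df)), "n_retained": len(retained),
        "n_isomir_records": int(len(isomirs)),
    }


def _stage_diffexpr(data: dict, cfg: PipelineConfig, outdir: Path, manifest: dict) -> None:
    counts = data["counts"].loc[data.get("retained", data["counts"].index)]
    table = diffexpr.de_scan(
        counts, data["covariates"],
        q_thresh=cfg.de_q_thresh, coef_thresh=cfg.de_coef_thresh,
    )
    table.to_csv(outdir / "de_table.tsv", sep="\t")
    data["de_table"] = table
    manifest["stages"]["diffexpr"] = {
        "n_tested": int(len(table)), "n_called": int(table["called"].sum()),
    }


def _stage_cluster(data: dict, cfg: PipelineConfig, outdir: Path, manifest: dict) -> None:
    matrix = data["normalized"]
    if "de_table" in data:
        called = list(data["de_table"].index[data["de_table"]["called"]])
        if len(called) >= 10:
            matrix = matrix.loc[called]
        else:
            logger.info("only %d DE-called miRNAs; clustering all retained", len(called))
    ks = range(cfg.consensus_k_range[0], cfg.consensus_k_range[1] + 1)
    sample_res = cluster.consensus_cluster(
        matrix.T, ks, n_resamples=cfg.consensus_resamples, seed=cfg.seed
    )
    k_samples = cluster.select_k(sample_res, min_cluster_size=3)
    sample_labels = pd.Series(sample_res.assignments[k_samples], index=matrix.columns)

    mirna_res = cluster.consensus_cluster(
        matrix, ks, n_resamples=cfg.consensus_resamples, seed=cfg.seed + 1
    )
    k_mirna = cluster.select_k(mirna_res, min_cluster_size=2)
    mirna_labels = pd.Series(mirna_res.assignments[k_mirna], index=matrix.index)

    scores = {}
    for mod in sorted(mirna_labels.unique()):
        members = list(mirna_labels.index[mirna_labels == mod])
        if len(members) >= 2:
            scores[f"M{mod}"] = cluster.module_meta_score(
                matrix, members, module=f"M{mod}"
            ).score
    meta = pd.DataFrame(scores).T

    cov_design = encode_covariates(data["covariates"])
    # baseline = the control-enriched cluster
    disease = data["covariates"]["disease"]
    control_frac = {
        c: float((disease[sample_labels == c] == "Control").mean())
        for c in sample_labels.unique()
    }
    baseline = max(control_frac, key=control_frac.get)
    assoc_frames = []
    for dz in ("COPD", "ILD"):
        outcome = (disease == dz).astype(float)
        assoc = cluster.associate_cluster(
            outcome, sample_labels, cov_design, family="logistic", baseline=baseline
        )
        assoc["outcome"] = dz
        assoc_frames.append(assoc)
    assoc_table = pd.concat(assoc_frames)
    sample_labels.rename("cluster").to_csv(outdir / "sample_clusters.tsv", sep="\t")
    mirna_labels.rename("module").to_csv(outdir / "mirna_modules.tsv", sep="\t")
    meta.to_csv(outdir / "module_meta_scores.tsv", sep="\t")
    assoc_table.to_csv(outdir / "cluster_associations.tsv", sep="\t")
    data["sample_clusters"] = sample_labels
    data["mirna_modules"] = mirna_labels
    manifest["stages"]["cluster"] = {
        "k_samples": int(k_samples), "k_mirna_modules": int(k_mirna),
        "baseline_cluster": int(baseline),
    }


def _stage_eqtl(data: dict, cfg: PipelineConfig, outdir: Path, manifest: dict) -> None:
    cov = encode_covariates(data["covariates"])
    recs = {}
    for label, expr in (("mirna", data["mirna_expression"]),
                        ("gene", data["gene_expression"])):
        rec = eqtl.eqtl_scan(
            data["genotypes"], expr, cov,
            p_threshold=cfg.eqtl_p_thresh, mode=cfg.eqtl_mode,
        )
        rec = eqtl.classify_cis_trans(
            rec, data["snp_positions"], data["feature_positions"], window=cfg.cis_window
        )
        rec.to_csv(outdir / f"eqtl_{label}.tsv", sep="\t", index=False)
        recs[label] = rec
    ftypes = pd.Series(
        ["mirna"] * len(data["mirna_expression"]) + ["gene"] * len(data["gene_expression"]),
        index=list(data["mirna_expression"].index) + list(data["gene_expression"].index),
    )
    summary, ratios = targets.tabulate_eqtl_summary(
        {"all": pd.concat(recs.values(), ignore_index=True)}, ftypes
    )
    summary.to_csv(outdir / "eqtl_summary.tsv", sep="\t", index=False)
    data["eqtl_mirna"] = recs["mirna"]
    data["eqtl_gene"] = recs["gene"]
    manifest["stages"]["eqtl"] = {
        "n_mirna_records": int(len(recs["mirna"])),
        "n_gene_records": int(len(recs["gene"])),
    }


def _stage_citnet(data: dict, cfg: PipelineConfig, outdir: Path, manifest: dict) -> None:
    cand = data["eqtl_mirna"].merge(
        data["eqtl_gene"], on="snp", suffixes=("_mirna", "_gene")
    )[["snp", "feature_mirna", "feature_gene"]]
    cand.columns = ["snp", "mirna", "gene"]
    cand = cand.drop_duplicates().head(cfg.max_triplets)
    cov = encode_covariates(data["covariates"])
    disease = data["covariates"]["disease"]
    conditions = [c for c in ("Control", "COPD", "ILD") if (disease == c).sum() >= 30]
    if not conditions:
        conditions = ["all"]
    networks, results = {}, {}
    for cond in conditions:
        samples = disease.index if cond == "all" else disease.index[disease == cond]
        res = citnet.cit_scan(
            cand,
            data["genotypes"][samples],
            data["mirna_expression"][samples],
            data["gene_expression"][samples],
            covariates=cov.loc[samples],
            n_perm=cfg.cit_n_perm, seed=cfg.seed, alpha=cfg.cit_alpha,
        )
        res.to_csv(outdir / f"cit_{cond}.tsv", sep="\t", index=False)
        results[cond] = res
        networks[cond] = citnet.build_network(res, data["eqtl_mirna"], cond)
    edges = [
        {"condition": c, "mirna": m, "gene": g,
         "n_triplets": len(net.provenance[(m, g)])}
        for c, net in networks.items()
        for m, gs in net.adjacency.items() for g in sorted(gs)
    ]
    pd.DataFrame(edges).to_csv(outdir / "network_edges.tsv", sep="\t", index=False)
    stage_info = {
        "n_candidates": int(len(cand)),
        "edges": {c: sum(len(g) for g in net.adjacency.values())
                  for c, net in networks.items()},
    }
    if len(networks) >= 2:
        (a, b) = list(networks)[:2]
        conn = citnet.differential_connectivity(
            networks[a], networks[b],
            universe_a=set(data["gene_expression"].index),
            universe_b=set(data["gene_expression"].index),
            q_thresh=cfg.connectivity_q_thresh,
        )
        conn.to_csv(outdir / f"connectivity_{a}_vs_{b}.tsv", sep="\t", index=False)
        stage_info["connectivity_pair"] = [a, b]
    data["networks"] = networks
    data["cit_results"] = results
    manifest["stages"]["citnet"] = stage_info


def _stage_targets(data: dict, cfg: PipelineConfig, outdir: Path, manifest: dict) -> None:
    loci = data.get("loci") or []
    utrs = data.get("utrs") or {}
    info: dict = {}
    if loci and utrs:
        locus = loci[0]
        canon_seed = targets.extract_seed(locus.mature_sequence, 0, mirna=locus.name)
        iso = data.get("isomirs")
        offsets = []
        if iso is not None and len(iso):
            here = iso[(iso["locus"] == locus.name) & (iso["offset5"] != 0)]
            offsets = list(here.sort_values("count", ascending=False)["offset5"].head(1))
        iso_off = int(offsets[0]) if offsets else -1
        genome_seq = data["genome"][locus.chrom] if data.get("genome") else locus.mature_sequence
        iso_seed = targets.extract_seed(
            locus.mature_sequence if locus.strand == "+" else locus.mature_sequence,
            iso_off, extended_sequence=genome_seq, mature_start=locus.start,
            mirna=locus.name,
        )
        canonical = targets.predict_targets(canon_seed, utrs)
        isomir = targets.predict_targets(iso_seed, utrs)
        universe = set(utrs)
        groups = targets.categorize_genes(canonical, isomir, universe)
        mirna_id = locus.name
        if mirna_id in data["mirna_expression"].index:
            corr = targets.correlate_targets(
                data["mirna_expression"].loc[mirna_id],
                data["gene_expression"], groups,
            )
            corr.to_csv(outdir / "target_correlations.tsv", sep="\t")
            profile = targets.spearman_profile(
                data["mirna_expression"].loc[mirna_id], data["gene_expression"]
            )
            anti_can = targets.anticorrelated_set(
                profile, canonical, q_thresh=cfg.anticorrelation_q_thresh
            )
            anti_iso = targets.anticorrelated_set(
                profile, isomir, q_thresh=cfg.anticorrelation_q_thresh
            )
            overlap = targets.anticorrelated_overlap(anti_can, anti_iso)
            info["anticorrelated_overlap"] = overlap
        info["seeds"] = {"canonical": canon_seed.sequence, "isomir": iso_seed.sequence}
        info["n_targets"] = {"canonical": len(canonical), "isomir": len(isomir)}
    nets = data.get("networks") or {}
    module_sets = {
        f"{cond}:{m}": genes
        for cond, net in nets.items() for m, genes in net.adjacency.items()
        if genes
    }
    if len(module_sets) >= 2:
        diss, _, order = targets.jaccard_module_cluster(module_sets)
        diss.to_csv(outdir / "module_jaccard.tsv", sep="\t")
        info["n_jaccard_modules"] = len(order)
    with open(outdir / "targets_summary.json", "w") as fh:
        json.dump(info, fh, indent=2, default=str)
    manifest["stages"]["targets"] = info


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    failures = validate_inputs(indir, config)
    hard = [f for f in failures if f.startswith("missing input")]
    if hard:
        raise FileNotFoundError("; ".join(hard))
    if failures:
        logger.warning("input validation issues: %s", failures)

    data: dict = {
        "counts": mio.read_matrix_tsv(indir / "counts.tsv"),
        "genotypes": mio.read_genotypes(indir / "genotypes.tsv"),
        "mirna_expression": mio.read_matrix_tsv(indir / "mirna_expression.tsv"),
        "gene_expression": mio.read_matrix_tsv(indir / "gene_expression.tsv"),
        "covariates": pd.read_csv(indir / "covariates.tsv", sep="\t", index_col=0),
    }
    for optional, loader in (
        ("reads", lambda: mio.read_reads_bed(indir / "reads.bed")),
        ("loci", lambda: mio.read_loci_gff3(indir / "loci.gff3")),
        ("genome", lambda: mio.read_fasta(indir / "genome.fa")),
        ("utrs", lambda: mio.read_fasta(indir / "utrs.fa")),
        ("snp_positions", lambda: pd.read_csv(indir / "snp_positions.tsv", sep="\t", index_col=0)),
        ("feature_positions", lambda: pd.read_csv(indir / "feature_positions.tsv", sep="\t", index_col=0)),
    ):
        name = {"reads": "reads.bed", "loci": "loci.gff3", "genome": "genome.fa",
                "utrs": "utrs.fa", "snp_positions": "snp_positions.tsv",
                "feature_positions": "feature_positions.tsv"}[optional]
        data[optional] = loader() if (indir / name).exists() else None

    manifest = {
        "config": dataclasses.asdict(config),
        "validation_failures": failures,
        "stages": {},
    }
    runners = {
        "quantify": _stage_quantify, "diffexpr": _stage_diffexpr,
        "cluster": _stage_cluster, "eqtl": _stage_eqtl,
        "citnet": _stage_citnet, "targets": _stage_targets,
    }
    for stage in STAGES:
        if not config.stages.get(stage, True):
            manifest["stages"][stage] = {"skipped": True}
            logger.info("stage %s skipped by configuration", stage)
            continue
        logger.info("running stage %s", stage)
        runners[stage](data, config, outdir, manifest)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return outdir


def simulate_and_run(
    outdir: str | Path,
    n_subjects: int = 120,
    n_triplets: int = 12,
    seed: int = 0,
    **config_kwargs,
) -> Path:
    """Convenience: simulate a cohort, write it, and run the full pipeline."""
    outdir = Path(outdir)
    spec = []
    for i in range(n_triplets):
        spec.append(synthdata.TripletSpec(synthdata.TRIPLET_CLASSES[i % 4], 0.8, 0.8))
    cfg = synthdata.SimConfig(
        n_subjects=n_subjects, n_snps=max(20, n_triplets),
        n_mirna=max(30, n_triplets), n_gene=max(30, n_triplets),
        triplet_spec=spec, seed=seed,
    )
    cohort = synthdata.simulate_cohort(cfg)
    synthdata.write_cohort(cohort, outdir / "inputs")
    pcfg = PipelineConfig(
        input_dir=str(outdir / "inputs"), output_dir=str(outdir / "run"),
        seed=seed, **config_kwargs,
    )
    return run_pipeline(pcfg)
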