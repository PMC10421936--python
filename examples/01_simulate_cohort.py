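"""Simulate a synthetic lung-cohort with planted SNP->miRNA->mRNA triplets.

Builds a small cohort (Hardy-Weinberg genotypes, four triplet classes, NB
read counts with batch effects, clinical covariates) and prints the planted
ground truth that every later analysis stage is measured against.
"""

from mirtriad import SimConfig, TripletSpec, simulate_cohort

config = SimConfig(
    n_subjects=80,
    n_snps=20,
    n_mirna=24,
    n_gene=24,
    triplet_spec=[
        TripletSpec("causal", 0.8, 0.8),
        TripletSpec("reactive", 0.8, 0.8),
        TripletSpec("independent", 0.8, 0.8),
        TripletSpec("null"),
    ],
    seed=7,
)
cohort = simulate_cohort(config)

print("planted triplets (class, snp, mirna, gene, slopes):")
print(cohort.truth_triplets.to_string(index=False))
print()
print("sample-level truth (first 5 rows):")
print(cohort.truth_samples.head().to_string())
print()
print(f"count matrix: {cohort.counts.shape[0]} miRNAs x {cohort.counts.shape[1]} samples,"
      f" median library size {int(cohort.covariates['lib_size'].median())}")
# Each triplet row is a causal claim the CIT stage should (or should not)
# recover; the sample table carries the cluster/disease/batch structure the
# clustering and DE stages should find.
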