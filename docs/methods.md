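# Methods

This note documents the statistical models, defaults, numerical choices and
limitations of `mirtriad`, stage by stage.

## Synthetic cohorts

The generator produces every input the pipeline consumes, with ground truth.

* **Genotypes.** Each SNP's minor-allele frequency is uniform on a
  configurable range (default 0.2–0.5, so dosage groups stay populated at
  moderate n) and genotypes are Binomial(2, maf): Hardy–Weinberg, no LD.
* **Triplets.** Classes over (genotype L, miRNA G, gene T), with L
  standardized to unit variance and standard-normal noise:
  causal `G = aL + e, T = bG + e`; reactive `T = aL + e, G = bT + e`;
  independent `G = aL + e, T = bL + e` (common driver, no G–T path); null
  all-noise. Effects are standardized slopes (default 0.8, strong enough
  that component-test power, not effect definition, is what the CIT
  calibration measures); with unit-variance noise the implied correlations
  are analytically predictable (e.g. cor(L,T) = ab/√((1+a²)(1+b²(1+a²))) for
  causal).
* **Counts.** Negative binomial via the Gamma–Poisson mixture with size θ
  (default 2, a typically overdispersed small-RNA value); the library-size
  term enters the log-mean as log(lib/median lib), matching depth-as-covariate
  modelling downstream, plus a batch shift (default 0.4 on protocol B).
* **Reads.** Multinomial 5' offsets at a locus; on the minus strand the 5'
  end is the interval end, so an upstream offset extends the window to the
  right. Read sequences are copied from the synthetic genome — no
  sequencing-error model.
* **Full cohorts** add cluster labels shifting disjoint miRNA modules (1.5
  SD), cluster-dependent disease enrichment (a control-enriched baseline
  cluster plus COPD- and ILD-enriched ones), clinical covariates (age
  ~N(63, 10), roughly 60% former smokers — magnitudes of a chronic
  lung-disease cohort), alternating two-protocol batches, and 3'UTRs with a
  planted seed site for the first miRNA in half the genes.

What the generator does **not** emulate: LD structure, realistic genome or
UTR base composition, GC/length biases, multi-mapping ambiguity, dropout, or
correlated covariates. Passing tests therefore demonstrate correctness of
the statistical machinery under the stated generative assumptions, not
robustness to every artifact of real cohorts.

All generators draw from one explicit `numpy` Generator per call; nothing
uses global random state, and fixed seeds give bit-identical outputs.

## Quantification

A read counts toward a locus when it overlaps it by at least one base on the
same strand; a read overlapping k loci increments all k, while per-sample
totals count each read once if it hit any locus (those raw totals, not
pseudocount-inflated sums, are the RPM denominator, keeping them
interpretable as locus-aligned read counts). Coordinates are 0-based
half-open internally; GFF3 is converted on read/write. Multi-mapped reads
are whole-counted, not fractionally weighted.

Read-length QC formalizes "clustered differently" as a robust outlier rule:
per-sample length histograms (15–36 nt, proportions), Euclidean distance to
the per-bin median profile, and failure beyond median + 5×MAD of the
distances (threshold configurable). With identical profiles the MAD is 0 and
nothing is flagged.

Normalization is log2((count+1)/total × 1e6). The detection filter keeps a
miRNA when ≥ 50% of samples show ≥ 2 counts; it is idempotent.

Batch adjustment is parametric empirical-Bayes ComBat (location/scale with
covariate preservation), backed by scanpy's implementation. One behavior is
worth stating plainly: EB shrinkage pulls per-feature batch-location
estimates toward the across-feature prior mean, so after adjustment the
per-feature batch means agree only up to a sampling-noise-order residual
(~0.12 at 200 samples/batch, unit variance — the R reference implementation
leaves the same residual). Exact per-feature mean equalization would require
forgoing shrinkage; we keep the EB form and document the residual. Planted
signals orthogonal to batch pass through essentially untouched (<1%
distortion in our checks). Single batch: identity; singleton batch: error.

## Differential expression

Per-miRNA NB GLM, log link, depth entering as log total counts (a covariate,
not an offset). Fitting alternates IRLS for the slopes with bounded Brent
maximization of the profile likelihood in log θ (θ ∈ [1e-3, 1e7], moment
start) until |Δ log L| < 1e-8 or 100 alternations; non-convergence is
flagged, never raised. The disease test is the 2-df LRT against the
no-disease model; a negative statistic beyond 1e-6 warns and clips to 0.
BH is the exact step-up definition with NaNs excluded from n. The call rule
is q < 0.1 and max(|coef_COPD|, |coef_ILD|) > 0.22; reported fold changes
are exp(coef), so the cutoff is the 1.25-fold rule. Dispersion shrinkage
across features (edgeR/DESeq2-style) is deliberately out of scope.

## Clustering

`pam` solves tiny instances (≤ 2000 candidate medoid sets) exactly by
exhaustive search and uses BUILD + best-improvement SWAP beyond; both paths
end in a state where no single medoid/non-medoid exchange improves the
objective. (Pure BUILD+SWAP — ours and the reference R implementation alike —
lands in a strictly suboptimal local optimum on a few percent of tiny random
instances; solving those exactly is cheap and strictly better.)

Consensus clustering subsamples items only (fraction 0.8, consensus-
clustering convention; the feature dimension is left intact), clusters each
draw with PAM on Euclidean distances, and normalizes co-clustering by
co-sampling counts. Final assignments cut an average-linkage tree on
1 − consensus. `select_k` scores each k by the mean of the cophenetic
correlation and average item consensus; the highest score wins, ties are
broken by the larger drop at k+1 and then the smaller k, and candidates
whose smallest cluster falls under max(min size, half the balanced size n/k)
are excluded. The drop is a tie-break rather than an additive bonus because
PAM is deterministic given a subsample, which can make over-split solutions
look deceptively stable.

Meta-scores are PC1 over samples of the z-scored member miRNAs
(zero-variance members dropped with a warning), sign-fixed to correlate
positively with the module mean profile so "module up" always means a higher
score. Cluster–phenotype models are OLS/logistic with covariates against a
stated baseline cluster (the control-enriched one); logistic separation
falls back to an L2-penalized fit with the rows flagged and Wald p withheld.

## eQTL scan

Expression is residualized on the covariates (least squares via QR;
rank-deficient covariate sets are rejected naming the collinear columns).
`additive` mode correlates residualized genotype and expression over the
whole SNP × feature grid with matrix products (t, df = n − c − 2);
`anova` mode treats genotype as a ≤3-level factor on residualized expression
(F, df = (g−1, n − c − g)) and is the default in the pipeline's
configuration surface where factor coding matters. Monomorphic SNPs are
skipped and logged; NA dosages are dropped per SNP. cis means same
chromosome and |SNP − feature start| ≤ 1 Mb, boundary inclusive — the
conventional window, configurable. Both the network-input threshold
(p < 5e-4) and an FDR-style threshold are exposed in configuration.

## CIT

Covariates are residualized out of mediator and outcome (the residualized
degrees of freedom are subtracted in every component F test); the genotype
is left raw because it defines the permutation strata. Components for
L → M → T: (1) F for L in T ~ L; (2) F for L in M ~ T + L; (3) F for M in
T ~ L + M; (4) the equivalence-style conditional-independence test. For
test 4 the observed statistic is the F for L in T ~ M + L, and the reference
distribution is built by permuting the **mediator within genotype strata**:
this preserves the L–M association exactly (within-stratum sums are
invariant) while destroying M's sample-level link to T, i.e. it represents
the no-mediation alternative. p4 = (1 + #{F* ≤ F_obs})/(n_perm + 1): small
exactly when conditioning on the true mediator removes the L–T association
far better than conditioning on an L-equivalent pseudo-mediator can.
Permutation F statistics are computed in closed form from partial
correlations, vectorized over draws. With the default 100 draws the smallest
attainable p4 is 1/101 ≈ 0.0099 < α; fewer than 20 draws warns.

The omnibus p is the max of the four components, so weakening any single
link can only raise it. The reactive direction reuses the same seed, making
`cit_test(L, M, T).p_reactive == cit_test(L, T, M).p_causal` exact. Calls
use raw α = 0.05 in both directions — no multiplicity correction before
classification, matching a screening design where the eQTL filter has
already restricted the candidate space. Networks only ever contain
miRNA → gene edges from causal calls whose SNP–miRNA pair passed the eQTL
screen; provenance lists every contributing SNP. Differential connectivity
uses the union gene universe of the two conditions as the Fisher table
denominator.

## Targets

Seeds are mature positions 2–8 after the 5' shift, drawing on the extended
locus sequence when the shifted window leaves the mature sequence; U≡T and
all matching is DNA-alphabet (N never matches). Site classes: 7mer-m8 =
reverse complement of positions 2–8; 7mer-A1 = reverse complement of
positions 2–7 followed by A; 8mer = both, which suppresses the two 7mer
calls it contains. This replaces TargetScan-style context scoring with pure
seed-match set logic — adequate for comparing canonical and isomiR target
*sets*, but it ignores site context, conservation and efficacy.

Spearman profiles exclude constant genes; group-versus-neither comparisons
are two-sided rank-sum tests. Anticorrelated target sets use BH q < 0.25
over the whole tested gene universe with ρ < 0. Preranked GSEA uses the
weighted running sum (hit increments ∝ |score|^weight, default 1) with a
seeded gene-label permutation null — phenotype permutation would need raw
per-sample data that a preranked interface does not carry — and
NES = ES / mean(|permuted ES| of the same sign). Jaccard module clustering
is average linkage on 1 − Jaccard with scipy's deterministic leaf order;
two empty sets get Jaccard 0 by convention (logged).

## Pipeline

Stages run in dependency order on a validated input directory; every
threshold (detection 2/50%, DE q 0.1 and coef 0.22, eQTL p 5e-4, CIT α 0.05,
connectivity FDR 0.2, anticorrelation q 0.25, cis window 1 Mb) lives in one
YAML-loadable configuration and can be overridden by CLI flag. The manifest
records configuration, seeds and per-stage row counts; identical
configuration reproduces byte-identical outputs. Within-pipeline CIT
candidates are the join of SNP–miRNA and SNP–gene eQTL records, capped
(default 500) to bound runtime; conditions with fewer than 30 samples are
not scanned separately.

## Problem sizes used in validation

The shipped checks run at sizes chosen to make their statistical claims
sharp while staying desk-scale: CIT calibration on 500 independent and 100
causal triplets (n = 400, slopes 0.8, 100 permutation draws); end-to-end
network recovery on 200 triplets (50 per class); NB-GLM type-I calibration
on 2000 null features (n = 200) with coefficient recovery at n = 2000;
clustering recovery on 60 items in 3 well-separated clusters with 100
resamples; batch adjustment at 200 samples/batch. At these sizes the whole
validation suite completes in well under half an hour on one CPU.

## Known limitations

* The EB batch adjustment does not exactly equalize per-feature batch means
  (see above); analyses requiring exact equalization need an unshrunken
  location model instead.
* CIT p4 resolution is bounded by the permutation count; calls at α near
  1/(n_perm+1) are coarse.
* The eQTL scan offers no permutation-based feature-level FDR, conditional
  mapping or LD pruning; population structure must arrive as precomputed
  covariate columns.
* Seed matching knows nothing about site accessibility or conservation;
  overlap percentages on real UTRs will differ from context-scored tools.
* The consensus-clustering stability signal is limited by PAM's determinism
  given a subsample; very small k ranges can look uniformly stable.
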