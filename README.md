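# mirtriad

Integrative miRNA analysis for chronic lung disease cohorts (COPD, ILD and
controls): small-RNA quantification with 5'-isomiR grouping, negative-binomial
GLM differential expression, consensus clustering of expression subtypes,
eQTL scanning, causality-inference-test (CIT) construction of
disease-specific SNP → miRNA → mRNA networks with differential connectivity,
and seed-shift target analysis for 5' isomiRs.

The package is aimed at systems-biology analysts who want the full chain —
from aligned small-RNA reads and genotype dosages to condition-specific
mediation networks — as tested, reusable Python, together with a
synthetic-cohort generator that plants ground truth for every stage so each
statistical component can be validated end to end.

## The models at the core

**Differential expression.** For each miRNA, counts $y$ follow a log-link
negative binomial GLM, $\mathrm{Var}(y) = \mu + \mu^2/\theta$, with
sequencing depth, protocol, smoking, age, gender and the two disease
indicators as predictors; $\theta$ is estimated by maximum likelihood
alternating with IRLS. Disease significance is a likelihood-ratio test
(χ², 2 df) of the model with both disease terms against the model with
neither, BH-adjusted; a miRNA is called when $q < 0.1$ and either disease
coefficient exceeds 0.22 on the natural-log scale ($e^{0.22} \approx 1.25$-fold).

**Consensus clustering.** Samples (and miRNAs) are clustered by resampled
PAM on Euclidean distances of batch-adjusted log2 RPM; the consensus matrix
entry for two items is the fraction of co-clustering among resamples drawing
both. $k$ is chosen by the cophenetic and average-item-consensus scores with
a drop-off tie-break and a small-cluster exclusion; module meta-scores are
PC1 of the z-scored member miRNAs.

**CIT mediation networks.** For a triplet (SNP $L$, miRNA $G$, mRNA $T$) the
causal direction $L \to G \to T$ requires four component conditions:
$T \sim L$; $G \sim L \mid T$; $T \sim G \mid L$; and $L \perp T \mid G$,
the last tested against a permutation reference that preserves the $L$–$G$
association while destroying the mediated path. The omnibus
$p_{\text{causal}} = \max(p_1, \dots, p_4)$; the reactive direction swaps
$G$ and $T$. Calls at $\alpha = 0.05$: causal, reactive, independent
(both $\ge \alpha$), non-inferable (both $< \alpha$). Networks keep one
miRNA → gene edge per causal-called, eQTL-backed triplet; per-miRNA degree
differences between condition networks are tested by two-sided Fisher exact
tests (BH, FDR < 0.2), and scale-free topology is checked by the log–log
regression of degree frequency on degree.

**isomiR seeds.** The seed is the heptamer at mature positions 2–8; a 5'
isomiR shifts the start and hence the seed (miR-34c-5p: canonical
`GGCAGTG`, 1-base-left-shifted `AGGCAGT`). Target sites are the seed's
reverse complement in the 3'UTR (8mer / 7mer-m8 / 7mer-A1), and canonical
versus isomiR target sets are compared by Spearman-correlation rank-sum
tests, percent-distinct/Jaccard overlap, preranked GSEA and Jaccard module
clustering.

## Worked example

`examples/06_cit_network.py` simulates twelve SNP–miRNA–mRNA triplets
(six causal, three reactive, three independent, standardized slopes 0.8,
n = 400), runs the CIT and builds the network:

```
  snp mirna   gene  p_causal  p_reactive        call       class
 snp0  mir0  gene0     0.010       0.697      causal      causal
 snp1  mir1  gene1     0.010       0.148      causal      causal
 ...
 snp6  mir6  gene6     0.821       0.010    reactive    reactive
 snp9  mir9  gene9     0.980       0.941 independent independent

network: 6 miRNA->gene edges from causal calls with eQTL backing
scale-free check on a d^-2 degree distribution: slope -2.00, r -1.00
```

Every planted class is recovered: causal triplets have a small causal and
large reactive p-value, reactive triplets the mirror image, and independents
(common-driver) stay out of the network. The minimum attainable permutation
p with 100 draws is 1/101 ≈ 0.010. The other scripts under `examples/`
cover each capability the same way: cohort simulation, isomiR counting,
the NB-GLM scan, consensus clustering, the eQTL scan and the full pipeline.

A thin CLI wraps the same pipeline:

```bash
mirtriad simulate work --n-subjects 120 --seed 1
mirtriad run-all work/inputs work/run --seed 1
```

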