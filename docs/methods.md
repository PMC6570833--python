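# Methods

`ibdnet` implements a GWAS-to-network workflow for targeted SNP panels in
inflammatory bowel disease (IBD) and, by construction, any case–control
phenotype with a curated risk-locus panel. This note documents the models,
the defaults and why they were chosen, what the synthetic generators do and
do not emulate, and the numerical choices that affect results.

## Association statistics

Each SNP is coded as the number of copies of allele 1 (the minor allele).
For a case/control contrast the 2×2 allele-count table
(a, b; c, d) = (allele-1 in affected, allele-2 in affected; allele-1 in
unaffected, allele-2 in unaffected) is tallied over called genotypes only.

* **Allelic test.** The 1-df Pearson statistic
  χ² = N(ad − bc)² / ((a+b)(c+d)(a+c)(b+d)), no continuity correction.
  The asymptotic p is the chi-square upper tail, which for df = 1 equals
  2(1 − Φ(√x)). Yates' correction is deliberately absent: the test is the
  plain allelic test as used by standard GWAS toolkits, and the packaged
  panel's printed χ²/p pairs are consistent with the uncorrected form.
* **Odds ratio.** OR = ad/bc for allele 1 vs allele 2, 95% CI from the
  log-scale normal approximation exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)).
  Zero cells follow the literal quotient (0 numerator → 0, 0 denominator →
  +inf, 0/0 → NaN) with an undefined CI; a Haldane–Anscombe 0.5 correction
  is available by flag but off by default so that degenerate panel rows
  (e.g. an allele absent in cases, printed OR 0.0000) reproduce as printed.
  The OR is invariant to the total allele count, which is why it can be
  recomputed from printed frequencies alone; the χ² statistic is not,
  because per-SNP missingness changes the effective N.
* **HWE exact test.** Two-sided exact test conditional on allele counts:
  the p-value sums the probabilities of all heterozygote counts at most as
  probable as the observed one. Computed in log-gamma space in O(n); tests
  compare it against an exact rational-arithmetic enumeration.
* **QC gate.** A SNP is kept iff missing rate ≤ 0.05, MAF ≥ 0.01 (all
  samples), and HWE p ≥ 1e-6 in controls only. These are conventional GWAS
  defaults; all three are configurable. HWE is tested in controls because a
  true association itself distorts genotype proportions in cases.
* **Selection.** Results are filtered at raw p ≤ 0.05 (the workflow's
  design: a targeted panel of pre-selected candidates, not a genome-wide
  scan). A Benjamini–Hochberg column is emitted for information only and
  never gates selection.

A note on printed precision: the packaged panel prints χ² to three
decimals. The tail probability of a statistic known only to ±0.0005
carries a first-order uncertainty of pdf(x)·0.0005, so the test asserting
the χ²→p mapping uses that propagated bound (plus one ulp of the printed
p) rather than pretending the printed χ² pins p to six decimals.

## Protein-association networks

Risk genes (loci of the significant SNPs) are resolved to canonical
protein symbols through an optional alias table (identity fallback,
unmapped symbols reported). The network is the confidence-thresholded
interaction graph (combined score ≥ 0.400, "medium confidence") enriched
with at most 20 first-shell interactors (neighbors of seeds) and then at
most 10 second-shell interactors (neighbors of the first shell). Candidate
interactors are ranked by the summed confidence of their edges into the
network built so far, ties broken by symbol — a deterministic, monotone
"most strongly attached first" rule standing in for the proprietary
selection score of interaction-database services. All qualifying edges
among included nodes are materialized; nodes left without an edge are
hidden (removed), with hidden seeds reported on the graph object.
Channel-specific scores are accepted on load but only the combined score
gates edges.

## Centralities and the combined score

Three complementary notions of importance:

* degree centrality deg(v)/(n−1) — hubs;
* Latora harmonic closeness (1/(n−1))·Σ 1/d(u,v) with 1/∞ = 0 — reach,
  chosen over classic closeness because it natively handles the
  disconnected graphs that shell expansion can produce;
* betweenness normalized by (n−1)(n−2)/2 — bottlenecks.

Each centrality is min-max rescaled to [0, 1] across the network's nodes
(a constant column maps to 0 — it carries no ranking signal), then
combined as 0.2·deg + 0.3·clo + 0.5·bet. Normalization before weighting is
a design choice: the three raw centralities live on different scales, and
the weights are only meaningful on comparable ones. A raw-scale mode and a
confidence-weighted distance mode (d = 1 − score) exist by flag; defaults
compute on unweighted topology since edges-above-threshold is the stated
network semantics. Ties in the final ranking break by symbol ascending.

## Clustering

* **MCL** (protein networks): column-stochastic transition matrix from the
  adjacency (confidence as capacity) plus unit self-loops — the canonical
  damping against parity oscillation; expansion = matrix square, inflation
  = entrywise power r (default 3) with column renormalization; entries
  below 1e-5 are pruned; convergence when the max entry change falls below
  1e-8, error on non-convergence within 200 iterations. Clusters are read
  from attractor rows; overlapping attractor systems are merged so the
  assignment is a partition. Dense numpy implementation — the networks
  here are tens of nodes.
* **Edge-betweenness communities** (pathway networks): divisive
  Girvan–Newman with deterministic tie-breaking (lexicographic endpoint
  pair); among the partitions along the removal sequence the one with
  maximal Newman–Girvan modularity of the original graph is returned.
  Communities never span disconnected components.

Inflation is the granularity dial: cluster counts are non-decreasing in r
on fixed graphs (property-tested at r ∈ {1.5, 2, 3, 5}).

## Enrichment and complementary pathway networks

Over-representation is the hypergeometric upper tail P(X ≥ k) of the
query/set overlap against a background (default: union of all database
genes). Sets are ranked by p ascending, ties by larger overlap then set
id; the top 10 become seed pathways. BH adjustment is reported but does
not gate seed selection (selection is a fixed count, not a significance
cutoff). The service-grade "combined score" ranking used by online
enrichment tools requires their precomputed background ranks and has no
offline equivalent, so ranking is by p; a mode flag is reserved.

The pathway-pathway scaffold is built offline: nodes are all database
sets, edges are gene-overlap Jaccard ≥ 0.05 (the default floor keeps
single-gene coincidences out of small databases while preserving the
connectivity of genuinely related pathways). The complementary network
starts from the scaffold subgraph induced on the seeds and, while more
than one connected component remains, adds the intermediates of the
shortest scaffold path joining two components (fewest intermediates; ties
by larger summed Jaccard, then lexicographic node sequence). A final
pruning pass removes any added pathway whose removal does not increase
the component count, so every complementary pathway in the output is
structurally necessary. Seeds in scaffold components with no connecting
path are left as separate components with a warning.

## Ranking, comparison, disease network

A pathway's rank score is the arithmetic mean of the combined scores of
its member proteins **present in the analyzed network** — full database
membership does not dilute the score. Phenotype lists are compared as
exact Venn regions (2–4 lists; regions are asserted to partition the
union). Two methods' pathway lists merge into common/exclusive partitions.
The disease–disease network takes one pathway profile per phenotype (the
union of both methods' pathways), links profiles sharing ≥ 1 pathway and
weights edges by Jaccard; isolated phenotypes are retained and flagged.

## Synthetic data: what it emulates, what it does not

The generators reproduce the statistical structure the analysis assumes:

* **Genotypes.** Per SNP, a control allele-1 frequency f_U and a target
  allelic OR determine the case frequency
  f_A = OR·f_U/(1 − f_U + OR·f_U); individuals draw Binomial(2, f) under
  HWE within each group; calls are masked missing completely at random.
  The bundled panel specs reuse the packaged reference panel's (f_U, OR)
  pairs, and the default cohort is 364 CD + 209 UC cases vs 445 controls.
  Not modeled: linkage disequilibrium, population stratification,
  genotype-calling error, differential missingness. Planted HWE
  violations for QC tests are injected as explicit genotype counts, since
  frequency perturbation alone cannot break within-group HWE.
* **Interaction networks.** Planted-partition graphs (default 4 modules of
  10, p_in = 0.8, p_out = 0.02) with within-module confidences uniform on
  [0.45, 0.95] and half of the between-module confidences drawn below the
  0.400 threshold, so that thresholding sharpens the planted structure
  the way a medium-confidence cut does on real association networks.
  Not modeled: hubs/scale-free degree structure, evidence-channel
  correlation.
* **Gene sets.** One planted set sharing exactly k genes with the query;
  background sets leak at most one query gene.

Passing tests on these inputs demonstrate calibration and recovery under
the stated generative assumptions — they do not certify behavior under LD,
stratification, or database biases absent from the generators.

## Problem sizes in the calibration experiments

Type-I error uses 10,000 null SNPs at 200 cases / 200 controls (expected
retention 5% at α = 0.05, asserted within [0.04, 0.06]); OR recovery uses
200 replicate SNPs per true OR ∈ {0.5, 1, 2} at 5,000/5,000 (relative
bias of the mean estimate < 2%); MCL recovery averages the adjusted Rand
index over 20 planted-partition seeds (asserted > 0.9); centralities are
checked against exhaustive geodesic enumeration on 1,000 random graphs of
up to 7 nodes. These sizes make all three sampling distributions tight
enough that the assertions are stable across seeds.

## Known limitations

* Network-level results (node/edge/cluster counts, specific protein and
  pathway rankings) depend on the interaction database and pathway
  database supplied; the package deliberately does not try to reproduce
  any particular service snapshot.
* MCL here clusters the association graph's topology; services that
  cluster on auxiliary similarity data (e.g. domain architecture) will
  partition differently.
* The complementary-network rule is a documented greedy surrogate for
  proprietary connection algorithms of online pathway tools, not a
  re-implementation of any of them.
* The allelic test assumes HWE-consistent allele counting; no covariate
  adjustment, imputation, or stratification correction is provided.
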