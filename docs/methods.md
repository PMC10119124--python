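# Methods

This note documents the models implemented in codivkit, the defaults and why
they were chosen, the numerical choices that matter, and what the synthetic
data do and do not establish about real data.

## The question and the test

Given one dominant symbiont profiled across many host-derived metagenomes,
co-diversification predicts *mirrored* population structure: hosts that
belong to the same lineage should carry symbiont populations that are more
similar to each other than to those of the other lineage. codivkit
quantifies this with the global ParaFit test. Host and symbiont distance
matrices are embedded by principal coordinates analysis (PCoA); with host
coordinates `B` (hosts × axes), symbiont coordinates `C` (symbionts × axes)
and the 0/1 association matrix `A` (symbionts × hosts), the statistic is

    ParaFitGlobal = || Cᵀ A B ||²_F .

The null distribution is obtained by permuting host identities (one random
permutation of the columns of `A` per draw). With the one-to-one association
used throughout this package — each host contributes exactly one symbiont
population — this is identical to the classic ParaFit row shuffle, and it
makes the null exactly exchangeable when hosts are i.i.d. The p-value uses
the add-one estimator p = (1 + b)/(1 + n_perm), so at the default 1000
permutations "p ≤ 0.001" is attainable only when no permutation reaches the
observed statistic. Permutation ties are counted with a relative tolerance
of 1e-12 on the statistic.

Both implementations (PCoA with the Cailliez correction, and the ParaFit
statistic) are cross-checked in the test suite against the independent R
implementations in `ape` on small fixtures.

### PCoA and the Cailliez correction

PCoA double-centers −d²/2 (Gower) and eigendecomposes. Axes with eigenvalue
below 1e-8 × (largest eigenvalue) carry zero coordinates and are excluded
from ParaFit; the number of retained axes is therefore data-driven rather
than fixed. When the smallest eigenvalue falls below −1e-8 × (largest), the
Cailliez constant c — the largest real eigenvalue of the 2n × 2n block
matrix [[0, 2Δ₁], [−I, −4Δ₂]] with Δ₁ the centered −d²/2 and Δ₂ the
centered −d/2 — is added to all off-diagonal distances and the embedding is
recomputed. Each matrix (host and symbiont) is corrected independently and
only when it needs it; Jaccard presence/absence matrices with sampling noise
routinely do, Euclidean PC-space matrices never do.

## SNV variability

Per (position, sample), departure from consensus is d = 1 − max_count /
coverage, with the consensus and the competing (second-ranked) nucleotide
resolved at ties in the fixed order A < C < G < T so results are
deterministic. A position is *reported* as an SNV when the fraction of
samples that simultaneously pass the coverage gate (≥ 20×) and the variation
threshold (d > 1%) is at least the prevalence cutoff (90%). The per-sample
gates apply first and the prevalence gate last; raising any threshold can
only shrink the reported set (a property the tests check on random
fixtures).

Two sample-distance modes are provided: Jaccard distance on SNV
presence/absence sets (a pair of empty sets is at distance 0), used for the
ParaFit linkage; and Euclidean distance on departure vectors, used for
Ward clustering, with below-gate or uncovered entries imputed as 0 (logged).

**Prevalence in the co-diversification scenario.** A lineage-diagnostic SNV
is, by definition, carried by only one of the two host clusters, so with
balanced clusters its prevalence is ≈ 50% and a 90% gate would discard the
very signal under test. The genome-wide default therefore stays at 90%, but
the co-diversification chain (`run_codiversification`, the pipeline, the
acceptance script) sets the prevalence gate to 0.45 — just below the
cluster fraction — which retains cluster-diagnostic variants while still
suppressing sporadic error-driven positions.

## Codon variants, pN/pS, SAAVs

Without read-level data, a codon's variant composition is reconstructed from
positional counts: codon coverage is the minimum of the three positional
coverages, and counts are apportioned (largest-remainder rounding, ties to
the lower index) across codons **only when at most one position in the codon
is variable** (departure > 1%). Codons with two or more variable positions
are flagged ambiguous and excluded with a log line. The simulator places at
most one variant per codon, so on simulated data the reconstruction is
exact; on real pileups the equivalent information requires reads spanning
the whole codon — a documented limitation of this sequence-level stand-in.

pN/pS uses Nei–Gojobori site accounting: for each consensus codon, each of
the nine single-nucleotide neighbors contributes 1/3 site to the synonymous
or non-synonymous total (mutations creating stop codons count as
non-synonymous, the standard convention), so N_sites + S_sites = 3 per
codon exactly. Every non-consensus codon above the 1% frequency threshold
counts as one polymorphism, classified by whether it preserves the consensus
amino acid, and pN/pS = (N_obs/N_sites)/(S_obs/S_sites). S_obs = 0 with
N_obs > 0 yields +inf (flagged); no polymorphisms at all yields NaN.
Counts are pooled across samples by default; a per-sample scope (variants
called within each sample, then summed) is available because population-level
pooling versus per-sample averaging is a genuinely open choice for this
statistic.

SAAVs are emitted where a non-consensus amino acid exceeds 1% frequency in
the pooled counts; each record carries the BLOSUM62 score of the (consensus,
competing) pair — read verbatim from an NCBI-format matrix file — the
amino-acid-level departure, and the per-host-cluster prevalence (fraction of
the cluster's samples in which the variant individually passes the
threshold).

## Host population structure

Genotype likelihoods (3 diploid genotypes per individual and site,
normalized) are the substrate, never hard calls. The per-site allele
frequency maximizes Σᵢ log Σ_g L(g)·HWE(g|f) by EM (tolerance 1e-8 on f,
cap 500 iterations; the tests check agreement with a grid-search oracle).
The SNP test is the likelihood ratio 2[ℓ(f̂) − max(ℓ(0), ℓ(1))] against
chi-square df = 1; the boundary point-mass correction is deliberately
omitted, which makes the p-value conservative. Site filters: presence in ≥
50% of individuals, SNP p < 10⁻⁶, ML minor allele frequency ≥ 0.05 — three
independent gates, all required.

PCA uses a one-pass posterior-dosage covariance: E[g] under the HWE prior at
f̂, standardized by √(2f̂(1−f̂)), with pairwise-complete covariance for
missing entries. This replaces the iterated individual-allele-frequency
scheme of genotype-likelihood PCA tools; one pass is sufficient for
two-lineage recovery at the scales involved, and the downstream consumers
need only the cluster assignment and a distance matrix. Two clusters are
forced, by 2-means on PC1 with deterministic initialization at the two PC1
extremes (label 1 = lower-mean cluster). Host distances are Euclidean in PC
space over all positive-eigenvalue axes — with all axes kept this equals the
distance computed directly from the standardized dosages, which the tests
verify. How the original host distance matrix for ParaFit should be
constructed is not uniquely determined by the data; PC-space Euclidean
distance is this package's choice, stated openly.

## Ward clustering and congruence

The sample × SNV departure matrix is clustered with Ward linkage on
Euclidean distances (scipy's Lance–Williams implementation); the dendrogram
is exported as Newick with branch lengths equal to merge-height differences,
and the two-cluster cut takes the top split. Host/symbiont partition
agreement is summarized by the adjusted Rand index (1 = identical up to
relabeling, ≈ 0 at chance) plus the raw contingency table — a quantitative
stand-in for visual co-clustering.

## Enrichment

For each binary feature across genomes in two groups, the score (Rao) test
of the group coefficient in an intercept + group logistic model: U²/V with U
the score and V the expected information at the intercept-only fit. This
equals the Pearson chi-square of the 2×2 table (no continuity correction,
matching the score-test formulation); degenerate all-0/all-1 features give
statistic 0, p = 1. q-values are Benjamini–Hochberg; features with q < 0.05
are called enriched in the group with the higher occurrence proportion. In
the pipeline the features are SAAV occurrences per sample and the groups are
the inferred host clusters — the occurrence-type data this chain produces;
gene-function (KOfam-style) occurrence tables from annotation pipelines plug
into the same interface.

## The simulator: what it emulates, and what it does not

Hosts: two lineages of `n_hosts_per_cluster` diploid individuals. Per site,
an ancestral frequency p ~ U(0.05, 0.95); lineage frequencies from the
Balding–Nichols model Beta(p(1−F)/F, (1−p)(1−F)/F); genotypes
Binomial(2, p_c); depths Poisson; each read supports the carried allele with
probability 1 − ε. Zero-depth entries get flat likelihoods and a missing
flag.

Symbiont: a single-contig genome of contiguous, in-frame, forward-strand
genes (ATG start, sense codons, 0-based half-open coordinates), with
disjoint lineage-diagnostic SNV sets placed in distinct codons. Each host's
symbiont population carries its own lineage's set (vertical) or, with
probability `h_transmission`, the set of a uniformly drawn lineage
(horizontal, recorded in the truth object). At carried SNVs the within-host
alternate frequency is `within_host_minor_freq`; counts are Multinomial at
Poisson coverage with error spread evenly over the three wrong nucleotides.

Defaults are the package's reference study conditions: 15 hosts per lineage,
2000 host sites, F = 0.1, 20× host coverage with 1% read error, 30 genes of
50 codons (4.5 kb), 8 vs 16 diagnostic SNVs (the second lineage carries the
excess variable SNVs), 100× symbiont coverage with 0.1% error, within-host
alternate frequency 0.3 (an intermediate variability level; the real
within-host frequency spectrum is unknown, so this is an exposed knob, not a
claim), and strict vertical transmission. One RNG child stream per output
object, derived from the master seed by fixed labels, so changing one side
of the simulation does not perturb the other.

Not emulated: read-level data (quality scores, mapping), recombination or
within-lineage symbiont diversity beyond the diagnostic sets, indels,
strand-biased error, multi-symbiont communities, and a third (outgroup) host
population. Consequently, passing tests demonstrate the correctness and
calibration of the statistical machinery under the stated generative model —
not robustness to mapping artefacts, contamination, or strain mixtures in
real metagenomes.

## Calibration results the suite computes

- Type-I error: 500 fully-horizontal hologenomes (8 hosts/lineage, 200 host
  sites, 300 bp symbiont genome at 50×, 199 permutations each) give a
  rejection rate at α = 0.05 inside [0.03, 0.07]. Dataset sizes here are the
  package's desk-scale reference conditions; the permutation counts follow
  the test's definition.
- Power: the reference vertical-transmission scenario reaches the
  permutation floor p = 1/1001 with the mirrored clusters recovered exactly
  (both ARIs = 1).
- Host recovery: F = 0.1, 20+20 individuals, 5000 sites, 20× gives ARI = 1
  against the true lineages for every tested seed.

## Known limitations

- The codon reconstruction is undefined for codons with ≥ 2 variable
  positions (excluded, logged); real data would need spanning-read counts.
- The LRT p-value is conservative near the frequency boundary (no 50:50
  point-mass correction).
- ParaFit assumes the association matrix is one-to-one in the permutation
  scheme's exchangeability argument; many-to-many associations still run but
  the null is then the classic approximate one.
- The two-cluster host split is forced (k = 2); a third population would be
  absorbed into the nearest cluster rather than detected.
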