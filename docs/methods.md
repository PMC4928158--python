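# Methods

This document specifies the statistical model, the estimators, the
numerical choices, and the scope of the synthetic-data generator. Every
empirical statement here is exercised by the test suite or by
`scripts/acceptance.py`; nothing is claimed beyond what those compute.

## Data model and preprocessing

A cohort is a set of mutation records (sample, tumor type, gene, genomic
coordinates, ref/alt alleles, variant class, protein change with
amino-acid position, and single-base flanks for SNVs), a sample → tumor
type map, and gene annotations carrying protein length. Input tables in
mutation-table or MAF-like dialects are parsed with line-numbered errors;
protein-change strings (`p.G12D`, `p.R213*`, `p.K45fs`, `del`/`ins`/
`dup`/`delins` forms) are parsed totally, with a fallback for unusual
notations.

**Hyper-mutation filter.** Within each tumor type, per-sample mutation
counts are summarized by mean μ and sample standard deviation σ (n − 1
denominator); samples with burden strictly greater than μ + 2σ are
excluded from all subsequent estimation. Types with fewer than 3 samples
are never flagged (σ is unstable). Note the filter's behaviour on sparse
cohorts: when the per-sample mean burden is below ~1, μ + 2σ can sit
below 2–3 mutations, so the very samples carrying a genuine hotspot
mutation plus any background mutation are the ones removed. The
calibration and recovery experiments in the tests and acceptance script
therefore build their synthetic cohorts with the filter disabled; the
filter targets realistic exome-scale burdens (tens to thousands of
mutations per sample), not minimal simulated gene panels.

## Mutation subtypes

Each mutation is assigned one of 20 subtypes: {missense, nonsense,
silent} × {ATts, ATtv, CpG_CGts, NoCpG_CGts, CpG_CGtv, NoCpG_CGtv}, plus
`insertion` and `deletion`. Context classification is strand-symmetric: a
G>A call is mapped to its reverse complement C>T before classification,
and a C is "CpG" iff its CG dinucleotide appears on either strand given
the single-base flanks (for the pyrimidine-normalized representation,
C followed by G). SNVs with unknown (`N`) flanks fall back to the
non-CpG class with a warning. The 8 *composition categories* collapse
consequence: the six contexts plus insertion and deletion.

Correctness is established exhaustively: all 192 flanked
pyrimidine-normalized SNV combinations, and their reverse complements,
are checked against an independently written brute-force classifier.

## Hotspot detection

For tumor type *t*, gene *g* (protein length *L*), subtype *s*, the
cohort total E_gts of subtype-*s* mutations in *g* defines a per-position
Poisson rate λ = E_gts / L — i.e. the null hypothesis is that the gene's
own mutations of that subtype land uniformly along the protein. A
position with O observed subtype-*s* mutations scores the upper tail

    p_s = P(X ≥ O), X ~ Poisson(λ),

computed as `scipy.stats.poisson.sf(O − 1, λ)`, with O = 0 giving p = 1
and underflow clamped to the smallest positive double. An alternative
`p_mode="pmf"` scores P(X = O)-based extremeness for sensitivity
analysis; the tail mode is the default and the one used everywhere else.

Subtype p-values at a position are combined with Fisher's method,
x = −2 Σ ln p_s, referred to χ² with 2k degrees of freedom. By default k
counts the subtypes *observed at that position* (`k_mode="observed"`);
`k_mode="gene"` instead uses all subtypes active in the gene, which is
more conservative because unobserved subtypes contribute p = 1 (ln p = 0)
while inflating the degrees of freedom.

Combined p-values are Benjamini–Hochberg adjusted within each tumor type
(`statsmodels` `fdr_bh`), and positions with q < 0.001 are called
hotspots. Genes lacking a protein-length annotation are skipped with a
warning rather than silently dropped.

The Poisson tail, the Fisher identity (for k = 1 the combined p equals
the input; for k = 2 it equals exp(−x/2)(1 + x/2)), and the BH step-up
are each validated against independent oracle implementations over dense
parameter grids.

## Prevalence across tumor types

For each called hotspot and each tumor type with at least one carrier,
a 2×2 table of (carriers, non-carriers) × (this type, all other types)
is tested with the two-sided Fisher exact test under the standard
probability-mass rule (sum over tables with point probability ≤ that of
the observed table). Degenerate margins give p = 1 with a warning.
BH adjustment is applied jointly across all tested (hotspot, type) pairs;
pairs with q < 0.01 are *prevalent*, and a hotspot whose carriers all lie
in a single type is *exclusive* to it. The Fisher implementation is
checked against full hypergeometric enumeration for every valid table
with total ≤ 40.

## Signatures and composition

The rate matrix reports tumor-type × subtype mutation rates in
mutations / Mb / sample, using a surveyed coding territory of 30 Mb per
sample by default (a whole-exome scale; it is a display normalization and
cancels out of all hypothesis tests). Rate heterogeneity between groups
is tested with Kruskal–Wallis; an all-tied input returns p = 1 with a
warning. Hotspot composition counts, for each tumor type, the fraction of
its hotspots carrying at least one mutation of each of the 8 categories
(a hotspot can carry several, so fractions can sum above 1). Category
enrichment of one type against the pooled rest uses the same Fisher exact
machinery as prevalence.

## Association with molecular features

Expression values are transformed as log2(RPKM) with zeros replaced by
the column's smallest nonzero value before the log. Copy-number calls use
strict thresholds: < −1 deletion, > 1 amplification. For a hotspot in
gene *g*, samples are grouped as hotspot-carrier, non-hotspot-carrier
(mutated in *g* elsewhere), or unmutated; samples with a copy-number
deletion of *g* are excluded from the comparison groups since loss of the
locus confounds expression readouts.

Groups are compared feature-by-feature with a two-sided Mann–Whitney U
test. The exact branch enumerates all C(n1+n2, n1) assignments, measuring
extremeness as |U − n1·n2/2| with ties contributing 0.5, and is used when
min(n1, n2) < 8 *and* the number of splits is ≤ 150,000; otherwise the
tie-corrected normal approximation from scipy is used. All-tied inputs
return p = 1. mRNA and copy-number features are matched to the hotspot's
gene symbol; protein-array and drug features go through an explicit
gene → feature map. Hotspots with fewer than 2 carriers among covered
samples are skipped. Raw p-values are reported without FDR: these scans
are exploratory follow-ups on an already FDR-controlled hotspot set, and
the caller can adjust across whatever family of features they scan. The
exact branch is validated against a midrank rank-split enumeration oracle
for every group-size pair with n1 + n2 ≤ 10, and its null type-I error at
α = 0.05 is measured on 1000 independent null features (reported by the
acceptance script).

## Evaluation

Gene-set overlap compares hotspot genes against a reference list over a
declared universe with the two-sided Fisher exact test; genes outside the
universe are dropped with a warning, and a reference equal to the
universe is degenerate (p = 1). The same test can be run from printed
summary counts (hits-in-set/set-size vs hits-in-rest/rest-size).
Conservation comparison applies the Mann–Whitney machinery to per-site
conservation scores of hotspot vs non-hotspot mutated sites. Relative
protein positions (aa / protein length) are histogrammed over 20
equal-width bins on [0, 1].

## Synthetic-data generator

`SimulationConfig` specifies tumor types, cohort sizes, genes with
protein lengths, background cohort-mean counts per (type, gene, subtype),
planted hotspots, and an optional hyper-mutated fraction/multiplier. One
`numpy.random.default_rng(seed)` instance drives everything, so output is
byte-identical for a given seed.

What it emulates:

- per-(type, gene, subtype) background totals drawn Poisson around the
  configured cohort means, assigned to samples proportionally to their
  weight (hyper-mutated samples get a configurable multiplier);
- uniform placement of background mutations over amino-acid positions,
  matching the detector's null;
- flanking bases drawn to be consistent with the declared subtype, with
  half the SNVs emitted as their reverse-complement strand
  representation, so the strand-symmetric classifier is exercised in both
  orientations;
- planted hotspots with a fixed number of distinct carrier samples at one
  amino-acid position; planted indels have genomic breakpoints jittered
  by up to ±2 bases while still mapping to the same codon, emulating the
  coordinate wobble of real indel calls.

What it does not emulate: real codon structure or the genome's
trinucleotide composition (flanks are generated, not read from a
reference), expression- or replication-timing-correlated regional rates,
selection on passengers, sequencing coverage variation, or caller
artifacts. It is a calibration instrument for the statistics, not a tumor
genome simulator.

Measured on this generator (see `tests/test_acceptance.py` and
`scripts/acceptance.py`): across 100 null cohorts (two tumor types,
~120–150 samples each, three genes) at least 95 produce zero hotspot
calls at q < 0.001; across 50 cohorts with three planted hotspots
(6–8 carriers each) at least 95 % of planted sites are recovered; the
association scan's empirical type-I error on 1000 null features lies in
[0.03, 0.07] at nominal 0.05.

## Numerical choices

- Poisson tails via `poisson.sf`, never 1 − cdf, to preserve precision in
  the deep tail; results clamped to `np.nextafter(0, 1)` to avoid exact
  zeros entering logs.
- Fisher combination via `chi2.sf` on x with 2k df.
- BH via `statsmodels.stats.multitest.multipletests(method="fdr_bh")`.
- Fisher exact 2×2 via `scipy.stats.fisher_exact`; Kruskal–Wallis via
  `scipy.stats.kruskal`; the asymptotic Mann–Whitney branch via
  `scipy.stats.mannwhitneyu` with tie correction.
- Exact-test thresholds (Mann–Whitney exact when min(n1, n2) < 8 and
  ≤ 150,000 splits) bound worst-case enumeration cost while keeping the
  small-sample regimes exact.

## Limitations

- The uniform-within-protein background ignores codon degeneracy, local
  trinucleotide availability, and coverage: a position with few mutable
  pathways to a given subtype is treated like any other. This makes the
  test conservative at some positions and anti-conservative at
  mutation-prone motifs.
- Backgrounds are estimated from the same cohort being tested; in very
  small cohorts a strong hotspot inflates its own gene's λ and shrinks
  its significance.
- The μ + 2σ filter is burden-scale dependent (see above) and assumes
  roughly unimodal per-type burden distributions.
- Association scans report raw p-values by design; users scanning many
  features should adjust across their own feature family.
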