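# Methods

`apomixkit` re-implements, as a tested pipeline over synthetic data with
known truth, the population-genomic analyses used to study apomixis
(nucellar embryony) in Citrinae: introgression statistics across species,
the sheltering of heterozygous deleterious load in clonally reproducing
hybrids, bulked-segregant mapping of the apomixis locus, forward simulation
of reproductive-mode transitions, and MITE promoter-insertion genotyping.
This note records the models, the defaults and why, and what the synthetic
experiments do and do not demonstrate.

## Data model and conventions

Internal coordinates are 0-based half-open; VCF positions are converted at
the I/O boundary only. All statistics operate on biallelic records
(multi-allelic sites are dropped by default, splittable by option).
Genotypes are dosages in {0, 1, 2, missing}; phased haplotypes are carried
when available (the generator always emits them). Missing genotypes are
excluded from every frequency denominator; no imputation is performed.

**Polarization.** The ancestral allele is the outgroup major allele. Sites
whose outgroup minor-allele frequency exceeds `max_og_minor` (default 0.1),
or with no called outgroup genotype, are marked `unknown` and excluded from
polarized statistics. The choice is a declared default: polarization rules
in comparable studies are rarely printed, and the statistics below are
insensitive to the exact cutoff as long as polymorphic-outgroup sites are
removed. Per-population frequencies additionally require `min_n = 2` called
alleles.

**Block jackknife.** Genome-wide ratio statistics get standard errors from a
weighted delete-one-block jackknife (Busing's formulation) over 20
contiguous equal-span blocks per genome, weighted by per-block informative
sites; with equal weights it reduces exactly to the classic delete-1
jackknife, which the tests exploit as an oracle. Z = estimate/SE with a
two-sided normal p. Identical leave-one-out estimates give SE = 0 and a
degenerate-variance flag (p = 0 for a nonzero estimate, p = 1 otherwise).

**FDR.** Benjamini–Hochberg step-up q-values (statsmodels), with NaN
p-values propagated rather than dropped silently.

## Introgression statistics

All site-pattern statistics are frequency-based (population-level), not
single-genotype based, since the analyses contrast groups of accessions.
With derived frequencies p1, p2, p3, pO:

- **Patterson's D**: abba = (1−p1)·p2·p3·(1−pO), baba = p1·(1−p2)·p3·(1−pO);
  D = Σ(abba−baba)/Σ(abba+baba), jackknifed. Windows with fewer than 10
  informative sites are NaN, never 0.
- **f_d** (dynamic-donor estimator): the denominator substitutes
  max(p2, p3) for both donor slots site by site. Windows with D < 0 are NaN
  — the estimator is undefined there — and only the window statistic is
  reported, matching its published domain. A genome-wide number, when
  quoted, is the mean over defined windows.
- **f4 / f4-ratio**: f4(A,B;C,D) = mean (pA−pB)(pC−pD); the admixture
  proportion is α = f4(A,O;X,C)/f4(A,O;B,C). Population roles are explicit
  configuration, never inferred. Note that α is only informative when A and
  B share drift exclusive of C and O — on a star phylogeny the denominator
  has expectation zero, which is why the synthetic f4-ratio experiments use
  a hierarchical lineage structure.
- **f-branch**: for each branch b of a rooted bifurcating population tree,
  f_b(C) = median over A in b's sister clade of [min over B below b of
  f̂(A,B;C,O)], with f̂ = Σ(pB−pA)(pC−pO)/Σ(pC−pA)(pC−pO). Significance
  jackknifes the entire median-of-minima per block; BH correction runs over
  all testable (branch, donor) cells, and only positive f_b is flagged.
- **D_xy**: per site p_x(1−p_y)+p_y(1−p_x), summed per window and divided by
  accessible sites when provided, else by window bp (declared in the output
  metadata).
- **Ancestry profiling**: diagnostic markers are sites with
  |p_donor − p_background| ≥ `min_delta` (default 1.0, i.e. panel-fixed
  differences); a sample's donor proportion is its summed donor-allele
  dosage over 2× genotyped markers, and fragments are maximal runs of
  windows with donor fraction ≥ 0.5 (a heterozygous tract in a diploid).

## Deleterious load

Deleterious SNPs are defined by SIFT ≤ 0.05 (inclusive); LOF variants carry
an annotation flag; SVs of classes DEL/DUP/TRA/INV are counted as
deleterious wholesale (restrictable to genic overlap). Additive burden
counts alleles (het + 2·hom) — the published per-individual axis is
ambiguous between allele and variant counts, so a variant-count mode exists
behind a flag. Recessive burden is the homozygous-genotype count. A gene is
hemizygous when merged heterozygous deletions remove strictly more than 50%
of its length; merging first makes g_h invariant to how deletion calls are
fragmented. Burden–ancestry association uses Spearman's rank correlation
(average ranks, two-sided t-approximation p). Group contrasts are ratios of
means (or medians) with a seeded 1000-replicate percentile bootstrap.

## Hypothetical crosses

The primary pair metric is the expected fraction of deleterious loci at
which a Mendelian F1 of parents i, j is homozygous derived:
r = mean over loci of (d_i/2)(d_j/2). It is deterministic (no gamete RNG); a
Monte-Carlo gamete sampler is retained and agrees within 0.005 at 10k draws.
Because the published "ratio of overlapping deleterious mutations" formula
is not printed, a second defensible reading — the Jaccard overlap of carrier
sets — is implemented and labelled; neither is claimed to be the original.
Cohorts down-sample each group to a common size (seeded, without
replacement) before enumerating all pairs; the summary is
100·(mean_within − mean_between)/mean_within.

## BSA QTL scan

Per marker: SNP-index = alt/(ref+alt) per bulk (masked below depth 10);
ΔSNP-index = high − low; G = 2 Σ n·ln(n/ê) over the 2×2 bulk×allele table
(0·ln 0 ≡ 0); G′ = tricube-weighted mean of G over ±1 Mb (weights
(1−(d/W)³)³, renormalised; an isolated marker keeps its own G). P-values
come from a log-normal null fitted robustly to the bulk of the G′
distribution — median/MAD by default (σ = 1.4826·MAD), a Hampel-trimmed
variant behind a flag — then BH. Significant regions are maximal runs of
q < 0.01 markers with ≥ 3 markers, merged across gaps < 500 kb. The
segregation test is the uncorrected 1-df Pearson chi-squared: with Yates
correction the printed reference value (p = 0.2693 for 290:264) is not
reproduced, which fixes the convention.

## Forward simulation

Diploid individual-based Wright–Fisher with L biallelic deleterious-capable
loci. Fitness is multiplicative, w = Π(1−h·s)^het·(1−s)^hom, with dominance
h selecting recessive (0) vs additive (0.5) regimes. Parents are sampled
with probability ∝ fitness; sexual offspring unite two recombinant gametes
(adjacent-locus recombination fraction r, default 0.5 = free recombination);
clonal offspring copy the mother's genotype; facultative apomixis produces a
fraction σ of offspring sexually (default 0.05, anchored to the observation
that ~5% residual sexuality suffices to halt Muller's ratchet). Mutations
arrive at U per diploid genome per generation (default 0.2) at uniform loci;
selection coefficients are drawn per locus at initialisation (fixed s or
gamma DFE); loci fixed in a population fold their fitness cost into a
constant and are recycled, approximating infinite sites at fixed memory.

The canonical schedule: sexual burn-in (default 10·N generations,
overridable) → split into pO (sexual) and pI (apomictic) → a single
introgression pulse pO→pI of fraction 0.10 → pI splits into pS, which
switches to sexual reproduction at the split, and pA, which stays apomictic.
The transition summary reports the percent fitness decline from the
pre-switch value to the post-switch minimum, and the recovery generation.

**Problem sizes.** The shipped experiments use N = 250, L = 1200, 1000-gen
burn-in for the transition contrast; N = 2000, L = 300, 4000 generations for
mutation–selection balance; N = 100 for drift and ratchet checks. These are
the package's chosen desk-scale conditions: they reproduce the qualitative
contrasts (a large recessive-model dip in pS, absent in pA and in the
additive model; √(u/s) equilibrium within ~25%; 1−1/(2N) heterozygosity
decay) but the *magnitude* of the dip depends on N, U and the DFE, which are
not printed for the original simulations — the reference 13.48% decline is
therefore treated as qualitative, not as a target.

Known bias at small N: mean recessive-allele frequency at mutation–selection
balance falls below the deterministic √(u/s) when 2N·s·q*² is of order one
(drift dominates selection on rare recessives); the calibration check runs
at N = 2000 where the deficit is ~25% and documented rather than hidden.

## Synthetic data

The generator emulates the structure of a few-hundred-accession citrus
resequencing resource at desk scale. Ancestral frequencies are symmetric
Beta(0.8, 0.8); population frequencies follow the Balding–Nichols Beta at a
per-population F_ST (flat K-population layout, or an explicit lineage tree
for hierarchical drift); genotypes are Binomial(2, p) with phased
haplotypes. The outgroup is a population at F = 0.99, near-fixed at most
sites, rather than a separate species model. Species-diagnostic markers are
emulated by lineage-specific substitutions (`private_fixed`): sites driven
to fixation for the derived allele in one population, placed at the
lowest-ancestral-frequency sites — independent drift alone produces too few
genuinely fixed differences for marker-based ancestry profiling, exactly as
in real sister taxa versus diverged species. Introgression tracts have
geometric lengths (mean 1 Mb) and are planted haplotype by haplotype until
the target fraction m of the genome is covered exactly (the last tract is
clipped), with the truth BED recording every interval. Deleterious
annotations assign SIFT uniform in [0, 0.05] to a configured fraction of
SNPs (default 2.5%, the approximate genome-wide rate in the motivating
data) and uniform in (0.05, 1] elsewhere, with a LOF sub-fraction of 25%.

The BSA generator is a pseudo-testcross: the apomictic parent is
heterozygous at the QTL and all markers (alt in coupling), the sexual parent
homozygous, so markers segregate 1:1; gametes recombine along the marker map
(Haldane, default 5 cM/Mb over five 12-Mb chromosomes, ~60 cM each, QTL
mid-chromosome-1); bulks of 30 extreme-phenotype progeny are sequenced at
depth 60 with Binomial(depth, bulk frequency) alt counts. Insertion
evidence is Binomial(depth, θ) with θ = error, 0.5, 1−error for
absent/het/hom. Gene models are non-overlapping; per-sample heterozygous
deletions cover 80% of a configured fraction of genes, plus background
deletions kept below the 50% rule, so truth g_h is exact.

What passing these experiments shows: the estimators recover planted truth
under drift, binomial sampling and read noise at realistic desk scale. What
they do not show: robustness to mapping/calling artefacts, reference bias,
linkage disequilibrium from real demography (Balding–Nichols sites are
exchangeable), overlapping gene models, or mis-specified outgroups — real
data properties the generator deliberately does not model.

## MITE genotyping and decomposition

Zygosity is called from count summaries (insertion-supporting vs
reference-spanning reads), not BAMs, with explicit bands: absent ≤ 0.05,
het in [0.2, 0.8], hom ≥ 0.95, depth ≥ 10, gaps → no_call. The bands are
deliberately conservative: at depth 30 with 1% error they leave ~3–4% of
true hom/absent loci uncalled at the band edges while keeping made calls
>99% accurate — accuracy is reported over made calls, with the no-call rate
bounded separately.

Insertion haplotypes are decomposed by period detection, not alignment to a
MITE consensus (no consensus sequence is available): first a tandem search
over strides p dividing (length − 5) evenly, accepting self-match identity
≥ 0.8; then a two-unit split whose prefix and suffix units are homologous by
edit-distance identity ≥ 0.8 (edlib); otherwise a single `other` unit.
Consecutive units share a 5-bp target-site duplication, the only model
consistent with the reference lengths (3·202 − 2·5 = 596; 202 + 227 − 5 =
424), and every decomposition satisfies Σ units − (n−1)·5 = insertion length
exactly. TSD agreement in sequence is positional by construction; an exact
sequence check is optional since TSD identity between junctions is not
established for the reference haplotypes. Classification allows ±5 bp on
unit lengths.

## Numerical choices and degenerate inputs

Zero ABBA+BABA denominators flag the statistic undefined rather than
returning 0; empty windows and windows below the informative-site minimum
are NaN; constant G′ distributions refuse the null fit; zero-depth markers
are masked; empty populations and unbound roles raise configuration errors;
all stochastic functions require an explicit seed and identical seeds give
byte-identical output files.

## Limitations

Variant calling, phasing, annotation (SIFT computation), tree inference and
demographic inference are out of scope — trees, scores and population
assignments are inputs. The f4-ratio role assignment is explicit
configuration; Dsuite-style automatic P3 splitting is not replicated. The
forward simulator has no epistasis, no spatial structure and no
tree-sequence recording. Published magnitudes that depend on the full
234-accession data (SV counts, burden ratios, the 13.48% dip) are
reproduced directionally on synthetic conditions, not numerically.
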