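# Methods

## The question and the statistic

Given many genomes of one bacterial species sampled across geographic
regions, the package quantifies *geographic clustering* as the PERMANOVA R²
of the region factor on a tree-derived distance matrix: the fraction of
variation in pairwise patristic distances explained by region of origin.
Contrasting that clustering between functional gene groups separates two
explanations for it — dispersal limitation should affect all genes alike,
while local selection should act most strongly on environment-facing
(membrane) genes and least on conserved intracellular machinery (organelle
genes, mostly ribosomal).

## Tip filters

Before any test, a tree's tips are filtered: (1) among tips sharing a city,
only the highest-scoring one is kept (the score is an externally supplied
dedup/quality score; ties break on the lexicographically smallest tip id,
so the result is deterministic); (2) any tip left as the sole representative
of its region is removed (a single genome cannot inform within-region
variance); (3) the tree is testable only if at least two regions remain —
each then necessarily holding ≥ 2 tips. Untestable trees are carried
through with `status="untestable"`, never silently dropped. The filter is
idempotent.

## PERMANOVA

The implementation uses the Gower-centered trace formulation. With squared
distances, `A = −½ D∘D`, `G = JAJ` (`J = I − 11ᵀ/n`), `SS_total = tr(G)`.
For the one-factor design with one-hot group indicators, the hat matrix `H`
satisfies `tr(HGH) = tr(HG) = Σ_g (1_gᵀ G 1_g)/n_g = SS_model`, and
`SS_resid = SS_total − SS_model`. `R² = SS_model/SS_total`,
`F = [SS_model/(k−1)]/[SS_resid/(n−k)]`. The permutation null permutes group
labels without strata (the design is a single factor); the p-value is
`(1 + #{F* ≥ F})/(1 + n_perm)`, never exactly zero. Defaults: 999
permutations (the convention of the R implementations of this test), seed
mandatory in the API.

Numerical notes: when `SS_resid` is ≤ 0 up to rounding (perfect
separation), F is reported as +∞, which orders correctly in the permutation
comparison. When `SS_total ≈ 0` (all points identical) the result is
untestable with NaN statistics. On Euclidean-embeddable matrices `G` is
positive semidefinite and R² ∈ [0, 1]; on matrices with violated triangle
inequalities `G` is indefinite and R² < 0 is reachable — short, low-variance
genes produce such matrices in practice, and a constructed fixture
exercises the regime. R² is always the raw ratio, never an adjusted
version.

Multiple testing: species-tree p-values are Benjamini-Hochberg adjusted
across the species tested in one run. Gene-tree p-values are not adjusted,
because downstream group comparisons consume the R² values, not the
p-values.

## Group stratification and contrasts

Top-level cellular-component labels map to three groups: membrane;
organelle; everything else — including unannotated genes — pooled as
"metabolic" (in annotation sweeps of such data most unannotated genes'
biological-process terms are metabolic). A gene labeled both membrane and
organelle counts as membrane, since surface exposure is what the selection
hypothesis is about; conflicts are logged.

Contrasts use Kruskal-Wallis (tie-corrected, χ² approximation on k−1 df)
followed — only when the BH-adjusted omnibus p is below α = 0.05 — by
pairwise two-sided Wilcoxon rank-sum tests, exact when both groups have
n ≤ 25 and no ties, otherwise normal approximation with tie and continuity
correction. The reported statistic is the Mann-Whitney U of the first-named
group. Pairwise p-values are BH-adjusted within the run's family of
pairwise tests, separately from the omnibus family. Non-finite values
(undefined dN/dS ratios, untestable R²) are excluded with counts logged.

Covariate diagnostics compute the Pearson correlation of per-gene R² with
tip count, mean π (mean pairwise fraction of differing sites, pairwise
deletion), alignment length, and regional entropy `−Σ pᵢ ln pᵢ` (natural
log, zero-count regions contribute nothing). Zero-variance covariates are
flagged undefined rather than raising. A species with any BH-significant
covariate correlation is flagged for the analyst — never auto-dropped.

## dN/dS

One ratio per gene by Nei-Gojobori (1986) counting with Jukes-Cantor
correction, under NCBI translation table 11 (the organisms are bacteria).
Inclusion rules: the gene must show genuine nucleotide variation (a column
with two distinct non-gap, non-N bases; gap-versus-base differences do not
count), and the consensus first codon must be a bacterial start (ATG, TTG,
GTG); trailing consensus stop codons are trimmed and the length truncated
to a codon multiple. Site counting enumerates the three single-base changes
per codon position, excluding changes to stop codons from the denominator,
so S + N = 3 × codons exactly. Pairwise differences average over all
orderings of the changed positions with equal weight; orderings that pass
through a stop are dropped, and a codon pair whose every pathway is
stop-blocked is skipped for that pair. Codons containing a gap or N in
either sequence of a pair are skipped for that pair (pairwise deletion
preserves pairs in patchy alignments). S and N are averaged over sequences;
Sd and Nd over pairs. Saturation (p ≥ 3/4) or dS = 0 yields an undefined
ratio, reported with a reason and excluded from contrasts.

This counting method is a deliberate, documented substitution for
maximum-likelihood codon models: it is dependency-free, exact at desk
scale, and rank-based group contrasts need only the ordering of ratios.
A cross-check against an independent implementation of the same counting
scheme agrees up to its different stop-site convention (it counts
mutations-to-stop as nonsynonymous sites rather than excluding them).

## Abundance

Expected coverage of a genome of length g by r mapped reads of mean length
l is `c = 1 − (1 − l/g)^r` (each read independently covers a fraction l/g).
Cells whose *observed* covered fraction (an input, since it requires
per-base depths) falls below 0.5 of the expected value are zeroed; the
ratio direction is exposed as a flag because either convention appears in
practice. Rarefaction is one seeded multivariate-hypergeometric draw per
sample to a common depth (samples below the depth are dropped with a
warning); the depth is always a parameter. TPM divides counts by genome
length in kb and scales each sample to 10⁶; Shannon diversity is `−Σ qᵢ ln
qᵢ` of the normalized row and is scale-invariant. Compositions are compared
with the asymptotic two-sample Kolmogorov-Smirnov test.

## Synthetic data

The generator emulates the data regime of a multi-region MAG study with
interpretable knobs and full ground truth.

**Genealogy.** One island-model structured coalescent per dataset (the
shared species history): within-region pairwise coalescence at rate 1 per
pair in coalescent units (region size scaled by `effective_size`, default
1.0 — the canonical unit-scaled coalescent), per-lineage migration at total
rate m, destination uniform among the other regions. Simulation is
delegated to msprime (haploid samples, population size = `effective_size`),
whose time scale was verified against the Kingman closed form
E[T_MRCA] = 1 for two lineages and the panmixia limit (between/within
distance ratio → 1 as m → ∞). m = 0 with several regions is rejected before
starting, since the process would never terminate. Cities are assigned
round-robin within regions; with the default 7 cities per 8 samples one
city per region holds two tips, so the dedup filter always has work;
dedup scores are uniform on (0.5, 1).

**Sequences.** The root is a random stop-free codon sequence with an ATG
start. Evolution is Jukes-Cantor: per branch, Poisson(μ · branch length ·
sites) substitutions, uniform site, uniform alternative base; substitutions
that would create an in-frame stop are resampled, and the start codon is
held invariant (start loss is lethal in a real gene, and the framing rules
key on it).

**Selection.** Regional selection is modeled as character-state
convergence, not fitness-based forward simulation: it creates exactly the
region-correlated variation the clustering statistic measures. In selected
genes a fraction f of eligible sites is constrained; eligible sites are
first/second codon positions (changes there are almost always amino-acid
changing, so selected genes also gain dN/dS — local adaptation is
protein-level) at which every base keeps the root codon stop-free. Each
region receives a preferred base per constrained site, *distinct across
regions* (sampled without replacement over the four bases when regions ≤ 4):
regions sharing a preferred state would experience no differential
selection, diluting the signal the generator exists to create. Each tip's
state at a constrained site is overwritten with probability s by its
region's preferred base, skipped in the rare case the overwrite would
create a stop in the tip's mutated context.

**Gene trees** are rebuilt by neighbor joining from each gene's
Jukes-Cantor-corrected p-distances (saturated pairs capped at 5.0
substitutions/site), so tree-estimation noise is part of every recovery
test. Selected genes are labeled membrane (half) and metabolic (half,
alternating an explicit non-selected term with no annotation so both
ingestion paths are exercised); neutral genes are labeled organelle. The
truth record (selected ids, preferred states, parameters) is emitted with
the bundle, and truth/annotation consistency is asserted on every bundle.

**Defaults** (the standard recovery regime): 3 regions × 8 samples,
30 selected + 30 neutral genes of 300 codons, μ = 0.05 per site per
coalescent unit, m = 0.1, f = 0.1, s = 0.8, seed mandatory; byte-identical
outputs for equal seeds.

**What the generator does not emulate:** recombination and HGT, indels,
rate heterogeneity across sites, realistic demography, read-level noise,
annotation error. Passing recovery tests therefore show that the statistics
detect region-correlated convergence against coalescent and
tree-estimation noise — not that they are robust to, e.g., recombination.

### A known ceiling of the recovery regime

At the default μ and m, roughly a third of simulated species histories have
inter-region depths above ~15 coalescent units, i.e. > 1.5 expected
substitutions/site between regions. There, pairwise p-distances sit on the
0.75 saturation plateau, Jukes-Cantor distances hit the cap, and neutral
gene-tree R² rests at ≥ 0.97. In that regime the partial overwrite
(s = 0.8) mostly injects within-region heterogeneity — pairs with exactly
one overwritten tip differ at about three quarters of constrained sites —
so the selected-vs-neutral R² direction becomes uninformative. Measured
over seeds 1–60, the direction recovers in 85% of datasets, and in every
dataset whose neutral R² is below 0.97. The group-contrast pipeline
(Kruskal-Wallis + pairwise Wilcoxon) flags organelle < membrane in the
non-saturated seeds and stays quiet (≥ 18/20 seeds) when s = 0.

## Problem sizes used by the test suite

Unit tests run on scaled-down datasets (3 regions × 4 samples, 8 genes of
60 codons). The end-to-end checks use the full default regime: a 20-seed
recovery panel with 49 permutations per gene tree (R² does not depend on
the permutation count), 200 label shuffles at 199 permutations for the
calibration, and 2000 replicate genealogies for the coalescent closed
forms. The whole suite completes in a few minutes on one CPU.
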