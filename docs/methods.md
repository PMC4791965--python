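# Methods

This note documents the models implemented in `awmnet`, the choices made
where the design was genuinely open, and what the synthetic data do and
do not establish about real populations.

## Synthetic half-sib populations (`simpop`)

**Design.** A population is a set of sires, each with a half-sib family
out of ungenotyped dams; dams can recur across families with probability
`shared_dam_prob`. Contemporary groups are origin × birth-year labels
drawn per sib; their effects are fixed shifts drawn once per group. The
default sire panel is a 34-family commercial Nelore reference design
(780 animals, 17 paternal lineages, mtDNA origin known for 30 sires);
an arbitrary design is a one-line spec change.

**Founder haplotypes.** Each chromosome's founder pool of
`founder_pool_size` haplotypes comes from a first-order Markov chain: a
latent Gaussian AR(1) process with per-gap autocorrelation
exp(−λ·gap) is thresholded at Φ⁻¹(p_j), where p_j is the SNP's drawn
allele frequency (uniform over `maf_range`, minor allele randomized).
Thresholding keeps the realized MAF spectrum exactly as drawn — a plain
allele-copying chain would smear all frequencies toward the range mean —
while the single hazard λ (per bp) controls LD decay. Sires carry two
pool haplotypes (or one duplicated haplotype per chromosome with
probability `sire_autozygosity`, which plants sire inbreeding); dams are
fresh pool draws; each sib receives one recombined sire gamete and one
recombined dam gamete (Haldane crossovers at 1 cM/Mb), so sib–sire
Mendelian consistency holds by construction.

**Documented LD ground truth.** The expected two-locus r² of the pool at
distance d is computed by numerical quadrature of the thresholded-
bivariate-normal correlation over the MAF distribution (averaging over
minor-allele flips); this is generator theory, independent of any sample
estimator. From it, `ne_equivalent(λ, bin)` gives the pool's Sved
N_e-equivalent over a distance bin, and `decay_rate_for_ne` /
`decay_rate_for_target_r2` invert the map. A single exponential hazard
cannot reproduce a full Sved curve across all genomic scales
simultaneously, so calibrations are made *at the scale of the analysis
that consumes them* (e.g. one scenario calibrated to mean r² = 0.30 over
10–25 kb for the LD profile, another to N_e-equivalent 214 over its Ne
estimation bin); this is stated wherever both are reported.

**Phenotypes.** y = mean + CG + Σ(QTL dosage × effect) + polygenic +
residual. The polygenic term is a gene-drop on the pedigree (founders
N(0, σ²), offspring = parental mean + Mendelian sampling N(0, σ²/2));
`polygenic_fraction` (default 0.5) splits genetic variance between QTL
and polygene. Components are scaled empirically so the realized
narrow-sense h² (genetic variance over CG-free phenotypic variance)
equals `target_h2`. QTL sharing with the first (key) trait is honored
exactly per the sharing matrix's first column; other pairwise overlaps
emerge. Default trait panel: eight growth/meat-quality traits at their
reference heritabilities, means and SDs (e.g. carcass weight h² 0.26,
rib-eye area 0.55, back-fat 0.15).

**What the generator does not emulate:** genotyping error, ascertainment
bias of commercial arrays, selection, multi-generation pedigrees,
dam-side population structure, X/mtDNA inheritance, and a realistic
(non-exponential) LD curve. Passing tests therefore establish estimator
correctness and calibration under a clean half-sib model, not robustness
to those real-data features.

## Quality control and tagging (`qc`)

Filters: sample call rate, SNP call rate, then MAF (defaults 0.95 / 0.95
/ 0.05), repeated to a fixed point because removing SNPs can re-expose a
sample below threshold — this makes `apply_qc` idempotent. Monomorphic
SNPs are reported separately. The tagger is a deterministic greedy
windowed cover: repeatedly promote the SNP covering the most untagged
neighbors at r² ≥ threshold (default 0.8, window 50 SNPs), ties broken
by genomic order. r² uses pairwise-complete genotype correlations; no
imputation.

## Structure profiling (`popstruct`)

* **GRM**: VanRaden method 1, G = ZZ′/(2Σp(1−p)) with observed
  frequencies and mean imputation; chosen for its closed form and the
  F_GRM = G_ii − 1 identity.
* **ROH**: maximal runs with ≤ `max_het` heterozygotes (default 0), gaps
  ≤ 1 Mb, ≥ 30 SNPs; missing calls neither break nor are excluded from a
  run. F_ROH divides merged run length by the map's first-to-last bp
  span per chromosome — the denominator a SNP map can actually cover.
* **PCA**: eigendecomposition of the double-centered GRM; variance
  shares relative to the positive spectrum; signs fixed so the
  largest-|loading| entry is positive.
* **Clustering**: average linkage on d = max(G) − G (darker = less
  related in a heatmap); the transform is monotone so the dendrogram
  topology is what matters.
* **Fst**: Weir–Cockerham variance components per SNP, ratio of sums
  genome-wide; subpopulations under two genotyped animals are excluded.
  On literally duplicated groups the estimator is deterministically
  slightly negative (≈ −1/(2n)); that is a property of the estimator,
  not a bug.
* **Inbreeding depression**: OLS of adjusted phenotype on F, reported
  per 1 % increase in F.

## LD, blocks, and N_e (`ldblocks`)

Phase is resolved per SNP pair by a two-locus EM over the
double-heterozygote ambiguity (tolerance 1e-8, ≤ 1000 iterations;
non-convergence flagged). Both parental haplotypes of every animal enter
the counts. D′ confidence intervals (5th/95th bootstrap percentiles of
|D′|) come from a seeded multinomial resample of the 3×3 genotype table
— simpler and directly testable compared with the original likelihood
CI; Gabriel thresholds (0.70/0.98 strong LD, 0.90 strong recombination,
95 % informative-pair rule) are exposed as parameters. Blocks are
accepted greedily, longest span first, non-overlapping, with the
outermost pair required to be strong LD. N_e follows Sved with 1 cM ~
1 Mb; the r² − 1/n sample-size correction is off by default (a flag is
available); per-bin estimates aggregate across chromosomes with a
t-interval. Bin choice fixes the implied "generations ago" (1/(2c)) and
is reported alongside.

## Mixed-model association (`assoc`)

Contemporary-group effects are removed by subtracting group means before
any fit. Variance components come from REML maximized over
log(σ²_g/σ²_e) after one eigendecomposition of the pedigree NRM
(tabular method; implied parents added as founders); h² SE is
information-based (numerical curvature, delta method). Per-SNP tests are
GLS with V̂ fixed at the null fit — the two-stage approximation that
replaces per-SNP likelihood-ratio machinery at a fraction of the cost;
equivalence with exact per-SNP ML LRT is asserted within
|Δ(−log₁₀ p)| < 0.2 on n = 200 fixtures, and null simulations are
checked for p-value uniformity and λ_GC ∈ [0.9, 1.1]. Any PSD matrix can
stand in for the NRM (passing a GRM switches the relationship structure;
the pedigree NRM is the default). The FDR at a p-value cutoff is
P(1 − A/T)/((A/T)(1 − P)). A half-sib design identifies σ²_g only
through between-family resemblance (0.25 σ²_g), so single-realization
h² estimates carry SE ≈ 0.13 at 800 animals; recovery tests and the
acceptance report therefore average phenotype replicates.

## AWM (`awm`)

A SNP enters the AWM if its key-trait p ≤ α (default 0.05) or it reaches
p ≤ α in ≥ 3 other traits; one SNP per gene is kept (smallest key-trait
p, ties by id). Cells are effect/SE by default — "standardized effect"
is ambiguous between SE and trait-SD scaling, and effect/SE is the form
the pleiotropy statistic uses; a `standardize="trait_sd"` flag gives the
other reading. Genes are assigned to SNPs by nearest position on the
same chromosome, ties to the lower coordinate. Gene–gene Pearson
correlations across the trait columns feed PCIT.

## PCIT (`pcit`)

For each trio, first-order partials are compared with the direct
correlations through the mean ratio tolerance ε; an edge is discarded if
some third gene explains it (|r_xy| ≤ |ε·r_xz| and |r_xy| ≤ |ε·r_yz|).
Ratios are taken as absolute values by default (`signed_ratios` flips
this); ratios with |direct| < 1e-12 contribute zero; partials with
non-positive denominators are treated as zero. The O(n³) scan is a
numba-compiled triple loop (n = 1000 in seconds on one CPU) and is
checked for exact equality against a naive Python oracle. The |r| ≥ 0.95
magnitude filter runs *before* PCIT by default (entries below threshold
zeroed), matching a filter-then-infer reading; a post-filter mode is
available, and the mode is recorded in the run config since it changes
edge counts.

## Networks (`netview`) and pleiotropy (`pleio`)

The TF trio maximizes joint first-degree coverage |N(a)∪N(b)∪N(c)\trio|,
with ties broken by minimum pairwise neighbor overlap, then
lexicographic ids — a reconstruction of "span with minimum redundancy"
as a lexicographic objective, with both terms reported so alternatives
can be audited. Selection is exhaustive up to 10⁶ TF triples, greedy
beyond (submodular ≈ 70 % guarantee). The sub-network is the induced
subgraph on trio + neighbors, carrying original degrees as node
attributes. Exports are SIF plus a node-attribute TSV, byte-stable.

Pleiotropy: t = effect/SE per SNP and trait; V is the trait correlation
of t across all SNPs (a flag restricts to |t| < 2 "null" SNPs to reduce
signal contamination; default uses all, as nothing in the statistic's
definition restricts it); the statistic t′V⁻¹t is referred to
χ²(#traits). V is projected to the nearest PSD correlation matrix if
sampling noise requires, and a singular V is ridge-regularized (1e-8)
with a warning. SNPs with missing t (monomorphic) contribute zero terms,
are flagged, and rank after complete SNPs.

## Orchestration (`cli_io`)

Text PLINK PED/MAP only (alleles A/B, "0" missing, 1-based inclusive
coordinates); binary BED is out of scope at desk scale. Every written
table carries a provenance header (version, config digest, seed); the
config digest excludes the output directory so identical computations
hash identically. Stages run in a fixed order with dependency checks; a
failure raises a `StageError` naming the stage, and completed stages are
checkpointed and skipped on resume.

## Problem sizes

Default test and acceptance runs use 780–800 animals, 1.6–5 k SNPs over
2–4 chromosomes of 8–12 Mb, and 8 traits — sizes at which every
estimator's behavior (calibration, recovery, oracle equality) is already
measurable and the full pipeline completes in seconds. Statistics that
are scale-dependent (network node/edge counts, absolute p-value counts)
are reported as computed at these sizes and are not comparable to
770k-SNP studies; scale-free quantities (Fst, h², r̄², N_e, FDR
arithmetic, inbreeding coefficients) are.

## Known limitations

* The Gabriel block scan bootstraps every in-window pair; genome-scale
  runs should cap `max_span_snps` and lower `n_boot` (the pipeline stage
  is optional for this reason).
* Multi-trait REML (genetic correlations) is not implemented; trait
  correlations are phenotypic, and genetic correlations enter only
  through the generator's QTL sharing.
* The greedy tagger approximates a minimum cover; it is exact on the
  clean fixtures tested but carries no general optimality guarantee.
* GO enrichment is delegated: the ranked gene list is exported in the
  one-gene-per-line format external tools consume.
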