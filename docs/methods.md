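# Methods

This note documents the generative model behind the synthetic cross, the
statistical machinery of each pipeline stage, the numerical choices, and
what the tests do and do not establish about real data.

## The synthetic backcross

The simulator emulates a three-generation resource population derived from
two divergent breeds: A-founders (Iberian-like boars, default 3) and
B-founders (Landrace-like sows, default 79) produce F1s; five F1 males
backcrossed to B sows give the BC1 layer (159 by default, expected 25%
A-genome); F2 boars × B sows give a second backcross (79); F2 × F2 matings
give an F3 (54). Only BC1/BC/F3 animals are phenotyped (292 by default),
while all animals are genotyped — so the relationship matrix and Mendelian
checks span founders and descendants.

**Genome.** `n_chromosomes` × `snps_per_chromosome` biallelic SNPs
(default 10 × 200 on 100-Mb chromosomes). Founder haplotypes are Bernoulli
draws from breed-specific frequencies `p ± divergence/2` (divergence 0.5 by
default), so the cross carries both linkage LD and admixture LD. Meioses
follow the Haldane model (Poisson crossovers at 1 cM/Mb, no interference) —
sufficient to make pairwise r² decay with distance, which is all the
downstream analysis consumes.

**Annotation.** Each chromosome is laid out to exercise every branch of the
AWM assignment rule regardless of seed: a gene-bearing region (first 92%)
where ~60% of SNPs lie inside a gene, a 1-Mb band whose SNPs are 2.5 kb–1 Mb
from the nearest gene and within 10 kb of a placed miRNA, and a terminal
desert whose SNPs are > 1 Mb from any gene. Genes overlapping QTLs are
flagged as regulators (the planted truth); a further 10% of genes, a
22-gene GO-style list and all miRNAs complete the regulator catalogue.

**Phenotypes.** Twelve traits in two antagonistic blocks —
growth/conformation (BW125, BW155, BW180, CW, CL, HW, SW, BLW) and fatness
(BFT155, BFT180, BFTS, IMF). Each block owns `n_qtl_per_block` QTLs
(default 8) placed at gene-overlapping SNPs; a QTL affects every trait in
its block and, with probability 0.5, the opposite block with flipped sign —
the antagonism that makes the trait dendrogram split in two. The polygenic
term is simulated by mating-path accumulation (offspring breeding value =
parent average + Mendelian deviate with variance ½σ²ᵤ(1 − (F_s+F_d)/2),
inbreeding coefficients from the tabular A), which is exact under the
pedigree model without any large-matrix factorization. Genetic values are
rescaled so the realized heritability equals the configured value (0.35 per
trait by default) against the reference trait SDs (e.g. BW180 100.10 ±
14.91 kg, HW 21.62 ± 3.39 kg), and the recorded "true" QTL effects are the
rescaled ones, so recovery tests compare against what was actually planted.
Sex (±0.15 SD), nine slaughter batches (round-robin within the phenotyped
cohort, offsets ~N(0, 0.15 SD)) and an age trend (0.3 SD per age-SD around
180 ± 2.8 d) complete the fixed-effect structure the association model must
absorb. Genotype calls are masked missing at rate 0.02.

**What the simulator does not emulate:** real porcine SNP60 coordinates and
LD structure, selection/assortative mating, genotype-by-environment
effects, dominance/imprinting, and realistic minor-allele-frequency spectra.
Passing tests therefore demonstrate that the pipeline's *algorithms* are
correct and calibrated under the stated model, not that the biological
conclusions of any particular study are reproduced.

## Quality control

Animals with > 5% missing calls are removed first, then SNPs with
MAF < 5% computed on the remaining cohort (the order is a documented
choice; the reverse is a one-line change). Unmapped SNPs are dropped.
Mendelian checks flag offspring calls impossible under biallelic
inheritance given both genotyped parents (hom×hom cases and
opposite-homozygote forced heterozygotes); flagged calls are reported, not
altered, unless `zero_mendelian_calls` is set.

## Association scan

Variance components are estimated once per trait by REML on the null model
(EMMA-style: eigendecompose A, profile the restricted likelihood over
δ = σ²ᵤ/σ²ₑ with a 41-point log-grid scan plus bounded refinement in the
best bracket), then fixed for every SNP — the standard two-stage
approximation; `refit_each_snp=True` does the exact per-SNP refit for small
panels. Each SNP is tested by GLS after whitening with V^(−1/2): the −1/0/+1
indicator is mean-imputed per SNP, residualized against the fixed effects,
and the Wald statistic uses the exact GLS standard error (normal reference;
with ~290 records the t correction is negligible — type-I error on null
simulations sits inside [0.03, 0.07]). Monomorphic SNPs are flagged and
reported with p = 1. A matrix proportional to the identity raises an
explicit non-identifiability error rather than returning a boundary
estimate. Benjamini–Hochberg q-values are attached for reporting; the AWM
consumes nominal p-values.

## AWM construction

Effects are z-scored per trait over all QC-passing SNPs *before* selection
(the alternative order is available behind `--zscore-after-select`-style
configuration of the builder inputs). Selection keeps SNPs with
p < 0.05 for the key trait (HW) or for ≥ 3 of the 12 traits. Assignment:
distance 0 inside a feature, else the gap to the nearest boundary; nearest
gene wins under 2.5 kb, else nearest miRNA under 10 kb, SNPs > 1,000 kb
from any gene become standalone nodes named by SNP id, and
intermediate-distance SNPs are discarded (`drop_intermediate=False` assigns
them to the nearest gene instead — the printed rule is ambiguous, so both
readings are implemented and the discard reading is the default).
"Most-associated" in the 1-Mb dedup means the largest count of traits with
p < α; ties break on smaller key-trait p, then smaller position; distance
ties in assignment break lexicographically on feature id. Trait clustering
is agglomerative (Euclidean distance, average linkage — the original GUI
tool's exact settings are unstated, both are configurable), cut at k = 2.

## Network inference

Gene–gene correlations are Pearson correlations of AWM rows across the 12
trait columns; constant rows are excluded with a warning. PCIT visits every
triad (x, y, z), computes the three first-order partials
r_xy·z = (r_xy − r_xz·r_yz)/√((1−r²_xz)(1−r²_yz)), forms the local
tolerance ε as the mean of |partial/direct| over the terms whose direct
correlation is nonzero (a triad with all three zero is skipped — the
published definition leaves this to the implementer), and eliminates (x,y)
if |r_xy| ≤ ε·|r_xz| and |r_xy| ≤ ε·|r_yz| for some z. The implementation
is vectorized per conditioning node (O(n³) work, O(n²) memory) and is
verified edge-for-edge against a naive triple-loop oracle; 1−r² factors are
clamped at 10⁻¹² against degenerate conditioning. Surviving pairs carry the
*direct* correlation as weight; with only 12 trait columns these
correlations are noisy by construction and no p-value is attached. The
strong-edge reduction keeps |r| strictly greater than 0.86 and drops
isolated nodes. Topology reports per-node degree, mean degree 2E/N, and the
BFS mean shortest path over connected ordered pairs (unreachable pairs are
counted and excluded).

## Regulator trio

"Spanning most of the network" is read as maximizing the number of distinct
non-trio nodes adjacent to ≥ 1 member, and "redundancy" as the summed
pairwise shared-neighbor counts; a configuration using Σ degrees instead is
a one-line objective swap. The search is exhaustive over all C(R,3) trios
with boolean neighbor-matrix unions vectorized over the third member
(~470k trios for R = 142 finish well under a minute); redundancy is only
evaluated on the coverage-tied candidates, and remaining ties break
lexicographically. The trio runs on the thresholded network by default
(`trio_on_thresholded=False` uses the full PCIT graph).

## Linkage disequilibrium

Haplotype frequencies by EM over the double-heterozygote ambiguity,
initialized at linkage equilibrium (the two-locus likelihood is
well-behaved; a single start suffices), iterated to |Δf| < 10⁻⁸ or 1,000
iterations; missing genotypes are handled pairwise-complete. D = p_AB −
p_A·p_B; D′ = |D|/D_max with D_max = min(p_A·p_b, p_a·p_B) for D > 0 and
min(p_A·p_B, p_a·p_b) otherwise; r² = D²/(p_A p_a p_B p_b). Monomorphic or
fixed loci raise explicit errors.

## Determinism and problem sizes

One master seed drives every stage through named child streams
(`SeedSequence(seed, spawn_key)`), so a rerun is byte-identical (writers use
fixed float formatting and stable orderings; the manifest contains no
timestamps). The shipped study conditions — 2,000 SNPs, ~292 phenotyped
animals — were chosen as the scale at which the full pipeline, the
calibration simulations (100-seed coverage runs, 20-seed REML recovery at
n = 500, ≥ 2,000 null SNP-trait tests) and the oracle comparisons all run
comfortably on a single CPU; every parameter scales up via `SimConfig`.

## Known limitations

Two-stage variance-component reuse slightly miscalibrates very strong
signals (the exact-refit flag exists for that); the Wald normal reference
ignores the small-sample t correction; the AWM keeps only the nearest gene,
so LD can credit the wrong gene — the motivation for the LD module; PCIT's
O(n³) loop is practical to a few thousand nodes but not genome-scale
expression panels; and the trio objective treats coverage and redundancy
lexicographically rather than as a weighted combination.
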