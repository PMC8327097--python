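# Methods

This note documents the models, conventions and numerical choices behind
each stage, what the synthetic-data generators do and do not emulate, and
the known limitations of the desk-scale validation scenarios.

## Data model and coordinates

Genotypes are alternate-allele dosages {0, 1, 2} with −1 for missing; the
alternate allele is the minor allele at load time (ties resolved so the
lexicographically smaller letter is the reference).  All downstream
statistics (F_ST, r², HWE, Pi-HAT) are invariant to this orientation.
Coordinates are 1-based inclusive base pairs everywhere; BED import/export
converts to 0-based half-open.  Segment and region lengths are computed as
`stop − start` (no +1), matching the size arithmetic of the candidate-region
tables the consensus output mirrors.  When no genetic map is supplied, a
constant 1 cM/Mb is assumed (c = bp × 10⁻⁸ Morgan); array studies of sheep
rarely have a population-specific map, and every map-dependent result here
(iHH, N_E(t)) is documented as map-scale dependent.

Non-autosomal and unmapped variants (X/Y/MT, chromosome "0") are dropped at
load time with a logged count; all analyses are autosomal.

## QC

Thresholds: sample missingness strictly greater than 10% removes the
sample; SNP call rate < 90%, MAF < 0.01, or HWE exact p < 1e-10 removes the
variant.  The HWE test is the exact conditional test on allele counts with
the plain (not mid-) p-value — conservative and the common reading of the
1e-10 threshold.  The filter order is samples → variants → relatedness;
LD pruning (50 kb windows, 5 kb steps, r² > 0.5, windows interpreted in kb)
is applied only before PCA/tree building.  Each filter is idempotent.

Pi-HAT is method-of-moments IBD: per pair, observed IBS0/1/2 counts over
jointly called SNPs are equated to their allele-frequency expectations under
IBD 0/1/2 (frequencies from the full sample set), solved sequentially,
truncated to [0,1] and renormalized; PI_HAT = P(IBD=2) + P(IBD=1)/2.  No
small-sample correction is applied; on 10,000 unlinked SNPs the estimator is
within ±0.05 of truth in the validation suite, which is sufficient for
pruning at 0.1875 (the midpoint between 2nd-degree 0.25 and 3rd-degree
0.125 expectations).  Pruning is greedy: always remove the sample in the
most above-cutoff pairs, ties broken by higher missingness, then later
sample order — the removal heuristic of the usual tooling is not specified
anywhere, so this rule is pinned by tests instead.

## Diversity and differentiation

H_O is the per-individual heterozygous fraction of non-missing calls.  H_E
is the per-population mean over SNPs of unbiased expected heterozygosity
2p̂q̂·n/(n−1); its reported SD is across SNPs (a per-SNP quantity has no
per-individual SD).  F is (O_hom − E_hom)/(M − E_hom) with the unbiased
per-SNP E_hom.  Multi-locus Weir–Cockerham θ is the ratio of summed
per-locus a-components to summed (a+b+c) — ratio of averages, the standard
multi-locus behaviour — with monomorphic loci contributing nothing.
Permutation significance shuffles population labels among the two groups'
pooled samples; p = (1 + #{θ_perm ≥ θ_obs})/(n_perm + 1) with 1,000
permutations by default, seeded.

## ROH

Detection is the consecutive method: no sliding window, a run grows SNP by
SNP while the heterozygote (≤ 1) and missing (≤ 5) budgets and the 1 Mb gap
bound hold, and a completed run must also have ≥ 50 SNPs, ≥ 1 Mb span,
≥ 1 SNP/100 kb density, and homozygous end points.  Run selection is
deterministic — leftmost feasible start, longest feasible extension,
continue after the run — and is pinned against a brute-force enumeration of
every sub-run on fixtures up to 2,000 SNPs.  The "minimum SNPs in a sliding
window = 50" parameter is recorded but redundant with the consecutive-SNP
minimum under this method.  F_ROH divides per-sample total ROH length by
2.45 Gb (the ovine autosome length); islands are maximal runs of SNPs whose
ROH occupancy within a group reaches 50%, with island bounds at the first
and last qualifying SNP (not extended toward non-qualifying neighbours).
Private islands are the bp-subtraction of one group's islands by another's,
with whole-vs-segment retention recorded in the tags.

## LD and N_E

r² is the squared Pearson correlation of genotype dosages (composite LD; no
haplotype phase needed).  N_E(t) uses Sved's relation N_Et = (1/4c)(1/r̄²−1)
at c = 1/(2t): pairs within ±10% of the target c contribute, bins under 50
pairs are flagged unreliable, and the optional r̄² − 1/n sampling adjustment
is off by default (the bare relation is the cited form).  The validation
scenario runs a 50-diploid Wright–Fisher population for 200 generations on
5 Mb with per-site mutation 5e-4 to keep standing variation; without
mutation a population this small fixes most sites within 200 generations
and the surviving loci give degenerate LD.  Recovery is evaluated at recent
bins (t = 20–50), where the relation's drift-recombination assumptions
hold at this scale; at larger t the c-bins fall below the scale where a
5 Mb chromosome provides pairs, and mutation biases N̂ upward.

## Selection scans

Per-SNP F_ST = 1 − (p₁q₁ + p₂q₂)/(2 p̄r q̄r) with p̄r the unweighted mean of
the two group frequencies (sample-size weighting available).  Windows of
200 kb sliding by 60 kb tile each chromosome from bp 1, whole windows only;
windows with fewer than 3 informative SNPs are dropped.  ZF_ST standardizes
the window means over all retained windows of a comparison (empirical mean
0, SD 1 to 1e-9 by construction) and the candidate set is exactly the
ceil(0.001 × n_windows) largest positive values — this makes the top-0.1%
rule deterministic rather than dependent on percentile interpolation.

EHH at displacement j is Σ_h C(n_h,2)/C(n,2) over distinct extended
haplotypes among carriers of the core allele, computed bidirectionally with
an incremental group-refinement walk; it equals an explicit pair-counting
oracle on all test fixtures.  iHH integrates EHH over genetic distance by
trapezoids outward from the core until EHH falls below 0.05 (the crossing
trapezoid is included; nothing beyond contributes), sides summed, in cM
units.  Site-level iHH combines the two core alleles weighted by their
frequency in the population; alleles with fewer than two carriers
contribute nothing.  XP-EHH is ln(iHH_A/iHH_B), standardized over all
defined SNPs of a scan, with one-sided normal p-values per tail (positive →
selection in A) and significance at P < 0.001; records with a zero iHH are
excluded from standardization.  Significant SNPs of the same direction
within 200 kb merge into regions.

A calibration caveat: the null distribution of standardized XP-EHH on the
generators here is leptokurtic, so normal-theory tail fractions at P < 0.001
run ~3× nominal even with independent sites (and higher with strong mosaic
LD).  The Z-scale invariants hold exactly; only the normal tail mapping is
approximate.  Empirical-threshold scanning (rank-based candidate selection)
is the robust alternative when calibration matters.

## Structure

PCA mean-imputes missing genotypes per SNP, centers by 2p̂ and, with the
default Patterson scaling, divides by √(2p̂(1−p̂)); variance fractions are
eigenvalue shares.  Neighbor-joining follows Saitou–Nei with deterministic
tie-breaking by taxon label; a negative branch length is clamped to zero
with the deficit moved to its sister branch, preserving path lengths — NJ
reproduces additive matrices to 1e-9 in the suite.

## Synthetic data: what it emulates, and what it does not

Divergence is Balding–Nichols: per-SNP ancestral frequencies Uniform(0.05,
0.95), per-population frequencies Beta(p(1−F)/F, q(1−F)/F) (exactly p at
F = 0), so the target F_ST is an explicit, recoverable parameter.  Haplotype
structure comes from per-population founder pools (default 20 haplotypes)
and a Markov mosaic with switch probability 1 − exp(−rate·gap) per inter-SNP
gap (default rate 1e-6/bp, i.e. ~1 Mb founder segments and LD decaying over
a few hundred kb).  Founder pools carry **exact** allele counts
(stochastically rounded K·p_k, assigned by permutation) rather than iid
Bernoulli draws: iid pools of size K would add ≈ (1−F)/K of extra
between-population variance — with K = 20 that would inflate a programmed
F_ST of 0.10 to ≈ 0.145 — whereas exact-count pools keep the realized
population frequency at the Balding–Nichols draw while preserving mosaic
LD.  A `founders_per_pop=None` mode draws sites independently (no LD) for
null fixtures.  Genotypes are always the sum of the two haplotypes, and all
generators are deterministic under their seed.

Sweep injection replaces a carrier fraction's alleles with one donor
haplotype over a tract.  The default (fixed tract) makes EHH = 1 among
carriers across the whole tract — useful for exact EHH assertions but the
cross-population statistic is then flat over the tract, so the top-scoring
SNP is only localized to the tract, not the core.  The `eroded` mode draws
each carrier's per-side extent Exponential(tract/4) truncated at tract/2,
mimicking post-sweep recombination: EHH decays away from the core and the
XP-EHH peak localizes near it.  Even so, the argmax of the scan has jitter
of order 100 kb under these conditions — localization-rate checks should be
read with that resolution in mind.

Autozygosity injection copies the first haplotype over the second inside
per-sample tracts (overlaps merged), returning the true tract list for
recovery tests.  The Wright–Fisher simulator is a small discrete-generation
model with Poisson crossovers and per-site mutation on a fixed site grid —
an oracle for the LD → N_E chain, not a realistic demographic simulator.

None of the generators emulate genotyping error, allele-frequency
ascertainment of array design, overlapping generations, or admixture;
passing recovery tests demonstrates correctness of the estimators under the
stated models, not robustness to those real-data features.

## Validation scenario sizes

The reference scenarios are sized for a single CPU: divergence recovery at
n = 100/population × 5,000 SNPs × 10 seeds; sweep scans at n = 40/population
× 2,000 SNPs on 20 Mb with 100-founder pools (larger pools keep baseline
haplotype homozygosity low, as on a dense array in outbred sheep, so the
cross-population iHH ratio is signal- rather than founder-noise-dominated);
null calibration pooled over 5 seeds × 1,500 SNPs; Wright–Fisher recovery
over 5 seeds of 50 diploids × 200 generations.  Single-chromosome cohorts
overstate genome-wide relatedness whenever a long haplotype is shared (a
1 Mb sweep tract is 5% of a 20 Mb "genome" but 0.04% of the real 2.45 Gb
autosome), so sweep-scenario configs disable Pi-HAT pruning rather than let
it remove the carriers.
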