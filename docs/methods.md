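# Methods

This note documents the models, estimators and design choices behind
rhoscan, and what the synthetic-data tests do and do not demonstrate about
real cohort data.

## Data model

A segment is described by an ordered `SnpMap` (S-number label, rs id,
1-based chromosomal position, ancestral/derived alleles, sub-segment label)
and analysed through a `HaplotypePanel`: a chromosomes × sites matrix of
0 (ancestral) / 1 (derived) codes with per-chromosome cohort metadata
(population, phenotype, sex).  External coordinates are 1-based inclusive;
any half-open arithmetic is confined to the I/O layer.  Missing genotypes
are storable but rejected by every statistic unless the caller passes an
explicit drop-incomplete-rows flag, because all estimators below assume
complete phased haplotypes.

The bundled 29-SNP default map carries the segment span
(160,689,203–160,692,753, 3,551 bp) and seven rs identifiers; the remaining
positions are evenly spaced placeholders explicitly marked user-supplied in
the file header.  Analyses of real data should supply a measured map.

## Diversity statistics

`Hd` is Nei's unbiased haplotype diversity `n(1 − Σp_i²)/(n − 1)` over
*exact* haplotype string identity on the selected sites (no mismatch
tolerance — the convention of sequence-analysis desktop tools).  `θ_W` is
`S/a_{n−1}`; `π` is the mean pairwise difference computed from per-site
allele counts.  Both are reported on segment scale by default, with
per-site variants dividing by the bp span of the selected sites.

The recombination-strength profile reports `Hd/θ_W` per sub-segment with
`θ_W` on segment scale: mutation inflates `Hd` and `θ` together, while
recombination inflates only `Hd`, so the ratio tracks the net effect of
recombination.  Segment scale keeps the ratio dimensionless and comparable
across sub-segments of unequal length; a sub-segment with `S = 0` reports
an undefined (NaN) ratio rather than infinity.  The exonic synonymous SNP
S25 is grouped with the Post-Exon sub-segment.

## PAC recombination-rate estimation

The population recombination rate `ρ(x) = 4 N_e r(x)` is estimated with a
Li–Stephens product-of-approximate-conditionals (PAC) likelihood: haplotype
`k+1` is modelled as a mosaic copy of the first `k`, switching templates
between adjacent SNPs `j, j+1` with probability `1 − exp(−ρ_j/k)` (where
`ρ_j` integrates the per-bp rate over the interval) and mis-copying with
the standard PAC mutation term `θ̃/(2(k + θ̃))`, `θ̃ = 1/Σ_{i≤k} 1/i`.
Because the PAC likelihood depends on haplotype order, the log likelihood
is averaged in log space over 20 random orderings fixed once per call
(seeded, hence deterministic).

The rate map is parameterised as a background per-bp rate times per-bin
multipliers on 350-bp bins (a trailing partial bin is merged into its
neighbour).  Fitting is a two-stage grid search: the best uniform
segment-total rate from a log-spaced grid (2⁻¹…2⁸), then one coordinate-
ascent sweep of per-bin multipliers over {1/16, 1/4, 1, 4, 16, 64} with a
final background refinement; a second sweep changed neither peak placement
nor `ρ̄` materially in simulation, so one sweep is the default.  `rhohat`
for a bin is the segment-equivalent rate implied by the bin's local
intensity, so the per-bin profile and `ρ̄` (its bin-width-weighted mean,
equal to the segment-total rate) share one scale.  Conversion to cM/Mb uses
`r = ρ/(4N_e)` with `N_e = 10,000` (overridable), and rates are classified
against the hotspot range 10–120× the 0.89 cM/Mb genome average.

This is a maximum-likelihood substitute for the Bayesian machinery of the
original desktop estimator, whose priors and chain settings are not
reproducible; its accuracy claims therefore rest on simulation recovery,
not on numerical agreement with published per-bin profiles.  Recovery
experiments (run in the test suite) use n = 100 haplotypes: with a uniform
map of segment-total ρ = 20 the median `ρ̄` over 20 replicates falls within
a factor of 2 of the truth, and with a 40× central hotspot the argmax bin
falls inside the hotspot interval in ≥16/20 replicates.  The localization
experiment uses dense simulated marker panels (θ = 20, roughly 80–130
SNPs): at study-like density (~29 SNPs over 3.5 kb) the four-gamete-
incompatible intervals span most of the segment and single-bin peak
placement is information-limited, so sparse-panel profiles should be read
as segment-level rate evidence, not as bp-precise peak positions.

## Four-gamete rule and Rm

A site pair is incompatible when all four gamete types {00, 01, 10, 11}
are observed, implying a crossover (or recurrent mutation) strictly between
the sites.  The Hudson–Kaplan lower bound `Rm` selects disjoint
incompatible intervals greedily by earliest right endpoint, which is
optimal for interval point-cover; the test suite verifies exact agreement
with exhaustive search on small panels.

## Sperm typing

Clone design: clones are classified against the two parental haplotypes
(given, or inferred as the two most frequent clone classes).  A clone is a
recombinant iff it is a single-switch mosaic of the parentals; the switch
interval is the flanked pair of informative markers, widened across
markers where the parentals agree.  The genetic distance in cM is 100× the
frequency of the more abundant minor (recombinant) form, and the rate in
cM/Mb divides by the marker interval in Mb; Clopper–Pearson binomial
intervals are propagated through the same transformation.  Zero
recombinants yield a zero point estimate with a one-sided upper bound.
A strict reading that counts only the lowest-frequency duplicated clone
classes is available by passing explicit parentals and ignoring `other`
classes.

Pool design: with `P` positive runs out of `R` pools of `g` amplifiable
genomes, the detectable per-molecule fraction is either `P/(Rg)` (naive)
or `−ln(1 − P/R)/g` (Poisson-corrected for multi-recombinant pools; the
default, undefined when every run is positive).  An allele-specific design
captures only one of the two reciprocal recombinant classes, so the
fraction is multiplied by a `reciprocal_factor` (default 2) before
conversion; at the reference design point (5/77 runs, 100 genomes, 1 kb)
the naive estimator gives 129.9 cM/Mb and the corrected one is <4% higher.
The inter-marker bp distances of the original assays are not published in
main-text sources, so 1,000 bp is the default and must be overridden with
measured distances for real assays.

## LD and LD contrast

`r²` is the squared Pearson correlation of 0/1 codes computed from phased
haplotype counts; monomorphic sites yield flagged-undefined entries, and
entries below a threshold (default 0.1) are emitted as "low-LD points".
The LD-contrast statistic between two cohorts over a site window is the
squared Frobenius distance between their haplotype correlation matrices
(summed over site pairs `i < j`; a site monomorphic within one group
contributes zero correlation).  Significance is by permutation of cohort
labels over the pooled chromosomes with the add-one estimator
`p = (1 + #{null ≥ obs})/(n_perm + 1)`; the pooled rows are sorted
canonically and the split size fixed at max(n_A, n_B), which makes `p`
exactly invariant to swapping the groups.  The exhaustive mode tests every
SNP-flanked region, reports raw per-region significance bands at 0.05 and
0.01, and emits a Bonferroni column for reference without applying it to
the bands.  The "correlation" form of the contrast was chosen because the
inputs are phased; composite-LD variants for unphased genotypes are out of
scope.

## Median-joining networks

Nodes are haplotype strings; the network is the union of all minimum
spanning trees (edge `(u,v)` included iff its Hamming distance equals the
minimax path weight between `u` and `v`, within tolerance ε, default 0).
Median vectors — for binary data the site-wise majority of a triplet, with
ties resolved toward the ancestral code 0 — are added in rounds from
triples containing a linked pair, keeping only medians on a geodesic
between current nodes with connection cost within ε of the round minimum;
median vectors of degree ≤ 2 in the converged network are pruned as
obsolete.  All tie-breaks are lexicographic, so construction is
deterministic.  Torsos are the cycle basis of the graph; a SNP labelling
more than one edge is flagged recurrent.  The all-ancestral haplotype is
added (or re-flagged) as the ANC node and attached by minimum Hamming
cost.  Node radius follows the log of the within-network normalized
frequency (`1 + log10 f` for observed nodes), the node-size convention of
published haplotype-network figures.  No star-contraction or
frequency-weighted post-processing is applied.

The haplotype spectrum reports per-form counts and frequencies, the number
of forms at or below a rare threshold (default 1%), and the rare share of
forms.

## Association tests

Each haplotype is tested carrier-vs-rest between two cohorts of phased
chromosomes (totals = 2× subject counts).  `p_pearson` is the uncorrected
Pearson chi-square (df 1, two-sided, no continuity correction); `p_lrt` is
the G-test `G = 2ΣO·ln(O/E)` with `0·ln0 = 0`.  The Poisson deficit test
scales the count in the higher-frequency group by the ratio of chromosome
totals to get λ and refers the lower count to the lower Poisson tail; it
is deliberately not symmetric in the two groups and its λ is reported.
Single-table results are raw p-values; the screening mode over a spectrum
pair adds a Šidák column.  The tests are reported by formula name rather
than by any legacy program label, since the published labels do not map
one-to-one onto the formulas that reproduce their printed values.

## Synthetic-data generator

Neutral panels come from Hudson's back-in-time ancestral-recombination-
graph algorithm: with `k` lineages, coalescence at rate `k(k−1)/2` and
per-lineage recombination at rate `ρ_span/2` (per-bp rate integrated over
the lineage's ancestral span, breakpoints drawn proportional to the local
rate), tracking ancestral segments and sample counts so fully coalesced
material is dropped.  Mutations fall on marginal genealogies as a Poisson
process of intensity `θ/2` per segment under infinite sites and are mapped
to discrete bp positions (collisions shifted to the next free bp — rare at
the densities used).  Defaults mirror the study conditions: 3,551 bp,
θ = 5 per segment (≈29 segregating sites at n ≈ 600), background rate at
the genome-average equivalent (4·10⁴·0.89·10⁻⁸ per bp) with a 40× central
hotspot on [1525, 2025).  The simulator matches Watterson's `E[S]`,
msprime's segregating-site counts at matched parameters, and never
violates the four-gamete rule at ρ = 0.

Selection mode seeds a Wright–Fisher population of `2N` haplotypes from
the neutral coalescent and evolves it forward with additive fitness
`1 + s` per derived copy at a focal site, crossover per meiosis
`r(x) = ρ(x)/(4N)`, sampling haplotypes at the final generation;
monomorphic columns are dropped from the sample.  This forward simulator
is separate from the coalescent (no structured coalescent) for simplicity
and testability.

The pooled-assay simulator draws detectable recombinant molecules per run
as Poisson with mean `g · detectable_fraction · rate · bp · 10⁻⁸` and
scores a run positive iff at least one is present.

What the generator does *not* emulate: genotyping or phasing error,
demography (growth, bottlenecks, structure), gene conversion, and the Alu
insertion's sequence context.  Passing recovery tests therefore shows the
estimators are correct under their own model assumptions, not that those
assumptions hold for any particular cohort.

## Pipeline and reproducibility

The pipeline composes all stages over a configured panel (or a simulated
demo: one neutral pool of 190 + 406 chromosomes over exactly 29 sites,
split at random, so the two cohorts differ only by sampling noise).  Every
random stage draws from an explicit named seed recorded in
`manifest.json`, and TSV outputs are written with a fixed float format, so
a rerun with the same configuration is byte-identical.  The demo
subsamples each cohort to ≤100 haplotypes for the PAC stage (the forward
pass is quadratic in panel size) and uses 99 permutations for the
exhaustive contrast grid; both are configuration values, raised for real
analyses (the permutation default outside the demo is 10,000).  Stage
failures raise errors named after the stage and keep the outputs of
completed stages.

## Problem sizes used in the test suite

Oracle-equivalence tests run on ~100 random panels of up to 20×12;
Rm greedy-vs-exhaustive on panels of ≤8 sites; PAC recovery on 20
replicates each of hotspot (θ = 20) and uniform (θ = 8) maps with n = 100;
LD-contrast calibration on 200 random splits of a 200-chromosome pool at
199 permutations; pooled-assay recovery on 500 simulated assays at the
77-run design point.  These sizes were chosen to give stable pass/fail
behaviour for the stochastic properties while keeping the default test
run quick.
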