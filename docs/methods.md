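# Methods

This note documents the models and estimators implemented in `sdmal`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic-data generators do and do not emulate.

## Setting

The package analyses a meiotic-drive supergene in *Drosophila melanogaster*:
the *SD-Mal* haplotype of Zambia, which couples the driver locus
(*Sd-RanGAP*, chromosome *2L*) to an insensitive *Rsp* allele and the double
paracentric inversion *In(2R)Mal* on *2R*. Because recombination between
*SD-Mal* and wildtype (*SD⁺*) chromosomes is suppressed across the
supergene, the *SD-Mal* haplotypes behave as a small, semi-isolated
subpopulation: the analyses treat panels of haploid sequences (n = 9
*SD-Mal*, n = 10 per wildtype inversion class) as exchangeable haplotype
matrices and quantify diversity, differentiation, sweep history,
recombination history, and genetic load.

## Data model and filters

`HaplotypeMatrix` is a samples × sites matrix of 0/1 alleles with 1-based
positions; missing calls are encoded explicitly and excluded *pairwise*
(every statistic uses per-site non-missing sample counts), never imputed.
Multiallelic VCF records are dropped rather than decomposed because every
estimator here assumes biallelic sites. Coordinates are 1-based inclusive
throughout; BED input is converted at the reader boundary.

The published depth filter ("minimum sample depth of 8") is ambiguous about
aggregation. The default dialect requires *every* sample to have depth ≥ 8
at a site (the strict reading); a `mean` dialect (mean depth ≥ 8) is
offered as a configuration switch. Filters compose as predicates and are
idempotent; when a composed filter empties a matrix the error names the
first criterion that removed more than half the sites.

## Windowed statistics

Per site with j derived alleles among n called samples, the mean pairwise
difference is π_site = 2j(n−j)/(n(n−1)). Window quantities are sums of
per-site values; π per site divides by the window's callable-site count
(not its span) so that masking does not dilute the estimate. Tajima's D
uses the standard normalising constants recomputed from n:

    D = (π − S/a₁) / √(e₁S + e₂S(S−1)).

Because D is sensitive to S, the scan also reports D/D_min, where D_min is
the value of D when all S sites are singletons (π = 2S/n). D is flagged
undefined (NaN) when S = 0 and such windows are excluded from summaries.

F_ST uses the haploid Weir–Cockerham variance-component estimator. Per
site, with sample sizes n₁, n₂ and frequencies p₁, p₂,

    MSP = Σᵢ nᵢ(pᵢ − p̄)²,   MSG = Σᵢ nᵢpᵢ(1−pᵢ) / (n₁+n₂−2),
    n_c = (n₁+n₂) − (n₁²+n₂²)/(n₁+n₂),

and the window estimate is the ratio of summed numerators to summed
denominators, Σ(MSP − MSG) / Σ(MSP + (n_c−1)MSG) (ratio of averages). The
finite-sample correction means the estimate is slightly *negative* (about
−1/(n_c−1) per site) when the two panels have identical allele
frequencies; raw values are reported, not clipped — clipping is a
presentation choice. d_XY is the mean cross-panel mismatch fraction per
callable site; sites fixed identical in both panels contribute zero, so
only shared variant positions are enumerated.

Two window schemes emit the same record schema: fixed coordinate width
(default 10 kb) and equal-callable-site windows, mirroring the two ways
the original scan was described. The published π-variance correction for
non-independent SNPs in non-recombining regions is not implemented (the
exact estimator is unspecified); the empirical between-window standard
deviation is what the window table supports.

## Coalescent simulator

Time is measured in units of 4·N_e generations (the `ms` convention), so
with k lineages the coalescence rate is k(k−1) and the expected pairwise
TMRCA is 0.5. Three demographies:

* **constant** — the standard neutral coalescent;
* **growth** — exponential growth at rate α per 4N_e generations
  (default α = 0.26, reproduced from the published endpoint sizes
  N_past = 1,137,712 → N_present = 3,160,475 over 72,005 years at 10
  generations/year). Backward in time the population shrinks as e^{−αt},
  so waiting times invert the cumulative hazard in closed form;
* **sweep** — an absolute bottleneck to a single chromosome: the constant
  process runs until t_sweep, then all surviving lineages merge into one
  multifurcating ancestor at exactly t_sweep. This is a *hard-sweep
  caricature* (a scaled-N epoch would allow lineages to escape); it was
  chosen because the modelled history is a single-origin haplotype whose
  carriers all descend from one chromosome at the sweep onset.

Mutations are placed conditional on a fixed number of segregating sites S
(`ms -s` semantics): S mutations fall on branches multinomially by branch
length, restricted to branches subtending 1..n−1 tips (the branch above
the forced-merge root cannot carry polymorphism). Positions are uniform
without replacement — an infinite-sites region with no recombination,
matching the assumption of a non-recombining ~9.92 Mb inverted region.

Two code paths exist. The per-tree simulator builds explicit
parent-pointer genealogies. The batch kernel tracks only the waiting time
at each lineage level and the block-size partition of the sample (which
tips each lineage subtends); since a mutation on a lineage at level k is
carried by all tips of its block, π and D follow from block sizes alone
and thousands of replicates vectorise into a handful of array operations.
The test suite verifies that both paths agree in distribution with each
other and with msprime at matching parameters (haploid population size 0.5 makes
msprime's time unit equal 4N_e generations).

## Sweep-age ABC

Observed summaries are the region-wide π (summed over sites, not per bp)
and Tajima's D for the inverted region: π = 584.60, D = −1.33 for all
non-coding SNPs; π = 427.72, D = −1.45 for private SNPs only. The
segregating-site count S behind those summaries is not published; it is
recovered by inverting the definition of D, which at fixed π is strictly
monotone in S (root-finding on a bracket, then integer rounding; for the
all-SNP summaries this gives S = 2131).

Rejection sampling draws t ~ Uniform(0, 1] (in 4N_e units, the prior "0 to
4N_e generations") and S ~ round(Uniform(±5% of S_obs)), simulates
`reps_per_draw` sweep replicates at (t, S), averages (π, D), and accepts
when both averages fall within ε of the observed values, with ε read
per-statistic as 5% of each observed absolute value. Published-scale defaults
are 1000 replicates per draw and 10,000 accepted draws; the acceptance
script and tests run a reduced scale of 200 × 200, which finishes in well
under a minute on one CPU and reproduces the full-scale posterior mode to
within its stochastic scatter.

Posterior summaries: the maximum a posteriori estimate is the argmax of a
Gaussian kernel density (Silverman bandwidth) on a 1000-point grid, ties
broken toward smaller t; the credible interval is the central quantile
interval by default (the published interval 0.0837–0.1067 with a mode of
0.0884 near its lower edge is consistent with quantiles of a right-skewed
posterior), with highest-posterior-density intervals behind a flag. Time
converts to generations as t·4·N_e·f (N_e = 3,160,475, supergene
frequency f = 0.0147) and to years at 10 generations/year; this
reproduces the published ~1644 and ~1261 years for t = 0.0884 and 0.0679.

Model comparison simulates fixed-S replicates under the sweep (at the
estimated t), constant-size, and growth models and reports two-sided
empirical-CDF p-values for π and D, clipped to [1/reps, 1]. The default
simulation count is 10,000 per model (the original used 100,000) to keep
desk-scale runtime; a flag restores full scale. The growth model
conditions on fixed S like the others, for comparability.

## Drive crosses, LD, and the inversion block model

Genetic distances use the Kosambi map function d = 25·ln((1+2r)/(1−2r))
on pooled recombinant counts (pooling reproduces the published Table
values; per-cross averaging is also exposed). Note one published
discrepancy: the pooled counts give a 55.6% reduction for the *b–c*
interval where 54.6% is printed; the *c–px* reduction (92.4%) and the
87.3% distal reduction reproduce exactly, and only those are used as
checks.

Drive strength k is the per-cross proportion of progeny inheriting the
focal chromosome, averaged over crosses; the viability-corrected
k* = n_focal/(w·n_tester + n_focal) uses the weight w = n_focal/n_tester
pooled over female-transmission crosses (drive is male-specific, so
female transmission isolates viability). Significance against Mendelian
0.5 is a two-sided one-sample t-test on per-cross k*.

Two-locus LD from 2×2 haplotype counts: D = p_AB − p_A·p_B and
r² = D²/(p_A q_A p_B q_B); association uses the two-sided Fisher exact
test (sum of all equally-or-less-probable tables with fixed margins).
Neutral decay follows D_t = D₀(1−r)^t; the half-life is the first integer
generation at or below D₀/2. The map-distance→r conversion takes
r = d/100 directly at small distances (at 2.5 cM the inverse-Kosambi
alternative, provided behind `kosambi_to_r`, differs by <2%).

The probability that none of n recombinants separates a uniformly
positioned enhancer from the driver is ∫₀¹(1−u)ⁿdu = 1/(n+1) — for
n = 71, 1/72 < 0.014.

Inversions apply sequentially, each interval read as 1-based inclusive on
the arrangement existing at its turn (this ordering is what distinguishes
the distal-first history). The arrangement is kept as a minimal list of
(ref_start, ref_end, orientation) blocks; inverting splits boundary
blocks, reverses the covered blocks and flips their orientations, then
re-merges adjacent collinear runs. Applying the distal inversion
(2R:14,591,034–18,774,475) and then the proximal one (8,855,601–15,616,195
of the resulting arrangement) yields rearranged blocks of 1.03 Mb
(forward, displaced), 5.74 Mb (reverse) and 3.16 Mb (reverse). Where the
two published values for the distal inversion's proximal breakpoint
disagree by 31 bp, the figure-derived value (14,591,034) is used; block
lengths agree at 0.01 Mb precision either way.

## Recombination history

Pairwise r² is the squared Pearson correlation of 0/1 haplotype vectors
(equal to D²/(p_A q_A p_B q_B) for haploids), computed on biallelic,
non-singleton, fully genotyped sites, with pairs straddling the internal
inversion junctions excluded (the exact published exclusion coordinates
are not printed; defaults follow the assembly breakpoints and are
user-configurable). Distance bins are half-open 10-kb intervals.

The minimum number of historical crossovers is the Hudson–Kaplan bound
Rm: four-gamete incompatibility for every site pair, reduction to minimal
incompatible intervals, then a greedy earliest-right-endpoint scan for
the maximum set of pairwise-disjoint open intervals. Stronger bounds
(RecMin-style) are out of scope; on the published data both approaches
give the same value (15). Missing calls are not permitted in this scan
(how they were handled originally is unstated; requiring complete sites
is the conservative choice).

Shared/private classification: a focal-panel SNP is *shared* when the
derived allele segregates in at least one reference-panel haplotype at
the same position, otherwise *private*; an optional nucleotide check
flags allele mismatches as unassigned. Runs are maximal same-label
stretches over *all* SNPs including singletons (a different site view
than the r²/Rm filter set, deliberately). Single-SNP runs have length 0:
they count in run-number fractions but are excluded from density, which
is pooled SNPs per pooled kb over positive-length runs only.

## Genetic load

N/S ratios compare nonsynonymous to synonymous SNP counts per panel and
scope (all/private/shared); the fold change is the ratio of ratios, and
independence uses Pearson's χ² without continuity correction (the
uncorrected test reproduces the published significance pattern across
scopes). TE insertion calls are counted in 100-kb windows and as
per-library 2R/2L euchromatic count ratios compared across panels by
Kruskal–Wallis. Euchromatin boundaries are configuration values since the
published bounds are not printed.

## Synthetic data: what it does and does not emulate

The generators produce coalescent panels with the genealogical structure
the analyses assume (a low-frequency derived subpopulation under the
sweep model; neutral and growth panels for contrast), gene-conversion
tracts copied from a donor panel (tract lengths geometric with mean 1 kb
— memoryless, the standard tract model; Poisson tract counts per
haplotype; non-overlapping within a recipient), multinomial cross progeny
(drive k, recombination r, and per-class viability compose into class
probabilities), and a clean two-population split with no migration for
differentiation statistics.

They do *not* emulate: sequencing error or depth heterogeneity (depth
fields are synthetic when present), intragenic recombination within
panels (Rm on simulated panels is exactly 0, which the suite exploits as
an invariant), linked selection beyond the single hard sweep, overlapping
inversions' position effects on diversity, or TE family biology (TE
fixtures are count-level only). Passing tests therefore demonstrate
correctness of the estimators and recoverability of generative
parameters under the stated models — not robustness to the artefacts of
real short-read data.

## Numerical choices and scales

* Random numbers: every stochastic routine takes a NumPy `Generator` or a
  seed; identical seeds give bit-identical output, including fixture
  files.
* The S-inversion root-finder brackets (1, 10·a₁·π) and rounds to the
  nearest integer; prior draws for S round half-up.
* Degenerate inputs fail loudly: zero-length trees with S > 0, windows
  with S = 0 (flagged NaN rather than error), monomorphic loci in LD,
  zero margins in χ², r ≥ 0.5 in the Kosambi domain.
* Test problem sizes are deliberately desk-scale (hundreds of sites,
  hundreds to thousands of replicates, ABC at 200 × 200, model checks at
  10,000 replicates); these are the package's chosen defaults for
  reproducible examples, with published-scale settings available through
  configuration.

## Known limitations

The sweep model's forced multifurcation slightly overstates the star-ness
of young genealogies relative to a strong-but-finite sweep. The derived
S depends on the printed precision of π and D (±1 in S moves D by ~5e-4).
F_ST/d_XY window values at few shared polymorphic sites are noisy and are
flagged rather than smoothed. The per-window callable-site count equals
the window span unless a mask or depth matrix restricts it, because a
variants-only VCF carries no information about monomorphic-site
callability.
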