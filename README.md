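# sdmal

Population-genetic analysis of the *SD-Mal* meiotic-drive supergene of
*Drosophila melanogaster*.

Segregation Distorter (*SD*) is a selfish gene complex that is transmitted
from heterozygous males to well over 90% of functional sperm. In Zambian
populations the driving haplotype — *SD-Mal* — couples the driver
(*Sd-RanGAP* on *2L*) to an insensitive *Rsp* allele and a pair of
overlapping paracentric inversions, *In(2R)Mal*, that lock the components
together as a supergene. This package implements, as a reusable and tested
library plus CLI, the computational analyses needed to characterise such a
supergene from haplotype panels and cross data:

* **hapio** — haploid 0/1 haplotype matrices, VCF/BED/annotation I/O,
  composable site filters (biallelic, complete, non-singleton, depth).
* **popgen_windows** — windowed S, π, Watterson's θ, Tajima's D and
  D/D_min, haploid Weir–Cockerham F_ST, and d_XY.
* **coalescent_sim** — an `ms`-style coalescent (time in 4N_e generations)
  with constant-size, exponential-growth, and absolute-bottleneck sweep
  demographies, and fixed-S infinite-sites mutations.
* **abc_sweep** — rejection-sampling ABC for the sweep onset time, with
  KDE posterior mode, credible intervals, time-to-years conversion, and
  posterior-predictive model checks.
* **drive_crosses** — Kosambi map distances, transmission-ratio statistics
  (k and viability-corrected k*), two-locus LD and its neutral decay,
  Fisher exact association, the enhancer-escape bound, and sequential
  inversion application producing reference-relative block decompositions.
* **haplotype_structure** — pairwise r² vs distance, the Hudson–Kaplan
  minimum-recombination bound Rm, shared/private SNP classification and
  run statistics.
* **selection_load** — N/S polymorphism ratios with χ² tests; TE window
  counts, 2R/2L ratios and Kruskal–Wallis comparisons.
* **synthetic_data** — seeded generators for every input: coalescent
  panels, gene-conversion tracts, multinomial cross counts, two-population
  splits.

## The core models

Tajima's D on a region with S segregating sites and summed pairwise
diversity π (per-site mean pairwise difference 2j(n−j)/(n(n−1))):

    D = (π − S/a₁) / √(e₁S + e₂S(S−1)),   a₁ = Σ_{i<n} 1/i.

The recent spread of the supergene is dated by modelling the sweep as an
**absolute bottleneck**: all n sampled haplotypes are forced to coalesce
into a single ancestor at time t (units of 4N_e generations). Rejection
ABC draws t ~ U(0,1] and S ~ U(±5% of S_obs), simulates the sweep
coalescent conditioned on S, and accepts (t, S) when the simulated mean π
and D both fall within ε = 5% of the observed values. S_obs itself is
recovered by inverting the Tajima's D relation at the observed (π, D),
which is monotone in S.

Recombination history inside the inversion uses the four-gamete test: Rm
is the maximum number of pairwise-disjoint open intervals among minimal
incompatible site pairs — a lower bound on historical crossovers.

## Worked example

Dating the sweep from the published region-wide summaries of the inverted
region (π = 584.60, D = −1.33 over n = 9 haplotypes), at reduced scale:

```sh
sdmal abc --pi 584.60 -D -1.33 -n 9 --n-accept 200 --reps-per-draw 200 \
          --seed 1 -o abc_out
```

prints

```
mode t = 0.0951 (95% CI 0.0820-0.1098), ~1767 years; acceptance 2.11%
```

Reading: the posterior mode places the sweep onset at ≈0.095 × 4N_e
generations. With N_e = 3,160,475, a supergene frequency of 1.47% and 10
generations per year, that converts to roughly 1,800 years — the same
recent, rapid expansion indicated by the full-scale published estimate of
0.0884 (95% CI 0.0837–0.1067, ~1,644 years), whose interval the scaled
posterior reproduces. The acceptance rate is the fraction of prior draws
whose simulated summaries matched the observations within ε.

The experimental-genetics side is a library call away:

```python
>>> from sdmal.drive_crosses import kosambi_distance, ld_from_counts, TwoLocusCounts
>>> kosambi_distance(211, 1820)   # recombinants among progeny, b-c interval
11.808142020958744
>>> ld_from_counts(TwoLocusCounts(n_AB=3, n_Ab=3, n_aB=0, n_ab=198))
(0.014273356401384083, 0.49253731343283574)
```

— the inversion cuts the *b–c* map distance to 11.81 cM (vs 26.62 cM in
wildtype crosses), and across 204 sampled haplotypes the driver and the
inversion are in strong disequilibrium (D = 0.0143, r² = 0.493) despite
each being individually rare.

A self-contained demo of the whole pipeline on synthetic data:

```sh
sdmal run-all --config examples/demo.yaml --out-dir out   # fixtures, windows, LD, runs, ABC
sdmal verify --out-dir out                                # re-check manifest hashes
```

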