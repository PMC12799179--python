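# Methods

This note documents the models implemented in `introscan`, the defaults and
their rationale, the numerical choices, and what the synthetic-data tests do
and do not demonstrate about real data.

## The backcross-introgression model

The experimental design being modelled crosses a tropical donor (SK) with a
temperate recipient (VT) and runs 16 generations in which odd generations
recombine freely and even generations impose ~80% embryonic mortality
followed by a backcross of 300 recipient-line individuals, with the
population regrowing to its carrying capacity of ~1500 after every event.

`simulate_introgression` realizes this as a discrete-generation,
individual-based model per recombination window ("virtual chromosome"):

- **Generation 0** holds K = 1500 diploids whose haplotypes are drawn
  site-independently from the F1 frequency vector
  p_F1 = (p_VT + p_SK)/2 (the `synthetic_cross`). The linkage-equilibrium
  start mirrors initializing a forward simulation from frequency vectors;
  it means focal-allele carriers begin with *random* backgrounds, so
  within-window hitchhiking builds up only through post-F1 drift and
  selection, not from intact parental haplotypes.
- **Reproduction** draws mother and father uniformly with replacement (no
  explicit sexes; selfing allowed) until the population is back at K.
  Regrowth hits K exactly — the real census "varies around 1500"; the
  deterministic regrowth is a simplification.
- **Recombination** is a Poisson crossover process with per-base rate rho:
  the number of crossovers between adjacent tracked sites is
  Poisson(rho × distance) per meiosis, and a site's template haplotype
  follows crossover parity. Internally the per-interval crossovers are
  drawn as one Poisson total across gametes and assigned to uniformly
  random gametes — an exact sparse realization of the same process (the
  parity probability per interval is (1 − e^{−2 rho d})/2 either way).
- **Even generations**: exactly round(0.2 K) survivors are sampled (uniformly
  in the neutral model), then in `neutral_introgression` mode 300 migrants
  drawn from p_VT join the survivor pool, and the merged pool reproduces to
  K. With 300 survivors and 300 migrants the expected donor ancestry halves
  at each of the 8 even generations, which is what makes the closed-form
  recurrence hold. `drift_only` mode applies the bottleneck without
  migrants.
- **Mutation** at 1e-7 per site per gamete is implemented as Bernoulli
  allele flips (drawn as one binomial total); over 16 generations it is
  negligible, as expected.
- The **X chromosome is treated as autosomal** and all pools as 60
  chromosomes; no hemizygosity correction is applied.

The closed-form check: after n backcross events the expected frequency is
(1 − a) p_VT + a p_SK with a = (1/2)^(n+1). For the focal 2R SNP
(temperate-allele frequency 0.598 in VT, 0 in SK) this gives an expected
neutral shift of Δp ≈ 0.00117 after 8 events. A published treatment of the
same design quotes Δp = 0.00021; the plain ancestry-halving recurrence does
not reproduce that figure, and this package reports the recurrence value.
Either way the neutral shift is orders of magnitude below the observed
shifts that motivate the scan.

**Sequencing noise** is two-step binomial: chromosome sampling
Binomial(2 × 30, p)/60, then read sampling Binomial(depth, pool frequency),
with per-site depth Poisson(85) by default (a `constant_depth` switch exists
for exact oracle tests). The compound variance
p(1−p)[1/60 + (1 − 1/60)/85] is what the effective coverage
n_e = n r/(n + r) ≈ 35.2 summarizes: a binomial with denominator n_e has the
same variance.

## Pool-seq FST

The estimator works through identity probabilities. Within a pool, two
distinct reads are copies of the same chromosome with probability 1/n, so
the read-pair identity (a(a−1) + r(r−1))/(t(t−1)) estimates
1/n + (1 − 1/n) Q1 and is inverted for an unbiased Q1. Between pools the
read-frequency product is already unbiased for Q2. Per site,
FST = (Q1̄ − Q2)/(1 − Q2); the window value is the ratio of summed
numerators to summed denominators, excluding sites with no variation in
either pool. The moment conditions are exactly unbiased under the null; the
*per-site ratio* carries a small O(var²) negative bias (~7e-4 at p = 0.5,
n = 60, depth 85), which is precisely why multi-locus FST is reported as a
ratio of sums. Accuracy is pinned by a genotype-level Weir–Cockerham oracle
on Balding–Nichols populations with true FST 0.2: the window estimate
agrees with the oracle to < 0.02 absolute.

## The outlier scan and its envelope

The scan depends only on ranks: exactly ceil(0.01 n) sites are flagged
genome-wide (ties broken by stable site order), each window's flag count is
tested against Binomial(k, 0.01), and window calls compare the per-window
flag count of each replicate pool against the 95% nearest-rank quantile of
the same statistic computed on neutral-introgression simulations of the
same parental scenario. A window is called only when **all** F16 replicates
strictly exceed the envelope — a deliberately conservative AND rule whose
family-wise false-call rate is measured (not assumed) in the test suite.
"Rank-normalization" of FST is implemented as rank-based flagging only; no
Gaussian transform is applied, since every downstream quantity depends only
on ranks. The enrichment p is a discrete statistic; its null calibration is
therefore verified on the flag-count distribution and on tail probabilities
(super-uniformity), not with a continuous KS test.

The Fisher scan aggregates all F16 pools into one synthetic pool
(element-wise read sums), forms [[alt_syn, ref_syn], [alt_VT, ref_VT]] per
site, and reports two-sided exact p-values (sidedness is a package choice:
the scan is direction-agnostic), filtered at pooled minor-allele frequency
> 0.05, with BH q-values and the Bonferroni threshold alpha/m.

## Ecological association tests

Lagged summaries (mean, sample SD, max, min) are computed over the
`lag_days` consecutive days ending on the collection date, erroring on any
gap. The seasonality test is a binomial GLM whose successes are
round(freq × n_e) (round-half-even; the binomial denominator is the rounded
effective coverage, so pools contribute in proportion to their information),
with year and locality factors in the null model and the z-scored summary
added in the full model; significance is the 1-df LRT. Environmental values
are z-scored, so coefficients are per-SD and affine-invariant. Permutations
shuffle the environmental values within locality (preserving the factor
structure); the reported proportion counts permuted LRT statistics strictly
below the observed one on a 1/n_perm grid. Colocalization joins are
site-keyed with strict thresholds (clinal q < 0.05, seasonal p < 0.004).

## Line panels and expression

The epistasis test models per-line survival proportions with both focal-locus
main effects, their interaction, and optional covariates (symbiont status and
two inversion genotypes), using Type-III sums of squares with sum-to-zero
contrasts because the genotype classes are unbalanced; an assay-size-weighted
WLS variant is available behind a flag. Line-level uncertainty uses exact
Clopper–Pearson intervals from beta quantiles.

The expression test fits, per gene, a negative-binomial GLM with log link,
log normalization-factor offsets, and background × temperature interaction;
dispersion is estimated per gene by maximum likelihood with (i) a boundary
likelihood-ratio guard — if the NB log-likelihood improves on the Poisson
fit by less than 2 units the Poisson fit is used, the stable zero-dispersion
limit — and (ii) a method-of-moments fallback on optimizer failure. Wald
p-values per interaction contrast are BH-adjusted across genes. Offset
invariance is exact for the Poisson score; under NB weighting rescaling
shifts estimates at the 1e-3 level, which the tests bound explicitly. The
asymptotic Wald null is visibly anticonservative below ~8 replicates per
design cell; calibration is therefore demonstrated at 10 replicates per
cell, while power claims use the design's 3 replicates per cell.

## The synthetic-data generators

All generators derive sub-streams from the master seed as
`default_rng([seed, *counters])`, making every replicate independent and
bit-reproducible, and every generator emits its truth table.

- **Parental backgrounds**: by default, VT and SK frequencies are drawn
  independently from Beta(0.8, 0.8) truncated to [0.05, 0.95] — an
  intermediate-frequency spectrum resembling what pool-seq variant filters
  retain, with no claim about the real joint spectrum. A `correlated`
  constructor instead draws both parents around a shared ancestral frequency
  with Balding–Nichols divergence (default F = 0.1); this is the variant
  used in scan power studies, because in a real parental pair most of the
  genome is shared polymorphism and the divergence is concentrated at focal
  loci. Under the independent-background variant every window is maximally
  divergent, residual-ancestry noise saturates the flag budget, and no
  desk-scale scenario separates a selected window from the envelope.
- **Selection** in the F16 generator weights bottleneck survivors by
  1 + s × (tropical-allele dosage) at the focal loci — a genotype-level
  stand-in for the experiment's selection on phenotype. Because selection
  and backcross dilution balance, the equilibrium frequency of a single
  strongly selected allele is ≈ 0.36 starting from a VT frequency of 0 (the
  survivor pool reaches (1 + p)/2 and is then halved toward p_VT), closely
  matching the shift magnitudes that motivate this design. The
  `demo_scan_scenario` plants 8 SK-fixed differences under strong selection
  in one of twelve 75 kb windows.
- **Seasonal series**: daily temperature is a sinusoidal annual cycle plus
  AR(1) noise (phi 0.7, sd 2); collections are spread June–October over
  three years at one locality, 10 per year, mirroring a temperate seasonal
  sampling design. The true frequency is
  invlogit(logit(0.6) + beta × z(summary)) with beta defaulting to −0.089
  per SD of the 45-day temperature SD; observation adds the two-step pool
  noise at 30 diploids / 85×.
- **Line panels**: 64 lines, class frequencies (0.12, 0.35, 0.20, 0.33) for
  (tropical/tropical, tropical/temperate, temperate/tropical,
  temperate/temperate) — approximately the observed mix of homozygous
  combinations in reference panels — 100 embryos per line, baseline
  survival 0.25, and a +1.5 logit epistatic shift confined to the doubly
  tropical class. Covariates are generated with no effect.
- **Expression counts**: negative-binomial with gene-specific baselines
  (50–800 expected counts), background and temperature main effects
  ~N(0, 0.3) on the log scale, dispersion 0.1, log-normal normalization
  factors, and the interaction applied to carrier genes in the heated
  condition of non-reference backgrounds.

What the generators deliberately do **not** emulate: real linkage
disequilibrium and haplotype structure (the linkage-equilibrium start), 
inversions, demography, X hemizygosity, reference bias, or mapping/calling
artifacts. Passing tests therefore demonstrate the statistical machinery is
correct and calibrated under the design's sampling model — not that the
scan's power on real fly data equals the synthetic power.

## Numerical choices and problem sizes

Windows are 1-based inclusive; sliding PCA windows are half-open
[start, start + 100 kb) stepped by 50 kb, skipping windows with fewer than
2 polymorphic sites. The envelope quantile is nearest-rank
(ceil(q·n)-th order statistic). Degenerate fits (constant environment,
separation) raise a dedicated error rather than returning silently; a
sample coincident with a parent in PC space yields a signed-infinity
sentinel excluded from averages. Test and acceptance simulations use
desk-scale problem sizes — windows of tens of SNPs, 25–50 envelope
replicates, 12–50 pipeline runs — while the population-design constants
(K = 1500, 16 generations, 80% bottleneck, 300 migrants, 30-diploid pools
at 85×) are never scaled. The reference line-panel comparison (interaction
F(1,55) = 11.22) requires the study's deposited panel table, which is not
redistributable with this package; the corresponding acceptance test looks
for `data/dgrp_panel.csv` and fails with a clear message when absent.
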