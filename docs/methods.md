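# Methods

## Model

The locus has four allele classes: W (wild type; the only cleavable class),
D (the drive cassette; cleavage-resistant, disrupts the gene), r1
(cleavage-resistant, functional) and r2 (cleavage-resistant, null). The
target is a haplosufficient female-fertility gene: females need at least one
functional allele (W or r1) to reproduce; D/D, D/r2 and r2/r2 females are
sterile. Males are unaffected by the target gene.

**Germline transform.** In a germline stem cell pairing D with W, the W
allele is cut with probability *c*; a cut resolves by homology-directed
repair (fraction *hdr*, producing a second D — homing) or by end-joining
(fraction *ρg* of which is functional, → r1; else r2). Gametes then
segregate Mendelianly from the post-repair pair, so drive transmission is
*p* = (1 + *c·hdr*)/2 and the homed fraction of non-drive chromosomes is
*h* = 2*p* − 1 = *c·hdr*. Cell pairs without both D and W segregate
Mendelianly — there is no cleavage without a drive allele and a cleavable
target in the same cell.

**Embryo transform.** Nuclease deposited by a drive-carrying mother (rate
*d_m*) or father (*d_p*) cuts each zygotic W allele independently; when both
parents carry the drive the exposures combine independently,
1 − (1 − *d_m*)(1 − *d_p*). A cut resolves by HDR from the homologous
chromosome of the zygote (so a D/W embryo can be "homed" in the soma, a
W/r1 embryo copies r1) with fraction *hdr_e*, else by end-joining (r1 with
*ρe*, r2 otherwise). The modified pair enters a fraction *m* of the germline
stem cells; the rest retain the zygotic pair. Mosaicism is collapsed to this
two-component mixture; somatic fitness costs are read from the fitness table
keyed by (zygotic genotype, exposure) rather than simulated per cell —
matching the resolution at which such data are reported. An individual's
gamete distribution is the mixture over its germline components, and the
deposition flag passed to its offspring is per component (a gamete from a
D-containing cell exposes the embryo regardless of which allele it
transmits).

**Deterministic recursion.** Infinite population, discrete generations,
random mating, fair sex ratio. Female classes are weighted by fecundity
multipliers, male classes by fitness multipliers applied at mate choice;
gametes unite at random; every zygote passes through the embryo transform.
Two exact limits are used as oracles: with all rates zero and flat fitness
the drive is a neutral Mendelian marker (constant allele frequency), and
with end-joining, deposition and costs off the allele frequency follows
*q'* = *q* + *h·q*(1 − *q*) (from the first post-release generation, once
genotypes are in Hardy–Weinberg proportions; the release itself — pure
heterozygotes — is not). The egg-output index is the fecundity-weighted mean
of the female pool; multipliers are relative to wild type, so the index is
self-normalised to 1 for an all-wild-type population (an explicit
normalisation constant can be supplied instead, since experimental egg
counts are normalised to an observed generation). Total reproductive output
of zero freezes the trajectory with an extinction flag.

**Stochastic cage.** Individual-based with class-count bookkeeping: each
female fails to mate with a fixed probability, otherwise mates once with a
male drawn from the fitness-weighted male pool; her egg number is drawn with
replacement from an empirical clutch-size table scaled by her genotype's
fecundity multiplier; eggs hatch with a per-maternal-genotype hatch
probability; a fixed number of larvae (carrying capacity, 600) is drawn
without replacement (all, if fewer hatched); larvae survive to adulthood
independently; sexes are fair Bernoulli. All draws are binomial /
multinomial / multivariate-hypergeometric over genotype classes, so runtime
scales with class count, not census size. Replicate seeds spawn from the
master seed via `numpy.random.SeedSequence`, making ensembles reproducible
and order-independent.

## Parameters

Bundled strain files (`src/drivesim/params/*.yaml`) transcribe the measured
rates for the three characterised promoters; probabilities are decimals.

* Germline (*c*, *hdr*) per sex are solved from two measured quantities:
  transmission *p* = (1 + *c·hdr*)/2 and the mutated fraction of non-homed
  chromosomes *c*(1 − *hdr*)/(1 − *c·hdr*). For zpg: female *p* = 0.991 and
  mutated fraction 0.88 give *c* = 0.9978, *hdr* = 0.9841; male *p* = 0.92
  and 82/239 = 0.343 give *c* = 0.8949, *hdr* = 0.9387.
* Deposition: zpg 0 (none detected); nos *d_m* = 0.105; vas2 *d_m* = 0.70;
  paternal deposition 0 throughout; embryonic HDR fraction 0 (deposited-
  nuclease homing is at best minimal in this system). Mosaic fraction
  *m* = 1 — under *m* = 1 the vas2 file predicts maternally-received male
  transmission of 0.65 versus the measured 0.602, a documented cross-check
  rather than a fitted value.
* *ρg*, *ρe* (functional fraction of end-joins) are not separately measured;
  1/3 is used as the baseline — a neutral choice reflecting that one in
  three random indel frames is in-frame — and both are configurable.
* Fecundity multipliers (relative to wild type): carrier females 0.549
  (zpg), 0.555/0.397 by parental origin (nos), 0.08 (vas2); r1-carrying
  genotypes default to 1 (full restoration); nos males 0.9 at mate choice
  (reported as a general, unquantified reduction).
* Cage probabilities (mating failure 0.1, larva-to-adult survival 0.9,
  hatch 0.9) and the clutch-size table are realistic protocol-scale choices,
  not measured values; all are overridable in the YAML. The clutch table is
  over-dispersed with failed layers (mean ≈ 117).

## Synthetic data

The generators emulate: binomial marker inheritance at the true
transmission within clutches; over-dispersed clutch sizes (negative binomial
with zero-inflation); the drive/r1-balancer deposition pedigree (F2 r1/W
individuals with W converted at the true embryonic rate; F3 outcross with
4-fold dilution; finite amplicon depth); and pooled amplicon tables along a
trajectory, with abstract r1/r2 class frequencies decomposed into concrete
indel identities drawn from a Dirichlet-weighted spectrum (small
concentration, so the dominant r1 identity varies across seeds, as it does
between replicate cages). They do not emulate: batch effects between
experimental rounds, PCR/sequencing error, microhomology structure in the
indel spectrum, clustered repair within families, or linkage to anything
beyond the single locus — so passing tests demonstrate internal consistency
of the estimators and simulators, not robustness to those real-data
features.

## Numerical choices

* Classes with frequency below 1e-15 are pruned from the deterministic
  state each generation; frequencies renormalise to 1 within 1e-9.
* Proportion intervals are Wilson (via `scipy.stats.binomtest`); clutch-level
  s.e.m. is emitted alongside, since screens replicate at the clutch level.
  The depletion test is an exact one-sided binomial test against 0.5 with
  novel-R counted against WT (a deliberate simplification of multi-group
  ANOVA-style testing to a per-pool exact test).
* Sub-Mendelian transmission estimates (p < 0.5) convert to homing 0 with a
  flag rather than a negative rate.
* Amplicon coordinates are 0-based within the amplicon; the cut site is an
  inter-base coordinate and the 20-bp window is symmetric (10 bases each
  side), configurable. Registered (phenotypically confirmed) alleles win
  over rule-based classification; insertions ≥ 30 bp outside the window are
  treated as the incomplete-homing drive signature; other outside-window
  indels count as WT. In-frame/out-of-frame uses net length change mod 3
  only — no stop-codon or missense calling, which is why unregistered
  alleles are never called "confirmed". The 1% tracking threshold applies
  to the frequency among non-drive alleles (switchable to all alleles) and
  an allele exceeding it in any sampled generation is tracked in all.
* Extinction in either simulator freezes/truncates the trajectory with an
  explicit flag; ensemble summaries pad truncated replicates with NaN.

## Problem sizes

Default testing sizes: deterministic runs of 40–60 generations; stochastic
ensembles of 20 replicates at N = 600 and 200 replicates at N = 20,000 over
10 generations for the large-population agreement check (within 3 Monte
Carlo standard errors of the recursion); estimator-coverage checks use
500-progeny screens (500 replicates) and 500-individual deposition pools
(200 replicates). These sizes give stable Monte Carlo summaries at
interactive runtimes.

## Known limitations

Discrete non-overlapping generations; no age structure, density-dependent
larval mortality, spatial structure, migration or multiple mating. Alleles
are classes, not sequences (no per-site cleavage model). Exposure histories
do not extend beyond one generation (no grandparental "shadow drive": in
this system deposited-nuclease homing was assessed as at best minimal, and
the F2→F3 halving of mutation frequencies is consistent with plain Mendelian
inheritance). Fitness acts through female fecundity and male mate choice
only.
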