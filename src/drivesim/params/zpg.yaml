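# Baseline parameters, zpg-promoter drive (Cas9 under zero-population-growth
# regulatory regions, targeting the haplosufficient female-fertility locus).
#
# Germline cut/HDR rates are solved from two measured quantities per sex:
#   transmission p = (1 + c*hdr)/2   and
#   fraction of non-homed chromosomes that are mutated = c(1-hdr)/(1 - c*hdr).
# Female: p = 0.991 (no parental effect), mutated fraction 0.88 (192/218).
# Male:   p = 0.92  (93.5% paternal- / 90.6% maternal-received, averaged),
#         mutated fraction 82/239 = 0.343.
# Cross-checks: implied transmission 99.1% (female), 92.0% (male).
strain: zpg
germline:
  female:
    cut_prob: 0.997840
    hdr_frac: 0.984126
    r1_frac: 0.333333      # functional fraction of germline end-joins (choice)
  male:
    cut_prob: 0.894895
    hdr_frac: 0.938657
    r1_frac: 0.333333
# No detectable maternal or paternal deposition for this promoter.
deposition:
  cut_maternal: 0.0
  cut_paternal: 0.0
  hdr_frac: 0.0
  r1_frac: 0.333333
  germline_mosaic_frac: 1.0
fitness:
  female_fecundity:
    # heterozygous carrier females: 54.9% larval output relative to wild type
    # (residual somatic leakiness); no maternal/paternal effect observed.
    W/D: 0.549
  male_fitness: {}
cage:
  capacity: 600
  mating_failure_prob: 0.1      # not printed; realistic cage-protocol choice
  larva_survival_prob: 0.9      # not printed; realistic choice
  hatch_prob: 0.9               # baseline hatch of eggs from fertile females
  # Empirical-style per-female clutch-size table sampled with replacement
  # (over-dispersed with failed layers), stand-in for the experimental values.
  clutch_sizes: [0, 0, 12, 25, 34, 48, 55, 61, 68, 72, 79, 84, 88, 90, 95,
                 98, 102, 105, 108, 112, 115, 118, 121, 124, 127, 130, 133,
                 137, 140, 144, 148, 152, 157, 163, 170, 178, 188, 201, 215,
                 240]
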