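# Benchmark parameters, vas2-promoter drive (first-generation construct).
# Germline: paternal-received transmission 99.6% (male), 97.7% (female)
#   -> c*hdr = 0.992 / 0.954; germline EJ split not measured for this strain,
#   cut probabilities set slightly above c*hdr as for zpg.
# Deposition: strong maternal deposition, 70% of nuclease-sensitive alleles
#   end-joined in the embryo (r1-balancer screen). Cross-check (not force-fit):
#   with mosaic fraction 1 this predicts maternally-received male transmission
#   0.996 - 0.70*(0.996-0.5) = 0.65 vs the observed 60.2%.
# Fitness: heterozygous carrier females 8% fecund relative to wild type
#   (somatic leakiness); r1-balanced females used experimentally instead.
strain: vas2
germline:
  female:
    cut_prob: 0.980000
    hdr_frac: 0.973469      # product 0.954
    r1_frac: 0.333333
  male:
    cut_prob: 0.996000
    hdr_frac: 0.995984      # product 0.992
    r1_frac: 0.333333
deposition:
  cut_maternal: 0.70
  cut_paternal: 0.0
  hdr_frac: 0.0
  r1_frac: 0.333333
  germline_mosaic_frac: 1.0
fitness:
  female_fecundity:
    W/D: 0.08
  male_fitness: {}
cage:
  capacity: 600
  mating_failure_prob: 0.1
  larva_survival_prob: 0.9
  hatch_prob: 0.9
  clutch_sizes: [0, 0, 12, 25, 34, 48, 55, 61, 68, 72, 79, 84, 88, 90, 95,
                 98, 102, 105, 108, 112, 115, 118, 121, 124, 127, 130, 133,
                 137, 140, 144, 148, 152, 157, 163, 170, 178, 188, 201, 215,
                 240]
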