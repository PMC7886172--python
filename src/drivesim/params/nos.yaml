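# Parameters, nos-promoter drive.
# Germline from paternal-received transmission: 99.6% (female), 99.1% (male)
#   -> c*hdr = 0.992 / 0.982; EJ split not measured, cut set slightly higher.
# Deposition: moderate maternal deposition, 10.5% of nuclease-sensitive
#   alleles end-joined in the embryo; no significant paternal deposition.
# Fitness: carrier females 55.5% (paternal-received) / 39.7% (maternal-
#   received) relative larval output; a general unquantified reduction in
#   male fecundity is represented as a 0.9 mate-choice multiplier.
strain: nos
germline:
  female:
    cut_prob: 0.996000
    hdr_frac: 0.995984      # product 0.992
    r1_frac: 0.333333
  male:
    cut_prob: 0.990000
    hdr_frac: 0.991919      # product 0.982
    r1_frac: 0.333333
deposition:
  cut_maternal: 0.105
  cut_paternal: 0.0
  hdr_frac: 0.0
  r1_frac: 0.333333
  germline_mosaic_frac: 1.0
fitness:
  female_fecundity:
    W/D: 0.555
    W/D|maternal: 0.397
  male_fitness:
    W/D: 0.9
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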