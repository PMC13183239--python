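# Default synthetic vineyard: 12 cultivars / 7 varieties, 3 rows x 5 vines.
#
# Trait means, total SDs and hierarchical variance proportions follow the
# descriptive statistics and variance partitioning of a published
# 12-cultivar vineyard panel; proportions omit the residual, which is the
# shortfall from 1. For traits whose published summary is reported on the
# log scale (median + CV), mean is taken as the median and total_sd as
# CV * median / 100.
#
# Spectral links are this simulator's own forward-model choices: each trait
# is written into the spectrum as a Gaussian absorption feature at a
# physiologically sensible location (red edge for photosynthesis-linked
# traits, 1450/1940 nm water bands for water relations, SWIR dry-matter
# bands for structural traits). d13C is linked only weakly, emulating a
# trait the spectrum barely encodes.

design:
  n_cultivars: 12
  n_varieties: 7
  rows_per_cultivar: 3
  vines_per_row: 5

missing_rate: 0.03
spectral_noise_sd: 0.002

traits:
  E:
    mean: 3.24
    total_sd: 1.13
    proportions: {origin: 0.42, cultivar: 0.38, row: 0.08}
  A_max:
    mean: 21.83
    total_sd: 3.35
    proportions: {origin: 0.27, row: 0.19}
  g_s:
    mean: 0.26
    total_sd: 0.08
    proportions: {cultivar: 0.54, row: 0.15}
  N:
    mean: 2.75
    total_sd: 0.35
    proportions: {red_white: 0.12, row: 0.05}
  C:
    mean: 45.81
    total_sd: 0.78
    proportions: {origin: 0.08, cultivar: 0.32}
  d13C:
    mean: -27.88
    total_sd: 1.22
    proportions: {row: 0.08}
  Psi_pd:
    mean: -5.88
    total_sd: 1.47
    proportions: {red_white: 0.18, cultivar: 0.21, row: 0.07}
  WUE_intr:
    mean: 85.51
    total_sd: 25.07
    proportions: {cultivar: 0.52, row: 0.15}
  WUE_inst:
    mean: 6.70
    total_sd: 2.28
    proportions: {origin: 0.59, cultivar: 0.29, row: 0.04}
  Area:
    mean: 150.74
    total_sd: 34.30
    proportions: {origin: 0.15, cultivar: 0.09}
  LDMC:
    mean: 255.69
    total_sd: 21.98
    proportions: {red_white: 0.09, cultivar: 0.05}
  LMA:
    mean: 70.51
    total_sd: 6.75
    proportions: {cultivar: 0.04}

links:
  - {trait: A_max, center: 705, width: 30, strength: 0.10}
  - {trait: E, center: 1450, width: 45, strength: 0.08}
  - {trait: g_s, center: 715, width: 35, strength: 0.06}
  - {trait: g_s, center: 1940, width: 50, strength: 0.03}
  - {trait: N, center: 1510, width: 40, strength: 0.05}
  - {trait: N, center: 705, width: 25, strength: 0.05}
  - {trait: C, center: 2100, width: 60, strength: 0.05}
  - {trait: d13C, center: 705, width: 30, strength: 0.004}
  - {trait: Psi_pd, center: 1940, width: 55, strength: 0.05}
  - {trait: WUE_intr, center: 705, width: 45, strength: 0.03}
  - {trait: WUE_inst, center: 1450, width: 60, strength: 0.03}
  - {trait: Area, center: 750, width: 60, strength: 0.04}
  - {trait: LDMC, center: 2100, width: 80, strength: 0.08}
  - {trait: LDMC, center: 550, width: 40, strength: 0.03}
  - {trait: LMA, center: 1720, width: 60, strength: 0.06}
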