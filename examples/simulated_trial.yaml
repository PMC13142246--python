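# A synthetic trial at the reference design size: 6 environments x 12
# genotypes x 3 blocks, 13 traits, with genotype variance 48, interaction
# variance 3.4 and residual variance 110 on every trait (grain-yield-like
# magnitudes).
traits:
  - {code: PH}
  - {code: LC}
  - {code: INC}
  - {code: INL}
  - {code: SD}
  - {code: LW}
  - {code: LL}
  - {code: PL}
  - {code: PDW}
  - {code: LWW}
  - {code: BRIX}
  - {code: SWW}
  - {code: GY}
simulation:
  e: 6
  v: 12
  r: 3
  p: 13
  grand_means: [150, 12, 10, 18, 1.8, 7, 70, 25, 40, 120, 12, 180, 35]
  block_sd: 1.0
  env_sd: 4.0
  gen_sd: 6.9
  ge_sd: 1.85
  residual_cov: null   # identity scaled below is the default (unit variance)
intensity: 0.15
gge_traits: [GY, SWW]
outdir: metsel_out
seed: 1
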