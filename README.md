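# metsel

Selection analysis for balanced multi-environment trials (METs): which
genotypes to keep when the same set of varieties is evaluated across
several environments in a replicated randomized complete block design, and
which environments are worth testing in.

`metsel` is aimed at plant-breeding and agronomy workflows where three
questions recur:

1. **Is there anything to select on?** A balanced two-factor-with-blocks
   MANOVA with Pillai trace tests establishes whether genotype and
   genotype-by-environment (GE) effects are significant across the whole
   trait vector.
2. **Which genotype is closest to the ideal across many traits?** The
   multi-trait genotype-ideotype distance index (MGIDI) collapses a
   correlated trait panel into a few orthogonal factors and ranks
   genotypes by their distance to a hypothetical ideotype.
3. **Who wins where, and which environment is most informative?** GGE
   biplots (genotype + GE effects after removing environment means)
   partition environments into mega-environments, rank genotypes by mean
   performance and stability, and rank environments by discriminating
   ability and representativeness.

A synthetic trial generator with recorded ground truth makes every stage
testable without any field data.

## The models

**Trial model.** Observations follow the additive replicated-trial model

```
Y_ijkt = mu_t + beta_kt + E_it + V_jt + (EV)_ijt + eps_ijkt
```

for trait `t` of genotype `j` in environment `i`, block `k`, with
multivariate-normal residual vectors `eps ~ N(0, Sigma)` across traits.
On the complete balanced layout the sums-of-squares-and-cross-products
decomposition is closed form; each effect is tested with the Pillai trace
`V = tr(H (H + E)^-1)` and the standard approximate-F transform

```
s = min(p, q_h),  m = (|p - q_h| - 1)/2,  n = (q_e - p - 1)/2
F = [(2n + s + 1)/(2m + s + 1)] * (V/s)/(1 - V/s)
df1 = s(2m + s + 1),  df2 = s(2n + s + 1)
```

**MGIDI.** Each trait column of a two-way mean table is linearly rescaled
to 0–100 with 100 at the desirable end (`maximize` or `minimize` per
trait), standardized, and factor-analysed: factors with correlation-matrix
eigenvalue > 1 are retained, varimax-rotated, and regression scores
`S = Z R^-1 A` are computed for every genotype and for the all-100
ideotype row.  The index is the Euclidean distance
`MGIDI_i = [ sum_f (S_if - gamma_f)^2 ]^0.5`; smallest distance = best, and
per-factor shares of the squared distance expose each genotype's strengths
and weaknesses.

**GGE.** For one trait, the genotype-by-environment mean matrix is
environment-centered (`m_ij = Ybar_ij - mean_i Ybar_ij`) and decomposed by
SVD with singular value partitioning `m_ij = sum_k (l_k^a u_ik)(l_k^(1-a)
v_jk)`; `a = 1` (genotype-focused) drives which-won-where and
mean-vs-stability, `a = 0` (environment-focused) drives environment
evaluation.

## Worked example

Run the full pipeline on a bundled synthetic trial configuration
(6 environments x 12 genotypes x 3 blocks, 13 traits, genotype variance
48, interaction variance 3.4 per unit residual trait):

```sh
metsel all --config examples/simulated_trial.yaml --outdir demo --seed 1
```

`demo/report.md` then contains (abridged):

```
## MANOVA (Pillai trace)

     effect  Df  Pillai  approx_F  num_Df  den_Df      p_value
      block   2 1.76695   76.4006      26     262 1.09357e-106
environment   5 4.83507   302.177      65     670            0
   genotype  11 10.2479    146.73     143    1540            0
interaction  55 10.0899   8.95157     715    1846 1.00038e-312

## GGE biplot (GY)

PC1 95.63%, PC2 1.75% (PC1+PC2 97.37%) of GGE variation.

Mega-environments:
- E1, E2, E3, E4, E5, E6 won by V3
- unresponsive vertex genotypes: V4, V11, V8, V12

Top-ranked (most discriminating and representative) environment: E6
```

Reading this: the degrees of freedom (26, 262), (65, 670), (143, 1540),
(715, 1846) follow from the design dimensions alone; all effects are
significant, so both mean tables are worth analysing.  In this simulation
genotype main effects dominate the interaction, so PC1 carries 95.6% of
the GGE variation and a single genotype (V3) wins every environment — one
mega-environment — while four polygon-vertex genotypes win nowhere.  E6 is
the environment whose score vector is long (discriminating) and closest in
angle to the average-environment axis (representative).  The per-stage CSV
tables (`mgidi_overall.csv`, `gge_GY_sectors.csv`, `loadings_*.csv`, ...)
carry the full-precision numbers behind the report, and `--plots` adds SVG
renderings of the six biplot views.

Real data enter the same way with `--input trial.csv --traits
examples/traits_sorghum.yaml`, where the CSV has `ENV,GEN,REP` columns
plus one column per trait; the loader enforces full balance (every
environment x genotype x block cell exactly once) because the closed-form
decomposition assumes it.

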