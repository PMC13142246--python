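# Methods

This note records the statistical models implemented in `metsel`, the
numerical conventions chosen where several were defensible, what the
synthetic-data generator does and does not emulate, and the known
limitations.

## Trial model and MANOVA

The data model is a fully balanced replicated two-factor trial: every
genotype appears once per block, every block in every environment, with
`p` traits per plot,

    Y_ijkt = mu_t + beta_kt + E_it + V_jt + (EV)_ijt + eps_ijkt,

residual vectors across traits multivariate normal with positive-definite
covariance `Sigma`.  Balance is a hard requirement: the SSCP decomposition,
the Pillai tests and the contrast standard errors are closed-form only on
the complete grid, and silent imputation would change every downstream
statistic.  No imputation mode is provided; unbalanced data are rejected at
validation with an explicit list of missing/duplicated cells.

Hypothesis SSCP matrices are between-group outer products of marginal
means (block, environment, genotype) and of double-centered cell means
(interaction); the residual SSCP is the remainder of the total corrected
SSCP, so additivity holds to machine precision and is asserted in tests.
The Pillai trace `V = tr(H (H+E)^-1)` is mapped to an approximate F with

    s = min(p, q_h), m = (|p - q_h| - 1)/2, n = (q_e - p - 1)/2,
    F = [(2n+s+1)/(2m+s+1)] (V/s)/(1 - V/s),
    df1 = s(2m+s+1), df2 = s(2n+s+1).

With `p = 1` this reduces exactly to the univariate ANOVA F.  At the
boundary `V = s` the F statistic is reported as infinite with a warning
rather than an error, since degenerate (noise-free) inputs are legitimate
in testing.  The implementation is validated against a sum-coded
`statsmodels` MANOVA on the same data (agreement to ~1e-8) and against a
type-I-error simulation (nominal 5% within ±1.5% over 1,000 null trials).

Variance components use method-of-moments on expected mean squares:

    s2_res = MS_res,          s2_ge  = (MS_ge - MS_res)/r,
    s2_gen = (MS_gen - MS_ge)/(e r),  s2_block = (MS_block - MS_res)/(e v).

Negative estimates are reported with a flag, never truncated, so
recovery tests stay unbiased.  Contrasts of genotype cell means within an
environment use the pooled single-trait residual mean square (df = q_e);
for one-vs-rest the standard error is `sqrt(MS_res (1/r)(1 + 1/(v-1)))`,
for pairwise `sqrt(2 MS_res / r)`.  P-values are raw (no multiplicity
correction).

## MGIDI

1. **Rescaling.** Each trait column of a two-way mean table (genotype
   means, or genotype-environment cell means) is mapped linearly onto
   [0, 100] with 100 at the desirable end.  For a maximize trait the
   observed maximum maps to 100; for a minimize trait the observed minimum
   does.  Constant columns are an error (the map is undefined), not a
   silent drop.
2. **Weighting.** Optional per-trait weights (prior importance) multiply
   the rescaled columns before standardization, normalized to mean 1 so a
   common rescaling of all weights is inert.  Because columns are
   standardized afterwards, weights act through the correlation structure
   (relative leverage), not through raw scale.  The unweighted mode is the
   default and the reference behavior; where external weights are used
   they should be reported alongside results.
3. **Factor analysis.** The correlation matrix of the standardized
   (weighted) columns is eigendecomposed; factors with eigenvalue
   strictly > 1 are retained (Kaiser rule, no tolerance band — the
   boundary case of perfectly uncorrelated traits legitimately retains
   nothing and raises a retention error).  Initial loadings are
   eigenvector x sqrt(eigenvalue); varimax rotation is applied.
   Explained variance is reported as cumulative eigenvalue / p.
4. **Scores and ideotype.** Regression factor scores `S = Z R^-1 A` are
   computed for all rows and for the ideotype — the all-100 row passed
   through the identical weighting and standardization constants.  The
   index is the Euclidean distance to the ideotype in factor-score space;
   ranking is ascending and selection keeps `ceil(intensity * n)` rows
   (default intensity 0.15, which keeps 2 of 12).  Exact ties keep the
   original row order and are logged.
5. **Strengths and weaknesses.** Per-factor shares
   `(S_if - gamma_f)^2 / sum_f (S_if - gamma_f)^2`; a zero-distance row
   receives uniform shares with a log flag.

Numerical conventions: varimax uses the raw criterion (sum over factors of
the variance of squared loadings) via the standard SVD update, iterated to
relative criterion change < 1e-6 (max 1,000 sweeps), without Kaiser row
normalization — the plain criterion is what the 1-D angle-scan oracle in
the tests optimizes, and the distances are invariant to the choice.  After
rotation each factor's sign is flipped so its largest-magnitude loading is
positive; this is cosmetic (all distances are invariant under joint sign
flips and permutations of factors, which is asserted as a property test).
Dominant-factor reporting lists every factor with |loading| >= 0.5, so a
trait may appear under several factors.

## GGE biplots

For one trait the genotype x environment mean matrix is
environment-centered (column means removed), leaving genotype main effects
plus GE interaction.  The SVD with singular-value partitioning exponent
`a` allocates each singular value to genotype scores (`a = 1`) or
environment scores (`a = 0`); the full product of scaled score pairs
reconstructs the centered matrix exactly for either exponent (asserted at
machine precision).  Geometry uses the first two components, as biplots
do; the SVD is retained in full for invariance checks and so that the
environment-relationship cosines at full rank equal the column
correlations of the centered matrix.

Conventions and degenerate cases:

* **Sign.** Each PC is flipped so its environment-score sum is >= 0
  (genotype sum breaks exact-zero ties) — output is deterministic across
  linear-algebra backends, and every reported quantity is sign-invariant.
* **Sectors.** The convex hull of genotype points is traversed
  counterclockwise; boundary rays are the outward edge normals (the rays
  from the origin perpendicular to the hull edges).  Because genotype
  scores sum to zero, the origin is interior and the normal cone of each
  vertex is a well-defined angular interval.  An environment exactly on a
  boundary ray is assigned to the counterclockwise sector and logged.  A
  collinear genotype cloud raises a geometry error rather than guessing a
  polygon.
* **AEC.** The average-environment axis is the unit vector toward the mean
  environment point; a mean at the origin is an error (axis undefined).
  Genotype projections on the axis are signed mean performance, the
  perpendicular component signed instability; the ideal genotype sits on
  the axis at the maximum projection, and ranks are by distance to it with
  ties broken by label and flagged.
* **Environment metrics.** Vector length = discriminating ability; cosine
  to the AEC axis = representativeness; the ideal environment is the axis
  direction scaled to the maximum length.  Zero-length environment vectors
  get length 0 with an undefined-angle flag.  Environment evaluation uses
  the environment-focused partitioning (`a = 0`), matching that
  partitioning's stated purpose; genotype evaluation and mega-environment
  delineation use `a = 1`.

On an exactly-rank-2 centered matrix the 2-PC biplot is exact, so the
sector winner of every environment must equal the per-environment argmax
of the centered matrix; the test suite checks this exhaustively on 100
random rank-2 instances from the generator below.  On real (higher-rank)
data the biplot winner is an approximation whose quality is bounded by the
PC1+PC2 explained share, which is always reported.

## Synthetic trials

`simulate_met` draws every effect independently normal (per-trait or
scalar SDs) and residual vectors multivariate normal with arbitrary
`Sigma`, then **re-centers each effect to sum to zero** within its index
(the interaction is double-centered).  This makes the recorded truth equal
the estimand of the balanced decomposition, so parameter-recovery tests
are exact in expectation rather than approximate.  Each effect uses its
own child random stream (fixed spawn order), so enlarging one variance
component leaves the other sampled effects untouched — paired-seed tests
exploit this (e.g. doubling `Sigma` exactly doubles the residual mean
square).  A factor-structured option `Sigma = Lambda Lambda' + diag(psi)`
gives factor-analysis recovery tests a known loading matrix.

`simulate_rank2_means` builds genotype-environment mean tables whose
centered matrix has exactly two prescribed singular values (genotype-side
directions drawn orthonormal and orthogonal to the all-ones vector, so
environment-centering removes exactly the added environment offsets).  It
is the geometry oracle for the GGE module.

Default study conditions used in the tests mirror the reference trial:
6 environments x 12 genotypes x 3 blocks x 13 traits, genotype variance
48, interaction variance 3.4, residual variance 110 in grain-yield units.
Distributional checks use deliberately smaller designs (type-I error at
4 x 8 x 3 with 3 traits over 1,000 replicates; component recovery with a
single trait over 500 replicates) — sizes chosen so the whole suite stays
a desk-scale computation while the Monte-Carlo standard errors remain
small enough for 3-SE assertions to have teeth.

What the generator does *not* emulate: spatial field trend and plot-level
autocorrelation, heteroscedastic environments, unbalanced or incomplete
layouts, non-normal traits (counts, percentages near their bounds).
Passing tests therefore demonstrate correctness of the estimators and
geometry under the stated model, not robustness to field artefacts; for
data with strong spatial structure a spatially adjusted mixed-model
pre-analysis would be needed upstream of this package.

## Pipeline conventions

The CLI pipeline writes full-precision CSV tables (`%.10g`), a YAML
manifest of parameters and seed, a run log capturing every triggered
design decision (ties, boundary sectors, negative variance components,
zero-distance rows), and a markdown report that contains no information
absent from the CSVs (reports round to 6 significant digits).  Identical
configuration and seed produce byte-identical outputs; stages are
isolated, so toggling one stage does not change another's files.  MGIDI is
run on genotype means, on genotype-environment combinations, and within
each environment; GGE runs per requested trait in both partitioning
modes.

## Known limitations

* Balanced complete designs only; no REML / mixed-model path, no
  missing-data handling beyond rejection.
* Only the Pillai trace is implemented (no Wilks/Roy/Hotelling), as it is
  the statistic this analysis standardizes on.
* Selection gains per trait and alternative indices (FAI-BLUP,
  Smith-Hazel) are out of scope.
* With a single trait the MGIDI stage is undefined (the 1 x 1 correlation
  matrix has eigenvalue exactly 1, retaining nothing); single-trait
  studies should use the GGE stage, which is per-trait by construction.
* Biplot geometry is a 2-PC approximation on real data; sector winners are
  exact only when the centered matrix has rank <= 2.
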