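"""Synthetic multi-environment trials with recorded ground truth.

The generator draws from the additive replicated-trial model

    Y_ijkt = mu_t + beta_kt + E_it + V_jt + (EV)_ijt + eps_ijkt

with independent normal block, environment, genotype and interaction
effects and multivariate-normal residual vectors of arbitrary trait
covariance.  Sampled effects are re-centered to sum to zero within each
index so that the recorded truth coincides exactly with the estimand of the
balanced ANOVA decomposition — parameter-recovery tests are then unbiased
by construction.

A second generator builds genotype-environment mean tables whose
environment-centered matrix has exactly rank 2 with chosen singular
values; on such tables the 2-PC biplot geometry is exact, which gives the
GGE module a brute-force oracle (the sector winner must be the plain
per-environment argmax).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import MeanTable, MetDataError, TraitSpec, TrialDataset

__all__ = ["SimulationParams", "TruthRecord", "simulate_met", "simulate_rank2_means"]

# fixed spawn order of the per-effect random sub-streams; adding a new effect
# must append, never reorder, to keep existing seeds stable
_STREAMS = ("block", "env", "gen", "ge", "residual")


@dataclass
class SimulationParams:
    """Inputs of the trial simulator.

    Standard deviations may be scalars or per-trait vectors (length ``p``),
    in trait units.  ``residual_cov`` is the p x p positive-definite
    covariance of the within-plot residual vector across traits.
    """

    e: int
    v: int
    r: int
    p: int
    grand_means: np.ndarray
    block_sd: float | np.ndarray = 0.0
    env_sd: float | np.ndarray = 1.0
    gen_sd: float | np.ndarray = 1.0
    ge_sd: float | np.ndarray = 0.5
    residual_cov: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.e, self.v) < 2 or self.r < 1 or self.p < 1:
            raise MetDataError("need e >= 2, v >= 2, r >= 1, p >= 1")
        self.grand_means = np.broadcast_to(
            np.asarray(self.grand_means, dtype=float), (self.p,)
        ).copy()
        if self.residual_cov is None:
            self.residual_cov = np.eye(self.p)
        self.residual_cov = np.asarray(self.residual_cov, dtype=float)
        if self.residual_cov.shape != (self.p, self.p):
            raise MetDataError("residual_cov must be p x p")
        if not np.allclose(self.residual_cov, self.residual_cov.T):
            raise MetDataError("residual_cov must be symmetric")
        try:
            self._chol = np.linalg.cholesky(self.residual_cov)
        except np.linalg.LinAlgError:
            raise MetDataError("residual_cov must be positive definite") from None
        for name in ("block_sd", "env_sd", "gen_sd", "ge_sd"):
            sd = np.broadcast_to(
                np.asarray(getattr(self, name), dtype=float), (self.p,)
            ).copy()
            if np.any(sd < 0):
                raise MetDataError(f"{name} must be >= 0")
            setattr(self, name, sd)


@dataclass
class TruthRecord:
    """Ground truth behind one simulated dataset.

    Effects are centered (sum to zero within their index; the interaction is
    double-centered).  ``noiseless_means`` is the expectation of the
    genotype-environment cell mean: mu + E + V + EV.
    """

    params: SimulationParams
    block_effects: np.ndarray  # (r, p)
    env_effects: np.ndarray  # (e, p)
    gen_effects: np.ndarray  # (v, p)
    ge_effects: np.ndarray  # (e, v, p)
    noiseless_means: MeanTable

    def winners(self, trait: str | None = None) -> dict[str, str]:
        """Per environment, the genotype with the highest noiseless mean of
        the given trait (the quantity a which-won-where view estimates)."""
        frame = self.noiseless_means.to_frame()
        col = frame[trait] if trait else frame.iloc[:, 0]
        wide = col.unstack(level=0)  # index GEN, columns ENV
        return {env: str(wide[env].idxmax()) for env in wide.columns}


def _centered_normal(rng: np.random.Generator, sd: np.ndarray,
                     n: int, p: int) -> np.ndarray:
    eff = rng.standard_normal((n, p)) * sd
    return eff - eff.mean(axis=0, keepdims=True)


def simulate_met(params: SimulationParams) -> tuple[TrialDataset, TruthRecord]:
    """Draw one balanced trial dataset plus its :class:`TruthRecord`.

    Identical ``params`` (including seed) give bit-identical output.  Each
    effect uses its own child random stream so that, e.g., enlarging the
    residual covariance leaves the sampled genotype effects untouched.
    """
    ss = np.random.SeedSequence(params.seed)
    rngs = dict(zip(_STREAMS, (np.random.default_rng(c) for c in ss.spawn(len(_STREAMS)))))
    e, v, r, p = params.e, params.v, params.r, params.p

    beta = _centered_normal(rngs["block"], params.block_sd, r, p)
    env = _centered_normal(rngs["env"], params.env_sd, e, p)
    gen = _centered_normal(rngs["gen"], params.gen_sd, v, p)

    ge = rngs["ge"].standard_normal((e, v, p)) * params.ge_sd
    ge = ge - ge.mean(axis=0, keepdims=True)
    ge = ge - ge.mean(axis=1, keepdims=True)

    z = rngs["residual"].standard_normal((e, v, r, p))
    resid = z @ params._chol.T

    y = (
        params.grand_means[None, None, None, :]
        + beta[None, None, :, :]
        + env[:, None, None, :]
        + gen[None, :, None, :]
        + ge[:, :, None, :]
        + resid
    )

    env_labels = [f"E{i + 1}" for i in range(e)]
    gen_labels = [f"V{j + 1}" for j in range(v)]
    rep_labels = [f"R{k + 1}" for k in range(r)]
    traits = [TraitSpec(code=f"T{t + 1}") for t in range(p)]
    dataset = TrialDataset(env_labels, gen_labels, rep_labels, traits, y)

    cell_means = (
        params.grand_means[None, None, :]
        + env[:, None, :]
        + gen[None, :, :]
        + ge
    )
    rows = [(ei, gj) for ei in env_labels for gj in gen_labels]
    truth_table = MeanTable(
        row_labels=rows,
        trait_codes=[t.code for t in traits],
        values=cell_means.reshape(e * v, p),
        kind="by_genotype_environment",
    )
    truth = TruthRecord(params, beta, env, gen, ge, truth_table)
    return dataset, truth


def simulate_rank2_means(e: int, v: int, singular_values, seed: int,
                         grand_mean: float = 50.0,
                         env_spread: float = 5.0) -> MeanTable:
    """Genotype-environment mean table (single trait) whose
    environment-centered matrix has exactly two nonzero singular values.

    The centered matrix is built as ``s1 * u1 v1' + s2 * u2 v2'`` with
    random orthonormal directions, the genotype-side directions orthogonal
    to the all-ones vector so that centering is exact.  Environment main
    effects and a grand mean are added on top; environment-centering removes
    them again, recovering the rank-2 core bit-exactly up to rounding.
    """
    singular_values = np.asarray(singular_values, dtype=float)
    if e < 3 or v < 3:
        raise MetDataError("rank-2 geometry needs e >= 3 and v >= 3")
    if singular_values.shape != (2,) or np.any(singular_values <= 0):
        raise MetDataError("singular_values must be two positive numbers")

    rng = np.random.default_rng(seed)
    # genotype directions: orthonormal pair orthogonal to ones (so column
    # means of the core are zero)
    base = np.column_stack([np.ones(v), rng.standard_normal((v, 2))])
    q, _ = np.linalg.qr(base)
    u = q[:, 1:3]
    qe, _ = np.linalg.qr(rng.standard_normal((e, 2)))
    core = singular_values[0] * np.outer(u[:, 0], qe[:, 0]) + singular_values[
        1
    ] * np.outer(u[:, 1], qe[:, 1])

    env_offsets = rng.normal(0.0, env_spread, size=e)
    table = grand_mean + env_offsets[None, :] + core  # (v, e)

    env_labels = [f"E{i + 1}" for i in range(e)]
    gen_labels = [f"V{j + 1}" for j in range(v)]
    rows = [(ei, gj) for ei in env_labels for gj in gen_labels]
    values = table.T.reshape(e * v, 1)  # env-major rows
    return MeanTable(rows, ["SIM"], values, "by_genotype_environment")
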