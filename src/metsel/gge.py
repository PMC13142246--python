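"""GGE biplot mathematics and geometry.

A GGE model for one trait starts from the genotype-by-environment mean
matrix, removes each environment's mean over genotypes (so what remains is
the genotype main effect plus the genotype-environment interaction), and
decomposes the centered matrix M by SVD with singular value partitioning:

    m_ij = sum_k  (lambda_k^a u_ik) (lambda_k^(1-a) v_jk)

with a = 1 the singular values go to the genotype scores (genotype
evaluation, which-won-where, mean-vs-stability) and with a = 0 to the
environment scores (environment evaluation).  All geometry lives in the
first two principal components, as in the standard biplot views:

* which-won-where: convex hull of the genotype points; rays from the
  origin perpendicular to the hull edges cut the plane into sectors; each
  environment falls in one sector and the hull vertex of that sector is
  its winner; environments grouped by winner form mega-environments.
* average-environment coordination (AEC): the axis from the origin through
  the mean environment point; a genotype's projection on it is mean
  performance, the perpendicular component is instability; the "ideal"
  genotype sits on the axis at the largest projection and genotypes are
  ranked by distance to it.
* environment metrics: vector length = discriminating ability, cosine of
  the angle to the AEC axis = representativeness; the "ideal" environment
  lies on the axis at the maximum length.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .data import MeanTable, MetDataError

__all__ = [
    "GGEModel",
    "WhichWonWhere",
    "AECView",
    "EnvMetrics",
    "GeometryError",
    "center_matrix",
    "gge_svd",
    "which_won_where",
    "mean_vs_stability",
    "rank_genotypes",
    "environment_metrics",
    "rank_environments",
    "environment_relationship",
]

logger = logging.getLogger(__name__)


class GeometryError(MetDataError):
    """Degenerate geometry: collinear hull, undefined axis, bad grid."""


def center_matrix(means: MeanTable, trait: str) -> pd.DataFrame:
    """Environment-centered genotype-by-environment matrix for one trait.

    Rows = genotypes, columns = environments; each column has its mean over
    genotypes subtracted, so column sums are zero to machine precision.
    """
    if means.kind != "by_genotype_environment":
        raise GeometryError("need a by_genotype_environment mean table")
    frame = means.to_frame()[trait].unstack(level=0)  # index GEN, columns ENV
    # preserve first-appearance orders from the mean table
    env_order = list(dict.fromkeys(env for env, _ in means.row_labels))
    gen_order = list(dict.fromkeys(gen for _, gen in means.row_labels))
    frame = frame.reindex(index=gen_order, columns=env_order)
    if frame.isna().any().any():
        raise GeometryError("incomplete genotype-environment grid")
    return frame - frame.mean(axis=0)


@dataclass
class GGEModel:
    """Singular system of a centered matrix under one SVP mode."""

    trait: str
    genotypes: list[str]
    environments: list[str]
    M: np.ndarray  # centered, v x e
    singular_values: np.ndarray  # descending, full
    U: np.ndarray  # v x k left vectors (sign-fixed)
    V: np.ndarray  # e x k right vectors (sign-fixed)
    a: int  # partitioning exponent: 1 genotype-focused, 0 environment-focused
    n_pc: int

    @property
    def genotype_scores(self) -> np.ndarray:
        """SVP-scaled genotype scores, first ``n_pc`` components (v x n_pc)."""
        return (self.U * self.singular_values ** self.a)[:, : self.n_pc]

    @property
    def environment_scores(self) -> np.ndarray:
        """SVP-scaled environment scores, first ``n_pc`` components (e x n_pc)."""
        return (self.V * self.singular_values ** (1 - self.a))[:, : self.n_pc]

    @property
    def explained(self) -> np.ndarray:
        """Share of GGE variation per PC: lambda_k^2 / sum lambda^2.

        All-zero matrix (no genotypic or interaction variation) has no
        defined shares; NaN is returned.
        """
        lam2 = self.singular_values ** 2
        total = lam2.sum()
        if total == 0:
            return np.full_like(lam2, np.nan)
        return lam2 / total

    def reconstruct(self) -> np.ndarray:
        """Product of all scaled score pairs; equals M for any ``a``."""
        gs = self.U * self.singular_values ** self.a
        es = self.V * self.singular_values ** (1 - self.a)
        return gs @ es.T


def gge_svd(M: pd.DataFrame | np.ndarray, a: int, n_pc: int = 2,
            trait: str = "", genotypes: list[str] | None = None,
            environments: list[str] | None = None) -> GGEModel:
    """Full SVD of a centered matrix with singular value partitioning.

    Sign convention: each PC is flipped so the sum of its environment
    scores is >= 0 (genotype sum breaks exact-zero ties), making output
    deterministic across linear-algebra backends.
    """
    if isinstance(M, pd.DataFrame):
        genotypes = [str(g) for g in M.index]
        environments = [str(c) for c in M.columns]
        M = M.to_numpy(dtype=float)
    else:
        M = np.asarray(M, dtype=float)
        v, e = M.shape
        genotypes = genotypes or [f"V{j + 1}" for j in range(v)]
        environments = environments or [f"E{i + 1}" for i in range(e)]
    if a not in (0, 1):
        raise MetDataError("partitioning exponent a must be 0 or 1")
    v, e = M.shape
    if n_pc > min(v, e):
        raise MetDataError(f"n_pc={n_pc} exceeds min(v, e)={min(v, e)}")

    u, s, vt = np.linalg.svd(M, full_matrices=False)
    w = vt.T
    for k in range(len(s)):
        tot = w[:, k].sum()
        if tot < 0 or (tot == 0 and u[:, k].sum() < 0):
            u[:, k] = -u[:, k]
            w[:, k] = -w[:, k]
    return GGEModel(trait, genotypes, environments, M, s, u, w, a, n_pc)


@dataclass
class WhichWonWhere:
    """Polygon (which-won-where) view of a genotype-focused model."""

    hull_vertices: list[str]  # counterclockwise genotype labels
    boundary_angles: np.ndarray  # sector boundary ray angles, radians
    sector_of_env: dict[str, int]  # environment -> sector index (into hull)
    winner_of_env: dict[str, str]  # environment -> winning genotype
    mega_environments: dict[str, list[str]]  # winner -> environments
    unresponsive: list[str]  # hull vertices winning no environment


def _require_mode(model: GGEModel, a: int, view: str) -> None:
    if model.a != a:
        raise MetDataError(
            f"{view} needs a model with a={a} "
            f"({'genotype' if a else 'environment'}-focused partitioning)"
        )


def which_won_where(model: GGEModel) -> WhichWonWhere:
    """Sector decomposition of the biplot plane and per-environment winners.

    Boundary rays are perpendicular to the hull edges (equivalently, they
    are the outward edge normals); the sector of hull vertex g is the cone
    of directions in which g maximizes the inner product.  An environment
    exactly on a boundary is assigned to the counterclockwise sector
    (logged).
    """
    _require_mode(model, 1, "which_won_where")
    G = model.genotype_scores[:, :2]
    E2 = model.environment_scores[:, :2]
    try:
        hull = ConvexHull(G)
    except QhullError as exc:
        raise GeometryError(f"degenerate (collinear) genotype hull: {exc}") from None
    verts = list(hull.vertices)  # counterclockwise in 2-D

    h = len(verts)
    # outward normal angle of each edge (verts[i] -> verts[i+1]); for a CCW
    # polygon whose interior contains the origin (true here: genotype scores
    # sum to zero) this is the boundary between the sectors of its endpoints
    boundary = np.empty(h)
    for i in range(h):
        a_pt, b_pt = G[verts[i]], G[verts[(i + 1) % h]]
        d = b_pt - a_pt
        boundary[i] = math.atan2(-d[0], d[1])  # angle of (dy, -dx)

    sector_of_env: dict[str, int] = {}
    winner_of_env: dict[str, str] = {}
    two_pi = 2 * math.pi
    for j, env in enumerate(model.environments):
        vec = E2[j]
        theta = math.atan2(vec[1], vec[0])
        # vertex verts[(i+1) % h] owns the CCW interval
        # [boundary[i], boundary[i+1]); boundary membership -> CCW sector
        sector = None
        for i in range(h):
            start, end = boundary[i], boundary[(i + 1) % h]
            span = (end - start) % two_pi
            off = (theta - start) % two_pi
            if off < span or (span == 0 and off == 0):
                sector = (i + 1) % h
                if off == 0:
                    logger.warning(
                        "environment %s lies exactly on a sector boundary; "
                        "assigned to the counterclockwise sector", env,
                    )
                break
        if sector is None:  # numerically possible only at exact boundaries
            sector = int(np.argmax(G[verts] @ vec))
        sector_of_env[env] = sector
        winner_of_env[env] = model.genotypes[verts[sector]]

    mega: dict[str, list[str]] = {}
    for env, win in winner_of_env.items():
        mega.setdefault(win, []).append(env)
    unresponsive = [
        model.genotypes[vi] for vi in verts if model.genotypes[vi] not in mega
    ]
    return WhichWonWhere(
        hull_vertices=[model.genotypes[vi] for vi in verts],
        boundary_angles=boundary,
        sector_of_env=sector_of_env,
        winner_of_env=winner_of_env,
        mega_environments=mega,
        unresponsive=unresponsive,
    )


@dataclass
class AECView:
    """Average-environment-coordination view (mean performance vs
    stability) of a genotype-focused model."""

    genotypes: list[str]
    genotype_points: np.ndarray  # v x 2
    environment_points: np.ndarray  # e x 2
    avg_env_point: np.ndarray  # 2-vector
    axis: np.ndarray  # unit 2-vector toward the average environment
    projections: np.ndarray  # signed mean-performance component
    ordinates: np.ndarray  # signed stability component
    ideal_point: np.ndarray  # 2-vector on the axis
    distances: np.ndarray  # to the ideal genotype
    ranks: np.ndarray  # 1 = closest to ideal
    tie_flag: bool


def mean_vs_stability(model: GGEModel) -> AECView:
    """Project genotypes on the average-environment axis.

    Projection (abscissa) is signed mean performance — positive toward the
    average environment; the ordinate is the signed perpendicular component
    (larger magnitude = less stable).  The ideal genotype sits on the axis
    at the maximum projection; ranks are by distance to it.
    """
    _require_mode(model, 1, "mean_vs_stability")
    G = model.genotype_scores[:, :2]
    E2 = model.environment_scores[:, :2]
    avg = E2.mean(axis=0)
    norm = np.linalg.norm(avg)
    if norm == 0:
        raise GeometryError("average environment point at the origin; AEC axis undefined")
    axis = avg / norm
    perp = np.array([-axis[1], axis[0]])
    proj = G @ axis
    ordi = G @ perp
    ideal = axis * proj.max()
    dist = np.linalg.norm(G - ideal, axis=1)
    order = np.lexsort((model.genotypes, dist))
    ranks = np.empty(len(dist), dtype=int)
    ranks[order] = np.arange(1, len(dist) + 1)
    tie = bool(len(np.unique(np.round(dist, 12))) < len(dist))
    if tie:
        logger.warning("tied distances to the ideal genotype; ties broken by label")
    return AECView(
        genotypes=list(model.genotypes),
        genotype_points=G,
        environment_points=E2,
        avg_env_point=avg,
        axis=axis,
        projections=proj,
        ordinates=ordi,
        ideal_point=ideal,
        distances=dist,
        ranks=ranks,
        tie_flag=tie,
    )


def rank_genotypes(view: AECView) -> pd.DataFrame:
    """Genotypes ordered by closeness to the ideal genotype."""
    frame = pd.DataFrame(
        {
            "genotype": view.genotypes,
            "mean_performance": view.projections,
            "stability": view.ordinates,
            "distance_to_ideal": view.distances,
            "rank": view.ranks,
        }
    )
    return frame.sort_values("rank").reset_index(drop=True)


@dataclass
class EnvMetrics:
    """Discriminating ability and representativeness of each environment
    (environment-focused model)."""

    environments: list[str]
    points: np.ndarray  # e x 2
    lengths: np.ndarray  # vector length = discriminating ability
    axis: np.ndarray  # unit AEC axis
    cosines: np.ndarray  # representativeness (nan if length 0)
    angles: np.ndarray  # radians to the axis (nan if length 0)
    ideal_point: np.ndarray
    distances: np.ndarray  # to the ideal environment
    ranks: np.ndarray
    relationship: np.ndarray  # pairwise cosine matrix
    undefined: list[str]  # zero-length environments


def environment_metrics(model: GGEModel) -> EnvMetrics:
    """Vector lengths, angles to the AEC axis and the distance-to-ideal
    environment ranking."""
    _require_mode(model, 0, "environment_metrics")
    E2 = model.environment_scores  # n_pc components (2 in the biplot views)
    lengths = np.linalg.norm(E2, axis=1)
    avg = E2.mean(axis=0)
    norm = np.linalg.norm(avg)
    if norm == 0:
        raise GeometryError("average environment point at the origin; AEC axis undefined")
    axis = avg / norm
    with np.errstate(invalid="ignore", divide="ignore"):
        cosines = np.where(lengths > 0, (E2 @ axis) / np.where(lengths > 0, lengths, 1.0), np.nan)
        angles = np.arccos(np.clip(cosines, -1.0, 1.0))
    undefined = [env for env, L in zip(model.environments, lengths) if L == 0]
    if undefined:
        logger.warning("zero-length environment vector(s): %s", undefined)
    ideal = axis * lengths.max()
    dist = np.linalg.norm(E2 - ideal, axis=1)
    order = np.lexsort((model.environments, dist))
    ranks = np.empty(len(dist), dtype=int)
    ranks[order] = np.arange(1, len(dist) + 1)

    safe = np.where(lengths > 0, lengths, np.nan)
    rel = (E2 @ E2.T) / np.outer(safe, safe)
    np.fill_diagonal(rel, np.where(lengths > 0, 1.0, np.nan))
    return EnvMetrics(
        environments=list(model.environments),
        points=E2,
        lengths=lengths,
        axis=axis,
        cosines=cosines,
        angles=angles,
        ideal_point=ideal,
        distances=dist,
        ranks=ranks,
        relationship=rel,
        undefined=undefined,
    )


def rank_environments(metrics: EnvMetrics) -> pd.DataFrame:
    """Environments ordered by closeness to the ideal environment."""
    frame = pd.DataFrame(
        {
            "environment": metrics.environments,
            "discriminating_ability": metrics.lengths,
            "representativeness": metrics.cosines,
            "distance_to_ideal": metrics.distances,
            "rank": metrics.ranks,
        }
    )
    return frame.sort_values("rank").reset_index(drop=True)


def environment_relationship(model: GGEModel) -> pd.DataFrame:
    """Pairwise cosine matrix of environment score vectors (first two PCs).

    At full rank this approximates the correlation matrix of the centered
    matrix's environment columns.
    """
    _require_mode(model, 0, "environment_relationship")
    metrics = environment_metrics(model)
    return pd.DataFrame(
        metrics.relationship, index=model.environments, columns=model.environments
    )
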