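"""Multi-trait Genotype-Ideotype Distance Index (MGIDI).

Pipeline: (1) rescale each trait column of a two-way mean table linearly to
0-100 so that 100 is always the desirable end — for a trait to maximize the
observed maximum maps to 100, for a trait to minimize the observed minimum
does; (2) optionally weight the rescaled columns by prior trait importance;
(3) standardize columns and run an exploratory factor analysis on their
correlation matrix, retaining factors with eigenvalue > 1 (Kaiser) and
rotating the retained loadings with varimax; (4) compute regression factor
scores  S = Z R^-1 A  for every treatment and for the ideotype (the
all-100 row passed through the same weighting/standardization); (5) the
index is the Euclidean distance between a treatment's scores and the
ideotype's.  Smaller MGIDI = closer to ideal; selection keeps the lowest
``ceil(intensity * n)`` treatments.

The per-factor squared-deviation shares decompose each treatment's index
into factor contributions (its "strengths and weaknesses": a small share
means the traits of that factor are already near ideal).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import MeanTable, MetDataError, TraitSpec

__all__ = [
    "RescaledTable",
    "FactorModel",
    "MGIDIResult",
    "RescaleError",
    "RetentionError",
    "rescale_means",
    "varimax_criterion",
    "varimax_rotate",
    "fit_factor_model",
    "compute_scores",
    "ideotype_scores",
    "mgidi_index",
    "rank_and_select",
    "factor_contributions",
    "run_mgidi",
]

logger = logging.getLogger(__name__)


class RescaleError(MetDataError):
    """A trait column is constant and cannot be mapped to 0-100."""


class RetentionError(MetDataError):
    """No correlation-matrix eigenvalue exceeds 1; no factors retained."""


@dataclass
class RescaledTable:
    """Mean table after the 0-100 ideotype rescaling.

    Stores the per-column original extrema and their images so the mapping
    is invertible and auditable.
    """

    row_labels: list
    trait_codes: list[str]
    values: np.ndarray  # in [0, 100]
    kind: str
    max_original: np.ndarray
    min_original: np.ndarray
    max_new: np.ndarray
    min_new: np.ndarray
    directions: list[str]


def rescale_means(means: MeanTable, traits: list[TraitSpec]) -> RescaledTable:
    """Linear per-column map of a mean table onto [0, 100].

    For a maximize trait the new maximum is 100 (observed max -> 100,
    observed min -> 0); for a minimize trait the ends are flipped (observed
    max -> 0).  A constant column has no defined map and raises
    :class:`RescaleError`.
    """
    by_code = {t.code: t for t in traits}
    missing = [c for c in means.trait_codes if c not in by_code]
    if missing:
        raise MetDataError(f"no TraitSpec for trait(s) {missing}")

    x = means.values
    maxo, mino = x.max(axis=0), x.min(axis=0)
    const = np.isclose(maxo, mino)
    if const.any():
        bad = [c for c, flag in zip(means.trait_codes, const) if flag]
        raise RescaleError(f"constant trait column(s) {bad}: rescale undefined")

    directions = [by_code[c].direction for c in means.trait_codes]
    maxn = np.where([d == "maximize" for d in directions], 100.0, 0.0)
    minn = 100.0 - maxn
    rescaled = (maxn - minn) / (maxo - mino) * (x - maxo) + maxn
    return RescaledTable(
        row_labels=list(means.row_labels),
        trait_codes=list(means.trait_codes),
        values=rescaled,
        kind=means.kind,
        max_original=maxo,
        min_original=mino,
        max_new=maxn,
        min_new=minn,
        directions=directions,
    )


def varimax_criterion(loadings: np.ndarray) -> float:
    """Varimax objective: sum over factors of the variance of the squared
    loadings within that factor."""
    sq = np.asarray(loadings) ** 2
    return float(np.sum(sq.var(axis=0)))


def varimax_rotate(loadings: np.ndarray, tol: float = 1e-6,
                   max_iter: int = 1000) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal varimax rotation (raw criterion, no row normalization).

    Returns ``(rotated, rotation)`` with ``rotated = loadings @ rotation``
    and an orthonormal rotation matrix.  Iterates the standard SVD update
    until the relative criterion change falls below ``tol``; the criterion
    never decreases.  ``f = 1`` returns the identity rotation.
    """
    L = np.asarray(loadings, dtype=float)
    p, f = L.shape
    rot = np.eye(f)
    if f == 1:
        return L.copy(), rot
    d_old = 0.0
    for _ in range(max_iter):
        Lr = L @ rot
        grad = L.T @ (Lr ** 3 - Lr @ np.diag((Lr ** 2).sum(axis=0)) / p)
        u, s, vt = np.linalg.svd(grad)
        rot = u @ vt
        d = s.sum()
        if d_old > 0 and (d - d_old) / d_old < tol:
            break
        d_old = d
    return L @ rot, rot


@dataclass
class FactorModel:
    """Factor analysis of a (weighted, standardized) rescaled mean table."""

    correlation: np.ndarray  # R, p x p
    eigenvalues: np.ndarray  # all p, descending
    n_factors: int
    initial_loadings: np.ndarray  # p x f (principal-component loadings)
    loadings: np.ndarray  # p x f, varimax-rotated, sign-fixed
    rotation: np.ndarray  # f x f orthonormal
    communalities: np.ndarray
    uniquenesses: np.ndarray
    col_means: np.ndarray  # of the weighted rescaled matrix
    col_sds: np.ndarray
    weights: np.ndarray  # normalized (mean 1) per-trait weights
    scores: np.ndarray  # rows x f
    ideotype: np.ndarray  # f-vector gamma
    row_labels: list
    trait_codes: list[str]

    @property
    def explained_variance(self) -> np.ndarray:
        """Per-factor share of total variance = eigenvalue / p, for the
        retained factors."""
        return self.eigenvalues[: self.n_factors] / len(self.trait_codes)

    @property
    def cumulative_variance(self) -> np.ndarray:
        return np.cumsum(self.explained_variance)

    def loadings_frame(self, dominant_threshold: float = 0.5) -> pd.DataFrame:
        """Loadings table with a per-trait list of dominant factors
        (|loading| >= threshold; a trait may appear under several)."""
        cols = [f"FA{k + 1}" for k in range(self.n_factors)]
        frame = pd.DataFrame(self.loadings, index=self.trait_codes, columns=cols)
        frame["communality"] = self.communalities
        frame["dominant_factors"] = [
            ",".join(c for c, ld in zip(cols, row) if abs(ld) >= dominant_threshold)
            for row in self.loadings
        ]
        return frame


def fit_factor_model(rescaled: RescaledTable,
                     weights: np.ndarray | None = None) -> FactorModel:
    """Fit the factor model used by the index.

    ``weights`` are per-trait importances (default: all 1).  They are
    normalized to mean 1 and multiply the rescaled columns before
    standardization, modulating each trait's leverage on the correlation
    structure; a common scaling of all weights therefore changes nothing.
    """
    x = np.asarray(rescaled.values, dtype=float)
    n, p = x.shape
    if weights is None:
        weights = np.ones(p)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (p,):
        raise MetDataError(f"weights must have length {p}")
    if np.any(weights < 0) or weights.sum() == 0:
        raise MetDataError("weights must be non-negative and not all zero")
    weights = weights / weights.mean()

    xw = x * weights
    col_means = xw.mean(axis=0)
    col_sds = xw.std(axis=0, ddof=1)
    if np.any(col_sds == 0):
        bad = [c for c, s in zip(rescaled.trait_codes, col_sds) if s == 0]
        raise RescaleError(f"zero-variance column(s) {bad} after weighting")
    z = (xw - col_means) / col_sds

    corr = (z.T @ z) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    f = int(np.sum(eigvals > 1.0))
    if f == 0:
        raise RetentionError(
            "no eigenvalue of the correlation matrix exceeds 1; inspect the "
            "correlation structure (traits may be uncorrelated)"
        )
    initial = eigvecs[:, :f] * np.sqrt(eigvals[:f])
    rotated, rot = varimax_rotate(initial)

    # cosmetic sign fix: largest-|loading| entry of each factor positive
    signs = np.sign(rotated[np.argmax(np.abs(rotated), axis=0), np.arange(f)])
    signs[signs == 0] = 1.0
    rotated = rotated * signs
    rot = rot * signs

    communalities = (rotated ** 2).sum(axis=1)
    model = FactorModel(
        correlation=corr,
        eigenvalues=eigvals,
        n_factors=f,
        initial_loadings=initial,
        loadings=rotated,
        rotation=rot,
        communalities=communalities,
        uniquenesses=1.0 - communalities,
        col_means=col_means,
        col_sds=col_sds,
        weights=weights,
        scores=np.empty((0, f)),
        ideotype=np.empty(f),
        row_labels=list(rescaled.row_labels),
        trait_codes=list(rescaled.trait_codes),
    )
    model.scores = compute_scores(model, z)
    model.ideotype = ideotype_scores(model)
    return model


def compute_scores(model: FactorModel, standardized: np.ndarray) -> np.ndarray:
    """Regression factor scores S = Z R^-1 A for standardized rows Z."""
    z = np.atleast_2d(np.asarray(standardized, dtype=float))
    p = len(model.trait_codes)
    if z.shape[1] != p:
        raise MetDataError(f"expected {p} columns, got {z.shape[1]}")
    return z @ np.linalg.solve(model.correlation, model.loadings)


def ideotype_scores(model: FactorModel) -> np.ndarray:
    """Scores of the ideotype: the all-100 row in rescaled space (the
    desirable end of every trait), weighted and standardized with the
    model's stored constants."""
    ideal = np.full(len(model.trait_codes), 100.0) * model.weights
    z = (ideal - model.col_means) / model.col_sds
    return compute_scores(model, z)[0]


@dataclass
class MGIDIResult:
    """Distances to the ideotype plus (after ranking) selection metadata."""

    row_labels: list
    distances: np.ndarray
    ideotype: np.ndarray
    intensity: float | None = None
    ranks: np.ndarray | None = None  # 1 = closest to ideal
    selected: np.ndarray | None = None  # bool mask
    contributions: np.ndarray | None = None  # rows x f shares
    tie_warning: bool = False

    @property
    def selected_labels(self) -> list:
        if self.selected is None:
            raise MetDataError("rank_and_select has not been applied")
        return [lab for lab, s in zip(self.row_labels, self.selected) if s]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"treatment": [str(l) for l in self.row_labels],
                              "MGIDI": self.distances})
        if self.ranks is not None:
            frame["rank"] = self.ranks
            frame["selected"] = self.selected
        return frame


def mgidi_index(scores: np.ndarray, ideotype: np.ndarray,
                row_labels: list | None = None) -> MGIDIResult:
    """Euclidean distance of each row's factor scores to the ideotype
    scores."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    ideotype = np.asarray(ideotype, dtype=float)
    if scores.shape[1] != ideotype.shape[0]:
        raise MetDataError("scores and ideotype disagree on factor count")
    d = np.linalg.norm(scores - ideotype, axis=1)
    labels = row_labels if row_labels is not None else list(range(len(d)))
    return MGIDIResult(list(labels), d, ideotype)


def rank_and_select(result: MGIDIResult, intensity: float) -> MGIDIResult:
    """Rank treatments by ascending distance and keep the closest
    ``ceil(intensity * n)``.  Ties keep original order (stable sort) and are
    logged."""
    if not (0 < intensity <= 1):
        raise MetDataError("selection intensity must be in (0, 1]")
    d = result.distances
    n = len(d)
    order = np.argsort(d, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(1, n + 1)
    n_sel = math.ceil(intensity * n)
    selected = ranks <= n_sel
    tie = bool(len(np.unique(d)) < n)
    if tie:
        logger.warning(
            "tied MGIDI distances present; ties broken by original order"
        )
    result.intensity = intensity
    result.ranks = ranks
    result.selected = selected
    result.tie_warning = tie
    return result


def factor_contributions(scores: np.ndarray, ideotype: np.ndarray) -> np.ndarray:
    """Per-treatment share of each factor in the squared distance:
    share_if = (S_if - gamma_f)^2 / sum_f (S_if - gamma_f)^2.

    Rows at zero distance get uniform shares (logged)."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    dev2 = (scores - np.asarray(ideotype, dtype=float)) ** 2
    totals = dev2.sum(axis=1, keepdims=True)
    zero = totals[:, 0] == 0
    if zero.any():
        logger.warning(
            "%d treatment(s) at zero distance to the ideotype; uniform "
            "factor shares reported", int(zero.sum()),
        )
        totals[zero] = 1.0
        dev2[zero] = 1.0 / dev2.shape[1]
    return dev2 / totals


def run_mgidi(means: MeanTable, traits: list[TraitSpec],
              use_weights: bool = False, intensity: float = 0.15
              ) -> tuple[FactorModel, MGIDIResult]:
    """Full chain: rescale -> factor model -> distances -> selection.

    ``use_weights=False`` (default, the reference behavior) treats all
    traits equally; ``True`` applies the TraitSpec weights.
    """
    rescaled = rescale_means(means, traits)
    w = None
    if use_weights:
        by_code = {t.code: t.weight for t in traits}
        w = np.array([by_code[c] for c in means.trait_codes])
    model = fit_factor_model(rescaled, weights=w)
    result = mgidi_index(model.scores, model.ideotype, model.row_labels)
    result.contributions = factor_contributions(model.scores, model.ideotype)
    return model, rank_and_select(result, intensity)
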