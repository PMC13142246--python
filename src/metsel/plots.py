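"""Static SVG renderings of the six standard biplot views.

Content mirrors the usual which-won-where / mean-vs-stability / ranking /
discriminativeness / relationship / environment-ranking panels; styling is
deliberately plain.
"""

from __future__ import annotations

import math
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .gge import AECView, EnvMetrics, GGEModel, WhichWonWhere, which_won_where

__all__ = ["plot_which_won_where", "plot_mean_vs_stability",
           "plot_genotype_ranking", "plot_environment_metrics",
           "plot_environment_relationship", "plot_environment_ranking",
           "plot_all_views"]


def _scatter(ax, model: GGEModel) -> tuple[np.ndarray, np.ndarray]:
    G = model.genotype_scores[:, :2]
    E2 = model.environment_scores[:, :2]
    ax.scatter(G[:, 0], G[:, 1], c="tab:blue", s=20)
    for lab, (x, y) in zip(model.genotypes, G):
        ax.annotate(lab, (x, y), fontsize=8, color="tab:blue")
    ax.scatter(E2[:, 0], E2[:, 1], c="tab:red", marker="^", s=25)
    for lab, (x, y) in zip(model.environments, E2):
        ax.annotate(lab, (x, y), fontsize=8, color="tab:red")
    ax.axhline(0, lw=0.5, color="gray")
    ax.axvline(0, lw=0.5, color="gray")
    ev = model.explained
    ax.set_xlabel(f"PC1 ({100 * ev[0]:.2f}%)")
    ax.set_ylabel(f"PC2 ({100 * ev[1]:.2f}%)")
    return G, E2


def _save(fig, path: str | Path) -> Path:
    path = Path(path)
    fig.savefig(path, format="svg")
    plt.close(fig)
    return path


def plot_which_won_where(model: GGEModel, path: str | Path,
                         www: WhichWonWhere | None = None) -> Path:
    www = www or which_won_where(model)
    fig, ax = plt.subplots(figsize=(6, 6))
    G, _ = _scatter(ax, model)
    idx = [model.genotypes.index(g) for g in www.hull_vertices]
    poly = G[idx + idx[:1]]
    ax.plot(poly[:, 0], poly[:, 1], color="tab:green", lw=1)
    rmax = 1.2 * np.abs(np.concatenate([G.ravel(), model.environment_scores[:, :2].ravel()])).max()
    for ang in www.boundary_angles:
        ax.plot([0, rmax * math.cos(ang)], [0, rmax * math.sin(ang)],
                ls=":", color="gray", lw=0.8)
    ax.set_title(f"Which-won-where ({model.trait})")
    return _save(fig, path)


def plot_mean_vs_stability(model: GGEModel, view: AECView, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(6, 6))
    _scatter(ax, model)
    rmax = 1.2 * np.abs(view.genotype_points).max()
    ax.annotate("", xy=tuple(rmax * view.axis), xytext=(0, 0),
                arrowprops=dict(arrowstyle="->", color="tab:green"))
    perp = np.array([-view.axis[1], view.axis[0]])
    ax.plot([-rmax * perp[0], rmax * perp[0]], [-rmax * perp[1], rmax * perp[1]],
            color="tab:green", lw=0.8, ls="--")
    ax.scatter(*view.ideal_point, marker="o", facecolors="none",
               edgecolors="black", s=120)
    ax.set_title(f"Mean vs stability ({model.trait})")
    return _save(fig, path)


def plot_genotype_ranking(model: GGEModel, view: AECView, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(6, 6))
    _scatter(ax, model)
    for radius in np.linspace(0, view.distances.max(), 5)[1:]:
        ax.add_patch(plt.Circle(view.ideal_point, radius, fill=False,
                                color="tab:green", lw=0.6))
    ax.scatter(*view.ideal_point, marker="o", facecolors="none",
               edgecolors="black", s=120)
    ax.set_aspect("equal")
    ax.set_title(f"Genotype ranking ({model.trait})")
    return _save(fig, path)


def plot_environment_metrics(model: GGEModel, metrics: EnvMetrics,
                             path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(6, 6))
    _scatter(ax, model)
    for pt in metrics.points:
        ax.plot([0, pt[0]], [0, pt[1]], color="tab:red", lw=0.7)
    rmax = 1.2 * metrics.lengths.max()
    ax.annotate("", xy=tuple(rmax * metrics.axis), xytext=(0, 0),
                arrowprops=dict(arrowstyle="->", color="tab:green"))
    ax.set_title(f"Discriminativeness & representativeness ({model.trait})")
    return _save(fig, path)


def plot_environment_relationship(model: GGEModel, metrics: EnvMetrics,
                                  path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(6, 6))
    _scatter(ax, model)
    for pt in metrics.points:
        ax.plot([0, pt[0]], [0, pt[1]], color="tab:red", lw=0.9)
    ax.set_title(f"Environment relationship ({model.trait})")
    return _save(fig, path)


def plot_environment_ranking(model: GGEModel, metrics: EnvMetrics,
                             path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(6, 6))
    _scatter(ax, model)
    for radius in np.linspace(0, metrics.distances.max(), 5)[1:]:
        ax.add_patch(plt.Circle(metrics.ideal_point, radius, fill=False,
                                color="tab:green", lw=0.6))
    ax.scatter(*metrics.ideal_point, marker="o", facecolors="none",
               edgecolors="black", s=120)
    ax.set_aspect("equal")
    ax.set_title(f"Environment ranking ({model.trait})")
    return _save(fig, path)


def plot_all_views(model_g, www, aec, model_e, metrics, outdir: str | Path,
                   trait: str) -> list[Path]:
    """Write the six views for one trait; returns the written paths."""
    outdir = Path(outdir)
    return [
        plot_which_won_where(model_g, outdir / f"gge_{trait}_which_won_where.svg", www),
        plot_mean_vs_stability(model_g, aec, outdir / f"gge_{trait}_mean_stability.svg"),
        plot_genotype_ranking(model_g, aec, outdir / f"gge_{trait}_genotype_ranking.svg"),
        plot_environment_metrics(model_e, metrics, outdir / f"gge_{trait}_env_metrics.svg"),
        plot_environment_relationship(model_e, metrics, outdir / f"gge_{trait}_env_relationship.svg"),
        plot_environment_ranking(model_e, metrics, outdir / f"gge_{trait}_env_ranking.svg"),
    ]
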