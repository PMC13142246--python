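"""Balanced two-factor-with-blocks MANOVA and related univariate statistics.

For a complete (environment x genotype x block) layout the sums-of-squares
and cross-products (SSCP) decomposition is closed form: each effect's
hypothesis matrix H is a between-group SSCP of marginal means and the
residual matrix E is what remains of the total corrected SSCP.  The
multivariate test reported is the Pillai trace

    V = trace(H (H + E)^-1)

with the standard approximate-F transform

    s = min(p, q_h),  m = (|p - q_h| - 1)/2,  n = (q_e - p - 1)/2
    F = [(2n + s + 1) / (2m + s + 1)] * (V/s) / (1 - V/s)
    df1 = s (2m + s + 1),  df2 = s (2n + s + 1)

where p is the number of traits, q_h the hypothesis df and q_e the
residual df.  With p = 1 this collapses to the ordinary univariate F.

Variance components use the method of moments on expected mean squares of
the balanced layout; contrasts use the pooled residual mean square of the
single-trait model, so their df is the full residual df q_e.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.stats
import pandas as pd

from .data import MeanTable, MetDataError, TrialDataset

__all__ = [
    "EffectTest",
    "ManovaResult",
    "VarianceComponents",
    "ContrastResult",
    "RankError",
    "two_way_means",
    "design_dfs",
    "pillai_approx_f",
    "fit_manova",
    "anova_mean_squares",
    "variance_components",
    "contrast",
    "contrast_one_vs_rest",
    "contrast_pairwise",
]

EFFECTS = ("block", "environment", "genotype", "interaction")


class RankError(MetDataError):
    """H + E is singular; too many traits for the residual df."""


def two_way_means(dataset: TrialDataset, kind: str) -> MeanTable:
    """Genotype means (over environments and blocks) or
    genotype-environment cell means (over blocks)."""
    e, v, r, p = dataset.shape
    if kind == "by_genotype":
        vals = dataset.values.mean(axis=(0, 2))
        return MeanTable(list(dataset.genotypes), dataset.trait_codes, vals, kind)
    if kind == "by_genotype_environment":
        vals = dataset.values.mean(axis=2).reshape(e * v, p)
        rows = [(ei, gj) for ei in dataset.environments for gj in dataset.genotypes]
        return MeanTable(rows, dataset.trait_codes, vals, kind)
    raise MetDataError(f"unknown mean-table kind {kind!r}")


def design_dfs(e: int, v: int, r: int) -> dict[str, int]:
    """Degrees of freedom of every effect in the balanced layout, from the
    design dimensions alone."""
    q_e = e * v * r - 1 - (r - 1) - (e - 1) - (v - 1) - (e - 1) * (v - 1)
    return {
        "block": r - 1,
        "environment": e - 1,
        "genotype": v - 1,
        "interaction": (e - 1) * (v - 1),
        "residual": q_e,
    }


def pillai_approx_f(pillai: float, p: int, q_h: int, q_e: int
                    ) -> tuple[float, int, int]:
    """Approximate F and its (df1, df2) for a Pillai trace statistic.

    ``p`` = number of traits, ``q_h`` = hypothesis df, ``q_e`` = residual
    df.  At the boundary ``pillai == min(p, q_h)`` the F statistic is
    infinite and returned as ``inf`` with a warning.
    """
    s = min(p, q_h)
    if not (0.0 <= pillai <= s + 1e-12):
        raise MetDataError(f"Pillai statistic {pillai} outside [0, {s}]")
    m = (abs(p - q_h) - 1) / 2.0
    n = (q_e - p - 1) / 2.0
    df1 = int(round(s * (2 * m + s + 1)))
    df2 = int(round(s * (2 * n + s + 1)))
    ratio = pillai / s
    if ratio >= 1.0:
        warnings.warn("Pillai statistic at its upper boundary; F is infinite")
        return math.inf, df1, df2
    f = ((2 * n + s + 1) / (2 * m + s + 1)) * ratio / (1.0 - ratio)
    return f, df1, df2


@dataclass
class EffectTest:
    """Pillai test of one model effect."""

    effect: str
    q_h: int
    pillai: float
    approx_f: float
    df1: int
    df2: int
    p_value: float
    H: np.ndarray


@dataclass
class ManovaResult:
    effects: dict[str, EffectTest]
    q_e: int
    E: np.ndarray  # residual SSCP
    total: np.ndarray  # total corrected SSCP
    trait_codes: list[str]

    def to_frame(self) -> pd.DataFrame:
        """Summary table: one row per effect (Df, Pillai, approx F, num Df,
        den Df, p-value)."""
        rows = []
        for name in EFFECTS:
            t = self.effects[name]
            rows.append(
                {
                    "effect": name,
                    "Df": t.q_h,
                    "Pillai": t.pillai,
                    "approx_F": t.approx_f,
                    "num_Df": t.df1,
                    "den_Df": t.df2,
                    "p_value": t.p_value,
                }
            )
        rows.append({"effect": "residual", "Df": self.q_e, "Pillai": np.nan,
                     "approx_F": np.nan, "num_Df": np.nan, "den_Df": np.nan,
                     "p_value": np.nan})
        return pd.DataFrame(rows)


def _sscp(dev: np.ndarray, mult: float) -> np.ndarray:
    """mult * sum over rows of outer(dev_row, dev_row)."""
    flat = dev.reshape(-1, dev.shape[-1])
    return mult * (flat.T @ flat)


def fit_manova(dataset: TrialDataset) -> ManovaResult:
    """Balanced MANOVA of all effects with Pillai trace tests.

    Requires ``q_e >= p`` and a non-singular H + E (otherwise
    :class:`RankError` suggests reducing the trait list).
    """
    e, v, r, p = dataset.shape
    y = dataset.values
    dfs = design_dfs(e, v, r)
    q_e = dfs["residual"]
    if q_e < p:
        raise RankError(
            f"residual df {q_e} < number of traits {p}; reduce the trait set"
        )

    grand = y.mean(axis=(0, 1, 2))
    env_m = y.mean(axis=(1, 2))  # (e, p)
    gen_m = y.mean(axis=(0, 2))  # (v, p)
    block_m = y.mean(axis=(0, 1))  # (r, p)
    cell_m = y.mean(axis=2)  # (e, v, p)

    H = {
        "block": _sscp(block_m - grand, e * v),
        "environment": _sscp(env_m - grand, v * r),
        "genotype": _sscp(gen_m - grand, e * r),
        "interaction": _sscp(
            cell_m - env_m[:, None, :] - gen_m[None, :, :] + grand, r
        ),
    }
    total = _sscp(y - grand, 1.0)
    E = total - sum(H.values())

    effects: dict[str, EffectTest] = {}
    for name in EFFECTS:
        q_h = dfs[name]
        HpE = H[name] + E
        try:
            sol = scipy.linalg.solve(HpE, H[name], assume_a="sym")
        except (scipy.linalg.LinAlgError, ValueError) as exc:
            raise RankError(
                "H + E singular; reduce the number of traits or enlarge "
                f"the design ({exc})"
            ) from None
        pillai = float(np.trace(sol))
        s = min(p, q_h)
        pillai = min(max(pillai, 0.0), s)  # clip numerical round-off
        f, df1, df2 = pillai_approx_f(pillai, p, q_h, q_e)
        p_value = float(scipy.stats.f.sf(f, df1, df2)) if math.isfinite(f) else 0.0
        effects[name] = EffectTest(name, q_h, pillai, f, df1, df2, p_value, H[name])

    return ManovaResult(effects, q_e, E, total, dataset.trait_codes)


def anova_mean_squares(dataset: TrialDataset, trait: str) -> dict[str, float]:
    """Univariate mean squares of one trait under the balanced model."""
    e, v, r, _ = dataset.shape
    t = dataset.trait_index(trait)
    y = dataset.values[..., t]
    dfs = design_dfs(e, v, r)
    grand = y.mean()
    env_m, gen_m, block_m = y.mean(axis=(1, 2)), y.mean(axis=(0, 2)), y.mean(axis=(0, 1))
    cell_m = y.mean(axis=2)
    ss = {
        "block": e * v * np.sum((block_m - grand) ** 2),
        "environment": v * r * np.sum((env_m - grand) ** 2),
        "genotype": e * r * np.sum((gen_m - grand) ** 2),
        "interaction": r * np.sum(
            (cell_m - env_m[:, None] - gen_m[None, :] + grand) ** 2
        ),
    }
    total = np.sum((y - grand) ** 2)
    ss["residual"] = total - sum(ss[k] for k in EFFECTS)
    return {name: float(ss[name]) / dfs[name] for name in ss}


@dataclass
class VarianceComponents:
    """Method-of-moments variance components for one trait.

    Estimates may be negative; they are flagged, not truncated.
    """

    trait: str
    genotype: float
    interaction: float
    block: float
    residual: float
    negative_flags: dict[str, bool] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        comps = {
            "genotype": self.genotype,
            "interaction": self.interaction,
            "block": self.block,
            "residual": self.residual,
        }
        total = sum(max(c, 0.0) for c in comps.values())
        return pd.DataFrame(
            {
                "trait": self.trait,
                "component": list(comps),
                "estimate": list(comps.values()),
                "negative": [self.negative_flags.get(k, False) for k in comps],
                "pct_of_total": [
                    100.0 * max(c, 0.0) / total if total > 0 else np.nan
                    for c in comps.values()
                ],
            }
        )


def variance_components(dataset: TrialDataset, trait: str) -> VarianceComponents:
    """Expected-mean-squares estimators on the balanced layout:

    sigma2_res = MS_res; sigma2_ge = (MS_ge - MS_res)/r;
    sigma2_gen = (MS_gen - MS_ge)/(e r); sigma2_block = (MS_block - MS_res)/(e v).
    """
    e, v, r, _ = dataset.shape
    ms = anova_mean_squares(dataset, trait)
    comps = {
        "residual": ms["residual"],
        "interaction": (ms["interaction"] - ms["residual"]) / r,
        "genotype": (ms["genotype"] - ms["interaction"]) / (e * r),
        "block": (ms["block"] - ms["residual"]) / (e * v),
    }
    flags = {k: val < 0 for k, val in comps.items()}
    return VarianceComponents(
        trait=trait,
        genotype=comps["genotype"],
        interaction=comps["interaction"],
        block=comps["block"],
        residual=comps["residual"],
        negative_flags=flags,
    )


@dataclass
class ContrastResult:
    label: str
    estimate: float
    se: float
    df: int
    lower: float
    upper: float
    t_ratio: float
    p_value: float


def contrast(dataset: TrialDataset, trait: str, environment: str,
             coefficients: dict[str, float], label: str | None = None
             ) -> ContrastResult:
    """General linear contrast of genotype cell means within one environment.

    ``coefficients`` maps genotype label -> contrast coefficient c_j applied
    to that genotype's cell mean in ``environment``.  The variance is
    MS_res * sum(c_j^2) / r with the residual mean square pooled over the
    whole design (df = q_e).
    """
    e, v, r, _ = dataset.shape
    if environment not in dataset.environments:
        raise MetDataError(f"unknown environment {environment!r}")
    for g in coefficients:
        if g not in dataset.genotypes:
            raise MetDataError(f"unknown genotype {g!r}")
    ei = dataset.environments.index(environment)
    t = dataset.trait_index(trait)
    cell_means = dataset.values[ei, :, :, t].mean(axis=1)  # (v,)

    est = sum(
        c * cell_means[dataset.genotypes.index(g)] for g, c in coefficients.items()
    )
    ms = anova_mean_squares(dataset, trait)
    q_e = design_dfs(e, v, r)["residual"]
    csq = sum(c * c for c in coefficients.values())
    se = math.sqrt(ms["residual"] * csq / r)
    t_ratio = est / se if se > 0 else (0.0 if est == 0 else math.inf * np.sign(est))
    p_value = 2.0 * float(scipy.stats.t.sf(abs(t_ratio), q_e))
    t_crit = float(scipy.stats.t.ppf(0.975, q_e))
    return ContrastResult(
        label=label or "contrast",
        estimate=float(est),
        se=se,
        df=q_e,
        lower=float(est - t_crit * se),
        upper=float(est + t_crit * se),
        t_ratio=float(t_ratio),
        p_value=p_value,
    )


def contrast_one_vs_rest(dataset: TrialDataset, trait: str, environment: str,
                         genotype: str) -> ContrastResult:
    """Mean of one genotype minus the average of all other genotypes, within
    one environment.  SE = sqrt(MS_res (1/r)(1 + 1/(v-1)))."""
    v = len(dataset.genotypes)
    if genotype not in dataset.genotypes:
        raise MetDataError(f"unknown genotype {genotype!r}")
    coeff = {g: -1.0 / (v - 1) for g in dataset.genotypes}
    coeff[genotype] = 1.0
    return contrast(
        dataset, trait, environment, coeff,
        label=f"{genotype} vs others in {environment}",
    )


def contrast_pairwise(dataset: TrialDataset, trait: str, environment: str,
                      genotype_a: str, genotype_b: str) -> ContrastResult:
    """Pairwise difference of two genotypes within one environment."""
    coeff = {genotype_a: 1.0, genotype_b: -1.0}
    return contrast(
        dataset, trait, environment, coeff,
        label=f"{genotype_a} vs {genotype_b} in {environment}",
    )
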