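"""Orchestration: run the whole selection analysis from one configuration.

Stages (each optional): validation, MANOVA + variance components, two-way
means, MGIDI on genotype means / on genotype-environment means / within
each environment, and GGE biplot analysis per requested trait in both
partitioning modes.  Every stage writes tidy CSV tables into the output
directory; a YAML manifest records the configuration and seed, and a
markdown report summarizes what was produced.  Identical configuration and
seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gge as gge_mod
from . import manova as manova_mod
from . import mgidi as mgidi_mod
from .data import (MeanTable, MetDataError, TraitSpec, TrialDataset,
                   read_met_csv, validate_balanced, write_met_csv)
from .simulate import SimulationParams, simulate_met

__all__ = ["RunConfig", "run_pipeline", "generate_report"]

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"  # CSV precision; reports round to 6 significant digits


@dataclass
class RunConfig:
    """Configuration of one analysis run.

    Exactly one of ``input_csv`` / ``simulation`` must be set.  ``traits``
    lists the trait specifications (codes must match the CSV columns or the
    simulated trait count).
    """

    traits: list[TraitSpec]
    input_csv: str | None = None
    simulation: SimulationParams | None = None
    intensity: float = 0.15
    use_weights: bool = False
    do_manova: bool = True
    do_mgidi_overall: bool = True
    do_mgidi_combinations: bool = True
    do_mgidi_per_environment: bool = True
    gge_traits: list[str] = field(default_factory=list)
    plots: bool = False
    outdir: str = "metsel_out"
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.simulation is None):
            raise MetDataError(
                "exactly one of input_csv / simulation must be provided"
            )
        if not (0 < self.intensity <= 1):
            raise MetDataError("intensity must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        traits = [
            TraitSpec(
                code=str(t["code"]),
                direction=t.get("direction", "maximize"),
                weight=float(t.get("weight", 1.0)),
                units=str(t.get("units", "")),
            )
            for t in raw.get("traits", [])
        ]
        sim = None
        if "simulation" in raw and raw["simulation"] is not None:
            simraw = dict(raw["simulation"])
            if "residual_cov" in simraw and simraw["residual_cov"] is not None:
                simraw["residual_cov"] = np.asarray(simraw["residual_cov"], float)
            sim = SimulationParams(**simraw)
        kwargs = {
            k: raw[k]
            for k in (
                "input_csv", "intensity", "use_weights", "do_manova",
                "do_mgidi_overall", "do_mgidi_combinations",
                "do_mgidi_per_environment", "gge_traits", "plots", "outdir",
                "seed", "verbosity",
            )
            if k in raw
        }
        return cls(traits=traits, simulation=sim, **kwargs)


def _write(frame: pd.DataFrame, path: Path, index: bool = False) -> Path:
    frame.to_csv(path, index=index, float_format=FLOAT_FMT)
    return path


def _load_dataset(config: RunConfig, outdir: Path) -> TrialDataset:
    if config.input_csv is not None:
        return read_met_csv(config.input_csv, config.traits)
    params = dataclasses.replace(config.simulation, seed=config.seed)
    dataset, truth = simulate_met(params)
    # keep declared trait specs if they match the simulated trait count
    if len(config.traits) == len(dataset.traits):
        dataset = TrialDataset(
            dataset.environments, dataset.genotypes, dataset.blocks,
            list(config.traits),
            dataset.values,
        )
        truth.noiseless_means.trait_codes = dataset.trait_codes
    write_met_csv(dataset, outdir / "dataset.csv")
    truth_frame = truth.noiseless_means.to_frame().reset_index()
    _write(truth_frame, outdir / "truth_noiseless_means.csv")
    with open(outdir / "truth_winners.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(
            {code: truth.winners(code) for code in dataset.trait_codes}, fh
        )
    return dataset


def _mgidi_tables(tag: str, means: MeanTable, config: RunConfig, outdir: Path
                  ) -> dict[str, Path]:
    model, result = mgidi_mod.run_mgidi(
        means, config.traits, use_weights=config.use_weights,
        intensity=config.intensity,
    )
    out = {}
    out[f"mgidi_{tag}"] = _write(result.to_frame(), outdir / f"mgidi_{tag}.csv")
    out[f"loadings_{tag}"] = _write(
        model.loadings_frame(), outdir / f"loadings_{tag}.csv", index=True
    )
    contrib = pd.DataFrame(
        result.contributions,
        index=[str(l) for l in result.row_labels],
        columns=[f"FA{k + 1}" for k in range(model.n_factors)],
    )
    out[f"contributions_{tag}"] = _write(
        contrib, outdir / f"contributions_{tag}.csv", index=True
    )
    eig = pd.DataFrame(
        {
            "factor": [f"FA{k + 1}" for k in range(model.n_factors)],
            "eigenvalue": model.eigenvalues[: model.n_factors],
            "cumulative_variance_pct": 100 * model.cumulative_variance,
        }
    )
    out[f"eigen_{tag}"] = _write(eig, outdir / f"eigen_{tag}.csv")
    if result.tie_warning:
        logger.warning("MGIDI (%s): tied distances in ranking", tag)
    return out


def _gge_tables(trait: str, means_ev: MeanTable, config: RunConfig, outdir: Path
                ) -> dict[str, object]:
    centered = gge_mod.center_matrix(means_ev, trait)
    model_g = gge_mod.gge_svd(centered, a=1, trait=trait)
    model_e = gge_mod.gge_svd(centered, a=0, trait=trait)
    www = gge_mod.which_won_where(model_g)
    aec = gge_mod.mean_vs_stability(model_g)
    metrics = gge_mod.environment_metrics(model_e)

    paths: dict[str, Path] = {}
    paths["centered"] = _write(centered, outdir / f"gge_{trait}_centered.csv", index=True)
    for mode, model in (("svp1", model_g), ("svp2", model_e)):
        gs = pd.DataFrame(model.genotype_scores, index=model.genotypes,
                          columns=["PC1", "PC2"])
        es = pd.DataFrame(model.environment_scores, index=model.environments,
                          columns=["PC1", "PC2"])
        paths[f"scores_{mode}"] = _write(
            pd.concat({"genotype": gs, "environment": es}, names=["side", "label"]),
            outdir / f"gge_{trait}_scores_{mode}.csv", index=True,
        )
    sectors = pd.DataFrame(
        {
            "environment": model_g.environments,
            "sector": [www.sector_of_env[e] for e in model_g.environments],
            "winner": [www.winner_of_env[e] for e in model_g.environments],
        }
    )
    paths["sectors"] = _write(sectors, outdir / f"gge_{trait}_sectors.csv")
    paths["aec"] = _write(gge_mod.rank_genotypes(aec), outdir / f"gge_{trait}_aec.csv")
    paths["env_metrics"] = _write(
        gge_mod.rank_environments(metrics), outdir / f"gge_{trait}_env_metrics.csv"
    )
    paths["relationship"] = _write(
        pd.DataFrame(metrics.relationship, index=model_e.environments,
                     columns=model_e.environments),
        outdir / f"gge_{trait}_env_relationship.csv", index=True,
    )
    explained = pd.DataFrame(
        {
            "PC": np.arange(1, len(model_g.explained) + 1),
            "explained_pct": 100 * model_g.explained,
        }
    )
    paths["explained"] = _write(explained, outdir / f"gge_{trait}_explained.csv")

    if config.plots:
        from . import plots as plots_mod

        plots_mod.plot_all_views(model_g, www, aec, model_e, metrics, outdir, trait)
    return {"paths": paths, "www": www, "aec": aec, "metrics": metrics,
            "explained": model_g.explained}


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the output directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("metsel")
    root.addHandler(handler)
    root.setLevel(logging.INFO if config.verbosity else logging.WARNING)
    try:
        return _run(config, outdir)
    except Exception as exc:  # annotate with stage context
        raise type(exc)(f"pipeline failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, outdir: Path) -> Path:
    dataset = _load_dataset(config, outdir)

    defects = validate_balanced(dataset)
    pd.DataFrame([dataclasses.asdict(d) for d in defects],
                 columns=["kind", "env", "gen", "rep", "trait", "message"]
                 ).to_csv(outdir / "validation.csv", index=False)
    if defects:
        raise MetDataError(f"validation stage: {len(defects)} defect(s); see validation.csv")

    summary: dict[str, object] = {"stages": []}

    if config.do_manova:
        res = manova_mod.fit_manova(dataset)
        _write(res.to_frame(), outdir / "manova.csv")
        comps = pd.concat(
            [manova_mod.variance_components(dataset, c).to_frame()
             for c in dataset.trait_codes],
            ignore_index=True,
        )
        _write(comps, outdir / "variance_components.csv")
        summary["stages"].append("manova")

    means_v = manova_mod.two_way_means(dataset, "by_genotype")
    means_ev = manova_mod.two_way_means(dataset, "by_genotype_environment")
    _write(means_v.to_frame().reset_index(), outdir / "means_by_genotype.csv")
    _write(means_ev.to_frame().reset_index(), outdir / "means_by_genotype_environment.csv")

    if config.do_mgidi_overall:
        _mgidi_tables("overall", means_v, config, outdir)
        summary["stages"].append("mgidi_overall")
    if config.do_mgidi_combinations:
        _mgidi_tables("combinations", means_ev, config, outdir)
        summary["stages"].append("mgidi_combinations")
    if config.do_mgidi_per_environment:
        ev_frame = means_ev.to_frame()
        for env in dataset.environments:
            sub = ev_frame.xs(env, level=0)
            sub_table = MeanTable(
                list(sub.index), list(sub.columns), sub.to_numpy(), "by_genotype"
            )
            _mgidi_tables(f"env_{env}", sub_table, config, outdir)
        summary["stages"].append("mgidi_per_environment")

    gge_summaries = {}
    for trait in config.gge_traits:
        if trait not in dataset.trait_codes:
            raise MetDataError(f"gge stage: unknown trait {trait!r}")
        gge_summaries[trait] = _gge_tables(trait, means_ev, config, outdir)
    if gge_summaries:
        summary["stages"].append("gge")
    summary["gge"] = gge_summaries

    manifest = {
        "seed": config.seed,
        "intensity": config.intensity,
        "use_weights": config.use_weights,
        "traits": [dataclasses.asdict(t) for t in config.traits],
        "input": config.input_csv or "simulated",
        "stages": summary["stages"],
        "gge_traits": list(config.gge_traits),
    }
    with open(outdir / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)

    report = generate_report(outdir, config, dataset, summary)
    (outdir / "report.md").write_text(report, encoding="utf-8")
    return outdir


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def generate_report(outdir: Path, config: RunConfig | None = None,
                    dataset: TrialDataset | None = None,
                    summary: dict | None = None) -> str:
    """Render a markdown summary from the tables present in ``outdir``.

    Only repeats information already in the CSV outputs; stages whose files
    are absent are reported as gaps.
    """
    outdir = Path(outdir)
    lines = ["# Multi-environment trial selection report", ""]
    if dataset is not None:
        e, v, r, p = dataset.shape
        lines += [f"Design: {e} environments x {v} genotypes x {r} blocks, "
                  f"{p} trait(s).", ""]

    manova_path = outdir / "manova.csv"
    if manova_path.exists():
        frame = pd.read_csv(manova_path)
        lines += ["## MANOVA (Pillai trace)", "",
                  "```\n" + frame.to_string(index=False, float_format=_fmt) + "\n```", ""]
    else:
        lines += ["## MANOVA", "", "_stage not run_", ""]

    any_mgidi = False
    for tag_path in sorted(outdir.glob("mgidi_*.csv")):
        any_mgidi = True
        tag = tag_path.stem.removeprefix("mgidi_")
        frame = pd.read_csv(tag_path)
        sel = frame[frame["selected"]] if "selected" in frame else frame
        lines += [f"## MGIDI selection ({tag})", "",
                  "Selected: " + ", ".join(sel["treatment"].astype(str)), ""]
        ranked = frame.sort_values("rank") if "rank" in frame else frame
        lines += ["```\n" + ranked.head(5).to_string(index=False, float_format=_fmt) + "\n```", ""]
    if not any_mgidi:
        lines += ["## MGIDI", "", "_stage not run_", ""]

    if summary and summary.get("gge"):
        for trait, info in summary["gge"].items():
            www = info["www"]
            metrics = info["metrics"]
            expl = info["explained"]
            lines += [f"## GGE biplot ({trait})", "",
                      f"PC1 {100 * expl[0]:.2f}%, PC2 {100 * expl[1]:.2f}% "
                      f"(PC1+PC2 {100 * (expl[0] + expl[1]):.2f}%) of GGE variation.", "",
                      "Mega-environments:"]
            for winner, envs in www.mega_environments.items():
                lines.append(f"- {', '.join(envs)} won by {winner}")
            if www.unresponsive:
                lines.append(
                    "- unresponsive vertex genotypes: " + ", ".join(www.unresponsive)
                )
            env_rank = gge_mod.rank_environments(metrics)
            best_env = env_rank.iloc[0]["environment"]
            lines += ["", f"Top-ranked (most discriminating and representative) "
                          f"environment: {best_env}", ""]
    else:
        for path in sorted(outdir.glob("gge_*_sectors.csv")):
            trait = path.stem.split("_")[1]
            sectors = pd.read_csv(path)
            lines += [f"## GGE biplot ({trait})", "",
                      "```\n" + sectors.to_string(index=False) + "\n```", ""]
        if not list(outdir.glob("gge_*_sectors.csv")):
            lines += ["## GGE biplots", "", "_stage not run_", ""]

    log_path = outdir / "run.log"
    if log_path.exists():
        warn = [ln for ln in log_path.read_text(encoding="utf-8").splitlines()
                if ln.startswith("WARNING")]
        if warn:
            lines += ["## Flagged anomalies", ""] + [f"- {w}" for w in warn] + [""]
    return "\n".join(lines) + "\n"
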