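"""Readers, validation, configuration and the end-to-end pipeline runner.

All interchange is plain CSV (UTF-8, comma-separated, header row, '.'
decimal) plus Newick for trees and YAML for configuration. The pipeline
runs: diversity -> PERMANOVA -> CWM at four scales -> slope decomposition
-> per-species trends -> phylogenetic signal -> PGLS -> trait covariation
-> environment models, writing one CSV per result plus a JSON manifest
(config hash, seeds, package version, per-stage record counts) sufficient
to reproduce the run exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community import (
    CoverTable,
    bray_curtis,
    diversity,
    permanova_marginal,
)
from .comparative import pgls, signal_test
from .cwm import (
    cwm_profiles,
    decompose,
    species_trends,
    trend_summary,
    _species_means,
)
from .phylo import Phylogeny
from .regression import mixed_fit, polyfit, sma_by_group, sma_fit
from .synth import SimulationConfig, make_dataset

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "read_tables", "run_pipeline", "ValidationError",
           "write_dataset", "load_config"]


class ValidationError(ValueError):
    """Cross-table validation failed; the message itemizes every problem."""


@dataclass
class PipelineConfig:
    """Paths and analysis settings for a pipeline run."""

    cover: str | None = None
    traits: str | None = None
    environment: str | None = None
    taxonomy: str | None = None
    tree: str | None = None
    out_dir: str = "results"
    domin_mapping: dict | None = None
    alpha_species_trends: float = 0.10
    n_permutations: int = 999
    n_signal_sims: int = 999
    permanova_terms: tuple = ("fire_freq",)
    seed: int = 0
    simulate: bool = False
    simulation: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_permutations < 99 or self.n_signal_sims < 99:
            raise ValueError("permutation/simulation counts must be >= 99")
        if int(self.seed) != self.seed:
            raise ValueError("seed must be an integer")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


def _config_hash(cfg: PipelineConfig) -> str:
    canon = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def read_tables(config: PipelineConfig):
    """Load and cross-validate cover, trait, environment and taxonomy tables.

    Returns ``(cover_table, traits, env, report)`` where ``report`` is the
    (empty, on success) list of validation findings. Orphan species,
    duplicate individual keys and unknown plots raise
    :class:`ValidationError` itemizing every failure.
    """
    taxonomy = pd.read_csv(config.taxonomy).set_index("species")
    cover_long = pd.read_csv(config.cover)
    if {"plot", "species", "cover"} <= set(cover_long.columns):
        matrix = (
            cover_long.pivot_table(index="plot", columns="species",
                                   values="cover", fill_value=0.0)
        )
    else:
        matrix = cover_long.set_index(cover_long.columns[0])
        matrix.index.name = "plot"
    traits = pd.read_csv(config.traits)
    env = pd.read_csv(config.environment)

    problems = []
    no_tax = set(matrix.columns) - set(taxonomy.index)
    if no_tax:
        problems.append(f"cover species missing from taxonomy: {sorted(no_tax)}")
    not_in_cover = set(traits["species"]) - set(matrix.columns)
    if not_in_cover:
        problems.append(
            f"trait species absent from cover table: {sorted(not_in_cover)}"
        )
    unknown_plots = set(traits["plot"]) - set(matrix.index)
    if unknown_plots:
        problems.append(f"trait records for unknown plots: {sorted(unknown_plots)}")
    env_unknown = set(env["plot"]) - set(matrix.index)
    if env_unknown:
        problems.append(f"environment rows for unknown plots: {sorted(env_unknown)}")
    if "individual" in traits.columns:
        dup = traits.duplicated(["plot", "species", "individual"])
        if dup.any():
            keys = traits.loc[dup, ["plot", "species", "individual"]]
            problems.append(
                f"duplicate (plot, species, individual) keys: "
                f"{keys.to_records(index=False).tolist()[:10]}"
            )
    if problems:
        raise ValidationError("; ".join(problems))
    cover = CoverTable(matrix=matrix, taxonomy=taxonomy)
    return cover, traits, env, []


def write_dataset(ds, out_dir) -> None:
    """Write a synthetic dataset as CSV/Newick/YAML files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    long = (
        ds.cover.matrix.stack().rename("cover").rename_axis(["plot", "species"])
        .reset_index()
    )
    long[long["cover"] > 0].to_csv(out / "cover.csv", index=False)
    ds.traits.to_csv(out / "traits.csv", index=False)
    ds.environment.to_csv(out / "environment.csv", index=False)
    ds.taxonomy.reset_index().to_csv(out / "taxonomy.csv", index=False)
    ds.tree.write(out / "tree.nwk")
    with open(out / "truth.yaml", "w") as fh:
        yaml.safe_dump(
            {k: v for k, v in ds.truth.items() if k != "species_means"}, fh,
            default_flow_style=False,
        )


def _seed_stream(seed: int):
    ss = np.random.SeedSequence(seed)
    while True:
        (child,) = ss.spawn(1)
        yield int(child.generate_state(1)[0] % (2 ** 31))


def run_pipeline(config: PipelineConfig):
    """Execute every stage and write one CSV per result plus a manifest.

    With ``config.simulate`` the input tables come from the synthetic
    generator (parameters in ``config.simulation``); otherwise they are
    read from the configured paths. Any stage failure aborts with the stage
    name; a FAILED marker file records the stage and cause.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _seed_stream(config.seed)
    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "stages": [],
    }

    def stage(name, func):
        try:
            info = func() or {}
        except Exception as err:
            (out / "FAILED").write_text(f"stage {name}: {err}\n")
            raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
        manifest["stages"].append({"name": name, **info})
        logger.info("stage %s done: %s", name, info)

    state = {}

    def load():
        if config.simulate:
            sim = SimulationConfig(**{**config.simulation,
                                      "rng_seed": config.seed})
            ds = make_dataset(sim)
            state.update(cover=ds.cover, traits=ds.traits, env=ds.environment,
                         tree=ds.tree, truth=ds.truth)
            write_dataset(ds, out / "simulated_input")
        else:
            cover, traits, env, _ = read_tables(config)
            tree = Phylogeny.from_file(config.tree) if config.tree else None
            state.update(cover=cover, traits=traits, env=env, tree=tree,
                         truth=None)
        return {"n_plots": len(state["cover"].matrix),
                "n_species": len(state["cover"].matrix.columns),
                "n_trait_records": len(state["traits"])}

    stage("load", load)

    def stage_diversity():
        div = diversity(state["cover"], state["tree"])
        div.to_csv(out / "diversity.csv")
        state["diversity"] = div
        return {"rows": len(div)}

    stage("diversity", stage_diversity)

    def stage_permanova():
        d = bray_curtis(state["cover"])
        d.to_csv(out / "bray_curtis.csv")
        env_plot = (
            state["env"].groupby("plot", sort=False).mean(numeric_only=True)
        )
        terms = [t for t in config.permanova_terms if t in env_plot.columns]
        res = permanova_marginal(
            d, env_plot.loc[d.index, terms],
            n_perm=config.n_permutations, seed=next(seeds),
        )
        res.table.to_csv(out / "permanova.csv")
        state["permanova"] = res
        return {"terms": terms, "n_perm": res.n_permutations}

    stage("permanova", stage_permanova)

    def stage_cwm():
        profiles = cwm_profiles(state["cover"], state["traits"])
        profiles.to_csv(out / "cwm_profiles.csv", index=False)
        state["profiles"] = profiles
        return {"rows": len(profiles)}

    stage("cwm", stage_cwm)

    def stage_decompose():
        dec = decompose(state["profiles"], state["env"])
        dec.slopes.to_csv(out / "cwm_slopes.csv")
        dec.pct_change.to_csv(out / "cwm_slope_changes.csv", index=False)
        pd.Series(dec.co_gradient).rename("co_gradient").to_csv(
            out / "co_gradient.csv"
        )
        state["decomposition"] = dec
        return {"traits": sorted(dec.co_gradient)}

    stage("decompose", stage_decompose)

    def stage_trends():
        trends = species_trends(state["traits"], state["env"],
                                alpha=config.alpha_species_trends)
        trends.to_csv(out / "species_trends.csv", index=False)
        trend_summary(trends).to_csv(out / "species_trend_summary.csv")
        state["trends"] = trends
        return {"rows": len(trends)}

    stage("species_trends", stage_trends)

    def stage_signal():
        if state["tree"] is None:
            return {"skipped": "no tree supplied"}
        sp_means = _species_means(state["traits"])
        rows = []
        for trait in ("n_mass", "sla"):
            res = signal_test(
                state["tree"], sp_means[trait].dropna(),
                n_sims=config.n_signal_sims, seed=next(seeds),
            )
            rows.append((trait, res.k, res.p_vs_bm, res.p_vs_white_noise,
                         res.n_null_sims, res.n_tips))
        sig = pd.DataFrame(
            rows, columns=["trait", "k", "p_vs_bm", "p_vs_white_noise",
                           "n_null_sims", "n_tips"],
        )
        sig.to_csv(out / "phylogenetic_signal.csv", index=False)
        state["signal"] = sig
        return {"traits": list(sig["trait"])}

    stage("signal", stage_signal)

    def stage_pgls():
        if state["tree"] is None:
            return {"skipped": "no tree supplied"}
        sp_means = _species_means(state["traits"]).dropna(subset=["sla", "n_mass"])
        fit = pgls(state["tree"], sp_means["sla"], sp_means["n_mass"])
        pd.DataFrame(
            {
                "coef": fit.params, "se": fit.bse, "p": fit.pvalues,
            }
        ).assign(lambda_hat=fit.lambda_hat, r_squared=fit.r_squared,
                 log_likelihood=fit.log_likelihood).to_csv(out / "pgls.csv")
        state["pgls"] = fit
        return {"lambda_hat": round(fit.lambda_hat, 4), "n": fit.n}

    stage("pgls", stage_pgls)

    def stage_covariation():
        traits = state["traits"].merge(
            state["cover"].taxonomy[["functional_group"]],
            left_on="species", right_index=True, how="left",
        )
        env_plot = state["env"].drop_duplicates("plot").set_index("plot")
        traits["fire_freq"] = traits["plot"].map(env_plot["fire_freq"])
        overall = sma_fit(traits["percent_n"], traits["sla"])
        by_fire = sma_by_group(traits, "percent_n", "sla", by="fire_freq")
        by_group = sma_by_group(traits, "percent_n", "sla",
                                by=["fire_freq", "functional_group"])
        pd.DataFrame(
            [{"scope": "all", "n": overall.n, "slope": overall.slope,
              "intercept": overall.intercept, "r": overall.r,
              "rho": overall.rho, "p_value": overall.p_value}]
        ).to_csv(out / "covariation_overall.csv", index=False)
        by_fire.to_csv(out / "covariation_by_fire.csv", index=False)
        by_group.to_csv(out / "covariation_by_group.csv", index=False)
        state["covariation"] = {"overall": overall, "by_fire": by_fire}
        return {"groups": len(by_group)}

    stage("covariation", stage_covariation)

    def stage_environment():
        env = state["env"]
        env_plot = env.drop_duplicates("plot")
        rows = []
        light = polyfit(env_plot["fire_freq"], env_plot["light_penetration"], 1)
        rows.append(("light_penetration", "linear", light.f_statistic,
                     light.df_num, light.df_den, light.p_value, light.r_squared))
        for var in ("n_mineralisation", "inorganic_n"):
            fit = mixed_fit(env[var], env["fire_freq"], env["plot"], degree=2)
            rows.append((var, "mixed_quadratic", fit.f_statistic, fit.df_num,
                         fit.df_den, fit.p_value, fit.r_squared))
        for var in ("richness", "shannon", "faith_pd", "pielou"):
            div = state["diversity"].dropna(subset=[var])
            fire = env_plot.set_index("plot").loc[div.index, "fire_freq"]
            fit = polyfit(fire, div[var], 2)
            rows.append((var, "quadratic", fit.f_statistic, fit.df_num,
                         fit.df_den, fit.p_value, fit.r_squared))
        table = pd.DataFrame(
            rows, columns=["response", "model", "f", "df_num", "df_den",
                           "p_value", "r_squared"],
        )
        table.to_csv(out / "environment_models.csv", index=False)
        state["env_models"] = table
        return {"models": len(table)}

    stage("environment_models", stage_environment)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return state, manifest
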