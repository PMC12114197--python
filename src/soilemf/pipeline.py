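"""End-to-end orchestration: indices -> diversity -> networks -> drivers."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import AbundanceTable
from .diversity import diversity_table
from .drivers import anova_tukey, mantel_grid, path_analysis, rf_importance
from .io import (
    read_abundance_tsv,
    read_indicator_csv,
    read_metadata_csv,
    sha256_of,
    write_manifest,
)
from .multifunctionality import DEFAULT_EFC_GROUP, MultifunctionalityIndex
from .network import CooccurrenceNetwork, per_treatment_networks, topology_frame

ENZYME_GROUP = ("S-ALP", "S-CAT", "S-CL", "S-UE", "S-SC")


@dataclass
class PipelineConfig:
    indicator_csv: str
    bacteria_tsv: str
    fungi_tsv: str
    metadata_csv: str
    output_dir: str
    groups: dict[str, list[str]] | None = None
    directions: dict[str, int] = field(default_factory=dict)
    constant_policy: str = "drop"
    min_prevalence: float = 0.2
    top_n: int | None = None
    rho_threshold: float = 0.6
    p_threshold: float = 0.05
    n_permutations: int = 999
    n_trees: int = 500
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def stage_seeds(self) -> dict[str, int]:
        """Deterministically split the master seed per randomized stage."""
        state = np.random.SeedSequence(self.seed).generate_state(3)
        names = ("network", "mantel", "rf")
        return {n: int(s % 2**31) for n, s in zip(names, state)}


def _default_groups(columns) -> dict[str, list[str]]:
    groups = {}
    efc = [c for c in DEFAULT_EFC_GROUP if c in columns]
    if efc:
        groups["EF-C"] = efc
    enzymes = [c for c in ENZYME_GROUP if c in columns]
    if enzymes:
        groups["EF-enzyme"] = enzymes
    return groups


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write CSV/GraphML outputs plus a manifest.

    Reruns with an identical config are byte-identical (the manifest
    carries no timestamps, and every randomized stage is seeded from the
    master seed).
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    outputs: dict[str, Path] = {}

    def _stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    # ---- inputs ----
    load = _stage("load")
    indicators = load(read_indicator_csv, config.indicator_csv)
    metadata = load(read_metadata_csv, config.metadata_csv)
    tables = {
        "bacteria": load(
            read_abundance_tsv, config.bacteria_tsv, "bacteria", metadata
        ),
        "fungi": load(read_abundance_tsv, config.fungi_tsv, "fungi", metadata),
    }

    # ---- EMF indices ----
    groups = config.groups or _default_groups(indicators.columns)
    emf_est = _stage("emf")(
        MultifunctionalityIndex(
            groups=groups,
            directions=config.directions,
            constant_policy=config.constant_policy,
        ).fit,
        indicators,
    )
    scores = pd.concat(
        [emf_est.standardized_, emf_est.ef_, emf_est.emf_], axis=1
    )
    scores.insert(0, "treatment", metadata.reindex(scores.index))
    outputs["emf_scores"] = outdir / "emf_scores.csv"
    scores.to_csv(outputs["emf_scores"], index_label="plot")

    # ---- alpha diversity ----
    div = {
        k: diversity_table(t, metadata) for k, t in tables.items()
    }
    diversity = pd.concat(div, names=["kingdom", "sample"]).reset_index()
    outputs["diversity"] = outdir / "diversity.csv"
    diversity.to_csv(outputs["diversity"], index=False)

    # ---- treatment contrasts (ANOVA + Tukey letters) ----
    tukey_rows = []

    def add_tukey(name, values):
        try:
            rep = anova_tukey(values, metadata.loc[values.index])
        except ValueError as exc:
            warnings.warn(f"Tukey skipped for {name}: {exc}", stacklevel=2)
            return
        t = rep.table.reset_index(names="treatment")
        t.insert(0, "variable", name)
        t["f_statistic"], t["p_value"] = rep.f_statistic, rep.p_value
        tukey_rows.append(t)

    add_tukey("EMF", emf_est.emf_)
    for g in emf_est.ef_.columns:
        add_tukey(g, emf_est.ef_[g])
    for k, d in div.items():
        for idx in ("shannon", "simpson", "chao1", "ace"):
            add_tukey(f"{k}_{idx}", d[idx])
    tukey = pd.concat(tukey_rows, ignore_index=True)
    tukey["alpha"] = 0.05
    outputs["tukey_report"] = outdir / "tukey_report.csv"
    tukey.to_csv(outputs["tukey_report"], index=False)

    # ---- co-occurrence networks ----
    topo_frames = {}
    for kingdom, table in tables.items():
        est = _stage("network")(
            CooccurrenceNetwork(
                min_prevalence=config.min_prevalence,
                top_n=config.top_n,
                rho_threshold=config.rho_threshold,
                p_threshold=config.p_threshold,
                seed=seeds["network"],
            ).fit,
            table,
        )
        outputs[f"{kingdom}_edges"] = outdir / f"{kingdom}_edges.csv"
        est.edge_list().to_csv(outputs[f"{kingdom}_edges"], index=False)
        outputs[f"{kingdom}_graphml"] = outdir / f"{kingdom}_network.graphml"
        nx.write_graphml(est.graph_, outputs[f"{kingdom}_graphml"])
        topo_frames[(kingdom, "all")] = est.topology_
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            per_t = per_treatment_networks(
                table,
                metadata,
                min_prevalence=config.min_prevalence,
                top_n=config.top_n,
                rho_threshold=config.rho_threshold,
                p_threshold=config.p_threshold,
                seed=seeds["network"],
            )
        for treatment, (_, summary) in per_t.items():
            topo_frames[(kingdom, treatment)] = summary
    topo = topology_frame({f"{k}:{t}": s for (k, t), s in topo_frames.items()})
    outputs["topology"] = outdir / "topology.csv"
    topo.to_csv(outputs["topology"], index_label="metric")

    # ---- Mantel grid ----
    grid = _stage("mantel")(
        mantel_grid, indicators, tables, config.n_permutations, seeds["mantel"]
    )
    outputs["mantel_grid"] = outdir / "mantel_grid.csv"
    grid.to_csv(outputs["mantel_grid"], index=False)

    # ---- driver attribution: RF importance + path analysis ----
    drivers_data = pd.DataFrame(
        {
            "EMF": emf_est.emf_,
            **{g: emf_est.ef_[g] for g in emf_est.ef_.columns},
            "bacteria_shannon": div["bacteria"]["shannon"],
            "fungi_shannon": div["fungi"]["shannon"],
        }
    )
    predictors = [c for c in drivers_data.columns if c != "EMF"]
    importance = _stage("rf")(
        rf_importance,
        drivers_data[predictors],
        drivers_data["EMF"],
        config.n_trees,
        10,
        seeds["rf"],
    )
    outputs["importance"] = outdir / "importance.csv"
    importance.to_csv(outputs["importance"], index_label="predictor")

    edges = [(p, "EMF") for p in predictors]
    path = _stage("path")(path_analysis, drivers_data, edges)
    coeffs = path.coefficients_.copy()
    coeffs["r2_child"] = coeffs["child"].map(path.r2_)
    coeffs["seed"] = config.seed
    outputs["path_coefficients"] = outdir / "path_coefficients.csv"
    coeffs.to_csv(outputs["path_coefficients"], index=False)

    # ---- manifest ----
    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "stage_seeds": seeds,
        "inputs": {
            name: {"path": str(p), "sha256": sha256_of(p)}
            for name, p in {
                "indicator_csv": config.indicator_csv,
                "bacteria_tsv": config.bacteria_tsv,
                "fungi_tsv": config.fungi_tsv,
                "metadata_csv": config.metadata_csv,
            }.items()
        },
        "outputs": {k: str(v) for k, v in outputs.items()},
    }
    outputs["manifest"] = outdir / "manifest.json"
    write_manifest(manifest, outputs["manifest"])
    return {"outputs": outputs, "manifest": manifest}
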