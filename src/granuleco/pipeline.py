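"""End-to-end analysis pipeline with a machine-readable report.

Orchestrates the full analysis graph on a loaded dataset or a synthetic
scenario: rarefaction -> prevalence/abundance filter -> Hill alpha profiles
and successive beta series -> phylogenetic-signal check -> NRI/NTI series
-> turnover series (betaNTI, RCbray) -> per-kingdom consensus networks,
modules, module dynamics and per-time-point network stats -> inter-kingdom
bipartite core network -> forward selection -> dbRDA + three-way variance
partitioning. Tidy TSVs are the source of truth; summary.json aggregates
per-stage means and significance-call fractions; run.log records every
effective parameter and seed.

One master seed drives everything: stage RNG streams are spawned from
``numpy.random.SeedSequence(master_seed)`` in a fixed documented order
(rarefy=0, signal=1, nulls=2, networks=3, bipartite=4, ordination=5, per
kingdom where applicable), so any stage can be re-run in isolation.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assembly, data_io, diversity, networks, ordination, synthetic
from .data_io import DEFAULT_STAGE_BOUNDARIES, STAGES

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("granuleco")

_STAGE_STREAMS = {
    "rarefy": 0,
    "signal": 1,
    "nulls": 2,
    "networks": 3,
    "bipartite": 4,
    "ordination": 5,
}


@dataclass
class PipelineConfig:
    """All knobs of the pipeline in one place."""

    # either explicit inputs ...
    prok_table: str | None = None
    euk_table: str | None = None
    prok_tree: str | None = None
    euk_tree: str | None = None
    env: str | None = None
    # ... or a synthetic scenario
    scenario_preset: str | None = None
    scenario_overrides: dict = field(default_factory=dict)

    rarefaction_depth: tuple | None = None  # None = min sample total per kingdom
    min_prevalence: float = 0.10
    min_rel_abundance: float = 0.001
    q_grid: tuple = (0, 1, 2)
    beta_variant: str = "local"
    n_null: int = 999
    signal_variable: str = "nitrate"
    signal_classes: int = 6
    signal_permutations: int = 999
    corr_threshold: float = 0.6
    alpha: float = 0.05
    core_prevalence: float = 0.75
    sparcc: dict = field(default_factory=dict)
    walktrap_steps: int = 4
    n_perm_ordination: int = 999
    forward_alpha: float = 0.05
    stage_boundaries: tuple = DEFAULT_STAGE_BOUNDARIES
    seed: int = 0
    outdir: str = "granuleco_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def seed_for(self, stage: str, kingdom_index: int = 0):
        """Deterministic per-stage RNG stream from the master seed."""
        return np.random.SeedSequence(
            self.seed, spawn_key=(_STAGE_STREAMS[stage], kingdom_index)
        )


def _stage_means(values: np.ndarray, stages: list) -> dict:
    out = {}
    v = np.asarray(values, dtype=float)
    for s in STAGES:
        sel = np.array([st == s for st in stages])
        out[s] = float(np.nanmean(v[sel])) if sel.any() else None
    return out


def _round(obj, nd=6):
    if isinstance(obj, dict):
        return {k: _round(v, nd) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round(v, nd) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return None if not np.isfinite(obj) else round(float(obj), nd)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def _load_or_simulate(config: PipelineConfig):
    if config.scenario_preset is not None:
        scenario = synthetic.preset_scenario(
            config.scenario_preset, seed=config.seed, **config.scenario_overrides
        )
        log.info("simulating scenario preset %r", config.scenario_preset)
        return synthetic.simulate_reactor_series(scenario)
    needed = [config.prok_table, config.euk_table, config.prok_tree, config.euk_tree, config.env]
    if any(v is None for v in needed):
        raise ValueError("config must give either a scenario_preset or all five input paths")
    pk, pt, env = data_io.load_dataset(
        config.prok_table, config.prok_tree, config.env, kingdom="prokaryote"
    )
    ek, et, _ = data_io.load_dataset(
        config.euk_table, config.euk_tree, config.env, kingdom="eukaryote"
    )
    return synthetic.SyntheticDataset(pk, ek, pt, et, env, {"asv_truth": None, "coupled_guilds": None, "stage_regime": None, "scenario": None})


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis graph; returns the JSON-ready summary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, outdir)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, outdir: Path) -> dict:
    log.info("effective config: %s", dataclasses.asdict(config))
    ds = _load_or_simulate(config)
    stages = ds.env.stages
    summary: dict = {
        "schema_version": 1,
        "seed": config.seed,
        "n_samples": ds.prok_table.n_samples,
        "stages": {s: int(sum(st == s for st in stages)) for s in STAGES},
        "kingdoms": {},
    }
    if ds.truth.get("asv_truth") is not None:
        ds.truth["asv_truth"].to_csv(outdir / "truth.tsv", sep="\t", index=False)

    tables = {}       # network-filtered tables
    full_tables = {}  # rarefied, unfiltered tables
    trees = {"prokaryote": ds.prok_tree, "eukaryote": ds.euk_tree}
    nets = {}
    module_labels = {}
    hill_wide = {}
    for ki, (kingdom, table) in enumerate(
        (("prokaryote", ds.prok_table), ("eukaryote", ds.euk_table))
    ):
        ksum: dict = {}
        log.info("[%s] %d samples x %d ASVs", kingdom, table.n_samples, table.n_asvs)
        depth = (
            int(config.rarefaction_depth[ki])
            if config.rarefaction_depth is not None
            else int(table.totals().min())
        )
        table = data_io.rarefy(
            table, depth, seed=config.seed_for("rarefy", ki).generate_state(1)[0] % 2**31
        )
        # the prevalence/abundance filter belongs to the network analysis;
        # diversity, null models and ordination run on the full rarefied table
        net_table = data_io.filter_prevalence_abundance(
            table, config.min_prevalence, config.min_rel_abundance
        )
        tables[kingdom] = net_table
        full_tables[kingdom] = table
        ksum["rarefaction_depth"] = depth
        ksum["n_asvs"] = table.n_asvs
        ksum["n_asvs_after_filter"] = net_table.n_asvs
        log.info(
            "[%s] rarefied to %d; %d ASVs, %d pass the network filter",
            kingdom, depth, table.n_asvs, net_table.n_asvs,
        )

        # diversity
        hp = diversity.hill_profile(table, config.q_grid)
        hp.to_csv(outdir / f"{kingdom}_hill_alpha.tsv", sep="\t", index=False)
        hill_wide[kingdom] = hp.pivot(index="sample_id", columns="q", values="qTD")
        bs = diversity.successive_beta_series(table, config.q_grid, config.beta_variant)
        bs.to_csv(outdir / f"{kingdom}_beta_series.tsv", sep="\t", index=False)
        ksum["n_beta_pairs_per_q"] = int((bs["q"] == bs["q"].iloc[0]).sum())
        ksum["alpha_stage_means"] = {
            str(q): _stage_means(
                hill_wide[kingdom][float(q)].to_numpy(), stages
            )
            for q in config.q_grid
        }
        pair_stages = [stages[t + 1] for t in range(table.n_samples - 1)]
        ksum["beta_dissimilarity_stage_means"] = {
            str(q): _stage_means(
                bs[bs["q"] == float(q)]["dissimilarity"].to_numpy(), pair_stages
            )
            for q in config.q_grid
        }

        # phylogenetic signal (needs enough ASVs for distance classes)
        if net_table.n_asvs < 10:
            ksum["phylo_signal"] = "skipped: fewer than 10 ASVs"
            log.warning("[%s] phylo-signal stage skipped: too few ASVs", kingdom)
            optima = None
        else:
            optima = assembly.env_optima(net_table, ds.env, config.signal_variable)
            cg = assembly.mantel_correlogram(
            optima,
            trees[kingdom],
            n_classes=config.signal_classes,
            n_perm=config.signal_permutations,
                seed=config.seed_for("signal", ki),
            )
            cg.classes.to_csv(outdir / f"{kingdom}_correlogram.tsv", sep="\t", index=False)
            first = cg.classes.iloc[0]
            ksum["phylo_signal"] = {
                "shortest_class_r": float(first["mantel_r"]),
                "shortest_class_p_corrected": float(first["p_corrected"]),
                "n_significant_classes": int(
                    (cg.classes["p_corrected"] <= config.alpha).sum()
                ),
            }
            log.info("[%s] phylo signal shortest-class r=%.3f", kingdom, first["mantel_r"])

        # NRI / NTI
        ses = assembly.nri_nti_series(
            table, trees[kingdom], n_null=config.n_null, seed=config.seed_for("nulls", ki)
        )
        ses.to_csv(outdir / f"{kingdom}_nri_nti.tsv", sep="\t", index=False)
        ksum["nri_stage_means"] = _stage_means(ses["nri"].to_numpy(), stages)
        ksum["nti_stage_means"] = _stage_means(ses["nti"].to_numpy(), stages)
        ksum["nri_mean"] = float(np.nanmean(ses["nri"]))
        ksum["nti_mean"] = float(np.nanmean(ses["nti"]))

        # turnover
        tos = assembly.turnover_series(
            table,
            trees[kingdom],
            n_null=config.n_null,
            seed=config.seed_for("nulls", ki + 2),
        )
        tos.to_csv(outdir / f"{kingdom}_turnover.tsv", sep="\t", index=False)
        ksum["bnti_mean"] = float(np.nanmean(tos["bnti"]))
        ksum["frac_bnti_deterministic"] = float(np.mean(np.abs(tos["bnti"]) > 2))
        ksum["frac_rc_deviating"] = float(np.mean(np.abs(tos["rc"]) > 0.95))
        ksum["bnti_stage_fraction_deterministic"] = _stage_means(
            (np.abs(tos["bnti"]) > 2).astype(float), pair_stages
        )
        ksum["rc_stage_fraction_deviating"] = _stage_means(
            (np.abs(tos["rc"]) > 0.95).astype(float), pair_stages
        )

        # consensus network (SparCC needs >= 10 samples, >= 4 ASVs)
        if table.n_samples < 10 or net_table.n_asvs < 4:
            ksum["network"] = "skipped: too few samples or ASVs for SparCC"
            log.warning("[%s] network stage skipped: dataset too small", kingdom)
            summary["kingdoms"][kingdom] = ksum
            continue
        net = networks.consensus_network_from_table(
            net_table,
            corr_threshold=config.corr_threshold,
            alpha=config.alpha,
            seed=config.seed_for("networks", ki).generate_state(1)[0] % 2**31,
            sparcc_kwargs=config.sparcc,
        )
        labels = networks.detect_modules(net, steps=config.walktrap_steps, table=net_table)
        nets[kingdom], module_labels[kingdom] = net, labels
        net.edges_table().to_csv(outdir / f"{kingdom}_edges.tsv", sep="\t", index=False)
        net.nodes_table().to_csv(outdir / f"{kingdom}_nodes.tsv", sep="\t", index=False)
        md = networks.module_dynamics(net, net_table)
        md.to_csv(outdir / f"{kingdom}_module_dynamics.tsv", sep="\t", index=False)
        st = networks.per_sample_network_stats(net, net_table, steps=config.walktrap_steps)
        st.to_csv(outdir / f"{kingdom}_network_stats.tsv", sep="\t", index=False)
        n_modules = len(set(labels.values()))
        ksum["network"] = {
            "n_nodes": net.n_nodes,
            "n_edges": net.n_edges,
            "n_modules": n_modules,
            "modularity_mean": float(np.nanmean(st["modularity"])) if len(st) else None,
        }
        stage_arr = np.array(stages)
        mod_summary = {}
        for m in sorted(set(labels.values())):
            sub = md[md["module"] == m]
            comp = sub.set_index("sample_id").loc[net_table.sample_ids, "completeness"].to_numpy()
            ab = sub.set_index("sample_id").loc[net_table.sample_ids, "abundance"].to_numpy()
            mod_summary[str(m)] = {
                "n_nodes": int(sum(1 for v in labels.values() if v == m)),
                "completeness_stage_means": _stage_means(comp, stages),
                "abundance_stage_means": _stage_means(ab, stages),
            }
        ksum["modules"] = mod_summary
        log.info(
            "[%s] network %d nodes / %d edges / %d modules",
            kingdom,
            net.n_nodes,
            net.n_edges,
            n_modules,
        )
        summary["kingdoms"][kingdom] = ksum

    # bipartite core network
    if len(nets) < 2:
        summary["bipartite"] = "skipped: within-kingdom networks unavailable"
        log.warning("bipartite stage skipped")
        _write_ordination(config, ds, full_tables, hill_wide, stages, outdir, summary)
        summary = _round(summary)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        log.info("report written to %s", outdir)
        return summary
    bip = networks.build_bipartite_core_network(
        tables["prokaryote"],
        tables["eukaryote"],
        core_prevalence=config.core_prevalence,
        corr_threshold=config.corr_threshold,
        alpha=config.alpha,
        seed=config.seed_for("bipartite").generate_state(1)[0] % 2**31,
        sparcc_kwargs=config.sparcc,
        prok_modules=module_labels["prokaryote"],
        euk_modules=module_labels["eukaryote"],
    )
    bip.edges_table().to_csv(outdir / "bipartite_edges.tsv", sep="\t", index=False)
    bip.module_pair_counts.to_csv(outdir / "bipartite_module_pairs.tsv", sep="\t", index=False)
    summary["bipartite"] = {
        "n_prok_core": len(bip.prok_core),
        "n_euk_core": len(bip.euk_core),
        "n_edges": bip.n_edges,
        "module_pairs": [
            {
                "prok_module": None if pd.isna(r["prok_module"]) else int(r["prok_module"]),
                "euk_module": None if pd.isna(r["euk_module"]) else int(r["euk_module"]),
                "n_edges": int(r["n_edges"]),
            }
            for _, r in bip.module_pair_counts.iterrows()
        ],
    }
    log.info("bipartite core network: %d edges", bip.n_edges)

    _write_ordination(config, ds, full_tables, hill_wide, stages, outdir, summary)

    summary = _round(summary)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("report written to %s", outdir)
    return summary


def _write_ordination(config, ds, full_tables, hill_wide, stages, outdir, summary):
    """Forward selection + dbRDA + variance partitioning per kingdom.

    Skipped (with a note in the summary) when the sample count cannot
    support the combined three-set model's degrees of freedom.
    """
    for ki, kingdom in enumerate(("prokaryote", "eukaryote")):
        table = full_tables[kingdom]
        other = "eukaryote" if kingdom == "prokaryote" else "prokaryote"
        n = table.n_samples
        abiotic_all = ds.env.frame[ds.env.variables].drop(
            columns=["latent_state"], errors="ignore"
        )
        n_stage_levels = len(set(stages))
        m_full = abiotic_all.shape[1] + 3 + (n_stage_levels - 1)
        if n - 2 <= m_full:
            summary["kingdoms"][kingdom]["ordination"] = (
                "skipped: too few samples for the combined model"
            )
            log.warning("[%s] ordination stage skipped: n too small", kingdom)
            continue
        dmat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                dmat[i, j] = dmat[j, i] = diversity.bray_curtis(
                    table.counts[i], table.counts[j]
                )
        seed_fs = config.seed_for("ordination", ki).generate_state(2)
        selected = ordination.forward_select_predictors(
            dmat,
            abiotic_all,
            alpha=config.forward_alpha,
            n_perm=config.n_perm_ordination,
            seed=int(seed_fs[0] % 2**31),
        )
        abiotic = abiotic_all[selected] if selected else abiotic_all
        biotic = hill_wide[other].loc[table.sample_ids].rename(
            columns=lambda q: f"{other}_qTD{int(q)}"
        )
        stage_df = pd.DataFrame({"stage": stages}, index=table.sample_ids)
        fit = ordination.dbrda(
            dmat,
            pd.concat([abiotic, biotic, stage_df], axis=1),
            n_perm=config.n_perm_ordination,
            seed=int(seed_fs[1] % 2**31),
        )
        vp = ordination.variance_partition(dmat, abiotic, biotic, stage_df)
        vp.as_frame().to_csv(outdir / f"{kingdom}_varpart.tsv", sep="\t", index=False)
        summary["kingdoms"][kingdom]["ordination"] = {
            "selected_abiotic": selected,
            "dbrda_r2": fit.r2,
            "dbrda_adj_r2": fit.adj_r2,
            "dbrda_p": fit.p_value,
            "varpart": vp.fractions,
        }
        log.info("[%s] dbRDA adjR2=%.3f (p=%.4f)", kingdom, fit.adj_r2, fit.p_value)
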