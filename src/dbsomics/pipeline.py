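"""Orchestration: one reproducible run over synthetic or user-supplied inputs.

The run configuration is a schema-validated YAML document (unknown keys are
rejected); every threshold defaults to the study's printed value and the
resolved configuration is echoed into the output directory. Stages execute in
dependency order; a stage failure aborts its dependents while independent
stages continue, and the run exits nonzero with a machine-readable error list.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import io as dio
from .annotation import write_bed
from .assays import qpcr_relative, tmt_protein_stats
from .deconvolution import build_reference_signals, fit_psea, select_models
from .diffexpr import (classify_degs, classify_rescue, cluster_samples,
                       estimate_size_factors, fit_differential,
                       normalized_group_means)
from .genesets import overlap_test
from .isoforms import detect_switches, test_isoforms_dual
from .methylome import annotate_regions, call_dmrs, call_methylation, \
    enrichment_permutation
from .network import extract_two_layer
from .simulate import (MARKER_GENES, PlantedEffect, RescueConfig, SimConfig,
                       generate_assay_tables, generate_counts,
                       generate_isoform_counts, generate_methylome,
                       generate_network)

logger = logging.getLogger("dbsomics")


class Stages(BaseModel):
    model_config = ConfigDict(extra="forbid")
    de: bool = True
    rescue: bool = True
    clustering: bool = True
    isoforms: bool = True
    methylome: bool = True
    psea: bool = True
    overlap: bool = True
    network: bool = True
    assays: bool = True


class Thresholds(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_mean: float = 40.0
    fc: float = 2.0
    rescue_fc: float = 1.2
    iso_fc: float = 1.3
    fdr: float = 0.05
    min_cov: int = 10
    min_diff: float = 50.0
    tile: int = 1000
    permutations: int = 1000
    psea_f_p: float = 0.01
    psea_adj_r2: float = 0.8


class SimSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_genes: int = 1200
    baseline_mean: float = 200.0
    dispersion: float = 0.05
    n_dbs_up: int = 60
    dbs_log2fc: float = 2.5
    rescue_n_down: int = 120
    n_dmrs: int = 20
    dmr_delta: float = 0.8


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    outdir: str = "dbsomics_run"
    stages: Stages = Stages()
    thresholds: Thresholds = Thresholds()
    sim: SimSection = SimSection()

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _sim_config(cfg: RunConfig) -> SimConfig:
    sc = SimConfig(seed=cfg.seed, n_genes=cfg.sim.n_genes,
                   baseline_mean=cfg.sim.baseline_mean,
                   dispersion=cfg.sim.dispersion,
                   rescue=RescueConfig(n_down=cfg.sim.rescue_n_down))
    rng = np.random.default_rng(cfg.seed + 100)
    n_marker = sum(len(v) for v in MARKER_GENES.values())
    up = rng.choice(np.arange(n_marker, sc.n_genes), size=cfg.sim.n_dbs_up,
                    replace=False)
    sc.planted_effects = [
        PlantedEffect(feature=f"g{i:05d}", log2fc=cfg.sim.dbs_log2fc,
                      treatment="DBS")
        for i in up
    ]
    span = sc.methylome.genome_length // max(cfg.sim.n_dmrs, 1)
    sc.methylome.planted_dmrs = [
        (i * span + span // 3, i * span + span // 3 + 1000,
         cfg.sim.dmr_delta if i % 2 == 0 else -cfg.sim.dmr_delta, "mCG")
        for i in range(cfg.sim.n_dmrs)
    ]
    return sc


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; returns the summary dict.

    Writes per-stage TSVs, summary.json, the resolved config, and a run log
    into cfg.outdir. Raises RuntimeError listing failed stages if any stage
    errored (dependent stages are skipped, independent ones still run).
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    import dbsomics
    logger.info("dbsomics %s | seed=%d | thresholds=%s", dbsomics.__version__,
                cfg.seed, cfg.thresholds.model_dump())
    (out / "config.resolved.yaml").write_text(
        yaml.safe_dump(cfg.model_dump(), sort_keys=True)
    )

    th = cfg.thresholds
    summary: dict = {"seed": cfg.seed}
    errors: list[dict] = []
    done: set[str] = set()

    def stage(name: str, deps: tuple[str, ...] = ()):
        def deco(fn):
            def run():
                if not getattr(cfg.stages, name, True):
                    logger.info("stage %s disabled", name)
                    return
                if any(d not in done for d in deps):
                    errors.append({"stage": name, "error": "dependency failed",
                                   "deps": list(deps)})
                    logger.error("stage %s skipped: dependency failed", name)
                    return
                t0 = time.time()
                try:
                    fn()
                    done.add(name)
                    logger.info("stage %s ok (%.1fs)", name, time.time() - t0)
                except Exception as exc:  # noqa: BLE001 - reported, run continues
                    errors.append({"stage": name, "error": str(exc)})
                    logger.exception("stage %s failed", name)
            return run
        return deco

    sc = _sim_config(cfg)
    state: dict = {}

    @stage("de")
    def _de():
        cm, truth = generate_counts(sc)
        state["cm"], state["truth"] = cm, truth
        dio.write_counts(cm, str(out / "counts.tsv"), str(out / "samples.tsv"))
        dio.write_truth(truth, str(out / "truth.json"))
        wt = cm.counts.loc[:, cm.samples["genotype"] == "WT"]
        wt_cm = type(cm)(counts=wt, samples=cm.samples.loc[wt.columns])
        res = fit_differential(wt_cm, ("DBS", "sham"), min_mean=th.min_mean)
        state["de_wt"] = res
        dio.write_table(res, str(out / "de_wt_dbs_vs_sham.tsv"))
        up, down = classify_degs(res, th.fc, th.fdr)
        state["up"], state["down"] = up, down
        summary["n_deg_up"] = int(len(up))
        summary["n_deg_down"] = int(len(down))
        summary["n_tested_genes"] = int(len(res))

    @stage("rescue", deps=("de",))
    def _rescue():
        cm = state["cm"]
        sham = cm.counts.loc[:, cm.samples["treatment"] == "sham"]
        sham_cm = type(cm)(counts=sham, samples=cm.samples.loc[sham.columns])
        ko_vs_wt = fit_differential(sham_cm, ("KO", "WT"),
                                    condition_col="genotype", min_mean=th.min_mean)
        ko = cm.counts.loc[:, cm.samples["genotype"] == "KO"]
        ko_cm = type(cm)(counts=ko, samples=cm.samples.loc[ko.columns])
        dbs_eff = fit_differential(ko_cm, ("DBS", "sham"), min_mean=th.min_mean)
        _, down = classify_degs(ko_vs_wt, th.rescue_fc, th.fdr)
        down = down.intersection(dbs_eff.index)
        means = normalized_group_means(cm)
        table = classify_rescue(ko_vs_wt.loc[down], dbs_eff, means,
                                fc_threshold=th.rescue_fc, fdr_threshold=th.fdr)
        state["rescue"] = table
        dio.write_table(table, str(out / "rescue.tsv"))
        summary["rescue_classes"] = table["class"].value_counts().to_dict()

    @stage("clustering", deps=("de",))
    def _clustering():
        cm = state["cm"]
        sf = estimate_size_factors(cm.counts)
        normed = cm.counts / sf
        top = state["de_wt"].sort_values("lfcShrunk", ascending=False).head(100).index
        order, _ = cluster_samples(normed, top)
        (out / "cluster_order.txt").write_text("\n".join(order) + "\n")
        summary["cluster_order"] = order

    @stage("isoforms", deps=("de",))
    def _isoforms():
        iso_cm, tech, iso_truth = generate_isoform_counts(sc)
        state["iso_truth"] = iso_truth
        iso_res = test_isoforms_dual(iso_cm, tech, ("DBS", "sham"),
                                     fc_threshold=th.iso_fc, fdr_threshold=th.fdr)
        switches = detect_switches(iso_res, state["de_wt"], iso_fc=th.iso_fc,
                                   gene_fc=th.rescue_fc, fdr_threshold=th.fdr)
        state["iso_res"] = switches
        dio.write_table(switches, str(out / "isoforms.tsv"))
        summary["n_dei"] = int(switches["consensus"].sum())
        summary["n_switches"] = int(switches["switch"].sum())

    @stage("methylome")
    def _methylome():
        tables, annot, m_truth = generate_methylome(sc)
        state["meth_truth"] = m_truth
        called = {k: call_methylation(v, th.min_cov) for k, v in tables.items()}
        sham = [v for k, v in called.items() if k.startswith("sham")]
        dbs = [v for k, v in called.items() if k.startswith("DBS")]
        dmrs = call_dmrs(sham, dbs, "mCG", resolution="base",
                         min_diff=th.min_diff, q_threshold=th.fdr,
                         chrom=annot.chrom)
        if len(dmrs):
            dmrs = dmrs.assign(feature=annotate_regions(dmrs, annot))
            enr = enrichment_permutation(dmrs, annot, n_trials=th.permutations,
                                         seed=cfg.seed)
            dio.write_table(enr, str(out / "dmr_enrichment.tsv"))
            write_bed(dmrs, str(out / "dmrs.bed"), annot.chrom,
                      extra_cols=["feature", "diff", "qvalue"])
            summary["dmr_enrichment_promoter_fold"] = float(
                enr.loc["promoter", "fold_enrichment"])
        summary["n_dmrs"] = int(len(dmrs))

    @stage("psea", deps=("de",))
    def _psea():
        cm = state["cm"]
        sf = estimate_size_factors(cm.counts)
        normed = cm.counts / sf
        wt = cm.samples["genotype"] == "WT"
        expr = normed.loc[:, wt.to_numpy()]
        cond = cm.samples.loc[wt.to_numpy(), "treatment"]
        signals = build_reference_signals(expr, MARKER_GENES)
        genes = state["de_wt"].index[:200]
        records = fit_psea(expr.loc[genes], signals, cond, treatment_level="DBS")
        kept = select_models(records, th.psea_f_p, th.psea_adj_r2)
        dio.write_table(kept, str(out / "psea.tsv"), index=False)
        summary["n_psea_retained"] = int(kept["gene"].nunique())

    @stage("overlap", deps=("de",))
    def _overlap():
        universe = state["de_wt"].index
        rng = np.random.default_rng(cfg.seed + 7)
        disease = list(rng.choice(universe, size=min(200, len(universe)),
                                  replace=False))
        res = overlap_test(state["up"], disease, universe)
        dio.write_table(pd.DataFrame([res.to_dict()]), str(out / "overlap.tsv"),
                        index=False)
        summary["overlap"] = res.to_dict()

    @stage("network", deps=("de", "isoforms"))
    def _network():
        edges, tf_flags = generate_network(sc)
        deg = set(state["up"]) | set(state["down"])
        dei = set(state["iso_res"].loc[state["iso_res"]["consensus"], "gene_id"])
        lfc = state["de_wt"]["lfcShrunk"].to_dict()
        g = extract_two_layer(edges, tf_flags.index, ("Jun", "Junb", "Fosl2"),
                              deg, dei, lfc)
        nodes = pd.DataFrame(
            [{"node": n, **g.nodes[n]} for n in g.nodes]
        )
        dio.write_table(nodes, str(out / "network_nodes.tsv"), index=False)
        dio.write_table(pd.DataFrame(list(g.edges), columns=["tf", "target"]),
                        str(out / "network_edges.tsv"), index=False)
        summary["network_nodes"] = int(g.number_of_nodes())

    @stage("assays")
    def _assays():
        ct_table, psm_table, a_truth = generate_assay_tables(sc)
        dio.write_table(ct_table, str(out / "ct_table.tsv"), index=False)
        target = sc.assays.target_genes[0]
        rq, test = qpcr_relative(ct_table, list(sc.assays.reference_genes), target)
        dio.write_table(rq, str(out / "qpcr.tsv"), index=False)
        summary["qpcr"] = {target: test["DBS"]}
        prot = tmt_protein_stats(psm_table, psm_table.attrs["groups"])
        dio.write_table(prot, str(out / "tmt_proteins.tsv"))
        summary["n_tmt_flagged"] = int(prot["flagged"].sum())

    for runner in (_de, _rescue, _clustering, _isoforms, _methylome, _psea,
                   _overlap, _network, _assays):
        runner()

    summary["errors"] = errors
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True,
                                                 default=str))
    logger.removeHandler(handler)
    handler.close()
    if errors:
        raise RuntimeError(f"stage failures: {json.dumps(errors)}")
    return summary
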