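"""Synthetic multi-omics data with planted, machine-readable ground truth.

Emulates the inputs of an acute-stimulation study in mouse dentate gyrus:
negative-binomial RNA-seq counts with batch effects and planted contrasts
(including a mutant-downregulation/rescue structure), isoform counts with
quantifier-style technical variance and planted switches, binomial
whole-genome bisulfite data with planted DMRs and class-specific promoter
methylation signatures, marker-driven cell-type mixtures, a TF->target graph,
and qPCR/TMT assay tables.

Every generator is deterministic under a fixed seed; all randomness is routed
through one numpy Generator per invocation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation
from .diffexpr import CountMatrix

__all__ = [
    "SimConfig",
    "TruthSet",
    "generate_counts",
    "generate_isoform_counts",
    "generate_methylome",
    "generate_network",
    "generate_assay_tables",
    "default_samples",
]

#: marker genes of the four dentate-gyrus populations used by the deconvolution
MARKER_GENES = {
    "granule": ["C1ql2", "Dsp", "Trpc6", "Pitpnm2", "Btg1"],
    "mossy": ["Calb2", "Fgf1"],
    "NSC": ["Nes", "Sox2", "Fabp7"],
    "NPC": ["Dcx", "Dpysl3"],
}


def default_samples() -> pd.DataFrame:
    """The acute-stimulation study design: WT and KO males, sham vs DBS,
    libraries prepared in two batches (3 WT sham, 4 WT DBS, 3 KO sham,
    4 KO DBS)."""
    rows = []
    layout = [("WT", "sham", 3), ("WT", "DBS", 4), ("KO", "sham", 3), ("KO", "DBS", 4)]
    i = 0
    for genotype, treatment, n in layout:
        for r in range(n):
            rows.append(
                {
                    "sample_id": f"{genotype}_{treatment}_{r + 1}",
                    "genotype": genotype,
                    "treatment": treatment,
                    "batch": f"b{(i % 2) + 1}",
                }
            )
            i += 1
    return pd.DataFrame(rows).set_index("sample_id")


@dataclass
class PlantedEffect:
    """Multiplicative log2 effect on one feature in samples of one group.

    genotype/treatment of None match every level (e.g. treatment='DBS',
    genotype=None plants a stimulation response in both genotypes).
    """

    feature: str
    log2fc: float
    genotype: str | None = None
    treatment: str | None = None

    def applies(self, genotype: str, treatment: str) -> bool:
        return (self.genotype is None or self.genotype == genotype) and (
            self.treatment is None or self.treatment == treatment
        )


@dataclass
class RescueConfig:
    """Planted mutant-downregulation with graded response to stimulation."""

    n_down: int = 120
    frac_rescued: float = 0.25
    frac_partial: float = 0.25
    # 4-fold loss: strong enough to be detectable at the study's n=3 sham
    # replicates per genotype (real effect sizes are smaller and unknown)
    down_log2fc: float = -2.0
    partial_log2fc: float = float(np.log2(1.12))


@dataclass
class MethylomeConfig:
    genome_length: int = 2_000_000
    site_retention: float = 0.04      # fraction of cytosines kept (coverage dropout)
    coverage_mean: float = 30.0
    n_per_group: int = 2
    n_genes: int = 80
    cpg_level: float = 0.75
    ch_level: float = 0.03
    up_promoter_level: float = 0.35   # lower mCG on stimulation-responsive genes
    planted_dmrs: list = field(default_factory=list)  # (start, end, delta, class)


@dataclass
class NetworkConfig:
    n_tfs: int = 20
    n_targets: int = 150
    density: float = 0.05
    seeds: tuple = ("Jun", "Junb", "Fosl2")


@dataclass
class AssayConfig:
    n_per_group: int = 4
    n_wells: int = 3
    reference_genes: tuple = ("Gapdh", "Actb", "Atf2")
    target_genes: tuple = ("Fos", "Bdnf", "Arc", "Npas4")
    target_log2fc: float = 2.0       # planted 4-fold induction
    ct_noise_sd: float = 0.1
    n_psms_per_protein: int = 4
    n_proteins: int = 200   # large unchanged background, as in real 10-plex runs
    n_flagged: int = 6
    protein_log2fc: float = float(np.log2(1.6))
    psm_cv: float = 0.10
    fraction_failing: float = 0.2
    channels_per_group: int = 5


@dataclass
class IsoformConfig:
    n_isoforms_max: int = 4
    gene_mean: float = 500.0
    n_switch: int = 30
    switch_fold: float = 2.5
    tech_log2_var: float = 0.01


@dataclass
class SimConfig:
    """Master configuration; every generator takes one of these."""

    seed: int = 0
    n_genes: int = 2000
    samples: pd.DataFrame = field(default_factory=default_samples)
    baseline_mean: float = 200.0
    log_mean_sd: float = 1.0
    dispersion: float = 0.05
    batch_sd: float = 0.10
    planted_effects: list = field(default_factory=list)
    rescue: RescueConfig | None = None
    isoforms: IsoformConfig = field(default_factory=IsoformConfig)
    methylome: MethylomeConfig = field(default_factory=MethylomeConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    assays: AssayConfig = field(default_factory=AssayConfig)

    def validate(self) -> None:
        for col in ("genotype", "treatment", "batch"):
            if col not in self.samples.columns:
                raise ValueError(f"sample sheet lacks column {col!r}")
        counts = self.samples.groupby(["genotype", "treatment"]).size()
        if (counts == 0).any():
            raise ValueError("a declared group has zero samples")


@dataclass
class TruthSet:
    """Planted ground truth emitted alongside each synthetic dataset."""

    lfc: dict = field(default_factory=dict)          # feature -> {group: log2fc}
    rescue_class: dict = field(default_factory=dict)  # gene -> class
    dmrs: list = field(default_factory=list)          # (start, end, delta, class)
    switch_isoforms: list = field(default_factory=list)
    celltype_effects: dict = field(default_factory=dict)  # gene -> (cell type, lfc)
    gene_class: dict = field(default_factory=dict)    # methylome gene classes

    def to_json_dict(self) -> dict:
        return {
            "lfc": self.lfc,
            "rescue_class": self.rescue_class,
            "dmrs": [list(d) for d in self.dmrs],
            "switch_isoforms": list(self.switch_isoforms),
            "celltype_effects": {k: list(v) for k, v in self.celltype_effects.items()},
            "gene_class": self.gene_class,
        }


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Gamma-Poisson draw with variance mean + alpha*mean^2 (Poisson as alpha->0)."""
    mean = np.maximum(mean, 1e-12)
    if alpha < 1e-12:
        return rng.poisson(mean)
    shape = 1.0 / alpha
    lam = rng.gamma(shape, alpha * mean)
    return rng.poisson(lam)


def _group_lfc_map(config: SimConfig, truth: TruthSet) -> dict:
    """Per-feature log2 multiplier per (genotype, treatment) group."""
    groups = list(
        config.samples[["genotype", "treatment"]].drop_duplicates().itertuples(index=False)
    )
    out: dict[str, dict[tuple, float]] = {}
    for eff in config.planted_effects:
        for g in groups:
            if eff.applies(g.genotype, g.treatment):
                out.setdefault(eff.feature, {}).setdefault((g.genotype, g.treatment), 0.0)
                out[eff.feature][(g.genotype, g.treatment)] += eff.log2fc
    for feat, per_group in out.items():
        truth.lfc.setdefault(feat, {})
        for (gt, tr), v in per_group.items():
            truth.lfc[feat][f"{gt}:{tr}"] = truth.lfc[feat].get(f"{gt}:{tr}", 0.0) + v
    return out


def _plant_rescue(config: SimConfig, gene_ids: list[str], base: np.ndarray,
                  rng: np.random.Generator, truth: TruthSet) -> dict:
    """Plant mutant-low genes whose stimulation response is rescued, partial,
    or absent; returns feature -> group -> extra log2fc.

    Effects go into robustly expressed genes (baseline at or above the
    configured mean) so a 4-fold loss stays above typical expression filters;
    marker genes are excluded to keep deconvolution reference signals clean.
    """
    rc = config.rescue
    extra: dict[str, dict[tuple, float]] = {}
    n_marker = sum(len(v) for v in MARKER_GENES.values())
    eligible = np.flatnonzero(base >= 1.5 * config.baseline_mean)
    eligible = eligible[eligible >= n_marker]
    if len(eligible) < rc.n_down:
        raise ValueError("too few well-expressed genes to plant the rescue set")
    chosen = rng.choice(eligible, size=rc.n_down, replace=False)
    n_resc = int(round(rc.frac_rescued * rc.n_down))
    n_part = int(round(rc.frac_partial * rc.n_down))
    for i, gi in enumerate(chosen):
        g = gene_ids[gi]
        per = extra.setdefault(g, {})
        for tr in ("sham", "DBS"):
            per[("KO", tr)] = per.get(("KO", tr), 0.0) + rc.down_log2fc
        if i < n_resc:
            per[("KO", "DBS")] -= rc.down_log2fc  # back to WT baseline
            cls = "rescued"
        elif i < n_resc + n_part:
            per[("KO", "DBS")] += rc.partial_log2fc
            cls = "partial"
        else:
            cls = "unchanged"
        truth.rescue_class[g] = cls
        truth.lfc.setdefault(g, {})
        for (gt, tr), v in per.items():
            truth.lfc[g][f"{gt}:{tr}"] = truth.lfc[g].get(f"{gt}:{tr}", 0.0) + v
    return extra


def generate_counts(config: SimConfig) -> tuple[CountMatrix, TruthSet]:
    """Gene-level NB counts with batch effects and planted contrasts."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = TruthSet()
    gene_ids = [f"g{i:05d}" for i in range(config.n_genes)]
    # reserve the marker symbols so mixtures and deconvolution can find them
    markers = [m for lst in MARKER_GENES.values() for m in lst]
    gene_ids[: len(markers)] = markers

    base = np.exp(
        rng.normal(np.log(config.baseline_mean), config.log_mean_sd, config.n_genes)
    )
    batches = sorted(config.samples["batch"].unique())
    batch_factor = {
        b: float(np.exp(rng.normal(0.0, config.batch_sd))) for b in batches
    }

    lfc_map = _group_lfc_map(config, truth)
    if config.rescue is not None:
        extra = _plant_rescue(config, gene_ids, base, rng, truth)
        for g, per in extra.items():
            tgt = lfc_map.setdefault(g, {})
            for k, v in per.items():
                tgt[k] = tgt.get(k, 0.0) + v

    idx = {g: i for i, g in enumerate(gene_ids)}
    mat = np.empty((config.n_genes, len(config.samples)), dtype=np.int64)
    for j, (sid, row) in enumerate(config.samples.iterrows()):
        mult = np.ones(config.n_genes)
        for feat, per in lfc_map.items():
            if feat in idx:
                v = per.get((row["genotype"], row["treatment"]))
                if v:
                    mult[idx[feat]] *= 2.0**v
        mean = base * mult * batch_factor[row["batch"]]
        mat[:, j] = _nb_draw(rng, mean, config.dispersion)

    counts = pd.DataFrame(mat, index=gene_ids, columns=config.samples.index)
    return CountMatrix(counts=counts, samples=config.samples.copy()), truth


def generate_isoform_counts(
    config: SimConfig,
) -> tuple[CountMatrix, pd.Series, TruthSet]:
    """Isoform counts that sum exactly to gene counts, with planted switches.

    Gene totals are NB and flat across groups for switch genes (the switch
    redistributes isoform proportions inside a fixed total); a per-isoform
    technical variance (of log2 abundance, quantifier-style) is emitted and
    also jitters the per-sample proportions, so the emitted scalar honestly
    describes planted noise.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    iso_cfg = config.isoforms
    truth = TruthSet()

    n_genes = config.n_genes
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    n_iso = rng.integers(1, iso_cfg.n_isoforms_max + 1, size=n_genes)
    base = np.exp(rng.normal(np.log(iso_cfg.gene_mean), 0.5, n_genes))
    all_props = [rng.dirichlet(np.full(int(k), 5.0)) for k in n_iso]

    # plant switches on the minor isoform (a short variant induced while the
    # major ones compensate), in genes where the full fold fits below 0.9
    eligible = np.flatnonzero(
        (n_iso >= 2)
        & np.array([p.min() * iso_cfg.switch_fold <= 0.9 for p in all_props])
    )
    switch_genes = rng.choice(
        eligible, size=min(iso_cfg.n_switch, len(eligible)), replace=False)
    switch_set = set(switch_genes.tolist())

    iso_rows, iso_gene, tech_var = [], [], []
    counts_cols = {sid: [] for sid in config.samples.index}
    for gi in range(n_genes):
        k = int(n_iso[gi])
        props = all_props[gi]
        boosted = None
        if gi in switch_set:
            boosted = int(np.argmin(props))
            p2 = props.copy()
            p2[boosted] = p2[boosted] * iso_cfg.switch_fold
            rest = 1.0 - p2[boosted]
            others = np.delete(props, boosted)
            p2_others = others / others.sum() * rest
            props_dbs = np.insert(p2_others, boosted, p2[boosted])
        ids = [f"{gene_ids[gi]}.i{t + 1}" for t in range(k)]
        iso_rows.extend(ids)
        iso_gene.extend([gene_ids[gi]] * k)
        tv = iso_cfg.tech_log2_var
        tech_var.extend([tv] * k)
        if boosted is not None:
            truth.switch_isoforms.append(ids[boosted])
        for sid, row in config.samples.iterrows():
            p = props_dbs if (boosted is not None and row["treatment"] == "DBS") else props
            if tv > 0:
                jit = p * np.exp(rng.normal(0.0, np.sqrt(tv) * np.log(2.0), k))
                p = jit / jit.sum()
            total = _nb_draw(rng, np.array([base[gi]]), config.dispersion)[0]
            counts_cols[sid].append(rng.multinomial(total, p))

    mat = np.column_stack(
        [np.concatenate(counts_cols[sid]) for sid in config.samples.index]
    )
    counts = pd.DataFrame(mat, index=iso_rows, columns=config.samples.index)
    features = pd.DataFrame({"gene_id": iso_gene}, index=iso_rows)
    cm = CountMatrix(counts=counts, samples=config.samples.copy(), features=features)
    tv = pd.Series(tech_var, index=iso_rows, name="tech_log2_var")
    return cm, tv, truth


def _random_annotation(rng: np.random.Generator, length: int, n_genes: int,
                       chrom: str = "chrSim") -> GenomeAnnotation:
    """Genes tiled along one synthetic chromosome with intergenic gaps."""
    span = length // n_genes
    genes, exons = [], []
    for i in range(n_genes):
        gid = f"mg{i:04d}"
        lo = i * span + int(0.25 * span)
        hi = i * span + int(0.80 * span)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append({"gene_id": gid, "start": lo, "end": hi, "strand": strand})
        n_ex = int(rng.integers(2, 6))
        edges = np.sort(rng.choice(np.arange(lo, hi), size=2 * n_ex, replace=False))
        for e in range(n_ex):
            exons.append({"gene_id": gid, "start": int(edges[2 * e]),
                          "end": int(edges[2 * e + 1])})
    return GenomeAnnotation(chrom=chrom, length=length,
                            genes=pd.DataFrame(genes), exons=pd.DataFrame(exons))


def _cytosine_sites(rng: np.random.Generator, length: int, retention: float):
    """Cytosine positions/strands/contexts from a generated reference sequence."""
    seq = rng.integers(0, 4, size=length, dtype=np.int8)  # 0=A 1=C 2=G 3=T
    comp = np.array([3, 2, 1, 0], dtype=np.int8)

    def contexts(s):
        n1 = np.roll(s, -1)
        n2 = np.roll(s, -2)
        ctx = np.where(n1 == 2, 0, np.where(n2 == 2, 1, 2))  # 0 CpG, 1 CHG, 2 CHH
        return ctx

    plus_c = np.flatnonzero(seq == 1)
    ctx_plus = contexts(seq)[plus_c]
    rc = comp[seq[::-1]]
    minus_c_rev = np.flatnonzero(rc == 1)
    ctx_minus = contexts(rc)[minus_c_rev]
    minus_c = length - 1 - minus_c_rev

    pos = np.concatenate([plus_c, minus_c])
    strand = np.array(["+"] * len(plus_c) + ["-"] * len(minus_c))
    ctx = np.concatenate([ctx_plus, ctx_minus])
    keep = rng.random(len(pos)) < retention
    order = np.argsort(pos[keep], kind="stable")
    names = np.array(["CpG", "CHG", "CHH"])
    return pos[keep][order], strand[keep][order], names[ctx[keep][order]]


def generate_methylome(
    config: SimConfig,
) -> tuple[dict[str, pd.DataFrame], GenomeAnnotation, TruthSet]:
    """Per-sample cytosine tables with planted DMRs and gene-class signatures.

    Returns ({sample: table}, annotation, truth). Sham/DBS samples per group
    per MethylomeConfig; methylated counts ~ Binomial(coverage, level) with
    levels shifted by each planted DMR's delta in DBS samples. Gene classes
    'up', 'down', 'unchanged' are assigned and 'up' promoters get a lower
    baseline mCG level.
    """
    mc = config.methylome
    rng = np.random.default_rng(config.seed + 2)
    truth = TruthSet()

    annot = _random_annotation(rng, mc.genome_length, mc.n_genes)
    pos, strand, ctx = _cytosine_sites(rng, mc.genome_length, mc.site_retention)

    dmrs = list(mc.planted_dmrs)
    for a, b, delta, _cls in dmrs:
        if not (0 <= a < b <= mc.genome_length):
            raise ValueError("planted DMR outside genome bounds")
    ds = sorted(dmrs)
    for (a1, b1, d1, _), (a2, b2, d2, _) in zip(ds, ds[1:]):
        if a2 < b1 and d1 != d2:
            raise ValueError("overlapping planted DMRs with conflicting deltas")
    truth.dmrs = dmrs

    # gene classes and their promoter signature
    gids = annot.genes["gene_id"].tolist()
    classes = np.array(["unchanged"] * len(gids), dtype=object)
    n_up = max(len(gids) // 4, 1)
    n_dn = max(len(gids) // 4, 1)
    perm = rng.permutation(len(gids))
    classes[perm[:n_up]] = "up"
    classes[perm[n_up:n_up + n_dn]] = "down"
    truth.gene_class = dict(zip(gids, classes))

    base_level = np.where(ctx == "CpG", mc.cpg_level, mc.ch_level).astype(float)
    proms = annot.promoters()
    up_ids = {g for g, c in truth.gene_class.items() if c == "up"}
    for _, p in proms[proms["gene_id"].isin(up_ids)].iterrows():
        m = (pos >= p["start"]) & (pos < p["end"]) & (ctx == "CpG")
        base_level[m] = mc.up_promoter_level

    class_of = {"CpG": "mCG", "CHG": "mCH", "CHH": "mCH"}
    # sham baseline inside a planted DMR leaves room for the full shift
    # (0.1 -> 0.9 for hypermethylation, 0.9 -> 0.1 for loss)
    for a, b, delta, cls in dmrs:
        m = (pos >= a) & (pos < b)
        if cls in ("mCG", "mCH"):
            m &= np.array([class_of[c] == cls for c in ctx])
        base_level[m] = 0.1 if delta > 0 else 0.9

    tables: dict[str, pd.DataFrame] = {}
    for grp, n in (("sham", mc.n_per_group), ("DBS", mc.n_per_group)):
        for r in range(n):
            level = base_level.copy()
            if grp == "DBS":
                for a, b, delta, cls in dmrs:
                    m = (pos >= a) & (pos < b)
                    if cls in ("mCG", "mCH"):
                        m &= np.array([class_of[c] == cls for c in ctx])
                    level[m] = np.clip(level[m] + delta, 0.0, 1.0)
            cov = rng.poisson(mc.coverage_mean, size=len(pos))
            meth = rng.binomial(cov, level)
            tables[f"{grp}_{r + 1}"] = pd.DataFrame(
                {
                    "chrom": annot.chrom,
                    "pos": pos,
                    "strand": strand,
                    "context": ctx,
                    "meth": meth,
                    "total": cov,
                }
            )
    return tables, annot, truth


def generate_network(config: SimConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Directed TF->target edge list plus a TF flag table; requested seed TFs
    are guaranteed present with out-degree >= 1 when density > 0."""
    nc = config.network
    rng = np.random.default_rng(config.seed + 3)
    if nc.n_tfs < len(nc.seeds):
        raise ValueError("n_tfs must be at least the number of seed TFs")
    tfs = list(nc.seeds) + [f"Tf{i:03d}" for i in range(nc.n_tfs - len(nc.seeds))]
    targets = [f"g{i:05d}" for i in range(nc.n_targets)]
    nodes = tfs + targets
    edges = []
    for tf in tfs:
        picks = rng.random(len(nodes)) < nc.density
        for n, hit in zip(nodes, picks):
            if hit and n != tf:
                edges.append((tf, n))
    if nc.density > 0:
        for s in nc.seeds:
            if not any(e[0] == s for e in edges):
                edges.append((s, targets[int(rng.integers(0, len(targets)))]))
    edge_df = pd.DataFrame(edges, columns=["tf", "target"])
    tf_flags = pd.Series(True, index=pd.Index(tfs, name="gene"), name="is_tf")
    return edge_df, tf_flags


def generate_assay_tables(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, TruthSet]:
    """qPCR Ct table and TMT PSM table with planted effects.

    Ct = baseline - log2(expression) + noise, replicate wells per sample;
    targets are induced by target_log2fc in the treated group. PSMs carry
    summed signal-to-noise and isolation-specificity fields with a configured
    fraction failing the quality filters; the first n_flagged proteins carry
    a planted protein_log2fc between channel groups.
    """
    ac = config.assays
    rng = np.random.default_rng(config.seed + 4)
    truth = TruthSet()
    if len(ac.reference_genes) < 3:
        raise ValueError("need >=3 reference genes")

    rows = []
    for grp in ("sham", "DBS"):
        for i in range(ac.n_per_group):
            sid = f"{grp}_{i + 1}"
            shift = rng.normal(0.0, 0.2)  # per-sample loading offset, cancels in dCt
            for gene in list(ac.reference_genes) + list(ac.target_genes):
                expr = 1.0
                if gene in ac.target_genes and grp == "DBS":
                    expr = 2.0**ac.target_log2fc
                    truth.lfc.setdefault(gene, {})["DBS"] = ac.target_log2fc
                base_ct = 22.0
                for w in range(ac.n_wells):
                    ct = base_ct - np.log2(expr) + shift + rng.normal(0.0, ac.ct_noise_sd)
                    rows.append(
                        {"sample_id": sid, "group": grp, "gene": gene,
                         "well": w + 1, "ct": round(float(ct), 4)}
                    )
    ct_table = pd.DataFrame(rows)

    n_ch = 2 * ac.channels_per_group
    ch_names = [f"ch{c + 1}" for c in range(n_ch)]
    grp_b = np.arange(n_ch) >= ac.channels_per_group
    psm_rows = []
    for pi in range(ac.n_proteins):
        prot = f"P{pi:04d}"
        fold = 2.0**ac.protein_log2fc if pi < ac.n_flagged else 1.0
        if pi < ac.n_flagged:
            truth.celltype_effects[prot] = ("protein", float(np.log2(fold)))
        base = np.exp(rng.normal(np.log(1000.0), 0.5))
        for k in range(ac.n_psms_per_protein):
            mean = base * np.exp(rng.normal(0.0, 0.3))
            inten = mean * np.where(grp_b, fold, 1.0)
            inten = inten * np.exp(rng.normal(0.0, ac.psm_cv, n_ch))
            failing = rng.random() < ac.fraction_failing
            if failing:
                sn = float(rng.uniform(20.0, 199.0))
                spec = float(rng.uniform(0.0, 0.49))
            else:
                sn = float(rng.uniform(250.0, 5000.0))
                spec = float(rng.uniform(0.6, 1.0))
            row = {"peptide": f"{prot}_pep{k + 1}", "protein": prot,
                   "sum_sn": round(sn, 2), "isolation_specificity": round(spec, 3)}
            row.update({c: round(float(v), 3) for c, v in zip(ch_names, inten)})
            psm_rows.append(row)
    psm_table = pd.DataFrame(psm_rows)
    psm_table.attrs["groups"] = {
        c: ("DBS" if b else "sham") for c, b in zip(ch_names, grp_b)
    }
    return ct_table, psm_table, truth
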