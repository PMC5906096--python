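"""Cytosine-level methylation quantification and DMR analysis.

Workflow: per-cytosine methylation levels with a coverage gate; DMR calling
by coverage-normalised, replicate-pooled Fisher exact tests at base or tile
resolution; annotation of regions against the promoter/exon/intron/intergenic
partition; permutation-based feature enrichment; and scale-regions metagene
profiles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import GenomeAnnotation

__all__ = [
    "call_methylation",
    "call_dmrs",
    "annotate_regions",
    "enrichment_permutation",
    "metagene_profile",
]

CYTOSINE_COLUMNS = ["chrom", "pos", "strand", "context", "meth", "total"]
CONTEXT_CLASS = {"CpG": "mCG", "CHG": "mCH", "CHH": "mCH"}


def call_methylation(raw: pd.DataFrame, min_coverage: int = 10) -> pd.DataFrame:
    """Filter a cytosine table to covered positions and add methylation levels.

    level = methylated / total reads. Positions with total < min_coverage are
    dropped; records with methylated > total are rejected (counted in the
    table's attrs under 'rejected').
    """
    df = raw.copy()
    bad = df["meth"] > df["total"]
    n_bad = int(bad.sum())
    if n_bad:
        df = df.loc[~bad]
    df = df.loc[df["total"] >= min_coverage].copy()
    df["level"] = df["meth"] / df["total"]
    df["context_class"] = df["context"].map(CONTEXT_CLASS)
    df.attrs["rejected"] = n_bad
    return df


def _normalize_coverage(tables: list[pd.DataFrame]) -> list[pd.DataFrame]:
    """Rescale every sample's counts so median coverages match the across-sample
    median of medians; counts rounded half-up, meth/total ratio preserved."""
    medians = [t["total"].median() for t in tables]
    target = float(np.median(medians))
    out = []
    for t, m in zip(tables, medians):
        f = target / m
        s = t.copy()
        total = np.floor(s["total"] * f + 0.5).astype(int)
        meth = np.floor(s["meth"] * f + 0.5).astype(int)
        s["total"] = total
        s["meth"] = np.minimum(meth, total)
        out.append(s)
    return out


def _pool(tables: list[pd.DataFrame], context_class: str) -> pd.DataFrame:
    subs = [
        t.loc[t["context"].map(CONTEXT_CLASS) == context_class,
              ["pos", "strand", "meth", "total"]]
        for t in tables
    ]
    pooled = (
        pd.concat(subs)
        .groupby(["pos", "strand"], as_index=False)[["meth", "total"]]
        .sum()
    )
    return pooled


def _fisher_pvals(ma, ua, mb, ub) -> np.ndarray:
    p = np.empty(len(ma))
    for i in range(len(ma)):
        p[i] = stats.fisher_exact([[ma[i], ua[i]], [mb[i], ub[i]]])[1]
    return p


def call_dmrs(
    group_a: list[pd.DataFrame],
    group_b: list[pd.DataFrame],
    context_class: str = "mCG",
    resolution: str | int = "base",
    min_diff: float = 50.0,
    q_threshold: float = 0.05,
    chrom: str = "chrSim",
) -> pd.DataFrame:
    """Call DMRs between two groups of cytosine tables (b minus a).

    Samples are coverage-normalised to the median, replicates pooled by
    summation, and each unit (base, or fixed-size tile when resolution is an
    integer) tested with a two-sided Fisher exact test on the pooled
    methylated/unmethylated counts; BH q-values. A DMR requires q <
    q_threshold and |level difference| >= min_diff percentage points. Tile
    levels are the average of the constituent base levels.

    Returns a BED-like DataFrame (0-based half-open start/end) with columns
    diff (points), pvalue, qvalue plus attrs 'n_tested' and 'n_untested'.
    """
    norm = _normalize_coverage(list(group_a) + list(group_b))
    a = _pool(norm[: len(group_a)], context_class)
    b = _pool(norm[len(group_a):], context_class)
    merged = a.merge(b, on=["pos", "strand"], suffixes=("_a", "_b"), how="outer")
    merged = merged.fillna(0)
    testable = (merged["total_a"] > 0) & (merged["total_b"] > 0)
    n_untested = int((~testable).sum())
    merged = merged.loc[testable].reset_index(drop=True)

    merged["lev_a"] = merged["meth_a"] / merged["total_a"]
    merged["lev_b"] = merged["meth_b"] / merged["total_b"]

    if resolution == "base":
        units = merged.assign(start=merged["pos"], end=merged["pos"] + 1)
        grouped = units.groupby(["start", "end"], as_index=False).agg(
            meth_a=("meth_a", "sum"), total_a=("total_a", "sum"),
            meth_b=("meth_b", "sum"), total_b=("total_b", "sum"),
            lev_a=("lev_a", "mean"), lev_b=("lev_b", "mean"),
        )
    else:
        tile = int(resolution)
        merged["start"] = (merged["pos"] // tile) * tile
        merged["end"] = merged["start"] + tile
        grouped = merged.groupby(["start", "end"], as_index=False).agg(
            meth_a=("meth_a", "sum"), total_a=("total_a", "sum"),
            meth_b=("meth_b", "sum"), total_b=("total_b", "sum"),
            lev_a=("lev_a", "mean"), lev_b=("lev_b", "mean"),
        )

    ma = grouped["meth_a"].to_numpy(int)
    ua = grouped["total_a"].to_numpy(int) - ma
    mb = grouped["meth_b"].to_numpy(int)
    ub = grouped["total_b"].to_numpy(int) - mb
    pvals = _fisher_pvals(ma, ua, mb, ub)
    qvals = multipletests(pvals, method="fdr_bh")[1]
    diff = 100.0 * (grouped["lev_b"] - grouped["lev_a"])

    out = pd.DataFrame(
        {
            "chrom": chrom,
            "start": grouped["start"].astype(int),
            "end": grouped["end"].astype(int),
            "context_class": context_class,
            "diff": diff,
            "meth_a": ma,
            "unmeth_a": ua,
            "meth_b": mb,
            "unmeth_b": ub,
            "pvalue": pvals,
            "qvalue": qvals,
        }
    )
    dmrs = out.loc[(out["qvalue"] < q_threshold) & (out["diff"].abs() >= min_diff)]
    dmrs = dmrs.reset_index(drop=True)
    dmrs.attrs["n_tested"] = len(out)
    dmrs.attrs["n_untested"] = n_untested
    dmrs.attrs["all_units"] = out
    return dmrs


def annotate_regions(regions: pd.DataFrame, annotation: GenomeAnnotation) -> pd.Series:
    """Label each region by the feature at its midpoint (precedence
    promoter > exon > intron > intergenic)."""
    mid = ((regions["start"] + regions["end"]) // 2).to_numpy()
    return pd.Series(annotation.label_at(mid), index=regions.index, name="feature")


def enrichment_permutation(
    dmrs: pd.DataFrame,
    annotation: GenomeAnnotation,
    n_trials: int = 1000,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Permutation test of DMR localisation against the genomic background.

    fold = (% of DMRs in a feature) / (% of the genome in that feature); each
    trial redraws |DMR| regions with the observed length multiset uniformly on
    the genome and annotates them the same way (midpoint label). Empirical
    one-sided p's with the add-one rule p = (r + 1) / (n + 1).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(dmrs)
    if n == 0:
        raise ValueError("no DMRs to test")
    lengths = (dmrs["end"] - dmrs["start"]).to_numpy()
    labels = annotation.labels()
    mid = ((dmrs["start"] + dmrs["end"]) // 2).to_numpy(int)
    obs_codes = labels[mid]
    obs_prop = np.bincount(obs_codes, minlength=4) / n

    # trial regions: uniform starts, observed length multiset, overlap allowed
    L = annotation.length
    starts = rng.integers(0, np.maximum(L - lengths, 1), size=(n_trials, n))
    mids = starts + lengths // 2
    trial_codes = labels[mids]  # (n_trials, n)
    trial_prop = np.stack(
        [(trial_codes == c).mean(axis=1) for c in range(4)], axis=1
    )  # (n_trials, 4)

    frac = annotation.genome_fractions()
    rows = []
    code_of = {"intergenic": 0, "intron": 1, "exon": 2, "promoter": 3}
    for name in ("promoter", "exon", "intron", "intergenic"):
        c = code_of[name]
        gf = frac[name]
        obs = obs_prop[c]
        fold = obs / gf if gf > 0 else np.nan
        r_ge = int((trial_prop[:, c] >= obs).sum())
        r_le = int((trial_prop[:, c] <= obs).sum())
        rows.append(
            {
                "feature": name,
                "dmr_fraction": obs,
                "genome_fraction": gf,
                "fold_enrichment": fold,
                "p_enrichment": (r_ge + 1) / (n_trials + 1),
                "p_depletion": (r_le + 1) / (n_trials + 1),
            }
        )
    return pd.DataFrame(rows).set_index("feature")


def metagene_profile(
    meth: pd.DataFrame,
    gene_sets: dict[str, list],
    annotation: GenomeAnnotation,
    context_class: str = "mCG",
    flank_bp: int = 2000,
    body_bins: int = 40,
    flank_bins: int = 10,
) -> pd.DataFrame:
    """Scale-regions mean methylation profiles per labelled gene set.

    Fixed-width flank bins upstream of the TSS and downstream of the TES, the
    gene body rescaled to body_bins; minus-strand genes are reversed so the
    TSS is leftmost. Bin value = mean level of covered cytosines of the
    requested context class; empty bins are NaN and excluded from set means.
    """
    df = meth.loc[meth["context"].map(CONTEXT_CLASS) == context_class]
    pos = df["pos"].to_numpy()
    lev = (df["meth"] / df["total"]).to_numpy()
    o = np.argsort(pos)
    pos, lev = pos[o], lev[o]
    csum = np.concatenate([[0.0], np.cumsum(lev)])

    def bin_means(edges: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(pos, edges)
        cnt = np.diff(idx).astype(float)
        tot = csum[idx[1:]] - csum[idx[:-1]]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cnt > 0, tot / cnt, np.nan)

    genes = annotation.genes.set_index("gene_id")
    n_bins = 2 * flank_bins + body_bins
    out = {}
    for name, ids in gene_sets.items():
        missing = [g for g in ids if g not in genes.index]
        if missing:
            raise KeyError(f"genes not in annotation: {missing}")
        acc = np.zeros(n_bins)
        cnt = np.zeros(n_bins)
        for g in ids:
            row = genes.loc[g]
            s, e = int(row["start"]), int(row["end"])
            up = np.linspace(s - flank_bp, s, flank_bins + 1)
            body = np.linspace(s, e, body_bins + 1)
            down = np.linspace(e, e + flank_bp, flank_bins + 1)
            edges = np.concatenate([up[:-1], body[:-1], down])
            edges = np.clip(edges, 0, annotation.length)
            vals = bin_means(edges)
            if row["strand"] == "-":
                vals = vals[::-1]
            ok = ~np.isnan(vals)
            acc[ok] += vals[ok]
            cnt[ok] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            out[name] = np.where(cnt > 0, acc / cnt, np.nan)
    prof = pd.DataFrame(out).T
    prof.columns = [f"bin_{i}" for i in range(n_bins)]
    return prof
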