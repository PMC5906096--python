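"""Dual-route isoform differential testing and switch detection.

Route A is the NB Wald test on isoform counts (sharing gene-level size
factors); route B inflates route A's variance with the quantifier's technical
(bootstrap-style) variance before the Wald test, emulating a
technical-variance-aware method. A consensus DEI must be significant by both
routes with concordant sign. A switch is a DEI whose gene shows no overall
expression change.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .diffexpr import CountMatrix, estimate_size_factors, fit_differential

__all__ = ["test_isoforms_dual", "detect_switches"]


def test_isoforms_dual(
    iso_counts: CountMatrix,
    tech_var: pd.Series | None,
    contrast: tuple[str, str],
    condition_col: str = "treatment",
    batch_col: str | None = "batch",
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
    min_mean: float = 0.0,
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-isoform dual-route differential test.

    tech_var holds per-isoform technical variance of log2 abundance per
    sample; when None, route B is skipped with a warning and the consensus
    falls back to route A alone. Size factors default to gene-level
    median-of-ratios on summed gene counts.
    """
    if iso_counts.features is None or "gene_id" not in iso_counts.features:
        raise ValueError("isoform CountMatrix needs a gene_id feature column")
    gene_map = iso_counts.features["gene_id"]

    if size_factors is None:
        gene_counts = iso_counts.counts.groupby(gene_map).sum()
        size_factors = estimate_size_factors(gene_counts)

    route_a = fit_differential(
        iso_counts, contrast, condition_col=condition_col, batch_col=batch_col,
        min_mean=min_mean, size_factors=size_factors,
    )

    res = route_a.rename(
        columns={c: f"{c}_a" for c in ("lfc", "se", "stat", "pvalue", "padj")}
    )
    res["gene_id"] = gene_map.loc[res.index]

    if tech_var is None:
        warnings.warn("technical variance missing: route B skipped; consensus "
                      "requires route A only")
        res["pvalue_b"] = np.nan
        res["padj_b"] = np.nan
        sig_b = pd.Series(True, index=res.index)
        concordant = pd.Series(True, index=res.index)
    else:
        test, ref = contrast
        cond = iso_counts.samples[condition_col]
        n_test = int((cond == test).sum())
        n_ref = int((cond == ref).sum())
        tv = tech_var.reindex(res.index).fillna(0.0).to_numpy()
        se_b = np.sqrt(res["se_a"].to_numpy() ** 2 + tv * (1.0 / n_test + 1.0 / n_ref))
        with np.errstate(divide="ignore", invalid="ignore"):
            stat_b = np.where(se_b > 0, res["lfc_a"].to_numpy() / se_b, 0.0)
        # same moderated-t reference as route A, so tech_var = 0 gives
        # identical tests by construction
        pval_b = 2.0 * stats.t.sf(np.abs(stat_b), df=route_a.attrs["df"])
        res["pvalue_b"] = pval_b
        res["padj_b"] = multipletests(pval_b, method="fdr_bh")[1]
        sig_b = res["padj_b"] < fdr_threshold
        concordant = pd.Series(True, index=res.index)  # shared point estimate

    cut = np.log2(fc_threshold)
    sig_a = res["padj_a"] < fdr_threshold
    big = res["lfc_a"].abs() >= cut
    res["consensus"] = (sig_a & sig_b & big & concordant).to_numpy()
    return res


def detect_switches(
    iso_results: pd.DataFrame,
    gene_results: pd.DataFrame,
    iso_fc: float = 1.3,
    gene_fc: float = 1.2,
    fdr_threshold: float = 0.05,
    gene_use_shrunken: bool = True,
) -> pd.DataFrame:
    """Isoform switches: consensus DEIs whose gene is not differentially
    expressed (gene FDR >= threshold or |gene fold| < gene_fc).

    Isoforms whose gene is absent from gene_results are flagged untested and
    never called switches.
    """
    cut_iso = np.log2(iso_fc)
    cut_gene = np.log2(gene_fc)
    lcol = "lfcShrunk" if gene_use_shrunken else "lfc"

    out = iso_results.copy()
    dei = (
        (out["padj_a"] < fdr_threshold)
        & (out["padj_b"].isna() | (out["padj_b"] < fdr_threshold))
        & (out["lfc_a"].abs() >= cut_iso)
    )
    tested = out["gene_id"].isin(gene_results.index)
    gene_lfc = out["gene_id"].map(
        lambda g: gene_results.loc[g, lcol] if g in gene_results.index else np.nan
    )
    gene_padj = out["gene_id"].map(
        lambda g: gene_results.loc[g, "padj"] if g in gene_results.index else np.nan
    )
    gene_de = tested & (gene_padj < fdr_threshold) & (gene_lfc.abs() >= cut_gene)
    out["gene_tested"] = tested
    out["gene_de"] = gene_de
    out["switch"] = (dei & tested & ~gene_de).to_numpy()
    return out
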