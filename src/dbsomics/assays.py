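"""Small-assay statistics: comparative-Ct qPCR and TMT proteomics.

qPCR uses the comparative Ct method with a multi-reference geometric mean:
replicate wells are averaged, dCt = Ct_target - geomean(Ct of reference
genes), relative quantity 2^-dCt scaled to control-group mean 1, and an
unpaired two-tailed t-test between groups (Welch by default).

TMT: peptide-spectrum matches failing the quality gates (summed
signal-to-noise < 200 across the 10 channels, or precursor isolation
specificity < 0.5) are excluded; protein channel intensities are sums of
passing PSMs, columns normalized to equal totals, per-protein unpaired
two-tailed t-test, and proteins with >= 50% group difference flagged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["qpcr_relative", "tmt_protein_stats", "filter_psms"]


def qpcr_relative(
    ct: pd.DataFrame,
    refs: list[str],
    target: str,
    control_group: str = "sham",
    welch: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Relative quantification of one target against reference genes.

    ct: long table with columns sample_id, group, gene, ct (one row per
    replicate well). Returns (per-sample table with columns group, dct,
    rel_quantity, fold; test dict with fold estimate, t, p).
    """
    genes = set(ct["gene"])
    missing = [r for r in refs if r not in genes]
    if missing or target not in genes:
        raise KeyError(f"missing genes in Ct table: {missing + [t for t in [target] if t not in genes]}")

    mean_ct = ct.groupby(["sample_id", "group", "gene"])["ct"].mean().reset_index()
    wide = mean_ct.pivot(index=["sample_id", "group"], columns="gene", values="ct")
    for r in refs:
        if wide[r].isna().any():
            raise KeyError(f"reference gene {r} missing for some sample")
    geo = np.exp(np.log(wide[refs]).mean(axis=1))
    dct = wide[target] - geo
    rq = np.power(2.0, -dct)

    out = pd.DataFrame({"dct": dct, "rel_quantity": rq}).reset_index()
    ctrl = out.loc[out["group"] == control_group, "rel_quantity"]
    if ctrl.empty:
        raise ValueError(f"no samples in control group {control_group!r}")
    out["fold"] = out["rel_quantity"] / ctrl.mean()

    groups = [g for g in out["group"].unique() if g != control_group]
    test: dict = {}
    for g in groups:
        a = out.loc[out["group"] == g, "fold"].to_numpy()
        b = out.loc[out["group"] == control_group, "fold"].to_numpy()
        fold = float(a.mean() / b.mean())
        if np.allclose(a.std(), 0) and np.allclose(b.std(), 0):
            test[g] = {"fold": fold, "t": np.nan, "pvalue": np.nan,
                       "note": "zero variance in both groups; test undefined"}
        else:
            t, p = stats.ttest_ind(a, b, equal_var=not welch)
            test[g] = {"fold": fold, "t": float(t), "pvalue": float(p)}
    return out, test


def filter_psms(psms: pd.DataFrame, sn_min: float = 200.0,
                spec_min: float = 0.5) -> pd.DataFrame:
    """Drop PSMs below the summed-S/N or isolation-specificity gates."""
    keep = (psms["sum_sn"] >= sn_min) & (psms["isolation_specificity"] >= spec_min)
    out = psms.loc[keep].copy()
    out.attrs["n_removed"] = int((~keep).sum())
    return out


def tmt_protein_stats(
    psms: pd.DataFrame,
    groups: dict[str, str],
    sn_min: float = 200.0,
    spec_min: float = 0.5,
    diff_threshold: float = 1.5,
    welch: bool = True,
) -> pd.DataFrame:
    """Protein-level quantification and testing from a 10-plex PSM table.

    groups maps reporter channel column -> group label (exactly two labels,
    >=2 channels each). Returns a per-protein table with channel intensities
    (column-normalized), group means, ratio, t, pvalue and a flag for
    proteins with a >= diff_threshold-fold difference either way.
    """
    channels = list(groups)
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError("need exactly two channel groups")
    for lab in labels:
        if sum(1 for c in channels if groups[c] == lab) < 2:
            raise ValueError(f"need >=2 channels in group {lab!r}")

    passing = filter_psms(psms, sn_min=sn_min, spec_min=spec_min)
    n_dropped_proteins = psms["protein"].nunique() - passing["protein"].nunique()

    prot = passing.groupby("protein")[channels].sum()
    totals = prot.sum(axis=0)
    prot = prot * totals.mean() / totals  # equal column totals

    ga = [c for c in channels if groups[c] == labels[0]]
    gb = [c for c in channels if groups[c] == labels[1]]
    mean_a = prot[ga].mean(axis=1)
    mean_b = prot[gb].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = mean_b / mean_a
    t, p = stats.ttest_ind(prot[gb], prot[ga], axis=1, equal_var=not welch)

    out = prot.copy()
    out[f"mean_{labels[0]}"] = mean_a
    out[f"mean_{labels[1]}"] = mean_b
    out["ratio"] = ratio
    out["t"] = t
    out["pvalue"] = p
    out["flagged"] = (ratio >= diff_threshold) | (ratio <= 1.0 / diff_threshold)
    out.attrs["n_psms_removed"] = passing.attrs["n_removed"]
    out.attrs["n_proteins_dropped"] = int(n_dropped_proteins)
    return out
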