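"""Count-based differential expression for stimulation-response designs.

Implements a negative-binomial log-linear model with a batch covariate, Wald
tests, fold-change shrinkage toward zero, threshold-based DEG classification,
the rescue taxonomy for genes downregulated in the mutant, and hierarchical
sample clustering.

The model family is NB with variance mu + alpha*mu^2. Per-gene dispersions are
estimated by method of moments and shrunk (on the log scale, fixed weight)
toward a mean-dispersion trend fitted across genes; coefficients are fitted by
IRLS with a log link and log-size-factor offsets, vectorised across genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "estimate_size_factors",
    "fit_differential",
    "normalized_group_means",
    "classify_degs",
    "classify_rescue",
    "cluster_samples",
]

_LN2 = np.log(2.0)

#: fixed column order of every differential-result table written to disk
RESULT_COLUMNS = ["baseMean", "lfc", "lfcShrunk", "se", "stat", "pvalue", "padj"]

#: prior df credited to the mean-dispersion trend in the moderated-t reference
DISPERSION_PRIOR_DF = 4


@dataclass
class CountMatrix:
    """Integer feature x sample count matrix with sample metadata.

    counts   : DataFrame, features in rows, samples in columns
    samples  : DataFrame indexed by sample id with at least the columns named
               by downstream calls (typically genotype, treatment, batch)
    features : optional per-feature metadata (biotype, gene<->isoform map)
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    features: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.counts.columns.duplicated().any():
            raise ValueError("sample ids must be unique")
        if not self.samples.index.equals(self.counts.columns):
            missing = self.counts.columns.difference(self.samples.index)
            if len(missing):
                raise ValueError(f"metadata missing for samples: {list(missing)}")
            self.samples = self.samples.loc[self.counts.columns]
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integral")

    def group_key(self, cols=("genotype", "treatment")) -> pd.Series:
        return self.samples[list(cols)].astype(str).agg(":".join, axis=1)


def estimate_size_factors(counts: pd.DataFrame | CountMatrix) -> pd.Series:
    """Median-of-ratios size factors against the per-feature geometric mean.

    Factors are rescaled so their geometric mean is 1. Raises if no feature
    has nonzero counts in every sample (a pseudo-reference over positive
    counts would be needed in that case).
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    k = counts.to_numpy(dtype=float)
    all_pos = (k > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no feature has nonzero counts in all samples; median-of-ratios is "
            "undefined (consider a pseudo-reference over positive counts)"
        )
    logk = np.log(k[all_pos])
    log_geo = logk.mean(axis=1)
    sf = np.median(np.exp(logk - log_geo[:, None]), axis=0)
    sf /= np.exp(np.mean(np.log(sf)))  # geometric mean of factors = 1
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _design_matrix(condition: pd.Series, contrast: tuple[str, str],
                   batch: pd.Series | None) -> tuple[np.ndarray, list[str]]:
    test, ref = contrast
    cond = (condition == test).astype(float).to_numpy()
    cols = [np.ones_like(cond)]
    names = ["intercept"]
    if batch is not None:
        levels = sorted(pd.unique(batch.astype(str)))
        for lev in levels[1:]:
            cols.append((batch.astype(str) == lev).astype(float).to_numpy())
            names.append(f"batch_{lev}")
    cols.append(cond)
    names.append("condition")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "design matrix is rank-deficient: batch is confounded with the "
            "condition (every batch level must mix both contrast levels)"
        )
    return X, names


def _mom_dispersion(k: np.ndarray, X: np.ndarray, sf: np.ndarray,
                    alpha0: float = 0.1) -> np.ndarray:
    """Method-of-moments dispersion via the Pearson moment equation.

    Fits the design at a pilot dispersion, then solves per gene (bisection)

        sum_j (k_j - mu_j)^2 / (mu_j + alpha * mu_j^2) = n - p,

    which uses all residual df of the design (important for small batched
    layouts where per-cell variances would retain almost none).
    """
    n, p = X.shape
    if n - p < 1:
        raise ValueError("design leaves no residual degrees of freedom")
    beta, _ = _irls_nb(k, X, np.full(k.shape[0], alpha0), np.log(sf))
    mu = np.exp(np.clip(beta @ X.T + np.log(sf), -30.0, 30.0))
    r2 = (k - mu) ** 2
    lo = np.full(k.shape[0], 1e-8)
    hi = np.full(k.shape[0], 10.0)
    for _ in range(40):
        mid = np.sqrt(lo * hi)
        s = (r2 / (mu + mid[:, None] * mu**2)).sum(axis=1) - (n - p)
        hi = np.where(s < 0, mid, hi)
        lo = np.where(s >= 0, mid, lo)
    return np.sqrt(lo * hi)


def _dispersion_trend(alpha: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Parametric trend alpha(mu) = a0 + a1/mu fitted by least squares."""
    ok = alpha > 1e-7
    if ok.sum() < 10:
        return np.full_like(alpha, max(float(np.median(alpha)), 1e-8))
    A = np.column_stack([np.ones(ok.sum()), 1.0 / np.maximum(mu[ok], 1e-8)])
    coef, *_ = np.linalg.lstsq(A, alpha[ok], rcond=None)
    a0, a1 = max(coef[0], 1e-8), max(coef[1], 0.0)
    return np.maximum(a0 + a1 / np.maximum(mu, 1e-8), 1e-8)


def _irls_nb(k: np.ndarray, X: np.ndarray, alpha: np.ndarray,
             offset: np.ndarray, n_iter: int = 30, tol: float = 1e-8):
    """Batched IRLS for NB regression with log link and fixed dispersion.

    k: (G, n) counts, X: (n, p), alpha: (G,), offset: (n,) log size factors.
    Returns beta (G, p) on the natural-log scale and covariance (G, p, p).
    """
    G, n = k.shape
    p = X.shape[1]
    # initialise from a linear fit on log counts
    z0 = np.log(k + 0.5) - offset
    beta = np.linalg.lstsq(X, z0.T, rcond=None)[0].T  # (G, p)
    XT = X.T
    for _ in range(n_iter):
        eta = beta @ XT + offset  # (G, n)
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        W = mu / (1.0 + alpha[:, None] * mu)  # (G, n)
        # working response
        z = eta - offset + (k - mu) / np.maximum(mu, 1e-12)
        XtWX = np.einsum("ni,gn,nj->gij", X, W, X)
        XtWz = np.einsum("ni,gn,gn->gi", X, W, z)
        # small ridge keeps degenerate (all-zero) genes solvable
        XtWX += 1e-10 * np.eye(p)[None, :, :]
        new = np.linalg.solve(XtWX, XtWz[:, :, None])[:, :, 0]
        step = new - beta
        beta = new
        if np.max(np.abs(step)) < tol:
            break
    eta = np.clip(beta @ XT + offset, -30.0, 30.0)
    mu = np.exp(eta)
    W = mu / (1.0 + alpha[:, None] * mu)
    XtWX = np.einsum("ni,gn,nj->gij", X, W, X) + 1e-10 * np.eye(p)[None, :, :]
    cov = np.linalg.inv(XtWX)
    return beta, cov


def _shrink_lfc(lfc: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Zero-centered normal-prior shrinkage (posterior mean).

    The prior scale is fit by matching the upper tail of the raw-LFC
    distribution (95th percentile of |LFC|), so a minority of genes with real
    effects widens the prior instead of being flattened by the null majority.
    """
    q95 = float(np.quantile(np.abs(lfc), 0.95))
    prior_var = max((q95 / 1.96) ** 2 - float(np.mean(se**2)), 1e-6)
    return lfc * prior_var / (prior_var + se**2)


def fit_differential(
    counts: CountMatrix,
    contrast: tuple[str, str],
    condition_col: str = "treatment",
    batch_col: str | None = "batch",
    min_mean: float = 40.0,
    size_factors: pd.Series | None = None,
    shrinkage_weight: float = 0.5,
) -> pd.DataFrame:
    """NB Wald differential test of contrast (test_level, ref_level).

    Features with raw mean <= min_mean across the compared samples are
    excluded before testing. Returns a table with the fixed column order
    feature (index), baseMean, lfc, lfcShrunk, se, stat, pvalue, padj, with
    log fold changes on the log2 scale.
    """
    test, ref = contrast
    meta = counts.samples
    keep = meta[condition_col].isin([test, ref])
    if (meta.loc[keep, condition_col] == test).sum() < 2 or \
       (meta.loc[keep, condition_col] == ref).sum() < 2:
        raise ValueError("need >=2 samples per contrast level")
    sub = counts.counts.loc[:, keep.to_numpy()]
    meta = meta.loc[keep.to_numpy()]

    raw_mean = sub.mean(axis=1)
    tested = sub.loc[raw_mean > min_mean]
    if tested.empty:
        raise ValueError(f"no feature passes the raw-mean filter ({min_mean})")

    if size_factors is None:
        sf = estimate_size_factors(tested)
    else:
        sf = size_factors.loc[sub.columns]
    sfv = sf.to_numpy()

    batch = meta[batch_col] if batch_col and batch_col in meta else None
    if batch is not None and batch.nunique() < 2:
        batch = None
    X, names = _design_matrix(meta[condition_col], contrast, batch)
    ci = names.index("condition")

    k = tested.to_numpy(dtype=float)
    y = k / sfv
    alpha_mom = _mom_dispersion(k, X, sfv)
    mu_hat = y.mean(axis=1)
    alpha_trend = _dispersion_trend(alpha_mom, mu_hat)
    w = shrinkage_weight
    alpha = np.exp(w * np.log(alpha_trend) + (1 - w) * np.log(alpha_mom))

    beta, cov = _irls_nb(k, X, alpha, np.log(sfv))
    lfc = beta[:, ci] / _LN2
    se = np.sqrt(np.maximum(cov[:, ci, ci], 0.0)) / _LN2
    # features flat across all samples: force the exact degenerate answer
    flat = (k == k[:, [0]]).all(axis=1) & np.allclose(sfv, 1.0)
    lfc[flat] = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se > 0, lfc / se, 0.0)
    # moderated t: residual df plus a fixed prior-df credit (4) for the
    # mean-dispersion trend toward which per-gene dispersions are shrunk;
    # accounts for dispersion-estimation uncertainty at small per-group n
    df_mod = max(X.shape[0] - X.shape[1], 1) + DISPERSION_PRIOR_DF
    pval = 2.0 * stats.t.sf(np.abs(stat), df=df_mod)
    padj = multipletests(pval, method="fdr_bh")[1]
    shrunk = _shrink_lfc(lfc, se)

    res = pd.DataFrame(
        {
            "baseMean": y.mean(axis=1),
            "lfc": lfc,
            "lfcShrunk": shrunk,
            "se": se,
            "stat": stat,
            "pvalue": pval,
            "padj": padj,
        },
        index=tested.index,
    )
    res.index.name = "feature"
    res.attrs["df"] = df_mod
    res.attrs["size_factors"] = sf
    return res


def normalized_group_means(
    counts: CountMatrix,
    group_cols=("genotype", "treatment"),
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-feature mean of normalized counts within each genotype:treatment group."""
    sf = estimate_size_factors(counts) if size_factors is None else size_factors
    y = counts.counts / sf
    key = counts.group_key(group_cols)
    return y.T.groupby(key).mean().T


def classify_degs(
    results: pd.DataFrame, fc_threshold: float = 2.0, fdr_threshold: float = 0.05,
    use_shrunken: bool = True,
) -> tuple[pd.Index, pd.Index]:
    """Split a differential table into (up, down) sets at a fold and FDR gate.

    fc_threshold is a fold (2.0 for two-fold, 1.2 for ">20%").
    """
    if fc_threshold <= 0 or fdr_threshold <= 0:
        raise ValueError("thresholds must be positive")
    lfc = results["lfcShrunk" if use_shrunken else "lfc"]
    sig = results["padj"] < fdr_threshold
    cut = np.log2(fc_threshold)
    up = results.index[sig & (lfc >= cut)]
    down = results.index[sig & (lfc <= -cut)]
    return up, down


def classify_rescue(
    down_in_mutant: pd.DataFrame,
    dbs_effect: pd.DataFrame,
    means: pd.DataFrame | None = None,
    fc_threshold: float = 1.2,
    fdr_threshold: float = 0.05,
    strict_baseline: bool = False,
    use_shrunken: bool = True,
    mutant_dbs_group: str = "KO:DBS",
    wt_baseline_group: str = "WT:sham",
) -> pd.DataFrame:
    """Classify mutant-downregulated genes by their response to stimulation.

    down_in_mutant: differential table (mutant-sham vs WT-sham) restricted to
    the significantly downregulated gene set; dbs_effect: differential table
    of mutant-DBS vs mutant-sham. Classes: 'unchanged' (DBS FDR >= threshold),
    'partial' (significant but < fc_threshold increase), 'rescued'
    (significant and >= fc_threshold increase). With strict_baseline, rescued
    additionally requires the mutant-DBS group mean to reach the WT-sham mean;
    the baseline-reached flag is always reported.
    """
    missing = down_in_mutant.index.difference(dbs_effect.index)
    if len(missing):
        raise KeyError(f"genes absent from the DBS-effect table: {sorted(missing)}")
    lcol = "lfcShrunk" if use_shrunken else "lfc"
    cut = np.log2(fc_threshold)
    rows = []
    for g in down_in_mutant.index:
        d = dbs_effect.loc[g]
        baseline_ok = True
        if means is not None:
            baseline_ok = bool(
                means.loc[g, mutant_dbs_group] >= means.loc[g, wt_baseline_group]
            )
        if d["padj"] >= fdr_threshold:
            cls = "unchanged"
        elif d[lcol] >= cut:
            cls = "rescued"
            if strict_baseline and not baseline_ok:
                cls = "partial"
        else:
            cls = "partial"
        rows.append(
            {
                "gene": g,
                "class": cls,
                "mutant_lfc": down_in_mutant.loc[g, lcol],
                "mutant_padj": down_in_mutant.loc[g, "padj"],
                "dbs_lfc": d[lcol],
                "dbs_padj": d["padj"],
                "baseline_reached": baseline_ok,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def cluster_samples(
    expr: pd.DataFrame, features: pd.Index | list | None = None,
    log_transform: bool = True,
):
    """Average-linkage hierarchical clustering on correlation distance.

    expr: normalized counts (features x samples); features: subset to cluster
    on (e.g. top-100 stimulation-upregulated genes). Returns (ordered sample
    ids, linkage matrix). Ties broken deterministically by sample-id order;
    a constant matrix yields a flat ordering with a warning.
    """
    if expr.shape[1] < 2:
        raise ValueError("need >=2 samples")
    sub = expr.loc[features] if features is not None else expr
    m = np.log2(sub.to_numpy(dtype=float) + 1.0) if log_transform else sub.to_numpy(dtype=float)
    sd = m.std(axis=0)
    if np.allclose(m, m[:, [0]][:, np.zeros(m.shape[1], int)]) or (sd == 0).all():
        warnings.warn("constant expression matrix: correlation distance undefined; "
                      "returning flat sample ordering")
        return list(expr.columns), None
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(m.T)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum((dist + dist.T) / 2.0, 0.0)
    Z = hierarchy.average(squareform(dist, checks=False))
    order = hierarchy.leaves_list(Z)
    return [expr.columns[i] for i in order], Z
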