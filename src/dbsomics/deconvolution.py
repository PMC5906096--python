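"""Marker-gene, regression-based cell-type-specific expression analysis.

For each cell type a per-sample reference signal is the mean of its marker
genes' normalized expression (rescaled to mean 1). For every gene and cell
type a separate linear model is fitted,

    expr_g = coef.1 + coef.2 * signal + coef.3 * (signal x condition) + e,

so coef.1 captures background/noise, coef.2 the population-specific
expression, and coef.3 the condition-specific difference within that
population. Retained models require model F-test p < 0.01, adjusted R^2 >
0.8, and a small intercept relative to the fitted signal term.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["build_reference_signals", "fit_psea", "select_models"]


def build_reference_signals(
    expr: pd.DataFrame, markers: dict[str, list[str]]
) -> pd.DataFrame:
    """Per-sample reference signal per cell type (samples x cell types).

    Missing markers are reported via a warning and the signal built from the
    rest; a cell type with no marker present is an error. Signals are scaled
    to mean 1 across samples so coef.2 is interpretable as the mean expression
    attributable to the cell type.
    """
    signals = {}
    for ct, genes in markers.items():
        present = [g for g in genes if g in expr.index]
        missing = [g for g in genes if g not in expr.index]
        if not present:
            raise KeyError(f"all markers of cell type {ct!r} missing: {genes}")
        if missing:
            warnings.warn(f"markers missing for {ct}: {missing}")
        sig = expr.loc[present].mean(axis=0)
        m = sig.mean()
        signals[ct] = sig / m if m > 0 else sig + 1.0
    return pd.DataFrame(signals)


def fit_psea(
    expr: pd.DataFrame,
    signals: pd.DataFrame,
    condition: pd.Series,
    treatment_level: str | None = None,
) -> pd.DataFrame:
    """Fit one linear model per gene x cell type; condition must be binary.

    treatment_level names the stimulated level (the interaction's on-state);
    defaults to the lexicographically later level. Returns a record table with
    columns cell_type, coef.1..coef.3, pvalue.1..pvalue.3 (per-coefficient
    t-tests), f_pvalue, adj_r2.
    """
    if expr.shape[1] < 4:
        raise ValueError("need >=4 samples")
    cond = pd.Series(condition).loc[expr.columns]
    levels = sorted(cond.unique())
    if len(levels) != 2:
        raise ValueError("condition must be binary and non-constant "
                         "(signal and interaction are collinear otherwise)")
    if treatment_level is None:
        treatment_level = levels[1]
    elif treatment_level not in levels:
        raise ValueError(f"treatment level {treatment_level!r} not in condition")
    ind = (cond == treatment_level).astype(float).to_numpy()

    rows = []
    for ct in signals.columns:
        s = signals[ct].loc[expr.columns].to_numpy()
        X = np.column_stack([np.ones_like(s), s, s * ind])
        if np.linalg.matrix_rank(X) < 3:
            raise ValueError(f"collinear design for cell type {ct!r}")
        for g in expr.index:
            y = expr.loc[g].to_numpy(dtype=float)
            fit = sm.OLS(y, X).fit()
            rows.append(
                {
                    "gene": g,
                    "cell_type": ct,
                    "coef.1": fit.params[0],
                    "coef.2": fit.params[1],
                    "coef.3": fit.params[2],
                    "pvalue.1": fit.pvalues[0],
                    "pvalue.2": fit.pvalues[1],
                    "pvalue.3": fit.pvalues[2],
                    "f_pvalue": fit.f_pvalue,
                    "adj_r2": fit.rsquared_adj,
                }
            )
    return pd.DataFrame(rows)


def select_models(
    records: pd.DataFrame,
    f_p: float = 0.01,
    adj_r2: float = 0.8,
    intercept_ratio: float = 0.5,
    mean_signal: float = 1.0,
) -> pd.DataFrame:
    """Retain gene x cell-type models passing the selection criteria.

    Retained iff model F p < f_p, adjusted R^2 > adj_r2, and |coef.1| <=
    intercept_ratio * |coef.2| * mean_signal (the large-intercept exclusion;
    signals are scaled to mean 1 so mean_signal defaults to 1). Genes retained
    under several cell types keep all records, with the best-adjusted-R^2 one
    flagged.
    """
    rec = records.copy()
    small_intercept = rec["coef.1"].abs() <= (
        intercept_ratio * rec["coef.2"].abs() * mean_signal
    )
    rec["retained"] = (
        (rec["f_pvalue"] < f_p) & (rec["adj_r2"] > adj_r2) & small_intercept
    )
    kept = rec.loc[rec["retained"]].copy()
    if len(kept):
        best = kept.groupby("gene")["adj_r2"].idxmax()
        kept["best_model"] = False
        kept.loc[best, "best_model"] = True
    else:
        kept["best_model"] = pd.Series(dtype=bool)
    return kept
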