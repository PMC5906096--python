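"""Gene-symbol harmonization and gene-list overlap statistics.

Overlap significance uses the one-sided (enrichment) Fisher exact test on the
2x2 in-A x in-B table over a stated universe; the reported percentage is the
fraction of the comparison list covered (100 * |A and B| / |B|).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["harmonize_symbols", "overlap_test", "OverlapResult"]


def harmonize_symbols(
    genes: list[str],
    alias_map: pd.DataFrame | None = None,
    policy: str = "keep",
) -> tuple[list[str], dict]:
    """Map symbols to canonical names via a local alias table.

    alias_map: two columns (alias, canonical); matching is case-insensitive.
    policy: 'keep' (unmapped symbols pass through), 'drop', or 'strict'
    (unmapped symbols raise). Duplicates after mapping are collapsed and
    reported.
    """
    if policy not in ("keep", "drop", "strict"):
        raise ValueError(f"unknown policy {policy!r}")
    lut = {}
    if alias_map is not None:
        a_col, c_col = alias_map.columns[:2]
        lut = {
            str(a).lower(): str(c)
            for a, c in zip(alias_map[a_col], alias_map[c_col])
        }
    out, unmapped, seen, dups = [], [], set(), []
    for g in genes:
        key = str(g).lower()
        if key in lut:
            canon = lut[key]
        else:
            unmapped.append(g)
            if policy == "drop":
                continue
            canon = g
        if canon in seen:
            dups.append(canon)
            continue
        seen.add(canon)
        out.append(canon)
    if policy == "strict" and unmapped:
        raise KeyError(f"unmapped symbols: {unmapped}")
    return out, {"unmapped": unmapped, "duplicates": dups}


@dataclass
class OverlapResult:
    n_a: int
    n_b: int
    n_overlap: int
    universe: int
    pct_of_b: float
    odds_ratio: float
    pvalue: float

    def to_dict(self) -> dict:
        return {
            "n_a": self.n_a, "n_b": self.n_b, "n_overlap": self.n_overlap,
            "universe": self.universe, "pct_of_b": self.pct_of_b,
            "odds_ratio": self.odds_ratio, "pvalue": self.pvalue,
        }


def overlap_test(set_a, set_b, universe) -> OverlapResult:
    """One-sided Fisher enrichment test of two gene sets over a universe.

    Members outside the universe are clipped (reported via attrs is not
    needed: clipping is part of the contract). The percentage is of the
    comparison list B.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a = set(set_a) & universe
    b = set(set_b) & universe
    k = len(a & b)
    table = [
        [k, len(a) - k],
        [len(b) - k, len(universe) - len(a) - len(b) + k],
    ]
    odds, p = stats.fisher_exact(table, alternative="greater")
    pct = 100.0 * k / len(b) if b else 0.0
    return OverlapResult(
        n_a=len(a), n_b=len(b), n_overlap=k, universe=len(universe),
        pct_of_b=pct, odds_ratio=float(odds), pvalue=float(p),
    )
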