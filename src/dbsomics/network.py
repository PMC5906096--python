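"""Two-layer TF->target subgraph extraction with expression overlay.

Starting from seed transcription factors (identified as increased at the
protein level), layer 1 is their direct targets; layer 2 is the targets of
layer-1 nodes that are themselves TFs. Retained nodes are those with a gene-
or isoform-level expression call (DEG and/or DEI), plus the mediating layer-1
TFs needed to keep layer-2 nodes connected. Node categories follow the
overlay: 'both', 'DEG-only', 'DEI-only', or 'TF-path' for mediators.
"""

from __future__ import annotations

import warnings

import networkx as nx
import pandas as pd

__all__ = ["extract_two_layer"]


def _category(node: str, deg: set, dei: set) -> str:
    in_deg, in_dei = node in deg, node in dei
    if in_deg and in_dei:
        return "both"
    if in_deg:
        return "DEG-only"
    if in_dei:
        return "DEI-only"
    return "TF-path"


def extract_two_layer(
    edges: pd.DataFrame,
    tf_set,
    seeds,
    deg,
    dei,
    lfc: dict | pd.Series | None = None,
) -> nx.DiGraph:
    """Extract the seed -> layer-1 -> layer-2 regulatory subgraph.

    edges: DataFrame with columns (tf, target); tf_set: genes allowed to
    mediate layer-2 expansion; seeds: starting TFs (missing ones reported via
    warning); deg/dei: expression call sets; lfc: optional per-gene log2 fold
    change stored as a node attribute. Self-loops are dropped with a warning.
    """
    tf_set, deg, dei = set(tf_set), set(deg), set(dei)
    lfc = dict(lfc) if lfc is not None else {}

    g = nx.DiGraph()
    n_self = 0
    for tf, tgt in edges.itertuples(index=False):
        if tf == tgt:
            n_self += 1
            continue
        g.add_edge(tf, tgt)
    if n_self:
        warnings.warn(f"dropped {n_self} self-loop edge(s)")

    present = [s for s in seeds if s in g]
    missing = [s for s in seeds if s not in g]
    if missing:
        warnings.warn(f"seed(s) absent from the edge list: {missing}")

    layer1 = set()
    for s in present:
        layer1.update(g.successors(s))
    layer1 -= set(present)
    layer2 = set()
    mediators = {}
    for n in sorted(layer1 & tf_set):
        tgts = set(g.successors(n)) - set(present) - layer1
        kept_tgts = {t for t in tgts if t in deg or t in dei}
        if kept_tgts:
            mediators[n] = kept_tgts
            layer2.update(kept_tgts)

    keep1 = {n for n in layer1 if n in deg or n in dei}
    keep1 |= set(mediators)  # mediating TFs retained even if not DEG/DEI

    sub = nx.DiGraph()
    for s in present:
        sub.add_node(s, layer="seed", category=_category(s, deg, dei),
                     lfc=lfc.get(s))
    for n in keep1:
        sub.add_node(n, layer=1, category=_category(n, deg, dei), lfc=lfc.get(n))
    for n in layer2:
        sub.add_node(n, layer=2, category=_category(n, deg, dei), lfc=lfc.get(n))
    for s in present:
        for t in g.successors(s):
            if t in keep1:
                sub.add_edge(s, t)
    for m, tgts in mediators.items():
        for t in tgts:
            sub.add_edge(m, t)
    for n in sub.nodes:
        sub.nodes[n]["out_degree"] = sub.out_degree(n)
    return sub
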