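"""Readers and writers for the pipeline's plain-text formats.

Counts and sample sheets are TSV; cytosine reports are the standard 1-based
(chrom, pos, strand, context, methylated, total) dialect; bedGraph is 0-based
half-open; gene lists are one symbol per line; edge lists are two-column TSV.
All float serialization uses fixed formats so reruns are byte-identical.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .diffexpr import CountMatrix

FLOAT_FMT = "%.6g"


def write_counts(cm: CountMatrix, counts_path: str, samples_path: str) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="feature")
    cm.samples.to_csv(samples_path, sep="\t", index_label="sample_id")


def read_counts(counts_path: str, samples_path: str,
                features: pd.DataFrame | None = None) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    return CountMatrix(counts=counts, samples=samples, features=features)


def write_cytosine_report(table: pd.DataFrame, path: str) -> None:
    """1-based cytosine report: chrom, pos, strand, context, methylated, total."""
    out = table.copy()
    out["pos"] = out["pos"].astype(int) + 1
    out[["chrom", "pos", "strand", "context", "meth", "total"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_cytosine_report(path: str) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "pos", "strand", "context", "meth", "total"],
    )
    df["pos"] = df["pos"].astype(int) - 1  # back to 0-based internal coords
    return df


def write_bedgraph(table: pd.DataFrame, path: str) -> None:
    """bedGraph of methylation levels (0-based half-open, one line per cytosine)."""
    lev = table["meth"] / table["total"].where(table["total"] > 0, np.nan)
    with open(path, "w") as fh:
        for chrom, pos, v in zip(table["chrom"], table["pos"], lev):
            if np.isnan(v):
                continue
            fh.write(f"{chrom}\t{int(pos)}\t{int(pos) + 1}\t{v:.4f}\n")


def write_gene_list(genes, path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_gene_list(path: str) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_edges(edges: pd.DataFrame, path: str) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_edges(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def write_truth(truth, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1, sort_keys=True)


def read_truth(path: str) -> dict:
    with open(path) as fh:
        return json.load(fh)
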