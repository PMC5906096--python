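"""Interval model of a (synthetic or real) genome annotation.

Genes, exons and the derived promoter / intron / intergenic partition on a
single coordinate system. Internally 0-based half-open; the partition follows
the precedence promoter > exon > intron > intergenic, so every base pair has
exactly one label and the genome fractions sum to 1.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FEATURES = ("promoter", "exon", "intron", "intergenic")
_CODE = {"intergenic": 0, "intron": 1, "exon": 2, "promoter": 3}
_NAME = {v: k for k, v in _CODE.items()}


@dataclass
class GenomeAnnotation:
    """Gene/exon intervals on one chromosome plus the derived base-pair labels.

    genes : DataFrame with columns gene_id, start, end, strand ('+'/'-')
    exons : DataFrame with columns gene_id, start, end
    """

    chrom: str
    length: int
    genes: pd.DataFrame
    exons: pd.DataFrame
    promoter_bp: int = 2000
    _labels: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        g = self.genes
        if ((g["start"] < 0) | (g["end"] > self.length)).any():
            raise ValueError("gene outside genome bounds")
        self.genes = g.reset_index(drop=True)
        self.exons = self.exons.reset_index(drop=True)

    # -- derived interval sets -------------------------------------------------

    def tss(self) -> pd.Series:
        g = self.genes
        return pd.Series(
            np.where(g["strand"] == "+", g["start"], g["end"] - 1),
            index=g["gene_id"],
        )

    def promoters(self) -> pd.DataFrame:
        """Strand-aware promoters: promoter_bp upstream of the TSS."""
        g = self.genes
        plus = g["strand"] == "+"
        start = np.where(plus, g["start"] - self.promoter_bp, g["end"])
        end = np.where(plus, g["start"], g["end"] + self.promoter_bp)
        return pd.DataFrame(
            {
                "gene_id": g["gene_id"],
                "start": np.clip(start, 0, self.length),
                "end": np.clip(end, 0, self.length),
            }
        )

    def labels(self) -> np.ndarray:
        """Per-base-pair feature code under the stated precedence."""
        if self._labels is None:
            lab = np.zeros(self.length, dtype=np.uint8)
            for _, r in self.genes.iterrows():
                lab[r["start"]:r["end"]] = np.maximum(
                    lab[r["start"]:r["end"]], _CODE["intron"]
                )
            for _, r in self.exons.iterrows():
                lab[r["start"]:r["end"]] = np.maximum(
                    lab[r["start"]:r["end"]], _CODE["exon"]
                )
            for _, r in self.promoters().iterrows():
                lab[r["start"]:r["end"]] = np.maximum(
                    lab[r["start"]:r["end"]], _CODE["promoter"]
                )
            self._labels = lab
        return self._labels

    def genome_fractions(self) -> pd.Series:
        counts = np.bincount(self.labels(), minlength=4)
        return pd.Series(counts / self.length, index=[_NAME[i] for i in range(4)])

    def label_at(self, positions: np.ndarray) -> np.ndarray:
        """Feature name at each 0-based position."""
        positions = np.asarray(positions)
        if (positions < 0).any() or (positions >= self.length).any():
            raise ValueError("position outside genome bounds")
        codes = self.labels()[positions]
        return np.array([_NAME[c] for c in codes])

    # -- serialization ---------------------------------------------------------

    def to_gtf(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f'##sequence-region {self.chrom} 1 {self.length}\n')
            for _, g in self.genes.iterrows():
                attrs = f'gene_id "{g["gene_id"]}";'
                fh.write(
                    f"{self.chrom}\tdbsomics\tgene\t{g['start'] + 1}\t{g['end']}\t."
                    f"\t{g['strand']}\t.\t{attrs}\n"
                )
                for _, e in self.exons[self.exons["gene_id"] == g["gene_id"]].iterrows():
                    fh.write(
                        f"{self.chrom}\tdbsomics\texon\t{e['start'] + 1}\t{e['end']}\t."
                        f"\t{g['strand']}\t.\t{attrs}\n"
                    )

    @classmethod
    def from_gtf(cls, path: str, length: int | None = None,
                 promoter_bp: int = 2000) -> "GenomeAnnotation":
        import gffutils

        db = gffutils.create_db(
            path, ":memory:", force=True, keep_order=True,
            disable_infer_genes=True, disable_infer_transcripts=True,
        )
        genes, exons = [], []
        chrom = None
        for f in db.features_of_type("gene"):
            chrom = f.seqid
            genes.append(
                {"gene_id": f["gene_id"][0], "start": f.start - 1, "end": f.end,
                 "strand": f.strand}
            )
        for f in db.features_of_type("exon"):
            exons.append({"gene_id": f["gene_id"][0], "start": f.start - 1, "end": f.end})
        genes = pd.DataFrame(genes)
        exons = pd.DataFrame(exons)
        if length is None:
            length = int(genes["end"].max() + promoter_bp)
        return cls(chrom=chrom, length=length, genes=genes, exons=exons,
                   promoter_bp=promoter_bp)


def write_bed(intervals: pd.DataFrame, path: str, chrom: str,
              extra_cols: list[str] | None = None) -> None:
    """BED (0-based half-open) writer for interval tables with start/end columns."""
    cols = ["start", "end"] + (extra_cols or [])
    with open(path, "w") as fh:
        for _, r in intervals.iterrows():
            rest = "\t".join(str(r[c]) for c in (extra_cols or []))
            fh.write(f"{chrom}\t{int(r['start'])}\t{int(r['end'])}"
                     + (f"\t{rest}" if rest else "") + "\n")
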