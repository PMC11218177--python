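"""Toy reference genome and packaged annotation tables.

The synthetic cohort lives on a 5-contig, 250 Mb toy genome; the packaged
gene table places 60 genes (drivers, tumor suppressors and the functional
categories used by the germline analysis) at fixed coordinates on it. Real
cohorts replace these tables with their own gene intervals / category /
census files via the loader ``path`` arguments.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd

__all__ = [
    "CONTIGS",
    "load_gene_table",
    "load_gene_categories",
    "load_cgc_genes",
    "genes_overlapping",
]

#: contig name -> length (bp) of the toy genome
CONTIGS: dict[str, int] = {f"chr{i}": 50_000_000 for i in range(1, 6)}


def _data_path(name: str):
    return resources.files("multifoci.data").joinpath(name)


def load_gene_table(path: Optional[str | Path] = None) -> pd.DataFrame:
    """Gene intervals: columns gene, contig, start, end (0-based half-open)."""
    src = path if path is not None else _data_path("genes.tsv")
    df = pd.read_csv(src, sep="\t", dtype={"gene": str, "contig": str})
    required = {"gene", "contig", "start", "end"}
    if not required.issubset(df.columns):
        raise ValueError(f"gene table missing columns {required - set(df.columns)}")
    if (df["start"] >= df["end"]).any():
        bad = df[df["start"] >= df["end"]]["gene"].tolist()
        raise ValueError(f"malformed gene intervals (start >= end): {bad}")
    return df


def load_gene_categories(path: Optional[str | Path] = None) -> pd.DataFrame:
    """Gene -> functional category (immune, cell_cycle, proliferation,
    dna_repair, adhesion, other)."""
    src = path if path is not None else _data_path("gene_categories.tsv")
    return pd.read_csv(src, sep="\t", dtype=str)


def load_cgc_genes(path: Optional[str | Path] = None) -> list[str]:
    """Cancer Gene Census-style gene symbol list (packaged toy subset)."""
    src = path if path is not None else _data_path("cgc_genes.tsv")
    return pd.read_csv(src, sep="\t", dtype=str)["gene"].tolist()


def genes_overlapping(
    genes: pd.DataFrame, contig: str, start: int, end: int
) -> list[str]:
    """Gene symbols whose interval overlaps [start, end) on ``contig`` by >= 1 bp."""
    hit = (
        (genes["contig"] == contig)
        & (genes["start"] < end)
        & (genes["end"] > start)
    )
    return genes.loc[hit, "gene"].tolist()
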