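"""Plain-text readers and writers.

Genomic intervals use the BED dialect (0-based half-open) on disk;
genes are additionally written as GFF3 (1-based inclusive, per the
format).  Tabular outputs are TSV; tracks are bedGraph; contact matrices
are dense TSV with a JSON sidecar (see :mod:`chromadapt.hic`).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import InputError


def write_genes_bed(genes: pd.DataFrame, path: str | Path) -> None:
    bed = genes[["chrom", "start", "end", "gene_id"]]
    bed.to_csv(path, sep="\t", header=False, index=False)


def write_genes_gff3(genes: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in genes.itertuples(index=False):
            fh.write(
                f"{r.chrom}\tchromadapt\tgene\t{r.start + 1}\t{r.end}\t.\t+\t."
                f"\tID={r.gene_id}\n"
            )


def read_genes_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "gene_id"])
    if (df["end"] <= df["start"]).any():
        raise InputError(f"{path}: BED intervals must satisfy end > start")
    return df


def write_boundaries_bed(
    boundaries: pd.DataFrame, path: str | Path, flank: int = 0
) -> None:
    out = pd.DataFrame({
        "chrom": boundaries["chrom"],
        "start": np.maximum(boundaries["pos"] - flank, 0),
        "end": boundaries["pos"] + max(flank, 1),
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def read_tads_bed(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                     names=["chrom", "start", "end"])
    out: dict[str, list[tuple[int, int]]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(r.chrom, []).append((int(r.start), int(r.end)))
    return {c: sorted(v) for c, v in out.items()}


def write_tads_bed(
    tads: dict[str, list[tuple[int, int]]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(tads):
            for s, e in sorted(tads[chrom]):
                fh.write(f"{chrom}\t{s}\t{e}\n")


def write_bedgraph(
    chrom: str, bin_size: int, values: np.ndarray, path: str | Path
) -> None:
    with open(path, "w") as fh:
        for i, v in enumerate(values):
            if np.isfinite(v):
                fh.write(f"{chrom}\t{i * bin_size}\t{(i + 1) * bin_size}"
                         f"\t{v:.6g}\n")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise InputError(f"{path}: expression values must be non-negative")
    return df


def read_pair_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    req = {"pair_id", "gene_At", "gene_Dt"}
    if not req <= set(df.columns):
        raise InputError(f"{path}: pair map needs columns {sorted(req)}")
    return df


def read_edge_list(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    req = {"gene_a", "gene_b", "weight"}
    if not req <= set(df.columns):
        raise InputError(f"{path}: edge list needs columns {sorted(req)}")
    return df


def read_de_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    req = {"gene", "lfc", "padj", "direction"}
    if not req <= set(df.columns):
        raise InputError(f"{path}: DE table needs columns {sorted(req)}")
    return df
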