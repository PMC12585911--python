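"""Readers and writers for the plain-text genomic formats the pipeline touches.

BED6 is the native interval format (consumed and emitted unchanged). GFF3
gene annotations are converted to the internal 0-based half-open convention
on read. FASTA access goes through :mod:`pyfaidx` for on-disk genomes; small
in-memory genomes round-trip through plain FASTA text.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Optional, Sequence

import pandas as pd
from pyfaidx import Fasta

from .core import GeneModel, Genome, GenomicInterval, ReadAlignment

__all__ = [
    "read_bed6",
    "write_bed6",
    "read_bed_reads",
    "write_reads_bed",
    "read_fasta",
    "write_fasta",
    "read_gff3_genes",
    "write_gff3_genes",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_bedgraph",
    "write_bedgraph",
]


def read_bed6(path: str) -> List[GenomicInterval]:
    """Read a BED6 (or BED3) file into intervals."""
    out: List[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            strand = f[5] if len(f) >= 6 else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return out


def write_bed6(
    intervals: Iterable[GenomicInterval],
    path: str,
    names: Optional[Sequence[str]] = None,
    scores: Optional[Sequence[float]] = None,
) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else "."
            score = scores[i] if scores is not None else 0
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
            )


def read_bed_reads(path: str, sample_id: str = "") -> List[ReadAlignment]:
    """Read BED6 alignments; column 5 is taken as the mapping quality."""
    reads: List[ReadAlignment] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            mapq = int(float(f[4])) if len(f) >= 5 and f[4] != "." else 0
            strand = f[5] if len(f) >= 6 else "."
            reads.append(
                ReadAlignment(
                    GenomicInterval(f[0], int(f[1]), int(f[2]), strand),
                    mapq=mapq,
                    sample_id=sample_id,
                )
            )
    return reads


def write_reads_bed(reads: Iterable[ReadAlignment], path: str) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.sample_id or '.'}\t{r.mapq}\t{r.strand}\n"
            )


def read_fasta(path: str) -> Genome:
    """Load a FASTA file into an in-memory :class:`Genome` (pyfaidx-backed)."""
    fa = Fasta(path, read_ahead=10_000_000, sequence_always_upper=True)
    genome = Genome({name: str(fa[name][:]) for name in fa.keys()})
    fa.close()
    # drop the index sidecar created for a throwaway read
    for ext in (".fai",):
        try:
            os.remove(path + ext)
        except OSError:
            pass
    return genome


def write_fasta(genome: Genome, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome.sequences[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gff3_genes(path: str, feature_type: str = "gene") -> List[GeneModel]:
    """Read gene features from GFF3, converting 1-based inclusive to 0-based half-open."""
    genes: List[GeneModel] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9 or f[2] != feature_type:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID", attrs.get("gene_id", f"{f[0]}:{f[3]}"))
            genes.append(
                GeneModel(
                    GenomicInterval(f[0], int(f[3]) - 1, int(f[4]), f[6]),
                    gene_id=gene_id,
                )
            )
    return genes


def write_gff3_genes(genes: Iterable[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\trepairscape\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def read_expression_tsv(path: str) -> pd.Series:
    """Read a two-column TSV (gene_id, value) into a Series indexed by gene."""
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0], name=df.columns[1])


def write_expression_tsv(expr: pd.Series, path: str, value_name: str = "tpm") -> None:
    pd.DataFrame({"gene_id": expr.index, value_name: expr.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


def read_bedgraph(path: str) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "value"],
    )
    return df


def write_bedgraph(df: pd.DataFrame, path: str) -> None:
    df[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False
    )
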