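"""Readers and writers for the standard genomic text formats the pipeline touches.

Internal coordinates are uniformly 0-based half-open; GFF3 (1-based,
inclusive) is converted on read. Parsing of the container formats is
delegated to Biopython and pandas, with a thin validation layer that
reports the offending file and line on malformed input.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import GeneModel, GenomeAssembly, Interval


def write_fasta(genome: GenomeAssembly, path: str) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.contigs.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> GenomeAssembly:
    contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}
    return GenomeAssembly(contigs)


def write_genes_bed(genes: Sequence[GeneModel], path: str) -> None:
    """BED6-style gene table; thickStart carries the TSS."""
    with open(path, "w") as fh:
        for g in genes:
            s, e = g.promoter_window
            fh.write(f"{g.contig}\t{s}\t{e}\t{g.gene_id}\t0\t{g.strand}\t{g.tss}\n")


def read_genes_bed(path: str) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 7:
                raise ValueError(f"{path}:{lineno}: gene BED needs 7 columns, got {len(f)}")
            try:
                genes.append(
                    GeneModel(
                        gene_id=f[3],
                        contig=f[0],
                        tss=int(f[6]),
                        strand=f[5],
                        promoter_window=(int(f[1]), int(f[2])),
                    )
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return genes


def write_bed(intervals: Sequence[Interval], path: str) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\n")


def read_bed(path: str) -> list[Interval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns, got {len(f)}")
            try:
                out.append(Interval(f[0], int(f[1]), int(f[2])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return out


def read_gff3(path: str) -> pd.DataFrame:
    """GFF3 features as a DataFrame with 0-based half-open start/end."""
    cols = [
        "contig", "source", "type", "start", "end",
        "score", "strand", "phase", "attributes",
    ]
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ValueError(f"{path}:{lineno}: GFF3 needs 9 columns, got {len(f)}")
            try:
                start = int(f[3]) - 1  # 1-based inclusive -> 0-based half-open
                end = int(f[4])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            rows.append([f[0], f[1], f[2], start, end, f[5], f[6], f[7], f[8]])
    return pd.DataFrame(rows, columns=cols)


def write_bedgraph(records: pd.DataFrame, path: str, value_col: str) -> None:
    """bedGraph export of a score/delta track (one base-width spans per probe)."""
    with open(path, "w") as fh:
        for _, row in records.iterrows():
            fh.write(
                f"{row['contig']}\t{int(row['position'])}\t{int(row['position']) + 1}"
                f"\t{row[value_col]:.6g}\n"
            )


def read_bedgraph(path: str) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) != 4:
                raise ValueError(f"{path}:{lineno}: bedGraph needs 4 columns, got {len(f)}")
            try:
                rows.append([f[0], int(f[1]), float(f[3])])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed bedGraph values") from None
    return pd.DataFrame(rows, columns=["contig", "position", "value"])


def write_tsv_matrix(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=True)


def read_tsv_matrix(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_intensities(im, path: str) -> None:
    """TSV intensity matrix: probe_id, contig, start, one column per replicate."""
    df = im.probes.to_frame().drop(columns="length")
    df.insert(0, "probe_id", [f"p{i}" for i in range(len(df))])
    for r in range(im.n_replicates):
        df[f"rep{r + 1}"] = im.values[:, r]
    df.to_csv(path, sep="\t", index=False)
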