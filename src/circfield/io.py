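"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA/FASTQ go through Biopython, genome random access through pyfaidx,
GTF through gffutils; tables are pandas TSVs.
"""
from __future__ import annotations

import os
from typing import Iterable

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyfaidx import Fasta

from .models import Genome, MiRNA, Transcript


# ---------------------------------------------------------------- FASTA

def write_genome_fasta(genome: Genome, path: str, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_genome_fasta(path: str) -> Genome:
    fa = Fasta(path, sequence_always_upper=True)
    genome = Genome([(name, str(fa[name][:])) for name in fa.keys()])
    fa.close()
    return genome


def write_mirna_fasta(mirnas: Iterable[MiRNA], path: str) -> None:
    records = [
        SeqRecord(Seq(m.mature_seq), id=m.mirna_id, description="")
        for m in mirnas
    ]
    SeqIO.write(records, path, "fasta")


def read_mirna_fasta(path: str) -> list[MiRNA]:
    return [
        MiRNA(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")
    ]


def write_spliced_fasta(circs, path: str) -> None:
    """Spliced circRNA sequences keyed by circ_id; unsequenced circs skipped."""
    records = [
        SeqRecord(Seq(c.spliced_sequence), id=c.circ_id, description="")
        for c in circs
        if c.spliced_sequence is not None
    ]
    SeqIO.write(records, path, "fasta")


# ---------------------------------------------------------------- FASTQ

def write_fastq(reads: Iterable[tuple[str, str]], path: str) -> None:
    """Write (read_id, sequence) pairs with uniform Q40 qualities."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fastq")]


# ------------------------------------------------------------------ GTF

def write_gtf(transcripts: Iterable[Transcript], path: str) -> None:
    """Exon and CDS features with gene_id/transcript_id/gene_name attributes."""
    with open(path, "w") as fh:
        for tx in transcripts:
            attrs = (
                f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
                f'gene_name "{tx.gene_symbol}";'
            )
            for start, end in tx.exons:
                fh.write(
                    f"{tx.chrom}\tcircfield\texon\t{start + 1}\t{end}\t.\t"
                    f"{tx.strand}\t.\t{attrs}\n"
                )
            if tx.cds is not None:
                cs, ce = tx.cds
                fh.write(
                    f"{tx.chrom}\tcircfield\tCDS\t{cs + 1}\t{ce}\t.\t"
                    f"{tx.strand}\t0\t{attrs}\n"
                )


def read_gtf(path: str) -> list[Transcript]:
    db = gffutils.create_db(
        path,
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_tx: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tx_id = feat.attributes["transcript_id"][0]
        entry = by_tx.setdefault(
            tx_id,
            {
                "gene_id": feat.attributes["gene_id"][0],
                "gene_symbol": feat.attributes.get("gene_name", [tx_id])[0],
                "chrom": feat.seqid,
                "strand": feat.strand,
                "exons": [],
                "cds": None,
            },
        )
        iv = (feat.start - 1, feat.end)  # GTF is 1-based inclusive
        if feat.featuretype == "exon":
            entry["exons"].append(iv)
        else:
            cds = entry["cds"]
            entry["cds"] = iv if cds is None else (min(cds[0], iv[0]), max(cds[1], iv[1]))
    out = []
    for tx_id, e in sorted(by_tx.items()):
        out.append(
            Transcript(
                transcript_id=tx_id,
                gene_id=e["gene_id"],
                gene_symbol=e["gene_symbol"],
                chrom=e["chrom"],
                strand=e["strand"],
                exons=sorted(e["exons"]),
                cds=e["cds"],
            )
        )
    return out


# --------------------------------------------------------------- tables

def write_tsv(df: pd.DataFrame, path: str, index: bool = False) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_interactions_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"mirna_id", "gene_symbol"}
    if not required <= set(df.columns):
        raise ValueError(f"interactions table must have columns {sorted(required)}")
    if df.duplicated(["mirna_id", "gene_symbol"]).any():
        raise ValueError("duplicate (mirna_id, gene_symbol) pairs in interactions")
    return df


def read_de_mirna_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "mirna_id" not in df.columns:
        raise ValueError("DE-miRNA table must have a mirna_id column")
    return df


# --------------------------------------------------------- count matrix

def write_count_matrix(matrix, path: str) -> None:
    """TSV with a leading '#group' header row carrying sample group labels."""
    with open(path, "w") as fh:
        fh.write("#group\t" + "\t".join(matrix.group.loc[matrix.sample_ids]) + "\n")
        fh.write("circ_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for circ_id, row in matrix.counts.iterrows():
            fh.write(circ_id + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_count_matrix(path: str):
    from .diffexp import CountMatrix

    with open(path) as fh:
        group_line = fh.readline().rstrip("\n").split("\t")
        if group_line[0] != "#group":
            raise ValueError(f"{path}: missing '#group' header row")
        groups = group_line[1:]
        df = pd.read_csv(fh, sep="\t", index_col=0)
    group = pd.Series(groups, index=df.columns, name="group")
    return CountMatrix(counts=df, group=group)
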