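"""Annotation of back-splice junctions against gene models.

Resolves each junction to a host transcript (preferring exact exon-boundary
matches), classifies its origin (CDS/UTR exonic, intronic, exon-intron,
intergenic), computes transcript features — exon count, spliced length and
spliced sequence — and produces the per-chromosome / per-origin / isoform
summary tables.

Origin classes follow the precedence intergenic < intronic < exon_intron <
exonic, with exonic circles sub-typed CDS > 5'UTR > 3'UTR by the genomic
overlap of their contained exons.
"""
from __future__ import annotations

import logging
from collections import Counter

import pandas as pd
from intervaltree import IntervalTree

from .models import BackspliceJunction, CircRNA, Genome, Transcript, revcomp

logger = logging.getLogger(__name__)


class TranscriptIndex:
    """Interval index over transcript genomic spans."""

    def __init__(self, transcripts: list[Transcript]):
        self._trees: dict[str, IntervalTree] = {}
        for tx in transcripts:
            self._trees.setdefault(tx.chrom, IntervalTree()).addi(tx.start, tx.end, tx)

    def overlapping(self, junction: BackspliceJunction) -> list[Transcript]:
        tree = self._trees.get(junction.chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(junction.start, junction.end)]


def contained_exons(tx: Transcript, junction: BackspliceJunction) -> list[tuple[int, int]]:
    """Host exons fully inside [start, end), in genomic order."""
    return [
        (s, e) for s, e in tx.exons if s >= junction.start and e <= junction.end
    ]


def assign_host(
    junction: BackspliceJunction,
    transcripts: list[Transcript] | TranscriptIndex,
) -> tuple[Transcript | None, bool]:
    """Pick the host transcript for a junction, if any.

    Among same-strand transcripts overlapping the junction, a transcript
    with exon boundaries coinciding with *both* junction endpoints wins
    (boundary_match=True); ties are broken by most contained exons, then
    longest contained spliced length, then transcript id.
    """
    index = transcripts if isinstance(transcripts, TranscriptIndex) else TranscriptIndex(transcripts)
    candidates = [tx for tx in index.overlapping(junction) if tx.strand == junction.strand]
    if not candidates:
        return None, False

    def key(tx: Transcript):
        matched = any(s == junction.start for s, _ in tx.exons) and any(
            e == junction.end for _, e in tx.exons
        )
        inside = contained_exons(tx, junction)
        return (
            not matched,
            -len(inside),
            -sum(e - s for s, e in inside),
            tx.transcript_id,
        )

    best = min(candidates, key=key)
    boundary_match = not key(best)[0]
    return best, boundary_match


def _endpoint_in_exon(tx: Transcript, pos: int, is_end: bool) -> bool:
    # an endpoint is "in" an exon if the junction edge touches exonic bases
    p = pos - 1 if is_end else pos
    return any(s <= p < e for s, e in tx.exons)


def _intron_index(tx: Transcript, pos: int) -> int | None:
    for i in range(len(tx.exons) - 1):
        if tx.exons[i][1] <= pos < tx.exons[i + 1][0]:
            return i
    return None


def classify_origin(
    junction: BackspliceJunction,
    host: Transcript | None,
    boundary_match: bool,
) -> str:
    """Total classification of a junction into one origin class."""
    if host is None:
        return "intergenic"
    start_exonic = _endpoint_in_exon(host, junction.start, is_end=False)
    end_exonic = _endpoint_in_exon(host, junction.end, is_end=True)
    if not start_exonic and not end_exonic:
        i1 = _intron_index(host, junction.start)
        i2 = _intron_index(host, junction.end - 1)
        if i1 is not None and i1 == i2:
            return "intronic"  # ciRNA: a single intron circle
        return "exon_intron"  # spans exon(s) with intronic flanks
    if start_exonic != end_exonic:
        return "exon_intron"  # EIciRNA: one retained intron side
    return _exonic_subtype(junction, host)


def _exonic_subtype(junction: BackspliceJunction, host: Transcript) -> str:
    exons = contained_exons(host, junction) or [
        (max(s, junction.start), min(e, junction.end))
        for s, e in host.exons
        if s < junction.end and e > junction.start
    ]
    cds = host.cds
    if cds is not None and any(s < cds[1] and e > cds[0] for s, e in exons):
        return "exonic_cds"
    if cds is not None:
        utr5_is_left = host.strand == "+"
        all_left = all(e <= cds[0] for _, e in exons)
        all_right = all(s >= cds[1] for s, _ in exons)
        if (all_left and utr5_is_left) or (all_right and not utr5_is_left):
            return "exonic_utr5"
    return "exonic_utr3"


def spliced_sequence_of(genome: Genome, tx: Transcript, junction: BackspliceJunction) -> str:
    """Concatenated contained-exon sequence in transcription order."""
    seq = "".join(genome.fetch(tx.chrom, s, e) for s, e in contained_exons(tx, junction))
    return revcomp(seq) if tx.strand == "-" else seq


def transcript_features(
    genome: Genome,
    junction: BackspliceJunction,
    host: Transcript,
) -> tuple[int, int, str]:
    """(n_exons, spliced_length, spliced_sequence) for a boundary-matched circ."""
    exons = contained_exons(host, junction)
    if not exons:
        raise ValueError(
            f"no contained exons for {junction.circ_id} on {host.transcript_id}"
        )
    seq = spliced_sequence_of(genome, host, junction)
    return len(exons), sum(e - s for s, e in exons), seq


def annotate(
    junctions: list[BackspliceJunction],
    transcripts: list[Transcript],
    genome: Genome | None = None,
    alias: dict[str, str] | None = None,
) -> list[CircRNA]:
    """Annotate junctions: host, origin, and (when boundary-matched) features."""
    index = TranscriptIndex(transcripts)
    circs = []
    for junction in junctions:
        host, matched = assign_host(junction, index)
        origin = classify_origin(junction, host, matched)
        n_exons = length = seq = None
        if matched and host is not None:
            if genome is not None:
                n_exons, length, seq = transcript_features(genome, junction, host)
            else:
                exons = contained_exons(host, junction)
                n_exons, length = len(exons), sum(e - s for s, e in exons)
        circs.append(
            CircRNA(
                circ_id=junction.circ_id,
                junction=junction,
                host_gene=host.gene_symbol if host else None,
                host_transcript=host.transcript_id if host else None,
                origin=origin,
                n_exons=n_exons,
                spliced_length=length,
                spliced_sequence=seq,
                alias=(alias or {}).get(junction.circ_id),
            )
        )
    return circs


def to_frame(circs: list[CircRNA], length_mode: str = "spliced") -> pd.DataFrame:
    """One row per circ; ``length`` column selectable as spliced or genomic span."""
    if length_mode not in ("spliced", "genomic_span"):
        raise ValueError(f"unknown length mode {length_mode!r}")
    rows = []
    for c in circs:
        rows.append(
            {
                "circ_id": c.circ_id,
                "alias": c.alias,
                "chrom": c.junction.chrom,
                "start": c.junction.start,
                "end": c.junction.end,
                "strand": c.junction.strand,
                "host_gene": c.host_gene,
                "host_transcript": c.host_transcript,
                "origin": c.origin,
                "n_exons": c.n_exons,
                "spliced_length": c.spliced_length,
                "genomic_span": c.junction.span,
                "length": c.junction.span if length_mode == "genomic_span" else c.spliced_length,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "circ_id", "alias", "chrom", "start", "end", "strand", "host_gene",
            "host_transcript", "origin", "n_exons", "spliced_length",
            "genomic_span", "length",
        ],
    )


def summarize(circs: list[CircRNA], presence: dict[str, set[str]] | None = None) -> dict[str, pd.DataFrame]:
    """Summary tables: origin counts (per group when presence sets are given),
    per-chromosome counts, exon-count histogram, isoforms per gene."""
    by_id = {c.circ_id: c for c in circs}
    origin_overall = Counter(c.origin for c in circs)
    origin_df = pd.DataFrame(
        sorted(origin_overall.items()), columns=["origin", "n_circs"]
    )
    if presence:
        for group, ids in presence.items():
            per = Counter(by_id[i].origin for i in ids if i in by_id)
            origin_df[group] = origin_df["origin"].map(per).fillna(0).astype(int)

    chrom_counts = Counter(c.junction.chrom for c in circs)
    chrom_df = pd.DataFrame(sorted(chrom_counts.items()), columns=["chrom", "n_circs"])

    exon_hist = Counter(c.n_exons for c in circs if c.n_exons is not None)
    exon_df = pd.DataFrame(sorted(exon_hist.items()), columns=["n_exons", "n_circs"])

    iso = Counter(c.host_gene for c in circs if c.host_gene is not None)
    iso_df = pd.DataFrame(
        sorted(iso.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["gene", "n_isoforms"],
    )
    return {
        "origin": origin_df,
        "per_chromosome": chrom_df,
        "exon_histogram": exon_df,
        "isoforms_per_gene": iso_df,
    }


def realign_to_models(
    junctions: list[BackspliceJunction],
    genome: Genome,
    transcripts: list[Transcript] | TranscriptIndex,
    max_shift: int = 50,
) -> list[BackspliceJunction]:
    """Snap junctions onto exon boundaries within their homology window.

    A detected breakpoint is ambiguous whenever the circle's flanking bases
    repeat; among the equivalent representations, the one coinciding with
    both exon boundaries of a same-strand transcript is preferred (the
    convention annotation databases use). Junctions with no boundary-matched
    representation are returned unchanged.
    """
    from .bsj import homology_shifts

    index = transcripts if isinstance(transcripts, TranscriptIndex) else TranscriptIndex(transcripts)
    out = []
    for junction in junctions:
        chosen = junction
        for candidate in homology_shifts(genome, junction, max_shift):
            _, matched = assign_host(candidate, index)
            if matched:
                chosen = candidate
                break
        out.append(chosen)
    return out
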