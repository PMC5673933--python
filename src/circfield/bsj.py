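"""Back-splice junction detection, consensus intersection and caller I/O.

The detector is a deliberately simple anchor split-mapper: the two terminal
k-mers of a read that cannot be explained by a contiguous genome match are
located exactly in an anchor index; a read whose 5' anchor maps *downstream*
of its 3' anchor on the same chromosome and strand carries the head-to-tail
signature of a back-splice. Both anchors are extended inward to a consistent
breakpoint (ties shifted to the leftmost genomic representation, analogous
to indel left-alignment) and calls are aggregated per (junction, sample).

Consensus between two call sets keeps only junctions reported by both —
the dual-algorithm rule used to improve prediction accuracy — with the
consensus read count taken as the minimum of the two callers' counts.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

from .models import BackspliceJunction, Genome, JunctionCall, revcomp

logger = logging.getLogger(__name__)

DEFAULT_ANCHOR = 20
DEFAULT_MAX_SPAN = 2_000_000


@dataclass
class AnchorIndex:
    """Exact k-mer -> forward-genome locus index."""

    k: int
    loci: dict[str, list[tuple[str, int]]]

    def forward(self, kmer: str) -> list[tuple[str, int]]:
        return self.loci.get(kmer, [])

    def lookup(self, kmer: str) -> list[tuple[str, int, str]]:
        """Loci spelling ``kmer`` on either strand of the forward genome."""
        out = [(c, p, "+") for c, p in self.forward(kmer)]
        out += [(c, p, "-") for c, p in self.forward(revcomp(kmer))]
        return out


def index_genome(genome: Genome, k: int = DEFAULT_ANCHOR) -> AnchorIndex:
    """Build the anchor index; k must be at least 12 (uniqueness floor)."""
    if k < 12:
        raise ValueError("anchor k must be >= 12")
    loci: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for chrom, seq in genome:
        for pos in range(len(seq) - k + 1):
            loci[seq[pos : pos + k]].append((chrom, pos))
    return AnchorIndex(k=k, loci=dict(loci))


def _extend_forward(seq: str, genome_seq: str, pos: int) -> int:
    """Length of the longest prefix of seq matching genome_seq from pos."""
    n = min(len(seq), len(genome_seq) - pos)
    i = 0
    while i < n and seq[i] == genome_seq[pos + i]:
        i += 1
    return i


def _extend_backward(seq: str, genome_seq: str, end: int) -> int:
    """Length of the longest suffix of seq matching genome_seq ending at end."""
    n = min(len(seq), end)
    i = 0
    while i < n and seq[len(seq) - 1 - i] == genome_seq[end - 1 - i]:
        i += 1
    return i


def _contiguous(seq: str, index: AnchorIndex, genome: Genome) -> bool:
    k = index.k
    for anchor, offset in ((seq[:k], 0), (seq[-k:], len(seq) - k)):
        for chrom, pos in index.forward(anchor):
            start = pos - offset
            if start < 0:
                continue
            if genome.sequence(chrom)[start : start + len(seq)] == seq:
                return True
    return False


def _find_junction(
    seq: str,
    strand: str,
    index: AnchorIndex,
    genome: Genome,
    max_span: int,
    min_unique: int,
):
    k = index.k
    loci1 = index.forward(seq[:k])
    loci2 = index.forward(seq[-k:])
    if not loci1 or not loci2:
        return None
    if len(loci1) > min_unique or len(loci2) > min_unique:
        return None  # ambiguous anchors: discard rather than enumerate
    best = None
    for c1, p1 in loci1:
        gseq = genome.sequence(c1)
        for c2, p2 in loci2:
            if c2 != c1 or p1 <= p2:
                continue  # head-to-tail requires 5' anchor downstream
            m1 = _extend_forward(seq, gseq, p1)
            m2 = _extend_backward(seq, gseq, p2 + k)
            if m1 + m2 < len(seq):
                continue  # no consistent breakpoint
            b = len(seq) - m2  # leftmost genomic representation
            donor_end = p1 + b
            acceptor_start = p2 + k - (len(seq) - b)
            if acceptor_start < 0 or acceptor_start >= donor_end:
                continue
            if donor_end - acceptor_start > max_span:
                continue
            junction = BackspliceJunction(c1, acceptor_start, donor_end, strand)
            if best is None or (junction.start, junction.end) < (best.start, best.end):
                best = junction
    return best


def _gtag_ok(junction: BackspliceJunction, genome: Genome) -> bool:
    seq = genome.sequence(junction.chrom)
    s, e = junction.start, junction.end
    if s < 2 or e + 2 > len(seq):
        return False
    if junction.strand == "+":
        return seq[e : e + 2] == "GT" and seq[s - 2 : s] == "AG"
    return seq[s - 2 : s] == "AC" and seq[e : e + 2] == "CT"


def detect_backsplice(
    reads,
    index: AnchorIndex,
    genome: Genome,
    sample_id: str = "sample",
    caller_id: str = "circfield",
    max_span: int = DEFAULT_MAX_SPAN,
    min_unique: int = 1,
    require_gtag: bool = False,
) -> list[JunctionCall]:
    """Call back-splice junctions from (read_id, sequence) pairs.

    Reads shorter than two anchors are skipped (counted in the log); reads
    explainable by one contiguous genome match on either strand are treated
    as linear and produce no call.
    """
    k = index.k
    counts: dict[BackspliceJunction, int] = defaultdict(int)
    n_short = 0
    for _, seq in reads:
        seq = seq.upper()
        if len(seq) < 2 * k:
            n_short += 1
            continue
        oriented = ((seq, "+"), (revcomp(seq), "-"))
        if any(_contiguous(s, index, genome) for s, _ in oriented):
            continue
        for s, strand in oriented:
            junction = _find_junction(s, strand, index, genome, max_span, min_unique)
            if junction is not None:
                if require_gtag and not _gtag_ok(junction, genome):
                    continue
                counts[junction] += 1
                break
    if n_short:
        logger.info("%s: skipped %d reads shorter than 2k=%d", sample_id, n_short, 2 * k)
    return [
        JunctionCall(junction=j, sample_id=sample_id, caller_id=caller_id, read_count=n)
        for j, n in sorted(counts.items())
    ]


# ------------------------------------------------------------- consensus

def consensus(
    calls_a: list[JunctionCall],
    calls_b: list[JunctionCall],
    slack: int = 0,
) -> list[JunctionCall]:
    """Junctions reported by both callers, within +/- slack nt per endpoint.

    The consensus call carries the first caller's coordinates and the
    minimum of the two read counts; with the default slack of 0 the output
    junction set is exactly the intersection of the two inputs.
    """
    if slack < 0:
        raise ValueError("slack must be >= 0")
    by_key: dict[tuple[str, str], list[JunctionCall]] = defaultdict(list)
    for call in calls_b:
        by_key[(call.junction.chrom, call.junction.strand)].append(call)
    out = []
    for call in calls_a:
        j = call.junction
        best = None
        for other in by_key.get((j.chrom, j.strand), []):
            ds = abs(other.junction.start - j.start)
            de = abs(other.junction.end - j.end)
            if ds <= slack and de <= slack:
                if best is None or ds + de < best[0]:
                    best = (ds + de, other)
        if best is not None:
            out.append(
                JunctionCall(
                    junction=j,
                    sample_id=call.sample_id,
                    caller_id="consensus",
                    read_count=min(call.read_count, best[1].read_count),
                )
            )
    return out


# ------------------------------------------------------------- caller IO

DIALECTS = ("ciri2", "circexplorer2", "native_bed")


def read_caller_output(
    path: str,
    dialect: str,
    sample_id: str = "sample",
    caller_id: str | None = None,
) -> list[JunctionCall]:
    """Ingest an external caller's table, normalizing to 0-based half-open.

    CIRI2 TSVs are 1-based inclusive; CIRCexplorer2 tables and the native
    BED6+1 are already 0-based half-open.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    caller_id = caller_id or dialect
    calls = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if dialect == "ciri2":
        if not lines:
            return []
        header = lines[0].rstrip("\n").split("\t")
        try:
            cols = {
                name: header.index(name)
                for name in ("chr", "circRNA_start", "circRNA_end", "#junction_reads", "strand")
            }
        except ValueError as exc:
            raise ValueError(f"{path}: missing CIRI2 column ({exc})") from None
        for ln, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            f = line.split("\t")
            try:
                junction = BackspliceJunction(
                    f[cols["chr"]],
                    int(f[cols["circRNA_start"]]) - 1,
                    int(f[cols["circRNA_end"]]),
                    f[cols["strand"]],
                )
                count = int(f[cols["#junction_reads"]])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: malformed CIRI2 line {ln}: {exc}") from None
            calls.append(JunctionCall(junction, sample_id, caller_id, count))
        return calls
    for ln, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        f = line.split("\t")
        try:
            if dialect == "circexplorer2":
                junction = BackspliceJunction(f[0], int(f[1]), int(f[2]), f[5])
                count = int(f[12])
            else:  # native_bed: chrom start end circ_id read_count strand caller
                junction = BackspliceJunction(f[0], int(f[1]), int(f[2]), f[5])
                count = int(f[4])
                if len(f) > 6:
                    caller_id = f[6]
        except (IndexError, ValueError) as exc:
            raise ValueError(f"{path}: malformed {dialect} line {ln}: {exc}") from None
        calls.append(JunctionCall(junction, sample_id, caller_id, count))
    return calls


def write_native_bed(calls: list[JunctionCall], path: str) -> None:
    """BED6+1: chrom, start, end, circ_id, read_count, strand, caller_id."""
    with open(path, "w") as fh:
        for call in calls:
            j = call.junction
            fh.write(
                f"{j.chrom}\t{j.start}\t{j.end}\t{j.circ_id}\t{call.read_count}\t"
                f"{j.strand}\t{call.caller_id}\n"
            )


# ------------------------------------------------- junction equivalence

def homology_shifts(genome: Genome, junction: BackspliceJunction, max_shift: int = 50):
    """All equivalent breakpoint representations of one circle.

    When the bases entering the circle at the acceptor equal those leaving
    at the donor, the breakpoint can slide without changing the circular
    sequence; every slid coordinate pair denotes the same molecule. Returns
    the representations ordered leftmost first.
    """
    seq = genome.sequence(junction.chrom)
    s, e = junction.start, junction.end
    left = 0
    while (
        left < max_shift
        and s - left - 1 >= 0
        and seq[s - left - 1] == seq[e - left - 1]
    ):
        left += 1
    right = 0
    while (
        right < max_shift
        and e + right < len(seq)
        and seq[s + right] == seq[e + right]
    ):
        right += 1
    return [
        BackspliceJunction(junction.chrom, s + d, e + d, junction.strand)
        for d in range(-left, right + 1)
    ]


def canonical(genome: Genome, junction: BackspliceJunction) -> BackspliceJunction:
    """Leftmost equivalent representation — the detector's output convention."""
    return homology_shifts(genome, junction)[0]
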