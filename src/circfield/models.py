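"""Shared domain types for the circRNA field-effect pipeline.

Coordinates are 0-based half-open throughout ([start, end) on the forward
genome strand), matching the BED convention. Converters for 1-based caller
dialects live in :mod:`circfield.bsj`.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_ORIGINS = (
    "exonic_cds",
    "exonic_utr5",
    "exonic_utr3",
    "intronic",
    "intergenic",
    "exon_intron",
)

GROUPS = ("no_cancer", "adjacent", "tumor")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, N allowed)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Genome:
    """An in-memory genome: ordered (name, sequence) chromosome pairs."""

    chromosomes: list[tuple[str, str]]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, seq in self.chromosomes:
            if not seq:
                raise ValueError(f"chromosome {name!r} has empty sequence")
            if set(seq) - set("ACGT"):
                raise ValueError(f"chromosome {name!r} contains non-ACGT characters")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    def sequence(self, chrom: str) -> str:
        for name, seq in self.chromosomes:
            if name == chrom:
                return seq
        raise KeyError(chrom)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.sequence(chrom)[start:end]

    def __iter__(self):
        return iter(self.chromosomes)


@dataclass
class Transcript:
    """A single-isoform gene model with exons in genomic order.

    ``exons`` are (start, end) 0-based half-open intervals sorted ascending;
    ``cds``, when present, is the genomic CDS span used to classify circRNA
    origins into CDS vs UTR.
    """

    transcript_id: str
    gene_id: str
    gene_symbol: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        prev_end = None
        for start, end in self.exons:
            if start >= end:
                raise ValueError(f"{self.transcript_id}: exon {start}-{end} is empty")
            if prev_end is not None and start < prev_end:
                raise ValueError(f"{self.transcript_id}: exons overlap or unsorted")
            prev_end = end
        if self.cds is not None and self.exons:
            if self.cds[0] < self.exons[0][0] or self.cds[1] > self.exons[-1][1]:
                raise ValueError(f"{self.transcript_id}: CDS outside exon span")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass(frozen=True, order=True)
class BackspliceJunction:
    """A head-to-tail junction: acceptor at ``start``, donor at ``end``."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"junction start {self.start} !< end {self.end}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def circ_id(self) -> str:
        """Native identifier, 1-based inclusive for readability."""
        return f"circ_{self.chrom}_{self.start + 1}_{self.end}_{self.strand}"


@dataclass
class JunctionCall:
    """Per-sample, per-caller supporting-read evidence for one junction."""

    junction: BackspliceJunction
    sample_id: str
    caller_id: str
    read_count: int

    def __post_init__(self) -> None:
        if self.read_count < 1:
            raise ValueError("emitted calls require read_count >= 1")


@dataclass
class CircRNA:
    """An annotated back-splice junction."""

    circ_id: str
    junction: BackspliceJunction
    host_gene: Optional[str] = None
    host_transcript: Optional[str] = None
    origin: Optional[str] = None
    n_exons: Optional[int] = None
    spliced_length: Optional[int] = None
    spliced_sequence: Optional[str] = None
    alias: Optional[str] = None

    def __post_init__(self) -> None:
        if self.origin is not None and self.origin not in VALID_ORIGINS:
            raise ValueError(f"unknown origin class {self.origin!r}")
        if self.spliced_length is not None and self.spliced_sequence is not None:
            if self.spliced_length != len(self.spliced_sequence):
                raise ValueError("spliced_length != len(spliced_sequence)")


@dataclass
class MiRNA:
    """A mature miRNA sequence; T is normalized to U on construction."""

    mirna_id: str
    mature_seq: str

    def __post_init__(self) -> None:
        self.mature_seq = self.mature_seq.upper().replace("T", "U")
        if not 18 <= len(self.mature_seq) <= 26:
            raise ValueError(
                f"{self.mirna_id}: mature length {len(self.mature_seq)} outside 18-26"
            )
        if set(self.mature_seq) - set("ACGU"):
            raise ValueError(f"{self.mirna_id}: invalid characters in mature sequence")


@dataclass
class SpongeCandidate:
    """A circRNA-miRNA pair surviving all three sponge filters."""

    circ_id: str
    host_gene: str
    mirna_id: str
    n_seed_matches: int
    mirna_is_de: bool
    de_direction: Optional[str] = None


@dataclass
class TruthCirc:
    """One planted circRNA: junction, host, and per-group mean read counts."""

    junction: BackspliceJunction
    host_transcript: str
    group_means: dict[str, float]

    @property
    def circ_id(self) -> str:
        return self.junction.circ_id


@dataclass
class SimulationTruth:
    """Ground truth of a synthetic study, for scoring downstream stages."""

    circs: list[TruthCirc]
    fold_changes: dict[str, float] = field(default_factory=dict)
    planted_seed_sites: dict[tuple[str, str], int] = field(default_factory=dict)
    rng_seed: int = 0
    group_profile: str = "field_effect"

    def circ_by_id(self, circ_id: str) -> TruthCirc:
        for c in self.circs:
            if c.circ_id == circ_id:
                return c
        raise KeyError(circ_id)

    @property
    def junctions(self) -> list[BackspliceJunction]:
        return [c.junction for c in self.circs]
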