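"""miRNA-sponge candidate nomination.

A circRNA is nominated as a sponge candidate for a miRNA when three
filters all pass: (1) the miRNA has a validated interaction with the
circRNA-derived (host) gene, (2) the circularized spliced sequence carries
at least one exact complement of the miRNA seed, and (3) the miRNA appears
on the supplied differentially-expressed miRNA list. The seed is mature
positions 2-8 (a 7-mer) and matching is exact Watson-Crick reverse
complementation; overlapping occurrences count as distinct sites, and
scanning is wrap-aware by default so sites spanning the back-splice point
are found.
"""
from __future__ import annotations

import logging

import pandas as pd

from .models import CircRNA, MiRNA, SpongeCandidate, revcomp

logger = logging.getLogger(__name__)


def seed_of(mirna: MiRNA, start: int = 2, end: int = 8) -> str:
    """Seed = mature sequence at 1-based positions ``start..end`` (RNA)."""
    if len(mirna.mature_seq) < end:
        raise ValueError(
            f"{mirna.mirna_id}: mature sequence shorter than seed end {end}"
        )
    return mirna.mature_seq[start - 1 : end]


def seed_match_motif(seed: str) -> str:
    """DNA motif a target must contain: reverse complement of the seed."""
    seed = seed.upper().replace("T", "U")
    if set(seed) - set("ACGU"):
        raise ValueError(f"invalid seed characters in {seed!r}")
    return revcomp(seed.replace("U", "T"))


def count_seed_matches(spliced_sequence: str, seed: str, circular: bool = True) -> int:
    """Number of seed-complement sites in a (circularized) spliced sequence.

    Counts distinct start positions p in [0, L); with ``circular`` the
    sequence is extended by its own first seed_len-1 characters so sites
    wrapping across the back-splice junction are counted once.
    """
    motif = seed_match_motif(seed)
    seq = spliced_sequence.upper().replace("U", "T")
    if len(seq) < len(motif):
        raise ValueError("spliced sequence shorter than seed")
    scan = seq + (seq[: len(motif) - 1] if circular else "")
    count = 0
    p = scan.find(motif)
    while p != -1 and p < len(seq):
        count += 1
        p = scan.find(motif, p + 1)
    return count


def candidate_mirnas(
    circs: list[CircRNA],
    mirnas: list[MiRNA],
    interactions: pd.DataFrame,
    de_list,
    circular: bool = True,
    seed_start: int = 2,
    seed_end: int = 8,
) -> list[SpongeCandidate]:
    """Apply the three sponge filters over (circ, miRNA) pairs.

    ``interactions`` needs columns mirna_id and gene_symbol; ``de_list``
    may be a DataFrame with a mirna_id (and optional direction) column or
    any iterable of miRNA ids. Scope restriction to the most-expressed
    circs per group is the caller's responsibility (see
    :func:`circfield.diffexp.top_expressed`).
    """
    if isinstance(de_list, pd.DataFrame):
        de_ids = set(de_list["mirna_id"])
        directions = (
            dict(zip(de_list["mirna_id"], de_list["direction"]))
            if "direction" in de_list.columns
            else {}
        )
    else:
        de_ids = set(de_list)
        directions = {}
    mirna_by_id = {m.mirna_id: m for m in mirnas}
    by_gene: dict[str, list[str]] = {}
    for _, row in interactions.iterrows():
        by_gene.setdefault(row["gene_symbol"], []).append(row["mirna_id"])

    candidates: list[SpongeCandidate] = []
    for circ in circs:
        if circ.host_gene is None:
            continue
        if circ.spliced_sequence is None:
            logger.warning("skipping %s: no spliced sequence", circ.circ_id)
            continue
        for mirna_id in by_gene.get(circ.host_gene, []):  # filter 1
            mirna = mirna_by_id.get(mirna_id)
            if mirna is None:
                continue
            seed = seed_of(mirna, seed_start, seed_end)
            n = count_seed_matches(circ.spliced_sequence, seed, circular=circular)
            if n < 1:  # filter 2
                continue
            if mirna_id not in de_ids:  # filter 3
                continue
            candidates.append(
                SpongeCandidate(
                    circ_id=circ.circ_id,
                    host_gene=circ.host_gene,
                    mirna_id=mirna_id,
                    n_seed_matches=n,
                    mirna_is_de=True,
                    de_direction=directions.get(mirna_id),
                )
            )
    return candidates


def candidates_to_frame(candidates: list[SpongeCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "circ_id": c.circ_id,
                "host_gene": c.host_gene,
                "mirna_id": c.mirna_id,
                "n_seed_matches": c.n_seed_matches,
                "de_direction": c.de_direction,
            }
            for c in candidates
        ],
        columns=["circ_id", "host_gene", "mirna_id", "n_seed_matches", "de_direction"],
    )
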