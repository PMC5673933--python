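"""Synthetic study generator.

Builds a complete in-silico circRNA study — genome, gene models, a planted
circRNA truth set with three-group (no-cancer / tumor-adjacent / tumor)
abundance structure, back-splice-spanning reads with linear decoys, and
miRNA resources with seed-complement sites planted at known multiplicities —
so that every downstream stage of the pipeline can be exercised and scored
against ground truth without any external download.

The default field-effect preset mirrors the study design it emulates:
3 groups x 8 samples, adjacent tissue richest in detectable circRNAs,
tumor intermediate, non-cancer tissue poorest, junction read counts mostly
below 10 with a high tail.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import (
    GROUPS,
    BackspliceJunction,
    Genome,
    MiRNA,
    SimulationTruth,
    Transcript,
    TruthCirc,
    revcomp,
)

logger = logging.getLogger(__name__)

#: Per-group mean multipliers under the field-effect preset. Chosen so that
#: presence-detection of a log-uniform abundance spectrum reproduces the
#: adjacent > tumor > no-cancer ordering seen in gastric field cancerization.
FIELD_EFFECT_MULTIPLIERS = {"adjacent": 1.0, "tumor": 0.3, "no_cancer": 0.08}

DEFAULT_SAMPLES_PER_GROUP = 8
DEFAULT_DISPERSION = 0.2


def _rng(seed, *stream) -> np.random.Generator:
    return np.random.default_rng([int(seed), *[int(s) for s in stream]])


# --------------------------------------------------------------- genome

def generate_genome(n_chrom: int, chrom_length: int, rng_seed: int) -> Genome:
    """Uniform-random A/C/G/T chromosomes; byte-reproducible per seed."""
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if chrom_length < 1000:
        raise ValueError("chrom_length must be >= 1000")
    rng = _rng(rng_seed, 0)
    alphabet = np.frombuffer(b"ACGT", dtype="S1")
    chroms = []
    for i in range(n_chrom):
        seq = rng.choice(alphabet, size=chrom_length).tobytes().decode()
        chroms.append((f"chr{i + 1}", seq))
    return Genome(chroms)


# ---------------------------------------------------------- gene models

def generate_gene_models(
    genome: Genome,
    n_genes: int,
    exons_per_gene: tuple[int, int] = (3, 6),
    exon_len: tuple[int, int] = (150, 350),
    intron_len: tuple[int, int] = (100, 400),
    intergenic_len: tuple[int, int] = (200, 500),
    rng_seed: int = 0,
) -> list[Transcript]:
    """Place non-overlapping single-isoform genes along the chromosomes.

    Interior exons are covered by a CDS (first and last exon become UTRs)
    so that CDS-vs-UTR origin classification is exercisable; genes with
    fewer than three exons are left noncoding.
    """
    rng = _rng(rng_seed, 1)
    transcripts: list[Transcript] = []
    chrom_iter = iter(genome.chromosomes)
    chrom, seq = next(chrom_iter)
    cursor = int(rng.integers(*intergenic_len))
    for g in range(n_genes):
        n_ex = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
        lens = rng.integers(exon_len[0], exon_len[1] + 1, size=n_ex)
        gaps = rng.integers(intron_len[0], intron_len[1] + 1, size=n_ex - 1)
        footprint = int(lens.sum() + gaps.sum())
        while cursor + footprint > len(seq):
            try:
                chrom, seq = next(chrom_iter)
            except StopIteration:
                raise ValueError(
                    f"genome too small: placed {g} of {n_genes} genes"
                ) from None
            cursor = int(rng.integers(*intergenic_len))
        exons = []
        pos = cursor
        for i, length in enumerate(lens):
            exons.append((pos, pos + int(length)))
            pos += int(length)
            if i < n_ex - 1:
                pos += int(gaps[i])
        strand = "+" if rng.random() < 0.5 else "-"
        cds = (exons[1][0], exons[-2][1]) if n_ex >= 3 else None
        gid = f"gene{g + 1:04d}"
        transcripts.append(
            Transcript(
                transcript_id=f"tx{g + 1:04d}",
                gene_id=gid,
                gene_symbol=f"GENE{g + 1}",
                chrom=chrom,
                strand=strand,
                exons=exons,
                cds=cds,
            )
        )
        cursor = pos + int(rng.integers(*intergenic_len))
    return transcripts


# ---------------------------------------------------------------- truth

def generate_truth(
    transcripts: list[Transcript],
    n_circ: int,
    group_profile: str = "field_effect",
    fold_change_spec: dict | None = None,
    rng_seed: int = 0,
    base_mean_log10_range: tuple[float, float] = (-1.5, 1.5),
    isoform_fraction: float = 0.2,
    min_spliced_length: int = 150,
) -> SimulationTruth:
    """Plant ``n_circ`` circRNAs on exon boundaries of multi-exon transcripts.

    Per-circ base means are drawn log-uniform over ``base_mean_log10_range``
    (mostly-low counts with a high tail); under the field-effect preset the
    base mean is scaled per group by :data:`FIELD_EFFECT_MULTIPLIERS`, under
    the null preset all groups share it. A fraction of host genes receive a
    second circRNA isoform. ``fold_change_spec`` maps a circ index (or a
    circ_id produced by this generator) to the pooled-vs-no-cancer mean
    ratio to plant for that circ.
    """
    if group_profile not in ("field_effect", "null"):
        raise ValueError(f"unknown group profile {group_profile!r}")
    rng = _rng(rng_seed, 2)
    eligible = [
        tx for tx in transcripts if len(tx.exons) >= 2 and tx.spliced_length >= min_spliced_length
    ]
    if not eligible:
        raise ValueError("no eligible multi-exon transcripts")
    n_isoform_hosts = int(round(isoform_fraction * n_circ / 2))
    if n_circ > 2 * len(eligible):
        raise ValueError(
            f"cannot place {n_circ} circRNAs on {len(eligible)} eligible transcripts"
        )

    circs: list[TruthCirc] = []
    seen: set[BackspliceJunction] = set()
    order = rng.permutation(len(eligible))
    shuffled: list[Transcript] = [eligible[i] for i in order]
    # draw primaries first, then revisit the front of the list so a fraction
    # of genes receives a second circRNA isoform; remaining transcripts and a
    # second full pass serve as fallback when junction draws fail
    primary = shuffled[: max(1, n_circ - n_isoform_hosts)]
    hosts = primary + primary[:n_isoform_hosts] + shuffled[len(primary):] + shuffled

    for tx in hosts:
        if len(circs) >= n_circ:
            break
        junction = _draw_junction(tx, rng, min_spliced_length, seen)
        if junction is None:
            continue
        seen.add(junction)
        base = float(10.0 ** rng.uniform(*base_mean_log10_range))
        if group_profile == "field_effect":
            means = {g: base * FIELD_EFFECT_MULTIPLIERS[g] for g in GROUPS}
        else:
            means = {g: base for g in GROUPS}
        circs.append(TruthCirc(junction=junction, host_transcript=tx.transcript_id, group_means=means))
    if len(circs) < n_circ:
        raise ValueError(f"only placed {len(circs)} of {n_circ} requested circRNAs")

    truth = SimulationTruth(circs=circs, rng_seed=int(rng_seed), group_profile=group_profile)
    for key, fc in (fold_change_spec or {}).items():
        if isinstance(key, int):
            if not 0 <= key < len(circs):
                raise ValueError(f"fold-change index {key} out of range")
            circ = circs[key]
        else:
            matches = [c for c in circs if c.circ_id == key]
            if not matches:
                raise ValueError(f"fold change requested for unknown circ {key!r}")
            circ = matches[0]
        base = circ.group_means["no_cancer"] if group_profile == "null" else max(
            circ.group_means.values()
        )
        circ.group_means = {
            "no_cancer": base,
            "adjacent": base * fc,
            "tumor": base * fc,
        }
        truth.fold_changes[circ.circ_id] = float(fc)
    return truth


def _draw_junction(tx, rng, min_spliced_length, seen, max_tries: int = 8):
    n = len(tx.exons)
    for _ in range(max_tries):
        i = int(rng.integers(0, n))
        # favour 2-3 exon circles, the typical size in human tissue
        j = min(n - 1, i + int(rng.choice([1, 1, 2, 0])))
        if i > j:
            i, j = j, i
        length = sum(e - s for s, e in tx.exons[i : j + 1])
        if length < min_spliced_length:
            continue
        junction = BackspliceJunction(
            chrom=tx.chrom, start=tx.exons[i][0], end=tx.exons[j][1], strand=tx.strand
        )
        if junction not in seen:
            return junction
    return None


# ----------------------------------------------------------- count sims

def sample_ids_for(samples_per_group: int) -> dict[str, str]:
    """Deterministic sample naming: ``{group}_s{i}`` -> group."""
    return {
        f"{g}_s{i + 1}": g for g in GROUPS for i in range(samples_per_group)
    }


def _draw_counts(rng, mean: float, size: int, dispersion: float) -> np.ndarray:
    if mean <= 0:
        return np.zeros(size, dtype=int)
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean), size=size)


def simulate_counts(
    truth: SimulationTruth,
    samples_per_group: int = DEFAULT_SAMPLES_PER_GROUP,
    dispersion: float | None = None,
    rng_seed: int | None = None,
):
    """Draw a junction-read CountMatrix directly from the truth means.

    This bypasses read simulation and detection; it is the fast path for
    statistical calibration and for field-effect presence summaries.
    Dispersion defaults to 0.2 (NB) under the field-effect profile and to
    0 (Poisson) under the null profile.
    """
    from .diffexp import CountMatrix

    if dispersion is None:
        dispersion = DEFAULT_DISPERSION if truth.group_profile == "field_effect" else 0.0
    seed = truth.rng_seed if rng_seed is None else rng_seed
    rng = _rng(seed, 3)
    samples = sample_ids_for(samples_per_group)
    counts = pd.DataFrame(
        0, index=[c.circ_id for c in truth.circs], columns=list(samples), dtype=int
    )
    for circ in truth.circs:
        row = []
        for g in GROUPS:
            row.append(_draw_counts(rng, circ.group_means[g], samples_per_group, dispersion))
        counts.loc[circ.circ_id] = np.concatenate(row)
    group = pd.Series(samples, name="group")
    return CountMatrix(counts=counts, group=group)


# ----------------------------------------------------------------- reads

def simulate_reads(
    genome: Genome,
    transcripts: list[Transcript],
    truth: SimulationTruth,
    samples_per_group: int = DEFAULT_SAMPLES_PER_GROUP,
    read_len: int = 150,
    anchor: int = 20,
    linear_depth: float = 1.0,
    subst_rate: float = 0.0,
    dispersion: float | None = None,
    rng_seed: int | None = None,
) -> dict[str, list[tuple[str, str]]]:
    """Simulate per-sample single-end read sets as (read_id, sequence) lists.

    Junction reads cross each circ's back-splice point with the breakpoint
    uniformly placed at least ``anchor`` nt from both read ends; per-sample
    read counts follow the truth means (Poisson under the null profile, NB
    otherwise). Linear spliced-mRNA reads are added at ``linear_depth``-fold
    coverage as decoys. Circs whose spliced sequence is shorter than the
    read length are skipped with a warning.
    """
    from .annot import spliced_sequence_of

    if not 0 <= subst_rate <= 0.05:
        raise ValueError("subst_rate must be in [0, 0.05]")
    if read_len < 2 * anchor:
        raise ValueError("read_len must be >= 2 x anchor")
    if dispersion is None:
        dispersion = DEFAULT_DISPERSION if truth.group_profile == "field_effect" else 0.0
    seed = truth.rng_seed if rng_seed is None else rng_seed
    tx_by_id = {tx.transcript_id: tx for tx in transcripts}

    circ_seqs: dict[str, str] = {}
    for circ in truth.circs:
        host = tx_by_id[circ.host_transcript]
        seq = spliced_sequence_of(genome, host, circ.junction)
        if len(seq) < read_len:
            logger.warning(
                "skipping %s: spliced length %d < read length %d",
                circ.circ_id, len(seq), read_len,
            )
            continue
        circ_seqs[circ.circ_id] = seq

    mrnas = {}
    if linear_depth > 0:
        for tx in transcripts:
            seq = "".join(genome.fetch(tx.chrom, s, e) for s, e in tx.exons)
            if tx.strand == "-":
                seq = revcomp(seq)
            if len(seq) >= read_len:
                mrnas[tx.transcript_id] = seq

    out: dict[str, list[tuple[str, str]]] = {}
    for si, (sample, group) in enumerate(sample_ids_for(samples_per_group).items()):
        rng = _rng(seed, 4, si)
        reads: list[tuple[str, str]] = []
        for circ in truth.circs:
            if circ.circ_id not in circ_seqs:
                continue
            seq = circ_seqs[circ.circ_id]
            n = int(_draw_counts(rng, circ.group_means[group], 1, dispersion)[0])
            for i in range(n):
                a = int(rng.integers(anchor, read_len - anchor + 1))
                read = seq[len(seq) - a:] + seq[: read_len - a]
                reads.append((f"{sample}|junc|{circ.circ_id}|{i}", _mutate(read, subst_rate, rng)))
        for tx_id, seq in mrnas.items():
            n = int(rng.poisson(linear_depth * len(seq) / read_len))
            for i in range(n):
                p = int(rng.integers(0, len(seq) - read_len + 1))
                reads.append((f"{sample}|lin|{tx_id}|{i}", _mutate(seq[p : p + read_len], subst_rate, rng)))
        out[sample] = reads
    return out


def _mutate(seq: str, rate: float, rng) -> str:
    if rate <= 0:
        return seq
    n_mut = rng.binomial(len(seq), rate)
    if n_mut == 0:
        return seq
    arr = list(seq)
    for p in rng.choice(len(seq), size=n_mut, replace=False):
        arr[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[p]]
    return "".join(arr)


# ------------------------------------------------------- miRNA resources

@dataclass
class MirnaResources:
    """Bundle returned by :func:`generate_mirna_resources`."""

    mirnas: list[MiRNA]
    interactions: pd.DataFrame
    de_mirnas: pd.DataFrame
    genome: Genome
    controls: dict[str, str] = field(default_factory=dict)


def generate_mirna_resources(
    genome: Genome,
    transcripts: list[Transcript],
    truth: SimulationTruth,
    n_mirna: int,
    planted_sites: list[tuple] | None = None,
    rng_seed: int = 0,
    seed_len: int = 7,
    with_negative_controls: bool = True,
) -> MirnaResources:
    """Generate miRNAs, a validated-interaction table and a DE-miRNA list.

    ``planted_sites`` entries are ``(circ, k)`` — circ given as truth index
    or circ_id — each receiving a dedicated miRNA whose seed complement is
    written into the genome at ``k`` exon-interior positions of that circ's
    spliced sequence (at least a seed length away from the back-splice
    point). Planting is verified with the sponge scanner and the miRNA is
    re-drawn if spurious extra matches arise. Negative controls cover the
    three filters: interaction-without-site, site-without-interaction, and
    interaction+site without DE status. Returns a new, edited genome; the
    input genome is not modified.
    """
    from .annot import spliced_sequence_of
    from .sponge import count_seed_matches, seed_of

    planted_sites = list(planted_sites or [])
    rng = _rng(rng_seed, 5)
    tx_by_id = {tx.transcript_id: tx for tx in transcripts}
    chrom_seqs = {name: bytearray(seq, "ascii") for name, seq in genome}

    def resolve(circ_key) -> TruthCirc:
        if isinstance(circ_key, int):
            return truth.circs[circ_key]
        return truth.circ_by_id(circ_key)

    def current_spliced(circ: TruthCirc) -> str:
        g = Genome([(n, s.decode()) for n, s in chrom_seqs.items()])
        return spliced_sequence_of(g, tx_by_id[circ.host_transcript], circ.junction)

    def genomic_positions(circ: TruthCirc):
        """Spliced-index -> genomic coordinate map, transcript orientation."""
        tx = tx_by_id[circ.host_transcript]
        j = circ.junction
        coords = [
            p
            for s, e in tx.exons
            if s >= j.start and e <= j.end
            for p in range(s, e)
        ]
        return coords[::-1] if tx.strand == "-" else coords

    protected: set[tuple[str, int]] = set()

    def plant(circ: TruthCirc, motif_dna: str, k: int) -> None:
        coords = genomic_positions(circ)
        L = len(coords)
        tx = tx_by_id[circ.host_transcript]
        usable = L - 2 * seed_len - len(motif_dna)
        if k > 0 and usable < k * 2 * len(motif_dna):
            raise ValueError(
                f"cannot embed {k} sites of length {len(motif_dna)} in {circ.circ_id} (L={L})"
            )
        # non-overlapping spliced-space slots, >= seed_len from both ends,
        # never editing bases of circs whose site counts are already fixed
        positions: list[int] = []
        tries = 0
        while len(positions) < k:
            tries += 1
            if tries > 500:
                raise ValueError(f"failed to place {k} sites in {circ.circ_id}")
            p = int(rng.integers(seed_len, L - seed_len - len(motif_dna) + 1))
            if any(
                (tx.chrom, coords[p + off]) in protected
                for off in range(len(motif_dna))
            ):
                continue
            if all(abs(p - q) >= 2 * len(motif_dna) for q in positions):
                positions.append(p)
        comp = str.maketrans("ACGT", "TGCA")
        for p in positions:
            for off, base in enumerate(motif_dna):
                gpos = coords[p + off]
                b = base if tx.strand == "+" else base.translate(comp)
                chrom_seqs[tx.chrom][gpos] = ord(b)

    def random_mirna(mid: str) -> MiRNA:
        length = int(rng.integers(21, 23))
        seq = "".join(rng.choice(list("ACGU"), size=length))
        return MiRNA(mid, seq)

    mirnas: list[MiRNA] = []
    interactions: list[dict] = []
    de_ids: list[str] = []
    controls: dict[str, str] = {}
    serial = 0

    def plant_verified(circ: TruthCirc, k: int, mid: str) -> MiRNA:
        """Plant k sites and re-draw the miRNA until the scanner sees exactly k."""
        from .sponge import seed_match_motif

        for _ in range(30):
            mir = random_mirna(mid)
            seed = seed_of(mir, start=2, end=1 + seed_len)
            motif_dna = seed_match_motif(seed)
            if count_seed_matches(current_spliced(circ), seed, circular=True) > 0:
                continue  # pre-existing random match; re-draw
            if k > 0:
                snapshot = {n: bytes(s) for n, s in chrom_seqs.items()}
                plant(circ, motif_dna, k)
                got = count_seed_matches(current_spliced(circ), seed, circular=True)
                if got != k:
                    for n in chrom_seqs:
                        chrom_seqs[n][:] = snapshot[n]
                    continue
            chrom = tx_by_id[circ.host_transcript].chrom
            protected.update((chrom, p) for p in genomic_positions(circ))
            return mir
        raise RuntimeError(f"could not plant {k} clean sites for {circ.circ_id}")

    if n_mirna > 0 or planted_sites:
        for circ_key, k in planted_sites:
            circ = resolve(circ_key)
            serial += 1
            mid = f"sim-miR-{serial}"
            mir = plant_verified(circ, int(k), mid)
            mirnas.append(mir)
            host_gene = tx_by_id[circ.host_transcript].gene_symbol
            interactions.append(
                {"mirna_id": mid, "gene_symbol": host_gene, "evidence": "simulated"}
            )
            de_ids.append(mid)
            truth.planted_seed_sites[(circ.circ_id, mid)] = int(k)

        if with_negative_controls and truth.circs:
            used = {resolve(c).circ_id for c, _ in planted_sites}
            spare = [c for c in truth.circs if c.circ_id not in used]
            pool = spare or truth.circs
            picks = [pool[i % len(pool)] for i in range(3)]

            serial += 1
            mid = f"sim-miR-{serial}"  # interaction but no site
            mirnas.append(plant_verified(picks[0], 0, mid))
            interactions.append(
                {
                    "mirna_id": mid,
                    "gene_symbol": tx_by_id[picks[0].host_transcript].gene_symbol,
                    "evidence": "simulated",
                }
            )
            de_ids.append(mid)
            controls["interaction_no_site"] = mid
            truth.planted_seed_sites[(picks[0].circ_id, mid)] = 0

            serial += 1
            mid = f"sim-miR-{serial}"  # site but no interaction row
            mirnas.append(plant_verified(picks[1], 1, mid))
            de_ids.append(mid)
            controls["site_no_interaction"] = mid
            truth.planted_seed_sites[(picks[1].circ_id, mid)] = 1

            serial += 1
            mid = f"sim-miR-{serial}"  # interaction + site, not DE
            mirnas.append(plant_verified(picks[2], 1, mid))
            interactions.append(
                {
                    "mirna_id": mid,
                    "gene_symbol": tx_by_id[picks[2].host_transcript].gene_symbol,
                    "evidence": "simulated",
                }
            )
            controls["not_de"] = mid
            truth.planted_seed_sites[(picks[2].circ_id, mid)] = 1

        while len(mirnas) < n_mirna:
            serial += 1
            mirnas.append(random_mirna(f"sim-miR-{serial}"))

    inter_df = pd.DataFrame(interactions, columns=["mirna_id", "gene_symbol", "evidence"])
    de_df = pd.DataFrame({"mirna_id": de_ids, "direction": ["up"] * len(de_ids)})
    new_genome = Genome([(n, s.decode()) for n, s in chrom_seqs.items()])
    return MirnaResources(
        mirnas=mirnas,
        interactions=inter_df,
        de_mirnas=de_df,
        genome=new_genome,
        controls=controls,
    )


# ------------------------------------------------------------- pathways

def synthetic_pathways(
    transcripts: list[Transcript],
    n_terms: int = 10,
    genes_per_term: int = 15,
    rng_seed: int = 0,
) -> dict[str, tuple[str, set]]:
    """Random gene-set table (GMT-shaped) over the simulated gene universe."""
    rng = _rng(rng_seed, 6)
    symbols = sorted({tx.gene_symbol for tx in transcripts})
    table = {}
    for t in range(n_terms):
        size = min(genes_per_term, len(symbols))
        genes = set(rng.choice(symbols, size=size, replace=False))
        table[f"TERM{t + 1:03d}"] = (f"synthetic pathway {t + 1}", genes)
    return table
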