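"""Truth-based evaluation of the pipeline on synthetic studies.

Each function builds a fresh synthetic dataset from a seed, runs the
relevant pipeline stage, and scores it against the simulation truth:
detector recall/precision, consensus intersection exactness, null
calibration and power of the NB exact test, dispersion recovery, seed-site
scanner exactness, annotation round-trip fidelity, and the field-effect
presence ordering. These are the quantities the test suite asserts on and
the reproduction script reports.

Junction coordinates are compared in canonical (leftmost) representation:
the same circle admits several equivalent breakpoint coordinate pairs
whenever its flanking bases repeat, and detector and truth must be mapped
to a common representative before set comparison.
"""
from __future__ import annotations

import math

import numpy as np
from scipy import stats

from . import annot, bsj, diffexp, sponge, synthio
from .models import BackspliceJunction


def _study(seed: int, n_genes: int = 60, chrom_length: int = 200_000):
    genome = synthio.generate_genome(1, chrom_length, seed)
    transcripts = synthio.generate_gene_models(genome, n_genes, rng_seed=seed)
    return genome, transcripts


def detector_fidelity(
    seed: int,
    n_circs: int = 50,
    samples_per_group: int = 8,
    anchor: int = 20,
    linear_depth: float = 0.3,
) -> dict:
    """Recall/precision of the caller on an error-free field-effect study.

    Truth means are kept at >= 20 junction reads in the richest group so
    every planted circle is expected to be sequenced; comparison is on
    canonical junction coordinates pooled over all samples.
    """
    genome, transcripts = _study(seed)
    truth = synthio.generate_truth(
        transcripts,
        n_circs,
        group_profile="field_effect",
        rng_seed=seed,
        base_mean_log10_range=(math.log10(20), math.log10(50)),
    )
    reads = synthio.simulate_reads(
        genome,
        transcripts,
        truth,
        samples_per_group=samples_per_group,
        subst_rate=0.0,
        linear_depth=linear_depth,
        anchor=anchor,
        rng_seed=seed,
    )
    index = bsj.index_genome(genome, anchor)
    detected: set[BackspliceJunction] = set()
    per_sample_calls = {}
    for sample, rs in reads.items():
        calls = bsj.detect_backsplice(rs, index, genome, sample_id=sample)
        per_sample_calls[sample] = calls
        detected |= {c.junction for c in calls}
    truth_canon = {bsj.canonical(genome, j) for j in truth.junctions}
    tp = len(detected & truth_canon)
    return {
        "recall": tp / len(truth_canon),
        "precision": tp / len(detected) if detected else 0.0,
        "n_truth": len(truth_canon),
        "n_detected": len(detected),
        "calls": per_sample_calls,
    }


def consensus_perturbation_check(seed: int) -> dict:
    """Consensus at slack 0 against a partially coordinate-shifted copy.

    Half of the calls are shifted by +3 nt in the copy; the exact consensus
    must equal the unperturbed subset, per a brute-force set intersection.
    """
    fidelity = detector_fidelity(seed, n_circs=20, samples_per_group=1)
    sample = max(sorted(fidelity["calls"]), key=lambda s: len(fidelity["calls"][s]))
    calls = list(fidelity["calls"][sample])
    perturbed = []
    for i, c in enumerate(calls):
        j = c.junction
        if i % 2 == 1:
            j = BackspliceJunction(j.chrom, j.start + 3, j.end + 3, j.strand)
        perturbed.append(
            type(c)(junction=j, sample_id=c.sample_id, caller_id="copy", read_count=c.read_count)
        )
    cons = bsj.consensus(calls, perturbed, slack=0)
    expected = {c.junction for c in calls} & {p.junction for p in perturbed}
    got = {c.junction for c in cons}
    return {
        "n_calls": len(calls),
        "n_consensus": len(cons),
        "n_expected": len(expected),
        "exact": got == expected and len(expected) == (len(calls) + 1) // 2,
    }


def _null_truth(seed: int, n_circ: int, mean_log10_range, fold_changes=None):
    genome = synthio.generate_genome(1, 1_500_000, seed)
    transcripts = synthio.generate_gene_models(genome, 550, rng_seed=seed)
    return synthio.generate_truth(
        transcripts,
        n_circ,
        group_profile="null",
        rng_seed=seed,
        base_mean_log10_range=mean_log10_range,
        fold_change_spec=fold_changes,
    )


def null_calibration(seed: int, n_circ: int = 1000, dispersion: float = 0.2) -> dict:
    """Type-I error and p-value uniformity of the exact test under the null."""
    truth = _null_truth(seed, n_circ, (1.0, 2.2))
    matrix = synthio.simulate_counts(truth, 8, dispersion=dispersion, rng_seed=seed)
    est = diffexp.estimate_dispersion(matrix)
    res = diffexp.nb_exact_test(matrix, est)
    p = res["p_value"].values
    return {
        "n_circ": n_circ,
        "type_i_error": float((p < 0.05).mean()),
        "ks_distance": float(stats.kstest(p, "uniform").statistic),
        "common_dispersion": est.common,
    }


def dispersion_recovery(seed: int, n_circ: int = 200) -> dict:
    """Common dispersion recovered from Poisson and NB(0.2) simulations."""
    mean50 = (math.log10(50), math.log10(50))
    truth = _null_truth(seed, n_circ, mean50)
    out = {}
    for label, phi in (("poisson", 0.0), ("nb", 0.2)):
        matrix = synthio.simulate_counts(truth, 8, dispersion=phi, rng_seed=seed)
        out[f"common_dispersion_{label}"] = diffexp.estimate_dispersion(matrix).common
    out["n_circ"] = n_circ
    return out


def power_analysis(seed: int, n_circ: int = 160, n_de: int = 40, fold: float = 4.0) -> dict:
    """Detection rate of planted fold changes at mean 50, FDR < 0.05."""
    truth = _null_truth(
        seed,
        n_circ,
        (math.log10(50), math.log10(50)),
        fold_changes={i: fold for i in range(n_de)},
    )
    matrix = synthio.simulate_counts(truth, 8, dispersion=0.2, rng_seed=seed)
    est = diffexp.estimate_dispersion(matrix)
    res = diffexp.nb_exact_test(matrix, est).set_index("circ_id")
    de_ids = list(truth.fold_changes)
    sub = res.loc[de_ids]
    detected = (sub["fdr"] < 0.05) & (sub["log2_fc"] > 0)
    return {"n_de": n_de, "power": float(detected.mean())}


def sponge_exactness(seed: int, n_random_pairs: int = 1000) -> dict:
    """Planted-site recovery at k in {0, 1, 3}, wrap behaviour, oracle check."""
    genome, transcripts = _study(seed)
    truth = synthio.generate_truth(transcripts, 20, rng_seed=seed)
    res = synthio.generate_mirna_resources(
        genome, transcripts, truth, n_mirna=6,
        planted_sites=[(0, 1), (1, 3)], rng_seed=seed,
    )
    tx_by = {t.transcript_id: t for t in transcripts}
    mir_by = {m.mirna_id: m for m in res.mirnas}
    exact = []
    counts_by_k: dict[int, int] = {}
    for (circ_id, mirna_id), k in truth.planted_seed_sites.items():
        circ = truth.circ_by_id(circ_id)
        seq = annot.spliced_sequence_of(res.genome, tx_by[circ.host_transcript], circ.junction)
        got = sponge.count_seed_matches(seq, sponge.seed_of(mir_by[mirna_id]))
        exact.append(got == k)
        counts_by_k.setdefault(k, got)

    motif = sponge.seed_match_motif("GGAAUGU")
    wrap_seq = motif[3:] + "G" * 40 + motif[:3]
    wrap_circular = sponge.count_seed_matches(wrap_seq, "GGAAUGU", circular=True)
    wrap_linear = sponge.count_seed_matches(wrap_seq, "GGAAUGU", circular=False)

    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    agree = 0
    for _ in range(n_random_pairs):
        L = int(rng.integers(20, 150))
        seq = "".join(rng.choice(bases, L))
        seed_rna = "".join(rng.choice(bases, 7)).replace("T", "U")
        m = sponge.seed_match_motif(seed_rna)
        doubled = seq + seq
        oracle = sum(1 for p in range(L) if doubled[p : p + 7] == m)
        agree += sponge.count_seed_matches(seq, seed_rna, circular=True) == oracle
    return {
        "n_planted_pairs": len(exact),
        "planted_exact_fraction": float(np.mean(exact)),
        "recovered_k3": counts_by_k.get(3),
        "recovered_k1": counts_by_k.get(1),
        "recovered_k0": counts_by_k.get(0),
        "wrap_circular": wrap_circular,
        "wrap_linear": wrap_linear,
        "oracle_agreement_fraction": agree / n_random_pairs,
    }


def annotation_exactness(seed: int, n_circs: int = 50) -> dict:
    """Round-trip fidelity of annotation on truth junctions."""
    genome, transcripts = _study(seed)
    truth = synthio.generate_truth(transcripts, n_circs, rng_seed=seed)
    tx_by = {t.transcript_id: t for t in transcripts}
    circs = annot.annotate(truth.junctions, transcripts, genome)
    host_ok = feat_ok = 0
    for circ, tc in zip(circs, truth.circs):
        if circ.host_transcript == tc.host_transcript and circ.n_exons is not None:
            host_ok += 1
            tx = tx_by[tc.host_transcript]
            oracle_len = sum(
                e - s for s, e in tx.exons
                if s >= tc.junction.start and e <= tc.junction.end
            )
            feat_ok += circ.spliced_length == oracle_len == len(circ.spliced_sequence)
    origins = {c.origin for c in circs}
    return {
        "n_circs": n_circs,
        "host_recovery_rate": host_ok / n_circs,
        "feature_match_rate": feat_ok / n_circs,
        "origin_classes_valid": origins <= set(
            ("exonic_cds", "exonic_utr5", "exonic_utr3", "intronic", "intergenic", "exon_intron")
        ),
    }


def field_effect_ordering(seed: int, n_seeds: int = 20, n_circs: int = 50) -> dict:
    """Fraction of seeds with detected counts ordered adjacent > tumor > no-cancer."""
    _, transcripts = _study(seed)
    ordered = 0
    for i in range(n_seeds):
        sub_seed = seed * 1000 + i
        truth = synthio.generate_truth(transcripts, n_circs, rng_seed=sub_seed)
        matrix = synthio.simulate_counts(truth, 8, rng_seed=sub_seed)
        pres = diffexp.group_presence(matrix)
        if len(pres["adjacent"]) > len(pres["tumor"]) > len(pres["no_cancer"]):
            ordered += 1
    return {"n_seeds": n_seeds, "ordered_fraction": ordered / n_seeds}
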