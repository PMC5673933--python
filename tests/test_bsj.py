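"""Anchor index, back-splice detector, consensus and caller-output parsing."""
from __future__ import annotations

import numpy as np
import pytest

from circfield import bsj, synthio
from circfield.models import BackspliceJunction, Genome, JunctionCall, revcomp


def make_call(chrom, start, end, strand="+", count=5, sample="s1", caller="a"):
    return JunctionCall(BackspliceJunction(chrom, start, end, strand), sample, caller, count)


class TestAnchorIndex:
    def test_known_kmer_locus(self):
        g = synthio.generate_genome(1, 1000, 1)
        idx = bsj.index_genome(g, 12)
        kmer = g.sequence("chr1")[:12]
        assert ("chr1", 0, "+") in idx.lookup(kmer)

    def test_absent_kmer(self):
        g = Genome([("c", "A" * 2000)])
        idx = bsj.index_genome(g, 12)
        assert idx.lookup("ACGTACGTACGT") == []

    def test_k_too_small(self, genome):
        with pytest.raises(ValueError):
            bsj.index_genome(genome, 8)

    def test_matches_naive_scan(self):
        # oracle: brute-force scan of every genomic position on both strands
        g = synthio.generate_genome(1, 5000, 9)
        seq = g.sequence("chr1")
        k = 12
        idx = bsj.index_genome(g, k)
        rng = np.random.default_rng(0)
        for pos in rng.integers(0, len(seq) - k, size=50):
            kmer = seq[pos : pos + k]
            naive = [("chr1", p, "+") for p in range(len(seq) - k + 1) if seq[p : p + k] == kmer]
            naive += [
                ("chr1", p, "-")
                for p in range(len(seq) - k + 1)
                if revcomp(seq[p : p + k]) == kmer
            ]
            assert sorted(idx.lookup(kmer)) == sorted(naive)


class TestDetector:
    def test_constructed_junction_read(self):
        g = synthio.generate_genome(1, 5000, 2)
        seq = g.sequence("chr1")
        start, end = 1000, 1400
        circ = seq[start:end]
        read = circ[-75:] + circ[:75]
        idx = bsj.index_genome(g, 20)
        calls = bsj.detect_backsplice([("r1", read)], idx, g)
        assert len(calls) == 1
        j = calls[0].junction
        # compare up to breakpoint homology: same circle, one representation
        assert bsj.canonical(g, BackspliceJunction("chr1", start, end, "+")) == j
        assert calls[0].read_count == 1

    def test_contiguous_read_no_call(self):
        g = synthio.generate_genome(1, 5000, 2)
        read = g.sequence("chr1")[2000:2150]
        idx = bsj.index_genome(g, 20)
        assert bsj.detect_backsplice([("r1", read)], idx, g) == []

    def test_reverse_strand_read(self):
        g = synthio.generate_genome(1, 5000, 2)
        seq = g.sequence("chr1")
        circ = seq[1000:1400]
        read = revcomp(circ[-75:] + circ[:75])
        idx = bsj.index_genome(g, 20)
        calls = bsj.detect_backsplice([("r1", read)], idx, g)
        assert len(calls) == 1
        assert calls[0].junction.strand == "-"
        assert (calls[0].junction.start, calls[0].junction.end) == (
            bsj.canonical(g, BackspliceJunction("chr1", 1000, 1400, "+")).start,
            bsj.canonical(g, BackspliceJunction("chr1", 1000, 1400, "+")).end,
        )

    def test_short_reads_skipped(self):
        g = synthio.generate_genome(1, 5000, 2)
        idx = bsj.index_genome(g, 20)
        assert bsj.detect_backsplice([("r1", "ACGT")], idx, g) == []

    def test_recall_precision_on_simulated_study(self, genome, gene_models):
        truth = synthio.generate_truth(
            gene_models, 10, rng_seed=3, base_mean_log10_range=(1.4, 1.6)
        )
        reads = synthio.simulate_reads(
            genome, gene_models, truth, samples_per_group=1, linear_depth=0.5, rng_seed=7
        )
        idx = bsj.index_genome(genome, 20)
        detected = set()
        for sample, rs in reads.items():
            detected |= {c.junction for c in bsj.detect_backsplice(rs, idx, genome, sample_id=sample)}
        truth_canon = {bsj.canonical(genome, j) for j in truth.junctions}
        assert detected == truth_canon  # recall 1.0 and precision 1.0

    def test_max_span_respected(self, genome):
        g = synthio.generate_genome(1, 5000, 2)
        seq = g.sequence("chr1")
        circ = seq[100:4500]
        read = circ[-75:] + circ[:75]
        idx = bsj.index_genome(g, 20)
        assert bsj.detect_backsplice([("r", read)], idx, g, max_span=1000) == []
        calls = bsj.detect_backsplice([("r", read)], idx, g, max_span=5000)
        assert len(calls) == 1


class TestHomology:
    def test_shifts_share_circular_sequence(self, genome):
        # every representation of one circle spells the same circular RNA
        seq = genome.sequence("chr1")
        j = BackspliceJunction("chr1", 500, 900, "+")
        reps = bsj.homology_shifts(genome, j)
        ref = seq[j.start : j.end]
        for r in reps:
            rotated = seq[r.start : r.end]
            assert sorted(rotated + rotated) == sorted(ref + ref)
            assert rotated in ref + ref

    def test_canonical_is_leftmost_and_idempotent(self, genome):
        j = BackspliceJunction("chr1", 500, 900, "+")
        c = bsj.canonical(genome, j)
        assert c == bsj.canonical(genome, c)
        assert c.start <= j.start


class TestConsensus:
    def test_identical_inputs(self):
        calls = [make_call("c", 10 * i, 10 * i + 100, count=i + 1) for i in range(5)]
        out = bsj.consensus(calls, calls)
        assert {c.junction for c in out} == {c.junction for c in calls}
        assert all(c.caller_id == "consensus" for c in out)

    def test_disjoint_inputs(self):
        a = [make_call("c", 0, 100)]
        b = [make_call("c", 500, 600)]
        assert bsj.consensus(a, b) == []

    def test_partial_overlap_matches_bruteforce(self):
        rng = np.random.default_rng(5)
        coords = rng.choice(10_000, size=(30, 1), replace=False)
        a = [make_call("c", int(s), int(s) + 200, count=3) for s in coords[:20, 0]]
        b = [make_call("c", int(s), int(s) + 200, count=9) for s in coords[13:, 0]]
        out = bsj.consensus(a, b)
        expected = {c.junction for c in a} & {c.junction for c in b}
        assert {c.junction for c in out} == expected
        assert len(out) == 7
        assert all(c.read_count == 3 for c in out)  # min of the two callers

    def test_commutative_and_subset(self):
        rng = np.random.default_rng(6)
        a = [make_call("c", int(s), int(s) + 50) for s in rng.choice(5000, 15, replace=False)]
        b = [make_call("c", int(s), int(s) + 50) for s in rng.choice(5000, 15, replace=False)]
        ab = {c.junction for c in bsj.consensus(a, b)}
        ba = {c.junction for c in bsj.consensus(b, a)}
        assert ab == ba
        assert ab <= {c.junction for c in a} and ab <= {c.junction for c in b}

    def test_slack_matching(self):
        a = [make_call("c", 100, 200)]
        b = [make_call("c", 102, 199)]
        assert bsj.consensus(a, b, slack=0) == []
        out = bsj.consensus(a, b, slack=2)
        assert len(out) == 1 and out[0].junction == a[0].junction

    def test_negative_slack(self):
        with pytest.raises(ValueError):
            bsj.consensus([], [], slack=-1)


class TestCallerIO:
    def test_ciri2_coordinate_shift(self, tmp_path):
        p = tmp_path / "x.ciri"
        p.write_text(
            "circRNA_ID\tchr\tcircRNA_start\tcircRNA_end\t#junction_reads\tstrand\n"
            "c1\tchr1\t101\t200\t7\t+\n"
        )
        (call,) = bsj.read_caller_output(str(p), "ciri2")
        assert (call.junction.start, call.junction.end) == (100, 200)
        assert call.read_count == 7

    def test_circexplorer2_passthrough(self, tmp_path):
        p = tmp_path / "x.txt"
        fields = ["chr1", "100", "200", "circ/1", "0", "+", "100", "200", "0", "1", "100", "0", "9"]
        p.write_text("\t".join(fields) + "\n")
        (call,) = bsj.read_caller_output(str(p), "circexplorer2")
        assert (call.junction.start, call.junction.end, call.read_count) == (100, 200, 9)

    def test_native_bed_roundtrip(self, tmp_path):
        calls = [make_call("chr1", 5, 500, "-", count=3), make_call("chr2", 9, 99, "+", count=1)]
        p = tmp_path / "calls.bed"
        bsj.write_native_bed(calls, str(p))
        back = bsj.read_caller_output(str(p), "native_bed", sample_id="s1")
        assert [(c.junction, c.read_count) for c in back] == [
            (c.junction, c.read_count) for c in calls
        ]

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t5\t500\tc\t3\t+\tx\nchr1\tnotanint\t9\tc\t1\t+\tx\n")
        with pytest.raises(ValueError, match="line 2"):
            bsj.read_caller_output(str(p), "native_bed")

    def test_unknown_dialect(self, tmp_path):
        p = tmp_path / "f"
        p.write_text("")
        with pytest.raises(ValueError, match="dialect"):
            bsj.read_caller_output(str(p), "starchip")
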