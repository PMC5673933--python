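"""Count matrix, Venn overlaps, dispersion estimation and the NB exact test."""
from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from circfield import diffexp, synthio
from circfield.diffexp import (
    CountMatrix,
    adjust_fdr,
    build_matrix,
    estimate_dispersion,
    group_overlaps,
    nb_exact_test,
    top_expressed,
)
from circfield.models import BackspliceJunction, JunctionCall


def call(start, end, sample, count, chrom="chr1", strand="+"):
    return JunctionCall(BackspliceJunction(chrom, start, end, strand), sample, "x", count)


def matrix_from(counts: np.ndarray, groups: list[str]) -> CountMatrix:
    cols = [f"{g}_s{i}" for i, g in enumerate(groups)]
    df = pd.DataFrame(counts, index=[f"c{i}" for i in range(len(counts))], columns=cols)
    return CountMatrix(counts=df, group=pd.Series(groups, index=cols))


def simulate(n_circ, mean_a, mean_b, phi, n_a=8, n_b=16, seed=0):
    """NB counts for an A-side vs pooled B-side design."""
    rng = np.random.default_rng(seed)
    groups = ["no_cancer"] * n_a + ["adjacent"] * (n_b // 2) + ["tumor"] * (n_b - n_b // 2)
    means = np.concatenate([np.full(n_a, 1.0), np.full(n_b, 1.0)])
    rows = []
    for i in range(n_circ):
        mu = np.concatenate([np.full(n_a, mean_a[i]), np.full(n_b, mean_b[i])])
        if phi > 0:
            r = 1 / phi
            rows.append(rng.negative_binomial(r, r / (r + mu)))
        else:
            rows.append(rng.poisson(mu))
    return matrix_from(np.array(rows), groups)


class TestBuildMatrix:
    def test_single_entry(self):
        m = build_matrix({"s1": [call(0, 100, "s1", 6)]}, {"s1": "tumor"})
        assert m.counts.values.tolist() == [[6]]

    def test_absent_junction_zero(self):
        m = build_matrix(
            {"a": [call(0, 100, "a", 4)], "b": []}, {"a": "tumor", "b": "adjacent"}
        )
        assert m.counts.loc[:, "b"].tolist() == [0]

    def test_min_reads_filter(self):
        m = build_matrix(
            {"a": [call(0, 100, "a", 3), call(200, 300, "a", 7)]},
            {"a": "tumor"},
            min_reads=5,
        )
        assert len(m.counts) == 1

    def test_duplicate_sample_ids(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_matrix([("a", []), ("a", [])], {"a": "tumor"})


class TestTopExpressed:
    def test_ranking(self):
        m = matrix_from(np.array([[41], [37], [3]]), ["tumor"])
        top = top_expressed(m, "tumor", 2)
        assert top["circ_id"].tolist() == ["c0", "c1"]

    def test_tie_break_lexicographic(self):
        m = matrix_from(np.array([[5], [5], [5]]), ["tumor"])
        assert top_expressed(m, "tumor", 3)["circ_id"].tolist() == ["c0", "c1", "c2"]

    def test_default_depth_is_seven(self):
        m = matrix_from(np.arange(20).reshape(10, 2), ["tumor", "tumor"])
        assert len(top_expressed(m, "tumor")) == 7

    def test_invalid_n(self):
        m = matrix_from(np.array([[1]]), ["tumor"])
        with pytest.raises(ValueError):
            top_expressed(m, "tumor", 0)


class TestGroupOverlaps:
    def test_identical_presence(self):
        m = matrix_from(np.ones((27, 3), dtype=int), ["no_cancer", "adjacent", "tumor"])
        venn = group_overlaps(m)
        assert venn["no_cancer&adjacent&tumor"] == 27
        assert sum(v for k, v in venn.items() if k != "no_cancer&adjacent&tumor") == 0

    def test_disjoint_presence(self):
        counts = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1]])
        m = matrix_from(counts, ["no_cancer", "adjacent", "tumor"])
        venn = group_overlaps(m)
        assert venn["no_cancer"] == venn["adjacent"] == venn["tumor"] == 1
        assert venn["no_cancer&adjacent&tumor"] == 0

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 2, size=(40, 6))
        groups = ["no_cancer", "no_cancer", "adjacent", "adjacent", "tumor", "tumor"]
        m = matrix_from(counts, groups)
        venn = group_overlaps(m)
        # oracle: enumerate every feature's membership pattern directly
        sets = {g: set() for g in ("no_cancer", "adjacent", "tumor")}
        for i, row in enumerate(counts):
            if row[0] + row[1] >= 1:
                sets["no_cancer"].add(i)
            if row[2] + row[3] >= 1:
                sets["adjacent"].add(i)
            if row[4] + row[5] >= 1:
                sets["tumor"].add(i)
        total = 0
        for r in range(1, 4):
            for combo in itertools.combinations(("no_cancer", "adjacent", "tumor"), r):
                inside = set.intersection(*(sets[g] for g in combo))
                outside = set.union(*(sets[g] for g in sets if g not in combo), set())
                total += len(inside - outside)
                assert venn["&".join(combo)] == len(inside - outside)
        assert total == len(set.union(*sets.values()))


class TestDispersion:
    def test_poisson_counts_near_zero(self):
        means = np.full(200, 50.0)
        m = simulate(200, means, means, phi=0.0, seed=1)
        assert 0 <= estimate_dispersion(m).common < 0.05

    def test_nb_point_two_recovered(self):
        means = np.full(200, 50.0)
        m = simulate(200, means, means, phi=0.2, seed=2)
        assert estimate_dispersion(m).common == pytest.approx(0.2, abs=0.05)

    def test_constant_counts_floor_zero(self):
        m = matrix_from(np.full((5, 6), 7), ["tumor"] * 3 + ["adjacent"] * 3)
        est = estimate_dispersion(m)
        assert est.common == 0.0
        assert (est.tagwise == 0.0).all()

    def test_all_zero_matrix_rejected(self):
        m = matrix_from(np.zeros((3, 4), dtype=int), ["tumor"] * 2 + ["adjacent"] * 2)
        with pytest.raises(ValueError, match="no expressed"):
            estimate_dispersion(m)

    def test_full_shrinkage_collapses_to_common(self):
        means = np.full(50, 30.0)
        m = simulate(50, means, means, phi=0.2, seed=3)
        est = estimate_dispersion(m, prior_df=1e12)
        assert np.allclose(est.tagwise, est.common)


class TestExactTest:
    def test_identical_sides_p_one(self):
        counts = np.tile([5, 5, 5, 5, 5, 5], (3, 1))
        m = matrix_from(counts, ["no_cancer"] * 3 + ["adjacent", "adjacent", "tumor"])
        disp = estimate_dispersion(m)
        res = nb_exact_test(m, disp)
        assert (res["p_value"] == 1.0).all()

    def test_poisson_one_vs_one_binomial_tail(self):
        # 0 vs 10 with phi=0: conditional Binomial(10, 1/2), two-sided
        assert diffexp._split_pvalue(0, 10, 1, 1, 0.0) == pytest.approx(2 / 1024)

    def test_side_swap_symmetry(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            t = int(rng.integers(1, 200))
            y = int(rng.integers(0, t + 1))
            p1 = diffexp._split_pvalue(y, t, 8, 16, 0.2)
            p2 = diffexp._split_pvalue(t - y, t, 16, 8, 0.2)
            assert p1 == pytest.approx(p2, rel=1e-9)

    def test_zero_total_p_one(self):
        assert diffexp._split_pvalue(0, 0, 8, 16, 0.2) == 1.0

    def test_large_total_normal_approx_continuity(self):
        # approximation agrees with the exact computation near the crossover
        t = diffexp.NORMAL_APPROX_TOTAL
        ys = [t // 3, t // 2]
        for y in ys:
            exact = diffexp._split_pvalue(y, t, 8, 16, 0.2)
            approx = diffexp._split_pvalue(y, t + 1, 8, 16, 0.2)
            assert approx == pytest.approx(exact, abs=0.05)

    def test_planted_fold_changes_detected_with_sign(self):
        n_de = 40
        mean_a = np.full(160, 50.0)
        mean_b = np.concatenate([np.full(n_de, 200.0), np.full(120, 50.0)])
        m = simulate(160, mean_a, mean_b, phi=0.2, seed=5)
        res = nb_exact_test(m, estimate_dispersion(m)).set_index("circ_id")
        de = res.loc[[f"c{i}" for i in range(n_de)]]
        hits = (de["fdr"] < 0.05) & (de["log2_fc"] > 0)
        assert hits.mean() >= 0.8

    def test_empty_side_rejected(self):
        m = matrix_from(np.ones((2, 4), dtype=int), ["adjacent"] * 2 + ["tumor"] * 2)
        with pytest.raises(ValueError, match="non-empty"):
            nb_exact_test(m, estimate_dispersion(m))


class TestFdr:
    def test_hand_evaluated_step_up(self):
        assert adjust_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p(self):
        assert adjust_fdr([0.04]) == pytest.approx([0.04])

    def test_all_ones(self):
        assert adjust_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_monotone_in_p_ranks(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=100)
        fdr = adjust_fdr(p)
        order = np.argsort(p)
        assert (np.diff(fdr[order]) >= -1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.2])


class TestSimulateCounts:
    def test_null_profile_poisson_shape(self, gene_models):
        truth = synthio.generate_truth(gene_models, 10, group_profile="null", rng_seed=1)
        m = synthio.simulate_counts(truth, samples_per_group=4, rng_seed=1)
        assert m.counts.shape == (10, 12)
        assert set(m.group) == {"no_cancer", "adjacent", "tumor"}

    def test_determinism(self, gene_models):
        truth = synthio.generate_truth(gene_models, 10, rng_seed=2)
        a = synthio.simulate_counts(truth, 4, rng_seed=9)
        b = synthio.simulate_counts(truth, 4, rng_seed=9)
        assert a.counts.equals(b.counts)
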