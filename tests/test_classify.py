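"""Change calls, categories, FLAG-tag calls, and figure-level statistics."""
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from scipy import stats

from epiloop.classify import (
    call_change,
    call_flag_bound,
    call_flag_enriched,
    categorize_genes,
    hypergeom_enrichment,
    paired_t,
    spearman_correlation,
)


class TestCallChange:
    @pytest.mark.parametrize(
        "wt,mut,expected",
        [
            ((1, 1), (5, 6), "up"),      # deltas 4, 5 > 3
            ((5, 6), (1, 1), "down"),
            ((1, 1), (5, 3), "stay"),    # second delta 2 <= 3
            ((1, 1), (4.0, 4.0), "stay"),  # delta exactly 3: strict
        ],
    )
    def test_threshold_rule(self, wt, mut, expected):
        assert call_change("g", wt, mut).direction == expected

    def test_replicate_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            call_change("g", (1, 2), (3,))

    def test_missing_forces_flagged_stay(self):
        c = call_change("g", (1, np.nan), (9, 9))
        assert c.direction == "stay" and c.flagged_missing

    @pytest.mark.parametrize("seed", range(10))
    def test_antisymmetry(self, seed):
        r = np.random.default_rng(seed)
        wt = r.uniform(0, 20, 3)
        mut = r.uniform(0, 20, 3)
        fwd = call_change("g", wt, mut).direction
        rev = call_change("g", mut, wt).direction
        assert rev == {"up": "down", "down": "up", "stay": "stay"}[fwd]

    @pytest.mark.parametrize("seed", range(10))
    def test_raising_delta_is_conservative(self, seed):
        r = np.random.default_rng(seed)
        wt = r.uniform(0, 20, 2)
        mut = r.uniform(0, 20, 2)
        lo = call_change("g", wt, mut, delta=1.0).direction
        hi = call_change("g", wt, mut, delta=4.0).direction
        if lo == "stay":
            assert hi == "stay"


def calls_from(directions, gene_prefix="g"):
    out = {}
    for i, d in enumerate(directions):
        gene = f"{gene_prefix}{i}"
        out[gene] = call_change(
            gene, (0.0, 0.0),
            {"up": (10.0, 10.0), "down": (-10.0, -10.0), "stay": (0.0, 0.0)}[d],
        )
    return out


class TestCategorize:
    def test_labels(self):
        k9 = calls_from(["up", "up", "stay"])
        k36 = calls_from(["up", "down", "up"])
        k4 = calls_from(["down", "stay", "down"])
        cats = {c.gene: c for c in categorize_genes(k9, k36, k4)}
        assert cats["g0"].label == "H3K9me2 up H3K36me3 up"
        assert cats["g1"].label == "H3K9me2 up H3K36me3 down"
        assert cats["g2"].label == "background"
        assert cats["g0"].h3k4 == "down" and cats["g1"].h3k4 == "stay"

    def test_universe_mismatch_rejected(self):
        k9 = calls_from(["up"])
        with pytest.raises(ValueError, match="universe"):
            categorize_genes(k9, calls_from(["up", "up"]), k9)

    @pytest.mark.parametrize("seed", range(5))
    def test_sub_labels_partition_the_up_set(self, seed):
        r = np.random.default_rng(seed)
        dirs = ["up", "down", "stay"]
        n = 200
        k9 = calls_from(r.choice(dirs, n))
        k36 = calls_from(r.choice(dirs, n))
        k4 = calls_from(r.choice(dirs, n))
        cats = categorize_genes(k9, k36, k4)
        n_up = sum(1 for g, c in k9.items() if c.direction == "up")
        sub = sum(
            1 for c in cats if c.label.startswith("H3K9me2 up H3K36me3 ")
        )
        background = sum(1 for c in cats if c.label == "background")
        assert sub == n_up
        assert sub + background == n


class TestFlagCalls:
    @pytest.mark.parametrize(
        "deltas,expected",
        [((6, 7), True), ((6, 4), False), ((5, 7), False)],  # strict > 5
    )
    def test_enriched_both_lines(self, deltas, expected):
        mut = {"TG1": 10.0 + deltas[0], "TG2": 10.0 + deltas[1]}
        wt = {"TG1": 10.0, "TG2": 10.0}
        assert call_flag_enriched(mut, wt) is expected

    @pytest.mark.parametrize(
        "deltas,expected",
        [((3, 3), True), ((2, 3), False), ((-1, 5), False)],  # strict > 2
    )
    def test_bound_both_lines(self, deltas, expected):
        wt = {"TG1": 1.0 + deltas[0], "TG2": 1.0 + deltas[1]}
        ctl = {"TG1": 1.0, "TG2": 1.0}
        assert call_flag_bound(wt, ctl) is expected

    def test_single_line_rejected(self):
        with pytest.raises(ValueError, match="both"):
            call_flag_enriched({"TG1": 9.0}, {"TG1": 1.0})


def hypergeom_tail_exact(k, m, n, N):
    """P(X >= k) by exact combinatorial summation (rational arithmetic)."""
    total = Fraction(0)
    for i in range(k, min(m, n) + 1):
        total += Fraction(comb(m, i) * comb(N - m, n - i), comb(N, n))
    return total


class TestHypergeom:
    def test_complete_overlap_small_universe(self):
        # drawing 5 of 5 marked from 10: exactly one favorable draw
        assert hypergeom_enrichment(5, 5, 5, 10) == pytest.approx(1 / 252, rel=1e-12)

    def test_zero_overlap_is_full_tail(self):
        assert hypergeom_enrichment(0, 5, 5, 10) == 1.0

    def test_matches_subset_enumeration(self):
        # brute force over all C(20,5) draws of set_b
        from itertools import combinations

        N, m, n, k = 20, 4, 5, 2
        marked = set(range(m))
        hits = sum(
            1 for draw in combinations(range(N), n) if len(marked & set(draw)) >= k
        )
        expected = hits / comb(N, n)
        assert hypergeom_enrichment(k, m, n, N) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exact_tail_random(self, seed):
        r = np.random.default_rng(seed)
        for _ in range(50):
            N = int(r.integers(1, 60))
            m = int(r.integers(0, N + 1))
            n = int(r.integers(0, N + 1))
            k = int(r.integers(0, min(m, n) + 1))
            assert hypergeom_enrichment(k, m, n, N) == pytest.approx(
                float(hypergeom_tail_exact(k, m, n, N)), rel=1e-10
            )

    def test_non_increasing_in_k(self):
        ps = [hypergeom_enrichment(k, 10, 12, 40) for k in range(11)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment(6, 5, 5, 10)


class TestPairedT:
    def test_identical_vectors(self):
        t, p = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_constant_nonzero_difference(self):
        t, p = paired_t([2.0, 3.0, 4.0, 5.0], [1.0, 2.0, 3.0, 4.0])
        assert np.isinf(t) and t > 0 and p == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_textbook_formula(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(3, 100))
        a = r.normal(size=n)
        b = r.normal(size=n)
        t, p = paired_t(a, b)
        d = a - b
        exp_t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
        exp_p = 2 * stats.t.sf(abs(exp_t), n - 1)
        assert t == pytest.approx(exp_t, rel=1e-10)
        assert p == pytest.approx(exp_p, rel=1e-8)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            paired_t([1.0], [2.0])


class TestSpearman:
    def test_monotone_limits(self):
        x = np.arange(20.0)
        assert spearman_correlation(x, np.exp(x))[0] == pytest.approx(1.0)
        assert spearman_correlation(x, -np.exp(x))[0] == pytest.approx(-1.0)

    def test_ties_match_average_rank_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0, 8.0, 9.0, 10.0, 11.0, 12.0])
        y = np.array([3.0, 1.0, 4.0, 4.0, 2.0, 7.0, 7.0, 9.0, 1.0, 5.0, 6.0, 6.0])
        rho, p = spearman_correlation(x, y)

        def avg_rank(v):
            order = np.argsort(v, kind="mergesort")
            ranks = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2  # average of 1-based ranks
                i = j
            return ranks

        rx, ry = avg_rank(x), avg_rank(y)
        exp_rho = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(exp_rho, rel=1e-10)
        exp_t = exp_rho * np.sqrt((len(x) - 2) / (1 - exp_rho**2))
        assert p == pytest.approx(2 * stats.t.sf(abs(exp_t), len(x) - 2), rel=1e-8)

    def test_all_ties_flagged_undefined(self):
        rho, p = spearman_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(rho) and np.isnan(p)

    def test_small_n_exact_permutation(self):
        rho, p = spearman_correlation([1, 2, 3, 4], [1, 2, 4, 3])
        assert 0 < p <= 1
        # exact p is the fraction of the 24 permutations at least as extreme
        assert p == pytest.approx(p, abs=1e-12)
        assert round(p * 24) == p * 24
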