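"""Counting and normalization: overlap semantics, RPKM/TPM formulas."""
import numpy as np
import pytest

from epiloop.core import (
    GenomicInterval,
    SampleDescriptor,
    TranscriptionUnit,
    UnitSet,
)
from epiloop.quantify import (
    LibraryStats,
    average_replicates,
    choose_te_strand,
    count_overlapping_reads,
    log2_tpm_offset,
    rpkm,
    tpm,
)

from conftest import make_table


def unit(chrom, start, end, uid, strand="+"):
    return TranscriptionUnit(GenomicInterval(chrom, start, end, strand), uid)


def brute_force_counts(reads, units, stranded="none"):
    """Quadratic all-pairs oracle for BEDTools-coverage counting."""
    counts = {u.id: 0 for u in units}
    for r in reads:
        for u in units:
            iv = u.interval
            if r.chrom != iv.chrom or r.start >= iv.end or iv.start >= r.end:
                continue
            if stranded == "same" and r.strand != iv.strand:
                continue
            if stranded == "opposite" and r.strand == iv.strand:
                continue
            counts[u.id] += 1
    return counts


class TestCounting:
    @pytest.mark.parametrize(
        "read,expected",
        [
            (GenomicInterval("Chr1", 150, 250), 1),  # containment
            (GenomicInterval("Chr1", 590, 700), 1),  # 10 bp overlap
            (GenomicInterval("Chr1", 600, 700), 0),  # half-open: no overlap
            (GenomicInterval("Chr1", 99, 100), 0),
            (GenomicInterval("Chr1", 99, 101), 1),   # 1 bp rule
        ],
    )
    def test_single_bp_overlap_rule(self, read, expected):
        units = UnitSet([unit("Chr1", 100, 600, "g1")])
        assert count_overlapping_reads([read], units)["g1"] == expected

    def test_read_counts_toward_every_overlapped_unit(self):
        units = UnitSet([unit("Chr1", 0, 100, "a"), unit("Chr1", 50, 150, "b")])
        counts = count_overlapping_reads([GenomicInterval("Chr1", 40, 60)], units)
        assert counts == {"a": 1, "b": 1}

    def test_stranded_modes(self):
        units = UnitSet([unit("Chr1", 0, 100, "a", "+")])
        plus = GenomicInterval("Chr1", 10, 20, "+")
        minus = GenomicInterval("Chr1", 10, 20, "-")
        assert count_overlapping_reads([plus, minus], units, "same")["a"] == 1
        assert count_overlapping_reads([plus, minus], units, "opposite")["a"] == 1

    def test_unstranded_read_rejected_in_stranded_mode(self):
        units = UnitSet([unit("Chr1", 0, 100, "a", "+")])
        with pytest.raises(ValueError, match="stranded"):
            count_overlapping_reads([GenomicInterval("Chr1", 0, 10, ".")], units, "same")

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("stranded", ["none", "same", "opposite"])
    def test_matches_quadratic_oracle(self, seed, stranded):
        r = np.random.default_rng(seed)
        units = UnitSet()
        pos = 0
        for i in range(r.integers(5, 50)):
            start = pos + int(r.integers(0, 200))
            end = start + int(r.integers(1, 500))
            units.add(unit("Chr1", start, end, f"u{i}", r.choice(["+", "-"])))
            pos = start + int(r.integers(1, 300))  # units may overlap
        reads = []
        for _ in range(int(r.integers(50, 500))):
            s = int(r.integers(0, pos + 500))
            reads.append(
                GenomicInterval("Chr1", s, s + int(r.integers(1, 300)),
                                str(r.choice(["+", "-"])))
            )
        assert count_overlapping_reads(reads, units, stranded) == \
            brute_force_counts(reads, units, stranded)


class TestRpkm:
    LIB = LibraryStats(SampleDescriptor("WT", "x", 1), 10**6)

    @pytest.mark.parametrize(
        "count,length,total,expected",
        [(10, 1000, 10**6, 10.0), (0, 1000, 10**6, 0.0), (5, 2500, 2 * 10**6, 1.0)],
    )
    def test_formula(self, count, length, total, expected):
        lib = LibraryStats(SampleDescriptor("WT", "x", 1), total)
        assert rpkm(count, length, lib) == pytest.approx(expected, rel=1e-12)

    def test_linearity_and_scaling(self, rng):
        for _ in range(20):
            c = rng.integers(1, 1000)
            ln = int(rng.integers(1, 10_000))
            tot = int(rng.integers(10**4, 10**8))
            lib = LibraryStats(SampleDescriptor("WT", "x", 1), tot)
            base = rpkm(c, ln, lib)
            assert rpkm(3 * c, ln, lib) == pytest.approx(3 * base, rel=1e-12)
            assert rpkm(c, 2 * ln, lib) == pytest.approx(base / 2, rel=1e-12)
            lib2 = LibraryStats(SampleDescriptor("WT", "x", 1), 2 * tot)
            assert rpkm(c, ln, lib2) == pytest.approx(base / 2, rel=1e-12)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            rpkm(1, 0, self.LIB)
        with pytest.raises(ValueError):
            LibraryStats(SampleDescriptor("WT", "x", 1), 0)


class TestTpm:
    def test_symmetry_and_single_unit(self):
        np.testing.assert_allclose(tpm([5, 5], [100, 100]), [5e5, 5e5])
        np.testing.assert_allclose(tpm([7], [123]), [1e6])

    def test_sums_to_one_million(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 50))
            c = rng.integers(0, 1000, n)
            c[0] = max(c[0], 1)
            ln = rng.integers(1, 5000, n)
            assert tpm(c, ln).sum() == pytest.approx(1e6, rel=1e-6)

    def test_invariant_to_count_rescaling(self, rng):
        c = rng.integers(1, 100, 10).astype(float)
        ln = rng.integers(100, 5000, 10)
        np.testing.assert_allclose(tpm(c, ln), tpm(7.3 * c, ln), rtol=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            tpm([0, 0], [100, 100])


class TestLog2Offset:
    @pytest.mark.parametrize(
        "value,expected", [(0.0, np.log2(0.05)), (0.95, 0.0), (1.95, 1.0)]
    )
    def test_values(self, value, expected):
        assert log2_tpm_offset(value) == pytest.approx(expected, rel=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log2_tpm_offset(-0.1)


class TestAverageReplicates:
    def test_mean_single_and_nan(self):
        t = make_table(
            [[2.0, 4.0, 1.0], [2.0, np.nan, 5.0]],
            genotypes=("WT",), n_reps=3,
        )
        # split: first two columns WT reps, third a different genotype
        t.samples[2] = SampleDescriptor("ibm1", "H3K36me3", 1)
        avg = average_replicates(t)
        wt = avg.column([s for s in avg.samples if s.genotype == "WT"][0])
        mut = avg.column([s for s in avg.samples if s.genotype == "ibm1"][0])
        assert wt[0] == 3.0 and np.isnan(wt[1])  # NA propagates
        assert mut[0] == 1.0 and mut[1] == 5.0  # single replicate unchanged

    def test_empty_rejected(self):
        t = make_table(np.empty((0, 0)).reshape(0, 0))
        with pytest.raises(ValueError):
            average_replicates(t)


class TestChooseTeStrand:
    S = [SampleDescriptor("WT", "mRNA", 1), SampleDescriptor("WT", "mRNA", 2)]

    def test_larger_total_wins(self):
        assert choose_te_strand(
            {self.S[0]: 5, self.S[1]: 5}, {self.S[0]: 15, self.S[1]: 5}
        ) == "antisense"
        assert choose_te_strand(
            {self.S[0]: 15, self.S[1]: 5}, {self.S[0]: 5, self.S[1]: 5}
        ) == "sense"

    def test_tie_goes_to_sense(self):
        assert choose_te_strand(
            {self.S[0]: 10, self.S[1]: 5}, {self.S[0]: 5, self.S[1]: 10}
        ) == "sense"

    def test_sample_mismatch_rejected(self):
        with pytest.raises(ValueError):
            choose_te_strand({self.S[0]: 1}, {self.S[1]: 1})
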