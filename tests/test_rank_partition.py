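import itertools
import math

import numpy as np
import pytest
from skbio import DistanceMatrix

from barcodegap import (
    BarcodeError,
    RankCategory,
    boxplot_stats,
    classify_pair,
    mann_whitney_u,
    overlap_report,
    partition_distances,
    summarize_rank,
)
from conftest import make_record


class TestClassifyPair:
    def test_same_species_is_S(self):
        a = make_record("1", "ACGT", species="Terapon jarbua")
        b = make_record("2", "ACGT", species="Terapon jarbua")
        assert classify_pair(a, b) is RankCategory.S

    def test_congeners_are_G(self):
        a = make_record("1", "ACGT", species="Pampus argenteus")
        b = make_record("2", "ACGT", species="Pampus cinereus")
        assert classify_pair(a, b) is RankCategory.G

    def test_confamilial_across_genera_is_F(self):
        a = make_record("1", "ACGT", species="Pampus argenteus", family="Stromateidae")
        b = make_record("2", "ACGT", species="Peprilus paru", family="Stromateidae")
        assert classify_pair(a, b) is RankCategory.F

    def test_different_classes_raise(self):
        a = make_record("1", "ACGT", class_name="Actinopteri")
        b = make_record("2", "ACGT", species="Other sp", family="FamB",
                        order="OrderB", class_name="Chondrichthyes")
        with pytest.raises(BarcodeError):
            classify_pair(a, b)


class TestPartition:
    def _records(self):
        recs = []
        for sp, n in (("G a", 3), ("G b", 2), ("G c", 1)):
            for k in range(n):
                recs.append(make_record(f"{sp.replace(' ', '')}{k}", "ACGT", species=sp))
        return recs

    def test_counting_example_three_species_one_genus(self):
        records = self._records()
        n = len(records)
        m = DistanceMatrix(np.ones((n, n)) - np.eye(n),
                           ids=[r.record_id for r in records])
        part = partition_distances(m, records)
        assert len(part[RankCategory.S]) == 4   # C(3,2) + C(2,2)
        assert len(part[RankCategory.G]) == 11  # remainder of C(6,2)

    def test_partition_is_complete_and_disjoint(self, small_dataset):
        records, _, matrix, _ = small_dataset
        part = partition_distances(matrix, records)
        n = len(records)
        sizes = {cat: len(entries) for cat, entries in part.items()}
        assert sum(sizes.values()) == n * (n - 1) // 2
        seen = [frozenset(p) for entries in part.values() for p, _ in entries]
        assert len(seen) == len(set(seen))

    def test_all_conspecific_means_only_S(self):
        records = [make_record(f"r{i}", "ACGT") for i in range(4)]
        m = DistanceMatrix(np.zeros((4, 4)), ids=[r.record_id for r in records])
        part = partition_distances(m, records)
        assert len(part[RankCategory.S]) == 6
        assert all(not part[c] for c in RankCategory if c is not RankCategory.S)


class TestSummarizeRank:
    def test_basic_moments(self):
        records = [make_record(f"r{i}", "ACGT") for i in range(3)]
        entries = [(("r0", "r1"), 0.0), (("r0", "r2"), 1.0), (("r1", "r2"), 2.0)]
        s = summarize_rank(RankCategory.S, entries, records)
        assert (s.mean, s.median, s.minimum, s.maximum) == (1.0, 1.0, 0.0, 2.0)
        assert s.taxa == 1 and s.comparisons == 3
        assert s.se == pytest.approx(1.0 / math.sqrt(3))

    def test_single_entry_uses_se_zero_convention(self):
        records = [make_record("a", "ACGT"), make_record("b", "ACGT")]
        s = summarize_rank(RankCategory.S, [(("a", "b"), 0.154)], records)
        assert s.mean == s.median == s.minimum == s.maximum == 0.154
        assert s.se == 0.0

    def test_agrees_with_naive_recomputation(self, small_dataset):
        records, _, matrix, _ = small_dataset
        part = partition_distances(matrix, records)
        for cat, entries in part.items():
            if not entries:
                continue
            s = summarize_rank(cat, entries, records)
            values = sorted(d for _, d in entries)
            assert s.mean == pytest.approx(sum(values) / len(values), abs=1e-12)
            mid = len(values) // 2
            naive_median = (values[mid] if len(values) % 2
                            else 0.5 * (values[mid - 1] + values[mid]))
            assert s.median == pytest.approx(naive_median, abs=1e-12)


class TestBoxplotStats:
    def test_extreme_outlier_example(self):
        b = boxplot_stats([1, 2, 3, 4, 100])
        assert (b.median, b.q1, b.q3, b.iqr) == (3, 2, 4, 2)
        assert b.extreme_outliers == (100,)
        assert b.mild_outliers == ()
        assert (b.lower_whisker, b.upper_whisker) == (1, 4)

    def test_mild_outlier_example(self):
        b = boxplot_stats([1, 2, 3, 4, 8])
        assert b.mild_outliers == (8,)
        assert b.extreme_outliers == ()

    def test_degenerate_all_equal(self):
        b = boxplot_stats([1, 1, 1, 1, 1])
        assert b.iqr == 0
        assert b.mild_outliers == () and b.extreme_outliers == ()

    def test_too_few_values_raise(self):
        with pytest.raises(BarcodeError):
            boxplot_stats([1, 2, 3, 4])

    def test_hinges_are_tukey_convention(self):
        # n=7: hinge depth (4+1)/2 = 2.5, halves include the median
        b = boxplot_stats([1, 2, 3, 4, 5, 6, 7])
        assert (b.q1, b.median, b.q3) == (2.5, 4.0, 5.5)


class TestMannWhitney:
    def test_exact_tiny_example(self):
        U, _, p = mann_whitney_u([1, 2], [3, 4])
        assert U == 0.0
        assert p == pytest.approx(1 / 3)

    def test_identical_samples_sit_at_the_null_center(self):
        U, z, p = mann_whitney_u([1.0, 2.0, 3.0] * 4, [1.0, 2.0, 3.0] * 4)
        assert U == pytest.approx(len([1, 2, 3] * 4) ** 2 / 2)
        assert z == 0.0
        assert p == pytest.approx(1.0)

    def test_normal_approximation_close_to_exact_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            a = rng.normal(0, 1, 8)
            b = rng.normal(0.5, 1, 8)
            _, _, p_exact = mann_whitney_u(a, b)  # n<=8, no ties -> exact
            p_enum = exact_two_sided_p(a, b)
            assert p_exact == pytest.approx(p_enum, abs=1e-12)
            p_normal = normal_p(a, b)
            assert abs(p_normal - p_enum) <= 0.02

    def test_empty_sample_raises(self):
        with pytest.raises(BarcodeError):
            mann_whitney_u([], [1.0])


def exact_two_sided_p(a, b) -> float:
    """Enumerate all C(nA+nB, nA) label assignments (no ties assumed)."""
    pooled = list(a) + list(b)
    nA = len(a)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    def u_of(idx):
        return sum(ranks[pooled[i]] for i in idx) - nA * (nA + 1) / 2
    observed = u_of(range(nA))
    us = [u_of(c) for c in itertools.combinations(range(len(pooled)), nA)]
    lo = sum(u <= observed for u in us) / len(us)
    hi = sum(u >= observed for u in us) / len(us)
    return min(1.0, 2 * min(lo, hi))


def normal_p(a, b) -> float:
    from scipy import stats

    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method="asymptotic").pvalue)


class TestOverlapReport:
    def test_disjoint_categories_have_a_gap(self):
        s = [(("a", "b"), 0.1), (("a", "c"), 0.5)]
        g = [(("a", "d"), 10.2), (("b", "d"), 15.0)]
        r = overlap_report(s, g)
        assert not r.overlaps
        assert r.gap == pytest.approx(10.2 - 0.5)
        assert r.overlapping_pairs == ()

    def test_low_congeneric_entry_is_reported(self):
        s = [(("a", "b"), 0.1), (("a", "c"), 2.0)]
        g = [(("p1", "p2"), 0.154), (("b", "d"), 15.0)]
        r = overlap_report(s, g)
        assert r.overlaps
        assert (("p1", "p2"), 0.154) in r.overlapping_pairs

    def test_identical_lists_fully_overlap(self):
        entries = [(("a", "b"), 1.0), (("c", "d"), 2.0)]
        r = overlap_report(entries, entries)
        assert r.overlaps
        assert len(r.overlapping_pairs) == 4
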