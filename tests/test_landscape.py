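import itertools
import math

import numpy as np
import pytest
from scipy.stats import hypergeom

from rnasomatic.io_core import FunctionalClass
from rnasomatic.landscape import (
    association_test,
    build_matrix,
    class_tally,
    druggable_fraction,
    gene_ranking,
    hotspot_table,
    mean_nonsynonymous_per_tumor,
    round_half_up,
    substitution_spectrum,
    variant_type_tally,
    waterfall_sample_order,
)

from .conftest import make_variant


class TestSpectrum:
    def test_complement_collapsing(self):
        snvs = [make_variant(pos=i + 1, ref="G", alt="A") for i in range(10)]
        spec = substitution_spectrum(snvs)
        assert spec["C>T"] == 1.0
        assert sum(spec.values()) == pytest.approx(1.0)

    def test_uniform_twelve_changes(self):
        snvs = []
        pos = 1
        for ref, alt in itertools.permutations("ACGT", 2):
            for _ in range(50):
                snvs.append(make_variant(pos=pos, ref=ref, alt=alt))
                pos += 1
        spec = substitution_spectrum(snvs)
        for t, p in spec.items():
            assert p == pytest.approx(1 / 6)

    def test_sums_to_one(self, rng):
        snvs = []
        for i in range(500):
            ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
            snvs.append(make_variant(pos=i + 1, ref=str(ref), alt=str(alt)))
        assert sum(substitution_spectrum(snvs).values()) == pytest.approx(1.0, abs=1e-12)

    def test_strand_complement_invariance(self, rng):
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        snvs = []
        for i in range(200):
            ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
            snvs.append(make_variant(pos=i + 1, ref=str(ref), alt=str(alt)))
        flipped = [make_variant(pos=r.pos, ref=comp[r.ref], alt=comp[r.alt]) for r in snvs]
        assert substitution_spectrum(snvs) == substitution_spectrum(flipped)

    def test_non_snv_rejected(self):
        with pytest.raises(ValueError):
            substitution_spectrum([make_variant(ref="AT", alt="A")])

    def test_empty_input_all_zero(self):
        assert set(substitution_spectrum([]).values()) == {0.0}


class TestTallies:
    def test_class_tally_partitions(self, rng):
        classes = list(FunctionalClass)
        records = [
            make_variant(pos=i + 1, functional_class=classes[int(rng.integers(len(classes)))])
            for i in range(100)
        ]
        tally = class_tally(records)
        assert sum(tally.values()) == 100

    def test_printed_snv_class_counts_sum(self):
        # regression on the published cohort tallies: the six SNV classes must
        # sum to the SNV total
        counts = {"missense": 50270, "nonsense": 2311, "splicing": 1042,
                  "utr": 68819, "synonymous": 17057, "other": 1596}
        assert sum(counts.values()) == 141095

    def test_variant_type_tally(self):
        records = (
            [make_variant(pos=i + 1) for i in range(5)]
            + [make_variant(pos=100 + i, ref="A", alt="AT") for i in range(3)]
            + [make_variant(pos=200 + i, ref="AT", alt="A") for i in range(2)]
        )
        tally = variant_type_tally(records)
        assert tally == {"snv": 5, "insertion": 3, "deletion": 2, "total": 10}

    def test_mean_nonsynonymous_per_tumor(self):
        assert mean_nonsynonymous_per_tumor(144593, 17057, 3217) == 40


class TestMatrix:
    def test_single_hit(self):
        recs = [make_variant(gene="PIK3CA", functional_class=FunctionalClass.MISSENSE)]
        m = build_matrix(recs, ["S1"])
        assert m.cells.loc["PIK3CA", "S1"] == "missense"
        ranking = gene_ranking(m)
        assert ranking.iloc[0].pct_samples == 100.0

    def test_severity_precedence(self):
        recs = [
            make_variant(pos=10, gene="PIK3CA", functional_class=FunctionalClass.MISSENSE),
            make_variant(pos=20, gene="PIK3CA", functional_class=FunctionalClass.NONSENSE),
        ]
        m = build_matrix(recs, ["S1"])
        assert m.cells.loc["PIK3CA", "S1"] == "nonsense"

    def test_gene_pct_matches_hand_count(self, rng):
        samples = [f"S{i}" for i in range(20)]
        recs = []
        hand = {}
        for g in ("A", "B", "C"):
            mutated = rng.choice(samples, size=int(rng.integers(1, 15)), replace=False)
            hand[g] = len(mutated)
            for s in mutated:
                recs.append(make_variant(sample=str(s), gene=g,
                                         functional_class=FunctionalClass.MISSENSE))
        m = build_matrix(recs, samples)
        ranking = gene_ranking(m).set_index("gene")
        for g, n in hand.items():
            assert ranking.loc[g, "n_samples"] == n
            assert ranking.loc[g, "pct_samples"] == round_half_up(100 * n / 20, 1)

    def test_synonymous_not_counted_in_ranking(self):
        recs = [make_variant(gene="G", functional_class=FunctionalClass.SYNONYMOUS)]
        m = build_matrix(recs, ["S1"])
        assert gene_ranking(m).iloc[0].n_samples == 0

    def test_waterfall_order_deterministic(self):
        recs = [
            make_variant(sample="S1", gene="A", functional_class=FunctionalClass.MISSENSE),
            make_variant(sample="S2", gene="B", functional_class=FunctionalClass.MISSENSE),
            make_variant(sample="S3", gene="A", functional_class=FunctionalClass.MISSENSE),
        ]
        m = build_matrix(recs, ["S1", "S2", "S3"])
        order1 = waterfall_sample_order(m)
        order2 = waterfall_sample_order(m)
        assert order1 == order2
        # samples carrying the top-ranked gene come first
        assert order1[0] in {"S1", "S3"}


class TestHotspots:
    def _gene_records(self, counts, gene="PIK3CA"):
        recs = []
        pos = 1
        for label, n in counts.items():
            for _ in range(n):
                recs.append(make_variant(pos=pos, gene=gene,
                                         functional_class=FunctionalClass.MISSENSE,
                                         aa_change=label))
                pos += 1
        return recs

    def test_printed_pik3ca_row(self):
        # 483 hotspot mutations of 1,163 in-gene, cohort 3,217
        recs = self._gene_records(
            {"H1047R": 483, "r1": 170, "r2": 170, "r3": 170, "r4": 170})
        rows = hotspot_table(recs, cohort_size=3217, max_rows=1)
        top = rows[0]
        assert top.label == "H1047R"
        assert top.pct_cohort == 15.0
        assert top.pct_in_gene == 41.5

    def test_printed_akt1_rows(self):
        recs = self._gene_records({"E17K": 121, "x1": 19, "x2": 19}, gene="AKT1")
        rows = hotspot_table(recs, cohort_size=3217, max_rows=1)
        assert rows[0].pct_in_gene == 76.1
        assert rows[0].pct_cohort == 3.8
        other = rows[-1]
        assert other.label == "Other" and other.pct_in_gene == 23.9

    def test_single_mutation_full_share(self):
        rows = hotspot_table(self._gene_records({"X1Y": 1}), cohort_size=10, min_count=1)
        assert rows[0].pct_in_gene == 100.0

    def test_in_gene_shares_sum_to_100(self, rng):
        counts = {f"m{i}": int(rng.integers(1, 40)) for i in range(15)}
        rows = hotspot_table(self._gene_records(counts), cohort_size=100, min_count=1)
        assert sum(r.pct_in_gene for r in rows) == pytest.approx(100.0, abs=0.5)

    def test_bad_cohort_size(self):
        with pytest.raises(ValueError):
            hotspot_table([], cohort_size=0)


class TestDruggable:
    def test_all_and_none(self):
        recs = [make_variant(sample=f"S{i}", gene="EGFR",
                             functional_class=FunctionalClass.MISSENSE) for i in range(5)]
        samples = [f"S{i}" for i in range(5)]
        assert druggable_fraction(recs, samples, frozenset({"EGFR"})) == 1.0
        assert druggable_fraction(recs, samples, frozenset({"OTHER"})) == 0.0

    def test_matches_hand_count(self, rng):
        samples = [f"S{i}" for i in range(40)]
        druggable = frozenset({"A", "B"})
        recs, hand = [], set()
        for s in samples:
            for g in rng.choice(["A", "B", "C", "D"], size=2, replace=False):
                cls = (FunctionalClass.MISSENSE if rng.random() < 0.5
                       else FunctionalClass.SYNONYMOUS)
                recs.append(make_variant(sample=s, gene=str(g), functional_class=cls))
                if g in druggable and cls is FunctionalClass.MISSENSE:
                    hand.add(s)
        assert druggable_fraction(recs, samples, druggable) == len(hand) / 40

    def test_empty_list_is_error(self):
        with pytest.raises(ValueError):
            druggable_fraction([], ["S1"], frozenset())


def _fisher_two_sided_oracle(a, b, c, d):
    """Exhaustive hypergeometric enumeration with fixed margins."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    rv = hypergeom(n, col1, row1)
    p_obs = rv.pmf(a)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    return sum(rv.pmf(k) for k in range(lo, hi + 1)
               if rv.pmf(k) <= p_obs * (1 + 1e-7))


class TestAssociation:
    def test_perfect_separation(self):
        mutated = [True] * 10 + [False] * 10
        feature = [True] * 10 + [False] * 10
        res = association_test(mutated, feature)
        assert res["p_two_tailed"] == pytest.approx(2 / 184756, rel=1e-9)

    def test_balanced_independence(self):
        mutated = [True] * 10 + [False] * 10
        feature = ([True] * 5 + [False] * 5) * 2
        res = association_test(mutated, feature)
        assert res["odds_ratio"] == pytest.approx(1.0)
        assert res["p_two_tailed"] == pytest.approx(1.0)

    def test_haldane_correction_with_zero_cell(self):
        res = association_test([True] * 5 + [False] * 5,
                               [True] * 5 + [False] * 5)
        assert res["odds_ratio"] == pytest.approx((5.5 * 5.5) / (0.5 * 0.5))

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError):
            association_test([True] * 5, [True] * 5)

    def test_matches_enumeration_oracle_subset(self):
        # a representative sample of small tables; the exhaustive n<=20 sweep
        # runs in the acceptance suite
        for a, b, c, d in [(1, 2, 3, 4), (0, 5, 5, 0), (2, 2, 2, 2),
                           (6, 1, 1, 6), (0, 0, 3, 7), (4, 0, 2, 5)]:
            mutated = [True] * (a + b) + [False] * (c + d)
            feature = [True] * a + [False] * b + [True] * c + [False] * d
            if (a + b == 0 or c + d == 0) and (a + c == 0 or b + d == 0):
                continue
            res = association_test(mutated, feature)
            assert res["p_two_tailed"] == pytest.approx(
                _fisher_two_sided_oracle(a, b, c, d), abs=1e-9), (a, b, c, d)


class TestRounding:
    @pytest.mark.parametrize("value,expected", [
        (2.25, 2.3), (2.35, 2.4), (0.05, 0.1), (41.53, 41.5), (15.01, 15.0),
    ])
    def test_half_up(self, value, expected):
        assert round_half_up(value, 1) == expected
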