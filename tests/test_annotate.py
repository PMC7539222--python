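import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rnasomatic.annotate import (
    AnnotationIndex,
    IntervalSet,
    TranscriptModel,
    annotate_variants,
    attach_reference,
    build_panel_of_normals,
    classify_effect,
    homopolymer_run,
    translate,
)
from rnasomatic.io_core import FunctionalClass

from .conftest import make_variant


class TestPanelOfNormals:
    def test_union_semantics(self):
        normals = [[make_variant(sample=f"N{i}", pos=100)] for i in range(10)]
        pon = build_panel_of_normals(normals)
        assert pon == {("chr1", 100, "A", "G")}

    def test_singleton_variant_still_included(self):
        # present in exactly 1 of 10 normals: all enumerated variants go in
        normals = [[make_variant(sample=f"N{i}", pos=100)] for i in range(9)]
        normals.append([make_variant(sample="N9", pos=100), make_variant(sample="N9", pos=555)])
        pon = build_panel_of_normals(normals)
        assert ("chr1", 555, "A", "G") in pon

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            build_panel_of_normals([])

    def test_size_matches_set_union_oracle(self, rng):
        normals = []
        for i in range(8):
            normals.append([
                make_variant(sample=f"N{i}", pos=int(p))
                for p in rng.integers(1, 50, size=12)
            ])
        oracle = set()
        for callset in normals:
            for rec in callset:
                oracle |= {rec.key}
        assert build_panel_of_normals(normals) == oracle


class TestAnnotateVariants:
    def _index(self):
        return AnnotationIndex(
            dbsnp={("chr1", 10, "A", "G"): True, ("chr1", 20, "C", "T"): False},
            cosmic={("chr1", 10, "A", "G"): 120},
            population_af={"gnomad": {("chr1", 30, "G", "A"): 0.2}},
            editing_sites={("chr1", 40, "A>G")},
            low_complexity=IntervalSet([("chr1", 49, 60)]),
            clinical_db={("chr1", 10, "A", "G")},
            pon={("chr1", 70, "T", "C")},
        )

    def test_dbsnp_common_and_cosmic(self):
        (out,) = annotate_variants([make_variant(pos=10, ref="A", alt="G")], self._index())
        assert {"dbsnp", "dbsnp_common", "cosmic", "clinical_db"} <= out.annotations
        assert out.cosmic_occurrences == 120

    def test_low_complexity_interval(self):
        (out,) = annotate_variants([make_variant(pos=55, ref="A", alt="C")], self._index())
        assert out.annotations == {"low_complexity"}

    def test_editing_requires_matching_change(self):
        a2g = make_variant(pos=40, ref="A", alt="G")
        a2c = make_variant(pos=40, ref="A", alt="C")
        out = annotate_variants([a2g, a2c], self._index())
        assert "editing_site" in out[0].annotations
        assert "editing_site" not in out[1].annotations

    def test_population_af_flags(self):
        (out,) = annotate_variants([make_variant(pos=30, ref="G", alt="A")], self._index())
        assert out.pop_af == {"gnomad": 0.2}
        assert "high_pop_af:gnomad" in out.annotations

    def test_idempotent(self):
        recs = [make_variant(pos=10, ref="A", alt="G"), make_variant(pos=70, ref="T", alt="C")]
        once = annotate_variants(recs, self._index())
        twice = annotate_variants(once, self._index())
        assert [o.annotations for o in once] == [t.annotations for t in twice]

    def test_matches_linear_scan_oracle(self, rng):
        idx = self._index()
        recs = []
        for _ in range(200):
            pos = int(rng.integers(1, 100))
            ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
            recs.append(make_variant(pos=pos, ref=str(ref), alt=str(alt)))
        out = annotate_variants(recs, idx)
        for rec, got in zip(recs, out):
            expected = set()
            k = rec.key
            if k in idx.dbsnp:
                expected.add("dbsnp")
                if idx.dbsnp[k]:
                    expected.add("dbsnp_common")
            if k in idx.cosmic:
                expected.add("cosmic")
            for res, afs in idx.population_af.items():
                if k in afs:
                    expected.add(f"pop:{res}")
                    if afs[k] >= idx.max_pop_af_flag_threshold:
                        expected.add(f"high_pop_af:{res}")
            if (rec.ref, rec.alt) in {("A", "G"), ("T", "C")} and (
                rec.chrom, rec.pos, f"{rec.ref}>{rec.alt}") in idx.editing_sites:
                expected.add("editing_site")
            # linear scan over intervals
            if any(c == rec.chrom and s < rec.pos <= e
                   for c, s, e in idx.low_complexity):
                expected.add("low_complexity")
            if k in idx.clinical_db:
                expected.add("clinical_db")
            if k in idx.pon:
                expected.add("pon")
            assert got.annotations == expected, rec.key


class TestHomopolymer:
    def test_run_of_five(self):
        ref = {"chr1": "GGAAAAAGG"}
        assert homopolymer_run(ref, "chr1", 5, window=2) == 5

    def test_no_run(self):
        ref = {"chr1": "ACGTGCATG"}
        assert homopolymer_run(ref, "chr1", 5, window=2) == 1

    def test_out_of_range(self):
        with pytest.raises(IndexError):
            homopolymer_run({"chr1": "ACGT"}, "chr1", 99)

    @given(data=st.data())
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force(self, data):
        seq = "".join(data.draw(st.sampled_from("ACGT")) for _ in range(30))
        pos = data.draw(st.integers(min_value=1, max_value=30))
        window = data.draw(st.integers(min_value=1, max_value=6))
        lo = max(0, pos - 1 - window)
        hi = min(len(seq), pos + window)
        ctx = seq[lo:hi]
        brute = max(
            len(run)
            for run in __import__("itertools").groupby(ctx)
            for run in [list(run[1])]
        )
        assert homopolymer_run({"chr1": seq}, "chr1", pos, window=window) == brute


def _toy_model():
    # CDS 11..22 on +: codons from reference below
    reference = {"chr1": "TTTTTTTTTT" + "ATGTACGGATAG" + "TTTTTTTTTT"}
    model = TranscriptModel(
        gene="G1", chrom="chr1", strand="+",
        cds_intervals=[(11, 22)], utr5_intervals=[(1, 10)], utr3_intervals=[(23, 32)],
        splice_sites=frozenset(),
    )
    attach_reference(model, reference)
    return model, reference


class TestClassifyEffect:
    def test_stop_gain(self):
        model, _ = _toy_model()
        # codon 2 TAC -> TAA is a stop by the standard code
        rec = make_variant(pos=16, ref="C", alt="A")
        assert classify_effect(rec, model) is FunctionalClass.NONSENSE

    def test_missense_synonymous(self):
        model, _ = _toy_model()
        assert classify_effect(make_variant(pos=14, ref="T", alt="C"), model) is FunctionalClass.MISSENSE
        # GGA -> GGG stays glycine
        assert classify_effect(make_variant(pos=19, ref="A", alt="G"), model) is FunctionalClass.SYNONYMOUS

    def test_frameshift_vs_inframe(self):
        model, _ = _toy_model()
        fs = make_variant(pos=13, ref="GTA", alt="G")  # 2-bp deletion
        assert classify_effect(fs, model) is FunctionalClass.FRAMESHIFT
        inframe = make_variant(pos=13, ref="GTAC", alt="G")  # 3-bp deletion
        assert classify_effect(inframe, model) is FunctionalClass.INFRAME_INDEL

    def test_utrs_and_other(self):
        model, _ = _toy_model()
        assert classify_effect(make_variant(pos=5, ref="T", alt="A"), model) is FunctionalClass.UTR_5
        assert classify_effect(make_variant(pos=25, ref="T", alt="A"), model) is FunctionalClass.UTR_3
        assert classify_effect(make_variant(pos=40, ref="T", alt="A"), model) is FunctionalClass.OTHER

    def test_splice_site(self):
        model, reference = _toy_model()
        model2 = TranscriptModel(
            gene="G1", chrom="chr1", strand="+",
            cds_intervals=[(11, 22)], splice_sites=frozenset({23, 24}),
        )
        attach_reference(model2, reference)
        assert classify_effect(make_variant(pos=23, ref="T", alt="A"), model2) is FunctionalClass.SPLICING

    def test_matches_full_cds_retranslation_oracle(self, rng):
        # random SNVs in a random 60-codon gene; compare against re-translating
        # the whole mutated CDS
        seq = "".join(rng.choice(list("ACGT"), size=200))
        reference = {"chr1": seq}
        model = TranscriptModel(gene="G", chrom="chr1", strand="+", cds_intervals=[(11, 190)])
        attach_reference(model, reference)
        for _ in range(100):
            pos = int(rng.integers(11, 191))
            ref = seq[pos - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            rec = make_variant(pos=pos, ref=ref, alt=alt)
            got = classify_effect(rec, model)
            mutated = seq[:pos - 1] + alt + seq[pos:]
            before = translate(seq[10:190])
            after = translate(mutated[10:190])
            idx = (pos - 11) // 3
            if after[idx] == before[idx]:
                expected = FunctionalClass.SYNONYMOUS
            elif after[idx] == "*":
                expected = FunctionalClass.NONSENSE
            else:
                expected = FunctionalClass.MISSENSE
            assert got is expected, (pos, ref, alt)

    def test_minus_strand(self, rng):
        # minus-strand gene: CDS read right-to-left complemented
        seq = "T" * 10 + "CTATCCGTACAT" + "T" * 10  # revcomp = ATGTACGGATAG
        reference = {"chr1": seq}
        model = TranscriptModel(gene="G", chrom="chr1", strand="-", cds_intervals=[(11, 22)])
        attach_reference(model, reference)
        assert model.cds_sequence(reference) == "ATGTACGGATAG"
        # genomic G>T at pos 17 is C>A on the transcript: TAC -> TAA stop
        rec = make_variant(pos=17, ref="G", alt="T")
        assert classify_effect(rec, model) is FunctionalClass.NONSENSE
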