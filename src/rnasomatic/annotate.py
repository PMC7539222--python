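"""Annotation: database joins, homopolymer context, coding-effect classification,
and panel-of-normals construction.

The annotation index joins normalized variants against position/allele-keyed
resources (SNP database with common flag, somatic catalogue, population AF
maps, RNA-editing sites, low-complexity intervals, curated clinical list,
panel of normals) and attaches flag strings plus the numeric payloads the
filter engine thresholds on.
"""

from __future__ import annotations

import bisect
import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .io_core import FunctionalClass, ValidationError, VariantRecord

__all__ = [
    "AnnotationIndex",
    "TranscriptModel",
    "IntervalSet",
    "build_panel_of_normals",
    "annotate_variants",
    "homopolymer_run",
    "classify_effect",
    "load_annotation_index",
]

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


class IntervalSet:
    """Sorted, per-chromosome interval membership (0-based half-open)."""

    def __init__(self, intervals: Iterable[tuple] = ()):  # (chrom, start, end)
        self._by_chrom: dict = {}
        for chrom, start, end in intervals:
            self._by_chrom.setdefault(chrom, []).append((start, end))
        self._starts: dict = {}
        for chrom, ivs in self._by_chrom.items():
            merged = []
            for start, end in sorted(ivs):
                if merged and start <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], end))
                else:
                    merged.append((start, end))
            self._by_chrom[chrom] = merged
            self._starts[chrom] = [s for s, _ in merged]

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based position."""
        ivs = self._by_chrom.get(chrom)
        if not ivs:
            return False
        p0 = pos - 1
        i = bisect.bisect_right(self._starts[chrom], p0) - 1
        return i >= 0 and ivs[i][0] <= p0 < ivs[i][1]

    def __iter__(self):
        for chrom in sorted(self._by_chrom):
            for start, end in self._by_chrom[chrom]:
                yield chrom, start, end


@dataclass
class AnnotationIndex:
    """Position/allele-keyed annotation resources.

    Keys are normalized ``(chrom, pos, ref, alt)`` tuples throughout;
    ``editing_sites`` is keyed by ``(chrom, pos, "A>G"|"T>C")``.
    """

    dbsnp: dict = field(default_factory=dict)            # key -> is_common (bool)
    cosmic: dict = field(default_factory=dict)           # key -> occurrence count
    population_af: dict = field(default_factory=dict)    # resource -> {key -> af}
    editing_sites: set = field(default_factory=set)      # (chrom, pos, change)
    low_complexity: IntervalSet = field(default_factory=IntervalSet)
    clinical_db: set = field(default_factory=set)        # keys
    pon: set = field(default_factory=set)                # keys
    druggable_genes: frozenset = frozenset()
    driver_genes: frozenset = frozenset()
    max_pop_af_flag_threshold: float = 0.01

    def __post_init__(self) -> None:
        for resource, afs in self.population_af.items():
            for key, af in afs.items():
                if not 0.0 <= af <= 1.0:
                    raise ValidationError(
                        f"{resource}: AF {af} outside [0,1] for {key}"
                    )


def build_panel_of_normals(normal_callsets: Sequence[Sequence[VariantRecord]]) -> set:
    """Union of all normalized variant keys over >= 1 normal-tissue callsets."""
    if not normal_callsets:
        raise ValueError("panel of normals requires at least one normal callset")
    pon: set = set()
    for callset in normal_callsets:
        pon.update(rec.key for rec in callset)
    return pon


def _editing_change(ref: str, alt: str) -> Optional[str]:
    """A-to-I editing signature on either strand representation, else None."""
    if (ref, alt) == ("A", "G"):
        return "A>G"
    if (ref, alt) == ("T", "C"):
        return "T>C"
    return None


def annotate_variants(
    records: Sequence[VariantRecord],
    index: AnnotationIndex,
    reference: Optional[Mapping[str, str]] = None,
    transcript_models: Optional[Sequence["TranscriptModel"]] = None,
    homopolymer_window: int = 5,
) -> list:
    """Attach annotation flags (and numeric payloads) to each record.

    Pure function of (normalized key, index): re-annotation is idempotent.
    Returns new records; inputs are not mutated.
    """
    models_by_chrom: dict = {}
    for model in transcript_models or ():
        if reference is not None and getattr(model, "_cds_cache", None) is None:
            attach_reference(model, reference)
        models_by_chrom.setdefault(model.chrom, []).append(model)
    out = []
    for rec in records:
        flags = set()
        key = rec.key
        if key in index.dbsnp:
            flags.add("dbsnp")
            if index.dbsnp[key]:
                flags.add("dbsnp_common")
        occurrences = index.cosmic.get(key, 0)
        if key in index.cosmic:
            flags.add("cosmic")
        pop_af = {}
        for resource, afs in index.population_af.items():
            af = afs.get(key)
            if af is not None:
                pop_af[resource] = af
                flags.add(f"pop:{resource}")
                if af >= index.max_pop_af_flag_threshold:
                    flags.add(f"high_pop_af:{resource}")
        change = _editing_change(rec.ref, rec.alt)
        if change is not None and (rec.chrom, rec.pos, change) in index.editing_sites:
            flags.add("editing_site")
        if index.low_complexity.contains(rec.chrom, rec.pos):
            flags.add("low_complexity")
        if key in index.clinical_db:
            flags.add("clinical_db")
        if key in index.pon:
            flags.add("pon")
        gene = rec.gene
        fclass = rec.functional_class
        if rec.chrom in models_by_chrom:
            for model in models_by_chrom[rec.chrom]:
                if model.covers(rec.pos):
                    gene = model.gene
                    fclass = classify_effect(rec, model)
                    break
        hlen = rec.homopolymer_len
        if reference is not None and rec.chrom in reference:
            hlen = homopolymer_run(reference, rec.chrom, rec.pos, window=homopolymer_window)
        out.append(
            dataclasses.replace(
                rec,
                annotations=flags,
                pop_af=pop_af,
                cosmic_occurrences=occurrences,
                homopolymer_len=hlen,
                gene=gene,
                functional_class=fclass,
            )
        )
    return out


def homopolymer_run(reference: Mapping[str, str], chrom: str, pos: int, window: int = 5) -> int:
    """Longest single-nucleotide run overlapping or adjacent to ``pos`` within
    +/- ``window`` bases.  Always >= 1."""
    if window < 1:
        raise ValueError("window must be >= 1")
    seq = reference[chrom]
    if not 1 <= pos <= len(seq):
        raise IndexError(f"position {chrom}:{pos} outside reference")
    lo = max(0, pos - 1 - window)
    hi = min(len(seq), pos + window)
    context = seq[lo:hi].upper()
    best = run = 1
    for i in range(1, len(context)):
        run = run + 1 if context[i] == context[i - 1] else 1
        best = max(best, run)
    return best


@dataclass
class TranscriptModel:
    """Minimal single-transcript gene model for synthetic data.

    Intervals are 1-based inclusive, ordered, non-overlapping.  Splice sites
    are all positions within 2 bp of an internal exon boundary.
    """

    gene: str
    chrom: str
    strand: str
    cds_intervals: list   # of (start, end)
    utr5_intervals: list = field(default_factory=list)
    utr3_intervals: list = field(default_factory=list)
    splice_sites: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"bad strand {self.strand}")
        total = sum(e - s + 1 for s, e in self.cds_intervals)
        if total % 3 != 0:
            raise ValidationError(f"{self.gene}: CDS length {total} not divisible by 3")

    def covers(self, pos: int) -> bool:
        for s, e in (*self.cds_intervals, *self.utr5_intervals, *self.utr3_intervals):
            if s <= pos <= e:
                return True
        return pos in self.splice_sites

    def cds_positions(self) -> list:
        pos = []
        for s, e in self.cds_intervals:
            pos.extend(range(s, e + 1))
        return pos

    def cds_sequence(self, reference: Mapping[str, str]) -> str:
        seq = "".join(
            reference[self.chrom][s - 1 : e].upper() for s, e in self.cds_intervals
        )
        if self.strand == "-":
            seq = seq.translate(COMPLEMENT)[::-1]
        return seq

    def span(self) -> tuple:
        all_iv = [*self.cds_intervals, *self.utr5_intervals, *self.utr3_intervals]
        return min(s for s, _ in all_iv), max(e for _, e in all_iv)


def translate(cds: str) -> str:
    return "".join(
        GENETIC_CODE.get(cds[i : i + 3], "X") for i in range(0, len(cds) - len(cds) % 3, 3)
    )


def _in_any(pos: int, intervals: Iterable[tuple]) -> bool:
    return any(s <= pos <= e for s, e in intervals)


def classify_effect(rec: VariantRecord, model: TranscriptModel) -> FunctionalClass:
    """Classify a variant against a toy transcript model.

    Splice-site proximity takes precedence, then CDS codon translation for
    SNVs (standard genetic code, strand-aware), frameshift/in-frame for CDS
    indels, then UTR membership.  Anything else is ``other``.
    """
    if rec.chrom != model.chrom:
        raise ValueError(f"variant on {rec.chrom} vs model on {model.chrom}")
    if rec.pos in model.splice_sites:
        return FunctionalClass.SPLICING
    in_cds = _in_any(rec.pos, model.cds_intervals)
    if in_cds:
        if rec.is_snv:
            cds_pos = model.cds_positions()
            idx = cds_pos.index(rec.pos)  # 0-based offset on + strand
            if model.strand == "-":
                idx = len(cds_pos) - 1 - idx
                ref = rec.ref.translate(COMPLEMENT)
                alt = rec.alt.translate(COMPLEMENT)
            else:
                ref, alt = rec.ref, rec.alt
            codon_i = idx // 3
            within = idx % 3
            # reconstruct the reference codon from flanking CDS bases
            offsets = [codon_i * 3, codon_i * 3 + 1, codon_i * 3 + 2]
            return _codon_effect(model, offsets, within, ref, alt, rec)
        indel_len = abs(len(rec.ref) - len(rec.alt))
        if indel_len % 3 != 0:
            return FunctionalClass.FRAMESHIFT
        return FunctionalClass.INFRAME_INDEL
    if _in_any(rec.pos, model.utr5_intervals):
        return FunctionalClass.UTR_5
    if _in_any(rec.pos, model.utr3_intervals):
        return FunctionalClass.UTR_3
    return FunctionalClass.OTHER


def _codon_effect(model, offsets, within, ref, alt, rec) -> FunctionalClass:
    # reference must be reachable through the record's context; we rebuild the
    # codon from the stranded CDS coordinate map using the record's ref base
    # plus the model-declared reference bases cached on the model.
    cds = getattr(model, "_cds_cache", None)
    if cds is None:
        raise ValueError(
            "classify_effect needs model.attach_reference(reference) called first"
        )
    codon = list(cds[offsets[0] : offsets[2] + 1])
    if codon[within] != ref:
        raise ValueError(
            f"REF {ref} at {rec.chrom}:{rec.pos} disagrees with CDS base {codon[within]}"
        )
    aa_ref = GENETIC_CODE[("".join(codon))]
    codon[within] = alt
    aa_alt = GENETIC_CODE[("".join(codon))]
    if aa_alt == aa_ref:
        return FunctionalClass.SYNONYMOUS
    if aa_alt == "*":
        return FunctionalClass.NONSENSE
    return FunctionalClass.MISSENSE


def attach_reference(model: TranscriptModel, reference: Mapping[str, str]) -> TranscriptModel:
    """Cache the stranded CDS sequence on the model for codon lookups."""
    model._cds_cache = model.cds_sequence(reference)
    return model


# ---------------------------------------------------------------------------
# Resource loading (TSV/BED external interfaces)
# ---------------------------------------------------------------------------


def _read_keyed_tsv(path, value_col: Optional[str], cast):
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "pos": int, "ref": str, "alt": str})
    out = {}
    for row in df.itertuples(index=False):
        key = (row.chrom, int(row.pos), row.ref, row.alt)
        out[key] = cast(getattr(row, value_col)) if value_col else None
    return out


def load_annotation_index(
    resource_dir,
    population_resources: Sequence[str] = ("gnomad", "swegen"),
    max_pop_af_flag_threshold: float = 0.01,
):
    """Load the TSV/BED resource directory layout written by the simulator.

    Expected files: dbsnp.tsv, cosmic.tsv, popaf_<name>.tsv, editing.tsv,
    lowcomplexity.bed, clinicaldb.tsv, pon.tsv, druggable_genes.txt,
    driver_genes.txt (missing files load as empty resources).
    """
    from pathlib import Path

    from .io_core import read_bed

    d = Path(resource_dir)
    dbsnp, cosmic, clinical, pon = {}, {}, set(), set()
    if (d / "dbsnp.tsv").exists():
        dbsnp = {k: bool(v) for k, v in _read_keyed_tsv(d / "dbsnp.tsv", "common", int).items()}
    if (d / "cosmic.tsv").exists():
        cosmic = _read_keyed_tsv(d / "cosmic.tsv", "occurrences", int)
    pop = {}
    for name in population_resources:
        p = d / f"popaf_{name}.tsv"
        if p.exists():
            pop[name] = _read_keyed_tsv(p, "af", float)
    editing = set()
    if (d / "editing.tsv").exists():
        df = pd.read_csv(d / "editing.tsv", sep="\t", dtype={"chrom": str, "pos": int, "change": str})
        editing = {(r.chrom, int(r.pos), r.change) for r in df.itertuples(index=False)}
    lowc = IntervalSet()
    if (d / "lowcomplexity.bed").exists():
        lowc = IntervalSet((c, s, e) for c, s, e, *_ in
                           [(r + (0,))[:4] for r in read_bed(d / "lowcomplexity.bed")])
    if (d / "clinicaldb.tsv").exists():
        clinical = set(_read_keyed_tsv(d / "clinicaldb.tsv", None, str).keys())
    if (d / "pon.tsv").exists():
        pon = set(_read_keyed_tsv(d / "pon.tsv", None, str).keys())
    druggable = frozenset()
    if (d / "druggable_genes.txt").exists():
        druggable = frozenset((d / "druggable_genes.txt").read_text().split())
    drivers = frozenset()
    if (d / "driver_genes.txt").exists():
        drivers = frozenset((d / "driver_genes.txt").read_text().split())
    return AnnotationIndex(
        dbsnp=dbsnp, cosmic=cosmic, population_af=pop, editing_sites=editing,
        low_complexity=lowc, clinical_db=clinical, pon=pon,
        druggable_genes=druggable, driver_genes=drivers,
        max_pop_af_flag_threshold=max_pop_af_flag_threshold,
    )
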