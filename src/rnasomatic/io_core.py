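"""Domain types and readers/writers for the standard formats the pipeline touches.

Coordinate conventions: variants and FASTA lookups are 1-based; BED intervals
are 0-based half-open.  All conversions happen in this module.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import pysam

__all__ = [
    "FunctionalClass",
    "VariantRecord",
    "DepthTrack",
    "ClinicalRecord",
    "GeneSet",
    "VcfParseError",
    "VcfConfigError",
    "ValidationError",
    "ReferenceMismatchError",
    "read_vcf",
    "write_vcf",
    "normalize_variant",
    "read_bed",
    "write_bed",
    "read_depth_track",
    "write_depth_track",
    "read_clinical",
    "write_clinical",
    "read_gene_sets",
    "write_gene_sets",
    "load_reference",
]


class VcfParseError(ValueError):
    """Malformed VCF content."""


class VcfConfigError(ValueError):
    """A required VCF tag is missing or misconfigured."""


class ValidationError(ValueError):
    """A table row violates the schema (unknown enum level, bad value...)."""


class ReferenceMismatchError(ValueError):
    """A variant's REF allele disagrees with the reference sequence."""


class FunctionalClass(str, Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    SPLICING = "splicing"
    UTR_3 = "utr_3"
    UTR_5 = "utr_5"
    SYNONYMOUS = "synonymous"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    OTHER = "other"


_BASES = frozenset("ACGTN")


@dataclass
class VariantRecord:
    """One called variant for one sample.

    ``annotations`` is ``None`` until the record has been run through
    :func:`rnasomatic.annotate.annotate_variants`; afterwards it is a set of
    flag strings.  ``pop_af`` holds the per-resource maximum population allele
    frequency and ``cosmic_occurrences``/``homopolymer_len`` the numeric
    annotation payloads the filter engine thresholds on.
    """

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    vaf: float
    depth: int
    alt_depth: int
    base_quality: Optional[float] = None
    gene: Optional[str] = None
    functional_class: FunctionalClass = FunctionalClass.OTHER
    annotations: Optional[set] = None
    pop_af: Optional[dict] = None
    cosmic_occurrences: int = 0
    homopolymer_len: Optional[int] = None
    aa_change: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.depth < 0 or self.alt_depth < 0:
            raise ValidationError("depths must be >= 0")
        if self.alt_depth > self.depth:
            raise ValidationError(
                f"alt_depth {self.alt_depth} > depth {self.depth} at {self.chrom}:{self.pos}"
            )
        if not 0.0 <= self.vaf <= 1.0:
            raise ValidationError(f"vaf outside [0,1]: {self.vaf}")
        if self.depth > 0 and abs(self.vaf - self.alt_depth / self.depth) > 0.005:
            raise ValidationError(
                f"vaf {self.vaf} inconsistent with {self.alt_depth}/{self.depth}"
            )

    @property
    def key(self) -> tuple:
        """Positional identity used for set membership across callsets."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_insertion(self) -> bool:
        return len(self.alt) > len(self.ref)

    @property
    def is_deletion(self) -> bool:
        return len(self.alt) < len(self.ref)

    def annotated(self) -> bool:
        return self.annotations is not None


@dataclass
class DepthTrack:
    """Per-sample depth intervals; 0-based half-open, non-overlapping per chrom."""

    sample_id: str
    intervals: list  # of (chrom, start, end, depth)

    def __post_init__(self) -> None:
        for chrom, start, end, depth in self.intervals:
            if depth < 0:
                raise ValidationError(f"negative depth {depth} on {chrom}:{start}-{end}")
            if end <= start:
                raise ValidationError(f"empty interval {chrom}:{start}-{end}")


HISTOLOGY_LEVELS = ("ductal", "lobular", "other")
STATUS_LEVELS = ("pos", "neg", "missing")
NHG_LEVELS = ("G1", "G2", "G3", "missing")
PAM50_LEVELS = ("LumA", "LumB", "HER2E", "Basal", "Normal", "Unclassified")


@dataclass
class ClinicalRecord:
    sample_id: str
    age_years: float
    tumor_size_mm: Optional[float]
    n_positive_nodes: Optional[int]
    histology: str
    er_status: str
    pgr_status: str
    her2_status: str
    ki67_status: str
    nhg: str
    pam50: str
    rx_endocrine: bool
    rx_chemo: bool
    rx_her2: bool
    os_months: float
    os_event: bool

    def __post_init__(self) -> None:
        for name, value, levels in (
            ("histology", self.histology, HISTOLOGY_LEVELS),
            ("er", self.er_status, STATUS_LEVELS),
            ("pgr", self.pgr_status, STATUS_LEVELS),
            ("her2", self.her2_status, STATUS_LEVELS),
            ("ki67", self.ki67_status, STATUS_LEVELS),
            ("nhg", self.nhg, NHG_LEVELS),
            ("pam50", self.pam50, PAM50_LEVELS),
        ):
            if value not in levels:
                raise ValidationError(
                    f"sample {self.sample_id}: unknown {name} level {value!r}"
                )
        if self.os_months <= 0:
            raise ValidationError(f"sample {self.sample_id}: os_months must be > 0")


@dataclass
class GeneSet:
    name: str
    pathway_id: str
    genes: frozenset

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.name} is empty")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

VCF_HEADER_LINES = [
    ("INFO", "GENE", "1", "String", "Gene symbol"),
    ("INFO", "FCLASS", "1", "String", "Predicted functional class"),
    ("INFO", "AACHANGE", "1", "String", "Amino acid change label"),
    ("FORMAT", "GT", "1", "String", "Genotype"),
    ("FORMAT", "DP", "1", "Integer", "Read depth"),
    ("FORMAT", "AD", "R", "Integer", "Allelic depths (ref, alt...)"),
    ("FORMAT", "AF", "A", "Float", "Allele frequency"),
]


def read_vcf(
    path,
    sample_id: Optional[str] = None,
    *,
    af_tag: str = "AF",
    dp_tag: str = "DP",
    ad_tag: str = "AD",
) -> list:
    """Read a VCF into :class:`VariantRecord` objects, one per ALT allele.

    VAF precedence: the explicit AF tag if present, else AD/DP arithmetic.
    Multi-allelic sites are always split.  Tags are looked up in FORMAT of the
    (single) sample first, then in INFO.
    """
    path = str(path)
    try:
        vf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc
    records = []
    with vf:
        vcf_samples = list(vf.header.samples)
        if sample_id is None:
            if len(vcf_samples) != 1:
                raise VcfConfigError(
                    f"{path}: sample_id required for VCF with {len(vcf_samples)} samples"
                )
            sample_id = vcf_samples[0]
        for line_no, rec in enumerate(vf, start=1):
            if rec.alts is None:
                continue
            fmt = rec.samples[vcf_samples[0]] if vcf_samples else None

            def _tag(name):
                if fmt is not None and name in fmt and fmt[name] is not None:
                    return fmt[name]
                if name in rec.info:
                    return rec.info[name]
                return None

            dp = _tag(dp_tag)
            ad = _tag(ad_tag)
            af = _tag(af_tag)
            if dp is None:
                raise VcfConfigError(
                    f"{path} record {line_no} ({rec.chrom}:{rec.pos}): missing {dp_tag} tag"
                )
            dp = int(dp)
            for i, alt in enumerate(rec.alts):
                if ad is not None:
                    ad_seq = (ad,) if isinstance(ad, (int, float)) else tuple(ad)
                    alt_dp = int(ad_seq[i + 1]) if len(ad_seq) > i + 1 else int(ad_seq[0])
                elif af is not None and dp is not None:
                    af_i = af[i] if isinstance(af, tuple) else af
                    alt_dp = round(float(af_i) * dp)
                else:
                    raise VcfConfigError(
                        f"{path} record {line_no}: need {ad_tag} or {af_tag} to derive alt depth"
                    )
                if af is not None:
                    vaf = float(af[i] if isinstance(af, tuple) else af)
                else:
                    vaf = alt_dp / dp if dp > 0 else 0.0
                def _info(name, default=None):
                    try:
                        return rec.info.get(name, default)
                    except (KeyError, ValueError):  # tag not declared in header
                        return default

                records.append(
                    VariantRecord(
                        sample_id=sample_id,
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        vaf=vaf,
                        depth=dp,
                        alt_depth=alt_dp,
                        gene=_info("GENE"),
                        functional_class=FunctionalClass(_info("FCLASS", "other")),
                        aa_change=_info("AACHANGE"),
                    )
                )
    return records


def write_vcf(path, records: Sequence[VariantRecord], contigs: Optional[Iterable[str]] = None) -> None:
    """Write records (one sample) as an uncompressed VCF 4.2 file."""
    header = pysam.VariantHeader()
    if contigs is None:
        contigs = sorted({r.chrom for r in records})
    for chrom in contigs:
        header.contigs.add(chrom)
    for kind, tag, number, vtype, desc in VCF_HEADER_LINES:
        header.add_meta(
            kind, items=[("ID", tag), ("Number", number), ("Type", vtype), ("Description", desc)]
        )
    sample_ids = {r.sample_id for r in records}
    if len(sample_ids) > 1:
        raise ValueError(f"write_vcf writes one sample per file, got {sorted(sample_ids)}")
    sample = next(iter(sample_ids)) if sample_ids else "SAMPLE"
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt)):
            vrec = out.new_record(
                contig=r.chrom, start=r.pos - 1, stop=r.pos - 1 + len(r.ref),
                alleles=(r.ref, r.alt),
            )
            if r.gene is not None:
                vrec.info["GENE"] = r.gene
            vrec.info["FCLASS"] = r.functional_class.value
            if r.aa_change is not None:
                vrec.info["AACHANGE"] = r.aa_change
            vrec.samples[sample]["GT"] = (0, 1)
            vrec.samples[sample]["DP"] = r.depth
            vrec.samples[sample]["AD"] = (r.depth - r.alt_depth, r.alt_depth)
            vrec.samples[sample]["AF"] = (r.vaf,)
            out.write(vrec)


# ---------------------------------------------------------------------------
# Reference FASTA + variant normalization
# ---------------------------------------------------------------------------


def load_reference(path) -> Mapping[str, str]:
    """Load a FASTA into an in-memory chrom -> sequence mapping via pyfaidx."""
    import pyfaidx

    fasta = pyfaidx.Fasta(str(path))
    return {name: str(fasta[name][:]) for name in fasta.keys()}


def _ref_base(reference: Mapping[str, str], chrom: str, pos: int) -> str:
    seq = reference[chrom]
    if not 1 <= pos <= len(seq):
        raise ReferenceMismatchError(f"position {chrom}:{pos} outside reference")
    return seq[pos - 1].upper()


def normalize_variant(rec: VariantRecord, reference: Mapping[str, str]) -> VariantRecord:
    """Left-align and parsimony-trim a variant against the reference.

    SNVs are returned unchanged (after a REF consistency check).  The
    procedure is the standard one: right-trim shared suffix bases, extending
    left with reference sequence whenever an allele would empty out, then
    left-trim shared prefix bases.  Idempotent and never moves a variant
    rightwards.
    """
    chrom, pos, ref, alt = rec.chrom, rec.pos, rec.ref.upper(), rec.alt.upper()
    seq = reference.get(chrom)
    if seq is None:
        raise ReferenceMismatchError(f"chromosome {chrom} not in reference")
    if seq[pos - 1 : pos - 1 + len(ref)].upper() != ref:
        raise ReferenceMismatchError(
            f"REF {ref} at {chrom}:{pos} disagrees with reference "
            f"{seq[pos - 1:pos - 1 + len(ref)].upper()!r}"
        )
    if len(ref) == 1 and len(alt) == 1:
        return rec

    while True:
        if len(ref) > 0 and len(alt) > 0 and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            if pos == 1 and (len(ref) == 1 or len(alt) == 1):
                break  # at chromosome start: cannot left-extend further
            ref, alt = ref[:-1], alt[:-1]
            if len(ref) == 0 or len(alt) == 0:
                pos -= 1
                base = _ref_base(reference, chrom, pos)
                ref, alt = base + ref, base + alt
            continue
        break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if (pos, ref, alt) == (rec.pos, rec.ref, rec.alt):
        return rec
    return dataclasses.replace(rec, pos=pos, ref=ref, alt=alt)


def is_parsimonious(ref: str, alt: str) -> bool:
    """True when the allele pair carries no trimmable shared prefix/suffix."""
    if len(ref) > 1 and len(alt) > 1 and (ref[0] == alt[0] or ref[-1] == alt[-1]):
        return False
    return True


# ---------------------------------------------------------------------------
# BED / depth tracks
# ---------------------------------------------------------------------------


def read_bed(path) -> list:
    """Read BED3/BED4 rows as (chrom, start, end[, score]) tuples."""
    rows = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}:{line_no}: BED needs >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if len(parts) >= 4:
                rows.append((chrom, start, end, int(parts[3])))
            else:
                rows.append((chrom, start, end))
    return rows


def write_bed(path, rows: Iterable[tuple]) -> None:
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_depth_track(path, sample_id: str) -> DepthTrack:
    """BED4 with the 4th column holding per-interval depth."""
    rows = read_bed(path)
    intervals = []
    for row in rows:
        if len(row) != 4:
            raise ValidationError(f"{path}: depth track requires BED4 rows")
        intervals.append(row)
    return DepthTrack(sample_id=sample_id, intervals=intervals)


def write_depth_track(path, track: DepthTrack) -> None:
    write_bed(path, track.intervals)


# ---------------------------------------------------------------------------
# Clinical TSV
# ---------------------------------------------------------------------------

CLINICAL_COLUMNS = [
    "sample_id", "age", "size_mm", "nodes", "histology", "er", "pgr", "her2",
    "ki67", "nhg", "pam50", "rx_endocrine", "rx_chemo", "rx_her2",
    "os_months", "os_event",
]


def _parse_bool(value: str, row: int, col: str) -> bool:
    v = str(value).strip().lower()
    if v in {"1", "true", "yes"}:
        return True
    if v in {"0", "false", "no"}:
        return False
    raise ValidationError(f"row {row}: bad boolean {value!r} in column {col}")


def read_clinical(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != CLINICAL_COLUMNS:
        raise ValidationError(
            f"{path}: clinical header must be exactly {CLINICAL_COLUMNS}, got {list(df.columns)}"
        )
    records = []
    for idx, row in df.iterrows():
        def _status(col):
            v = row[col].strip()
            return "missing" if v == "" else v

        def _opt_float(col):
            v = row[col].strip()
            return None if v == "" else float(v)

        try:
            nodes = row["nodes"].strip()
            records.append(
                ClinicalRecord(
                    sample_id=row["sample_id"],
                    age_years=float(row["age"]),
                    tumor_size_mm=_opt_float("size_mm"),
                    n_positive_nodes=None if nodes == "" else int(nodes),
                    histology=_status("histology"),
                    er_status=_status("er"),
                    pgr_status=_status("pgr"),
                    her2_status=_status("her2"),
                    ki67_status=_status("ki67"),
                    nhg=_status("nhg"),
                    pam50=row["pam50"].strip() or "Unclassified",
                    rx_endocrine=_parse_bool(row["rx_endocrine"], idx, "rx_endocrine"),
                    rx_chemo=_parse_bool(row["rx_chemo"], idx, "rx_chemo"),
                    rx_her2=_parse_bool(row["rx_her2"], idx, "rx_her2"),
                    os_months=float(row["os_months"]),
                    os_event=_parse_bool(row["os_event"], idx, "os_event"),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} row {idx}: {exc}") from exc
        except ValueError as exc:
            raise ValidationError(f"{path} row {idx}: {exc}") from exc
    # histology "missing" is allowed as "other" per Table conventions; enum is closed
    return records


def write_clinical(path, records: Sequence[ClinicalRecord]) -> None:
    rows = []
    for r in records:
        rows.append({
            "sample_id": r.sample_id,
            "age": r.age_years,
            "size_mm": "" if r.tumor_size_mm is None else r.tumor_size_mm,
            "nodes": "" if r.n_positive_nodes is None else r.n_positive_nodes,
            "histology": r.histology,
            "er": "" if r.er_status == "missing" else r.er_status,
            "pgr": "" if r.pgr_status == "missing" else r.pgr_status,
            "her2": "" if r.her2_status == "missing" else r.her2_status,
            "ki67": "" if r.ki67_status == "missing" else r.ki67_status,
            "nhg": "" if r.nhg == "missing" else r.nhg,
            "pam50": r.pam50,
            "rx_endocrine": int(r.rx_endocrine),
            "rx_chemo": int(r.rx_chemo),
            "rx_her2": int(r.rx_her2),
            "os_months": r.os_months,
            "os_event": int(r.os_event),
        })
    pd.DataFrame(rows, columns=CLINICAL_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gene_sets(path) -> list:
    sets = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"{path}:{line_no}: GMT line needs name, id, and >= 1 gene"
                )
            sets.append(GeneSet(name=parts[0], pathway_id=parts[1], genes=frozenset(parts[2:])))
    return sets


def write_gene_sets(path, sets: Sequence[GeneSet]) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.pathway_id, *sorted(s.genes)]) + "\n")
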