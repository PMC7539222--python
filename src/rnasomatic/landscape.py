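"""Cohort-level mutation summarization: gene x sample matrices, hotspot
tables, substitution spectra, functional-class tallies, druggable fraction,
and Fisher association tests."""

from __future__ import annotations

import decimal
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import FunctionalClass, VariantRecord

__all__ = [
    "SUBSTITUTION_TYPES",
    "SEVERITY_ORDER",
    "NONSYNONYMOUS_CLASSES",
    "MutationMatrix",
    "HotspotRow",
    "round_half_up",
    "substitution_spectrum",
    "class_tally",
    "variant_type_tally",
    "mean_nonsynonymous_per_tumor",
    "build_matrix",
    "gene_ranking",
    "waterfall_sample_order",
    "hotspot_table",
    "druggable_fraction",
    "association_test",
]

SUBSTITUTION_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_PYRIMIDINE_COLLAPSE = {
    ("C", "A"): "C>A", ("C", "G"): "C>G", ("C", "T"): "C>T",
    ("T", "A"): "T>A", ("T", "C"): "T>C", ("T", "G"): "T>G",
    ("G", "T"): "C>A", ("G", "C"): "C>G", ("G", "A"): "C>T",
    ("A", "T"): "T>A", ("A", "G"): "T>C", ("A", "C"): "T>G",
}

# most-severe-first ordering used to collapse multiple hits per (gene, sample)
SEVERITY_ORDER = (
    FunctionalClass.FRAMESHIFT,
    FunctionalClass.NONSENSE,
    FunctionalClass.SPLICING,
    FunctionalClass.MISSENSE,
    FunctionalClass.INFRAME_INDEL,
    FunctionalClass.UTR_3,
    FunctionalClass.UTR_5,
    FunctionalClass.SYNONYMOUS,
    FunctionalClass.OTHER,
)

# "non-synonymous" tallies exclude synonymous and other-noncoding by default;
# UTR inclusion is controlled by the include_utr flag on the consumers.
NONSYNONYMOUS_CLASSES = frozenset(
    {
        FunctionalClass.MISSENSE,
        FunctionalClass.NONSENSE,
        FunctionalClass.SPLICING,
        FunctionalClass.FRAMESHIFT,
        FunctionalClass.INFRAME_INDEL,
    }
)

UTR_CLASSES = frozenset({FunctionalClass.UTR_3, FunctionalClass.UTR_5})


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (matching printed-table rounding)."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def nonsynonymous(records: Iterable[VariantRecord], include_utr: bool = False):
    allowed = NONSYNONYMOUS_CLASSES | (UTR_CLASSES if include_utr else frozenset())
    return [r for r in records if r.functional_class in allowed]


def substitution_spectrum(snvs: Sequence[VariantRecord]) -> dict:
    """Proportions of the six pyrimidine-reference substitution types.

    Purine-reference changes are collapsed to their complement.  Returns an
    all-zero map for empty input; proportions otherwise sum to 1.
    """
    counts = Counter()
    for rec in snvs:
        if not rec.is_snv:
            raise ValueError(
                f"substitution_spectrum requires SNVs; got {rec.ref}>{rec.alt}"
            )
        sub = _PYRIMIDINE_COLLAPSE.get((rec.ref.upper(), rec.alt.upper()))
        if sub is None:
            raise ValueError(f"unrecognized substitution {rec.ref}>{rec.alt}")
        counts[sub] += 1
    total = sum(counts.values())
    if total == 0:
        return {t: 0.0 for t in SUBSTITUTION_TYPES}
    return {t: counts[t] / total for t in SUBSTITUTION_TYPES}


def class_tally(records: Iterable[VariantRecord]) -> dict:
    """Count of records per functional class; values partition the input."""
    tally = Counter(r.functional_class for r in records)
    return {c: tally.get(c, 0) for c in FunctionalClass}


def variant_type_tally(records: Iterable[VariantRecord]) -> dict:
    """Counts of SNVs, insertions, and deletions plus the grand total."""
    out = {"snv": 0, "insertion": 0, "deletion": 0}
    for r in records:
        if r.is_snv:
            out["snv"] += 1
        elif r.is_insertion:
            out["insertion"] += 1
        else:
            out["deletion"] += 1
    out["total"] = out["snv"] + out["insertion"] + out["deletion"]
    return out


def mean_nonsynonymous_per_tumor(
    n_total: int, n_synonymous: int, cohort_size: int, ndigits: int = 0
) -> float:
    """Mean mutations per tumor after removing synonymous calls."""
    if cohort_size <= 0:
        raise ValueError("cohort_size must be positive")
    mean = (n_total - n_synonymous) / cohort_size
    return round_half_up(mean, ndigits)


@dataclass
class MutationMatrix:
    genes: list
    samples: list
    cells: pd.DataFrame  # gene x sample, values = class name or "wt"

    def mutated(self, nonsyn_only: bool = True) -> pd.DataFrame:
        """Boolean gene x sample matrix of (non-synonymous) mutation presence."""
        if not nonsyn_only:
            return self.cells != "wt"
        syn_like = {"wt", FunctionalClass.SYNONYMOUS.value, FunctionalClass.OTHER.value,
                    FunctionalClass.UTR_3.value, FunctionalClass.UTR_5.value}
        return ~self.cells.isin(syn_like)


def build_matrix(
    records: Sequence[VariantRecord],
    sample_ids: Sequence[str],
    genes: Optional[Sequence[str]] = None,
    severity: Sequence[FunctionalClass] = SEVERITY_ORDER,
) -> MutationMatrix:
    """Most-severe functional class per (gene, sample), "wt" elsewhere."""
    rank = {c: i for i, c in enumerate(severity)}
    best: dict = {}
    for rec in records:
        if rec.gene is None:
            continue
        key = (rec.gene, rec.sample_id)
        cur = best.get(key)
        if cur is None or rank[rec.functional_class] < rank[cur]:
            best[key] = rec.functional_class
    if genes is None:
        genes = sorted({g for g, _ in best})
    cells = pd.DataFrame("wt", index=list(genes), columns=list(sample_ids))
    for (gene, sample), cls in best.items():
        if gene in cells.index and sample in cells.columns:
            cells.loc[gene, sample] = cls.value
    return MutationMatrix(genes=list(genes), samples=list(sample_ids), cells=cells)


def gene_ranking(matrix: MutationMatrix, k: Optional[int] = None) -> pd.DataFrame:
    """Genes ranked by number of samples with >= 1 non-synonymous variant.

    Ties break alphabetically.  Percentages are of all samples in the matrix,
    rounded half-up to one decimal.
    """
    mut = matrix.mutated(nonsyn_only=True)
    counts = mut.sum(axis=1)
    df = pd.DataFrame({"gene": counts.index, "n_samples": counts.values})
    df["pct_samples"] = [
        round_half_up(100.0 * n / len(matrix.samples), 1) for n in df["n_samples"]
    ]
    df = df.sort_values(["n_samples", "gene"], ascending=[False, True]).reset_index(drop=True)
    return df.head(k) if k is not None else df


def waterfall_sample_order(
    matrix: MutationMatrix,
    subtype: Optional[Mapping[str, str]] = None,
    top_genes: Optional[Sequence[str]] = None,
) -> list:
    """Deterministic waterfall column order: histological subtype blocks, then
    a hierarchical presence/absence (memo) sort on the ranked genes."""
    if top_genes is None:
        top_genes = list(gene_ranking(matrix)["gene"])
    mut = matrix.mutated(nonsyn_only=True)

    def sort_key(sample: str):
        block = subtype.get(sample, "~") if subtype else ""
        presence = tuple(
            0 if (g in mut.index and mut.loc[g, sample]) else 1 for g in top_genes
        )
        return (block, presence, sample)

    return sorted(matrix.samples, key=sort_key)


@dataclass
class HotspotRow:
    gene: str
    label: str  # amino-acid change or variant key string
    n_mutations: int
    pct_cohort: float
    pct_in_gene: float


def hotspot_table(
    gene_records: Sequence[VariantRecord],
    cohort_size: int,
    max_rows: int = 12,
    min_count: int = 2,
) -> list:
    """Table-style hotspot rows for one gene's non-synonymous records.

    Records are grouped by amino-acid-change label (falling back to the
    variant key), rows sorted by count descending, the tail aggregated into a
    residual "Other" row.  Cohort percentage = mutation count / cohort size;
    in-gene percentage = count / total gene mutations; both half-up to one
    decimal.
    """
    if cohort_size <= 0:
        raise ValueError("cohort_size must be positive")
    genes = {r.gene for r in gene_records if r.gene is not None}
    if len(genes) > 1:
        raise ValueError(f"hotspot_table takes one gene at a time, got {sorted(genes)}")
    gene = next(iter(genes)) if genes else ""
    counts = Counter()
    for rec in gene_records:
        label = rec.aa_change or f"{rec.chrom}:{rec.pos}{rec.ref}>{rec.alt}"
        counts[label] += 1
    total = sum(counts.values())
    if total == 0:
        return []
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    rows, other = [], 0
    for label, n in ordered:
        if len(rows) < max_rows and n >= min_count:
            rows.append(HotspotRow(
                gene=gene, label=label, n_mutations=n,
                pct_cohort=round_half_up(100.0 * n / cohort_size, 1),
                pct_in_gene=round_half_up(100.0 * n / total, 1),
            ))
        else:
            other += n
    if other:
        rows.append(HotspotRow(
            gene=gene, label="Other", n_mutations=other,
            pct_cohort=round_half_up(100.0 * other / cohort_size, 1),
            pct_in_gene=round_half_up(100.0 * other / total, 1),
        ))
    return rows


def druggable_fraction(
    records: Sequence[VariantRecord],
    sample_ids: Sequence[str],
    druggable_genes: frozenset,
) -> float:
    """Fraction of samples with >= 1 non-synonymous variant in a druggable gene."""
    if not druggable_genes:
        raise ValueError("druggable gene list is empty")
    hit = {
        r.sample_id
        for r in nonsynonymous(records)
        if r.gene in druggable_genes
    }
    return len(hit & set(sample_ids)) / len(sample_ids)


def association_test(
    mutated: Sequence[bool], feature: Sequence[bool]
) -> dict:
    """Fisher's exact test of mutation status against a dichotomized feature.

    Returns the 2x2 table, the sample odds ratio (Haldane 0.5 correction when
    any cell is zero), and one-/two-tailed exact hypergeometric p-values.
    """
    if len(mutated) != len(feature):
        raise ValueError("mutated and feature vectors differ in length")
    a = sum(1 for m, f in zip(mutated, feature) if m and f)
    b = sum(1 for m, f in zip(mutated, feature) if m and not f)
    c = sum(1 for m, f in zip(mutated, feature) if not m and f)
    d = sum(1 for m, f in zip(mutated, feature) if not m and not f)
    table = [[a, b], [c, d]]
    if (a + b == 0 or c + d == 0) and (a + c == 0 or b + d == 0):
        raise ValueError("all samples fall in one cell; association undefined")
    if min(a, b, c, d) == 0:
        oratio = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        oratio = (a * d) / (b * c)
    _, p_two = stats.fisher_exact(table, alternative="two-sided")
    _, p_greater = stats.fisher_exact(table, alternative="greater")
    _, p_less = stats.fisher_exact(table, alternative="less")
    return {
        "table": table,
        "odds_ratio": oratio,
        "p_two_tailed": float(p_two),
        "p_one_tailed_greater": float(p_greater),
        "p_one_tailed_less": float(p_less),
    }
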