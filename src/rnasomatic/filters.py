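"""Stringent post-hoc filter engine: negative filters, positive rescues,
and per-variant audit trails.

Negative predicates are evaluated exhaustively (no short-circuit) so the
verdict names every violated filter; rescues are then applied to anything
that failed.  The SNP filter removes database variants only when they are
absent from the somatic catalogue (dbSNP-common AND not-COSMIC).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .io_core import VariantRecord

__all__ = [
    "NEGATIVE_FILTERS",
    "RESCUE_FILTERS",
    "FilterConfig",
    "FilterVerdict",
    "UnannotatedError",
    "evaluate_variant",
    "apply_filters",
]

NEGATIVE_FILTERS = (
    "low_complexity",
    "dbsnp_noncosmic",
    "swegen",
    "gnomad_af",
    "pon",
    "editing_site",
    "homopolymer",
    "min_vaf",
    "min_depth",
    "min_alt_depth",
)

RESCUE_FILTERS = ("clinical_db", "cosmic_hotspot")

# filters that read annotation flags and therefore require annotated records
_ANNOTATION_FILTERS = frozenset(
    {"low_complexity", "dbsnp_noncosmic", "swegen", "gnomad_af", "pon", "editing_site"}
)


class UnannotatedError(ValueError):
    """A record lacks the annotation an enabled filter needs."""


@dataclass(frozen=True)
class FilterConfig:
    """One point in filter-parameter space.

    Defaults follow the final published thresholds (VAF >= 0.05, depth >= 8)
    with the caller's minimum supporting-read count of 2.
    """

    min_vaf: float = 0.05
    min_depth: int = 8
    min_alt_depth: int = 2
    max_pop_af: float = 0.01
    min_homopolymer_run: int = 5
    swegen_binary: bool = True
    cosmic_hotspot_min_occurrences: int = 5
    enabled_negative: frozenset = frozenset(NEGATIVE_FILTERS)
    enabled_rescue: frozenset = frozenset(RESCUE_FILTERS)

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_vaf <= 1.01:
            raise ValueError(f"min_vaf outside range: {self.min_vaf}")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        object.__setattr__(self, "enabled_negative", frozenset(self.enabled_negative))
        object.__setattr__(self, "enabled_rescue", frozenset(self.enabled_rescue))
        unknown = self.enabled_negative - set(NEGATIVE_FILTERS)
        if unknown:
            raise ValueError(f"unknown negative filters: {sorted(unknown)}")
        unknown = self.enabled_rescue - set(RESCUE_FILTERS)
        if unknown:
            raise ValueError(f"unknown rescue filters: {sorted(unknown)}")

    def with_values(self, **kwargs) -> "FilterConfig":
        return replace(self, **kwargs)


@dataclass
class FilterVerdict:
    variant_key: tuple
    sample_id: str
    passed: bool
    failed_filters: list
    rescued_by: list

    def __post_init__(self) -> None:
        if self.rescued_by and not self.failed_filters:
            raise ValueError("rescue cannot fire when no negative filter failed")
        expected = not self.failed_filters or bool(self.rescued_by)
        if self.passed != expected:
            raise ValueError("verdict inconsistent with failures/rescues")


def _require_annotated(rec: VariantRecord, name: str) -> None:
    if rec.annotations is None:
        raise UnannotatedError(
            f"filter {name!r} requires annotations but {rec.chrom}:{rec.pos} "
            f"{rec.ref}>{rec.alt} is unannotated"
        )


def _negative_fails(rec: VariantRecord, cfg: FilterConfig, name: str) -> bool:
    if name in _ANNOTATION_FILTERS:
        _require_annotated(rec, name)
    ann = rec.annotations or set()
    if name == "min_vaf":
        return rec.vaf < cfg.min_vaf
    if name == "min_depth":
        return rec.depth < cfg.min_depth
    if name == "min_alt_depth":
        return rec.alt_depth < cfg.min_alt_depth
    if name == "low_complexity":
        return "low_complexity" in ann
    if name == "dbsnp_noncosmic":
        return "dbsnp_common" in ann and "cosmic" not in ann
    if name == "swegen":
        if cfg.swegen_binary:
            return "pop:swegen" in ann
        if rec.pop_af is None:
            raise UnannotatedError("swegen AF filter needs annotated population AFs")
        return rec.pop_af.get("swegen", 0.0) >= cfg.max_pop_af
    if name == "gnomad_af":
        if rec.pop_af is None:
            raise UnannotatedError("gnomad_af filter needs annotated population AFs")
        return rec.pop_af.get("gnomad", 0.0) >= cfg.max_pop_af
    if name == "pon":
        return "pon" in ann
    if name == "editing_site":
        return "editing_site" in ann
    if name == "homopolymer":
        if rec.homopolymer_len is None:
            raise UnannotatedError(
                f"homopolymer filter needs homopolymer_len on {rec.chrom}:{rec.pos}"
            )
        return rec.homopolymer_len >= cfg.min_homopolymer_run
    raise ValueError(f"unknown negative filter {name!r}")


def _rescue_fires(rec: VariantRecord, cfg: FilterConfig, name: str) -> bool:
    _require_annotated(rec, name)
    ann = rec.annotations or set()
    if name == "clinical_db":
        return "clinical_db" in ann
    if name == "cosmic_hotspot":
        return (
            "cosmic" in ann
            and rec.cosmic_occurrences >= cfg.cosmic_hotspot_min_occurrences
        )
    raise ValueError(f"unknown rescue filter {name!r}")


def evaluate_variant(rec: VariantRecord, cfg: FilterConfig) -> FilterVerdict:
    """Full audit of one record: every enabled negative predicate is
    evaluated, then rescues are tried on anything that failed."""
    failed = [n for n in NEGATIVE_FILTERS
              if n in cfg.enabled_negative and _negative_fails(rec, cfg, n)]
    rescued = []
    if failed:
        rescued = [n for n in RESCUE_FILTERS
                   if n in cfg.enabled_rescue and _rescue_fires(rec, cfg, n)]
    return FilterVerdict(
        variant_key=rec.key,
        sample_id=rec.sample_id,
        passed=not failed or bool(rescued),
        failed_filters=failed,
        rescued_by=rescued,
    )


def apply_filters(cohort: Sequence[VariantRecord], cfg: FilterConfig):
    """Filter a cohort; returns (passed records, verdict table).

    ``|passed| + |failed| == |input|`` always holds; the verdict table has
    one row per input record in input order.
    """
    passed, verdicts = [], []
    for rec in cohort:
        v = evaluate_variant(rec, cfg)
        verdicts.append(v)
        if v.passed:
            passed.append(rec)
    return passed, verdicts


def verdicts_to_frame(verdicts):
    import pandas as pd

    return pd.DataFrame(
        {
            "sample_id": [v.sample_id for v in verdicts],
            "chrom": [v.variant_key[0] for v in verdicts],
            "pos": [v.variant_key[1] for v in verdicts],
            "ref": [v.variant_key[2] for v in verdicts],
            "alt": [v.variant_key[3] for v in verdicts],
            "passed": [v.passed for v in verdicts],
            "failed_filters": [";".join(v.failed_filters) for v in verdicts],
            "rescued_by": [";".join(v.rescued_by) for v in verdicts],
        }
    )
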