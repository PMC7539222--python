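"""DNA-truth-guided filter derivation.

RNA variants inside the DNA capture footprint are partitioned into
somatic-in-DNA / germline-in-DNA / RNA-unique by normalized-key membership,
filter configurations are scored against that truth (sensitivity on the
somatic class, specificity on everything else), and the filter-variable
space is searched exhaustively over a value grid.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional, Sequence

from .annotate import IntervalSet
from .filters import FilterConfig, evaluate_variant
from .io_core import VariantRecord, is_parsimonious

__all__ = [
    "ConcordanceLabel",
    "Concordance",
    "ScoredConfig",
    "classify_concordance",
    "concordance_percentages",
    "score_config",
    "grid_search",
]


class ConcordanceLabel(str, Enum):
    SOMATIC_IN_DNA = "somatic_in_dna"
    GERMLINE_IN_DNA = "germline_in_dna"
    RNA_UNIQUE = "rna_unique"


@dataclass(frozen=True)
class Concordance:
    variant_key: tuple
    label: ConcordanceLabel


@dataclass(frozen=True)
class ScoredConfig:
    cfg: FilterConfig
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float
    specificity: float
    objective: float


def _check_normalized(records: Sequence[VariantRecord], what: str) -> None:
    for rec in records:
        if not is_parsimonious(rec.ref, rec.alt):
            raise ValueError(
                f"{what} contains non-parsimonious allele {rec.ref}>{rec.alt} at "
                f"{rec.chrom}:{rec.pos}; normalize callsets first"
            )


def classify_concordance(
    rna: Sequence[VariantRecord],
    dna_somatic: Sequence[VariantRecord],
    dna_germline: Sequence[VariantRecord],
    regions: Optional[IntervalSet] = None,
) -> list:
    """Label each in-region RNA variant by DNA-callset membership.

    Somatic membership takes precedence over germline.  RNA variants outside
    ``regions`` (the DNA capture footprint) are excluded before labeling, so
    the three label counts partition the in-region RNA set.
    """
    _check_normalized(rna, "RNA callset")
    _check_normalized(dna_somatic, "DNA somatic callset")
    _check_normalized(dna_germline, "DNA germline callset")
    somatic_keys = {r.key for r in dna_somatic}
    germline_keys = {r.key for r in dna_germline}
    labels = []
    seen = set()
    for rec in rna:
        if regions is not None and not regions.contains(rec.chrom, rec.pos):
            continue
        if rec.key in seen:  # duplication-free: one label per unique key
            continue
        seen.add(rec.key)
        if rec.key in somatic_keys:
            label = ConcordanceLabel.SOMATIC_IN_DNA
        elif rec.key in germline_keys:
            label = ConcordanceLabel.GERMLINE_IN_DNA
        else:
            label = ConcordanceLabel.RNA_UNIQUE
        labels.append(Concordance(variant_key=rec.key, label=label))
    return labels


def concordance_percentages(labels: Sequence[Concordance], ndigits: int = 1) -> dict:
    """Partition shares as percentages, rounded half-up to ``ndigits``."""
    from .landscape import round_half_up

    total = len(labels)
    out = {}
    for label in ConcordanceLabel:
        n = sum(1 for c in labels if c.label is label)
        out[label.value] = {
            "count": n,
            "pct": round_half_up(100.0 * n / total, ndigits) if total else 0.0,
        }
    return out


def score_config(
    cfg: FilterConfig,
    labeled_rna: Sequence[tuple],  # (VariantRecord, ConcordanceLabel)
    objective: str = "youden",
    sensitivity_weight: float = 0.5,
) -> ScoredConfig:
    """Score one configuration against labeled RNA variants.

    tp/fn count somatic-in-DNA records passing/failing the filters; fp/tn
    count the pooled non-somatic records (germline-in-DNA + RNA-unique)
    passing/failing.  Default objective is Youden's J; "f1" and "weighted"
    (weighted J) are selectable.
    """
    tp = fp = fn = tn = 0
    for rec, label in labeled_rna:
        ok = evaluate_variant(rec, cfg).passed
        if label is ConcordanceLabel.SOMATIC_IN_DNA:
            tp, fn = (tp + 1, fn) if ok else (tp, fn + 1)
        else:
            fp, tn = (fp + 1, tn) if ok else (fp, tn + 1)
    if tp + fn == 0:
        raise ValueError(
            "no somatic-in-DNA records: sensitivity undefined; check the truth "
            "labels (or the fixture) supplied to score_config"
        )
    sens = tp / (tp + fn)
    spec = tn / (tn + fp) if (tn + fp) > 0 else 1.0
    if objective == "youden":
        obj = sens + spec - 1.0
    elif objective == "weighted":
        obj = 2.0 * (sensitivity_weight * sens + (1.0 - sensitivity_weight) * spec) - 1.0
    elif objective == "f1":
        obj = 2.0 * tp / (2.0 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    else:
        raise ValueError(f"unknown objective {objective!r}")
    return ScoredConfig(cfg=cfg, tp=tp, fp=fp, fn=fn, tn=tn,
                        sensitivity=sens, specificity=spec, objective=obj)


def _config_sort_key(sc: ScoredConfig) -> tuple:
    cfg = sc.cfg
    return (
        -sc.objective,
        -sc.specificity,
        -cfg.min_vaf,
        repr(cfg),
    )


def grid_search(
    grid: Mapping[str, Sequence],
    labeled_rna: Sequence[tuple],
    base: Optional[FilterConfig] = None,
    objective: str = "youden",
    budget: int = 10 ** 6,
) -> list:
    """Exhaustively score the cartesian product of the grid.

    Every grid key must be a :class:`FilterConfig` field.  Ranking is by
    objective descending with deterministic tie-breaking (higher specificity,
    then higher min_vaf, then lexicographic config repr).
    """
    base = base or FilterConfig()
    keys = sorted(grid)
    for k in keys:
        if not hasattr(base, k):
            raise ValueError(f"grid key {k!r} is not a FilterConfig field")
    n_combos = 1
    for k in keys:
        n_combos *= len(grid[k])
    if n_combos > budget:
        raise ValueError(
            f"grid has {n_combos} combinations, over budget {budget}; coarsen the grid"
        )
    scored = []
    for values in itertools.product(*(grid[k] for k in keys)):
        cfg = base.with_values(**dict(zip(keys, values)))
        scored.append(score_config(cfg, labeled_rna, objective=objective))
    scored.sort(key=_config_sort_key)
    return scored


def scored_to_frame(scored: Sequence[ScoredConfig], grid_keys: Sequence[str]):
    import pandas as pd

    rows = []
    for rank, sc in enumerate(scored, start=1):
        row = {
            "rank": rank, "objective": sc.objective,
            "sensitivity": sc.sensitivity, "specificity": sc.specificity,
            "tp": sc.tp, "fp": sc.fp, "fn": sc.fn, "tn": sc.tn,
        }
        for k in grid_keys:
            v = getattr(sc.cfg, k)
            row[k] = ";".join(sorted(v)) if isinstance(v, frozenset) else v
        rows.append(row)
    return pd.DataFrame(rows)
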