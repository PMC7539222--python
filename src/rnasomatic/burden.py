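"""Callable regions and tumor mutational burden per expressed megabase.

A sample's expressed megabases are its callable bases (depth >= 4 by
default, matching the calling step's callable definition) divided by 1e6;
TMB is non-synonymous mutations per expressed megabase, and samples are
stratified high/low against the cohort median (ties labeled high).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .io_core import DepthTrack, ValidationError, VariantRecord
from .landscape import nonsynonymous

__all__ = ["TMBRecord", "callable_regions", "compute_tmb", "stratify"]

CALLABLE_MIN_DEPTH = 4


@dataclass
class TMBRecord:
    sample_id: str
    nonsyn_count: int
    rna_mb: float
    tmb: float
    label: Optional[str] = None  # "high" | "low"


def callable_regions(track: DepthTrack, min_depth: int = CALLABLE_MIN_DEPTH):
    """Maximal merged intervals with depth >= min_depth, plus total bases."""
    keep = defaultdict(list)
    for chrom, start, end, depth in track.intervals:
        if depth < 0:
            raise ValidationError(f"negative depth on {chrom}:{start}-{end}")
        if depth >= min_depth:
            keep[chrom].append((start, end))
    merged, total = [], 0
    for chrom in sorted(keep):
        for start, end in sorted(keep[chrom]):
            if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
                prev = merged[-1]
                merged[-1] = (chrom, prev[1], max(prev[2], end))
            else:
                merged.append((chrom, start, end))
    total = sum(end - start for _, start, end in merged)
    return merged, total


def compute_tmb(
    records: Sequence[VariantRecord],
    tracks: Mapping[str, DepthTrack],
    sample_ids: Optional[Sequence[str]] = None,
    min_depth: int = CALLABLE_MIN_DEPTH,
    include_utr: bool = False,
) -> list:
    """Per-sample non-synonymous mutations per expressed megabase."""
    if sample_ids is None:
        sample_ids = sorted(tracks)
    missing = [s for s in sample_ids if s not in tracks]
    if missing:
        raise ValueError(f"samples without depth track: {missing}")
    counts = defaultdict(int)
    for rec in nonsynonymous(records, include_utr=include_utr):
        counts[rec.sample_id] += 1
    out = []
    for sample in sample_ids:
        _, bases = callable_regions(tracks[sample], min_depth=min_depth)
        rna_mb = bases / 1e6
        if rna_mb <= 0:
            raise ValueError(f"sample {sample} has zero callable bases")
        out.append(TMBRecord(
            sample_id=sample,
            nonsyn_count=counts.get(sample, 0),
            rna_mb=rna_mb,
            tmb=counts.get(sample, 0) / rna_mb,
        ))
    return out


def stratify(records: Sequence[TMBRecord], cutoff: Optional[float] = None) -> list:
    """Label each sample high/low; default cutoff is the cohort median
    (even n: mean of the middle two).  high iff tmb >= cutoff."""
    if not records:
        return []
    if cutoff is None:
        cutoff = float(np.median([r.tmb for r in records]))
    return [replace(r, label="high" if r.tmb >= cutoff else "low") for r in records]
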