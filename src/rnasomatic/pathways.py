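"""Binary pathway mutation status and its hierarchical clustering.

A pathway is mutated in a sample when at least one member gene carries a
non-synonymous variant.  Samples/pathways are clustered with Euclidean
distance and Ward linkage (the Ward.D2 update).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io_core import GeneSet, VariantRecord
from .landscape import nonsynonymous

__all__ = ["PathwayStatusMatrix", "pathway_status", "cluster_matrix", "plot_heatmap"]


@dataclass
class PathwayStatusMatrix:
    pathways: list
    samples: list
    cells: pd.DataFrame  # pathway x sample, {0,1}


def pathway_status(
    records: Sequence[VariantRecord],
    gene_sets: Sequence[GeneSet],
    sample_ids: Sequence[str],
    include_utr: bool = False,
) -> PathwayStatusMatrix:
    """Binary pathway x sample matrix; genes absent from all sets are ignored."""
    if not gene_sets:
        raise ValueError("pathway_status requires at least one gene set")
    mutated_genes = {}
    for rec in nonsynonymous(records, include_utr=include_utr):
        if rec.gene is not None:
            mutated_genes.setdefault(rec.sample_id, set()).add(rec.gene)
    cells = pd.DataFrame(
        0, index=[gs.name for gs in gene_sets], columns=list(sample_ids), dtype=int
    )
    for gs in gene_sets:
        for sample in sample_ids:
            if mutated_genes.get(sample, set()) & gs.genes:
                cells.loc[gs.name, sample] = 1
    return PathwayStatusMatrix(
        pathways=[gs.name for gs in gene_sets], samples=list(sample_ids), cells=cells
    )


@dataclass
class ClusterResult:
    row_order: list
    col_order: list
    row_linkage: Optional[np.ndarray]
    col_linkage: Optional[np.ndarray]


def _ward_order(data: np.ndarray):
    if np.allclose(data, data[0]):  # zero variance: nothing to cluster
        return None
    link = hierarchy.linkage(data, method="ward", metric="euclidean")
    order = hierarchy.leaves_list(link)
    return link, order


def cluster_matrix(matrix: PathwayStatusMatrix) -> ClusterResult:
    """Ward/Euclidean agglomerative clustering of rows and columns.

    Constant rows/columns yield a warning and identity ordering rather than a
    degenerate dendrogram.  Leaf order is deterministic (scipy index
    tie-break).
    """
    values = matrix.cells.to_numpy(dtype=float)
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("clustering needs >= 2 rows and >= 2 columns")
    row_res = _ward_order(values)
    col_res = _ward_order(values.T)
    if row_res is None:
        warnings.warn("constant pathway matrix rows: row clustering skipped")
        row_link, row_order = None, list(range(values.shape[0]))
    else:
        row_link, row_order = row_res[0], list(row_res[1])
    if col_res is None:
        warnings.warn("constant pathway matrix columns: column clustering skipped")
        col_link, col_order = None, list(range(values.shape[1]))
    else:
        col_link, col_order = col_res[0], list(col_res[1])
    return ClusterResult(
        row_order=[matrix.pathways[i] for i in row_order],
        col_order=[matrix.samples[i] for i in col_order],
        row_linkage=row_link,
        col_linkage=col_link,
    )


def plot_heatmap(matrix: PathwayStatusMatrix, result: ClusterResult, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = matrix.cells.loc[result.row_order, result.col_order]
    fig, ax = plt.subplots(figsize=(10, max(3, 0.3 * len(result.row_order))))
    ax.imshow(data.to_numpy(), aspect="auto", cmap="coolwarm", interpolation="nearest")
    ax.set_yticks(range(len(result.row_order)))
    ax.set_yticklabels(result.row_order, fontsize=6)
    ax.set_xticks([])
    ax.set_xlabel(f"{len(result.col_order)} samples")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
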