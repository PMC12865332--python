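"""QC filtering, normalization, marker scoring and doublet re-annotation.

Cells with too few detected genes are removed first, then sparsely detected
genes; expression is depth-normalized and log2-transformed; per-cell-type
marker scores are the mean log-normalized expression of a type's marker set
minus the mean over the union of all marker genes (so a per-cell additive
shift cancels); flagged doublets are re-annotated as the pair of cell types
with the two highest marker scores.
"""

from __future__ import annotations

import logging

import anndata as ad
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "qc_filter",
    "normalize_log",
    "marker_scores",
    "annotate_doublets",
    "celltype_proportions",
]


def qc_filter(
    raw: ad.AnnData, min_genes_per_cell: int = 200, min_cells_per_gene: int = 3
) -> ad.AnnData:
    """Remove low-coverage cells, then sparsely detected genes.

    A cell is kept when it detects (count > 0) at least ``min_genes_per_cell``
    genes; afterwards a gene is kept when detected in at least
    ``min_cells_per_gene`` of the retained cells. Cells are filtered before
    genes; the operation is idempotent.
    """
    counts = raw.layers.get("counts", raw.X)
    counts = np.asarray(counts)
    detected = counts > 0
    cell_keep = detected.sum(axis=1) >= min_genes_per_cell
    if not cell_keep.any():
        raise ValueError(
            f"no cell detects >= {min_genes_per_cell} genes "
            f"(min_genes_per_cell threshold removed everything)"
        )
    gene_keep = detected[cell_keep].sum(axis=0) >= min_cells_per_gene
    if not gene_keep.any():
        raise ValueError(
            f"no gene is detected in >= {min_cells_per_gene} cells "
            f"(min_cells_per_gene threshold removed everything)"
        )
    logger.info(
        "qc_filter: cells %d -> %d, then genes %d -> %d "
        "(order: cells first, then genes)",
        raw.n_obs,
        int(cell_keep.sum()),
        raw.n_vars,
        int(gene_keep.sum()),
    )
    return raw[cell_keep, gene_keep].copy()


def normalize_log(m: ad.AnnData, scale: float = 1e4) -> ad.AnnData:
    """Depth-normalize each cell to ``scale`` total counts, then log2(x + 1).

    The raw counts layer is preserved (created from ``X`` if absent).
    """
    out = m.copy()
    counts = np.asarray(
        out.layers.get("counts", out.X), dtype=float
    )
    if "counts" not in out.layers:
        out.layers["counts"] = counts.copy()
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    out.X = np.log2(counts / totals * scale + 1.0)
    return out


def marker_scores(
    m: ad.AnnData, markers: dict[str, list[str]]
) -> pd.DataFrame:
    """Per-cell scores for each cell type from its marker gene set.

    ``score(cell, type) = mean(expr over type's markers) -
    mean(expr over the union of all marker genes)``, computed on the
    log-normalized matrix. Marker genes absent from the matrix are dropped
    with a warning; a type whose markers are all absent raises.
    """
    present = set(m.var_names)
    used: dict[str, list[str]] = {}
    for ctype, genes in markers.items():
        if not genes:
            raise ValueError(f"marker set for {ctype!r} is empty")
        kept = [g for g in genes if g in present]
        dropped = sorted(set(genes) - set(kept))
        if dropped:
            logger.warning(
                "marker_scores: %d marker(s) of %s absent from matrix: %s",
                len(dropped),
                ctype,
                ", ".join(dropped[:5]),
            )
        if not kept:
            raise ValueError(
                f"no marker genes of cell type {ctype!r} present in the matrix"
            )
        used[ctype] = kept

    X = np.asarray(m.X, dtype=float)
    col = {g: i for i, g in enumerate(m.var_names)}
    union = sorted({g for genes in used.values() for g in genes})
    union_mean = X[:, [col[g] for g in union]].mean(axis=1)
    scores = {
        ctype: X[:, [col[g] for g in genes]].mean(axis=1) - union_mean
        for ctype, genes in used.items()
    }
    return pd.DataFrame(scores, index=m.obs_names)


def annotate_doublets(
    scores: pd.DataFrame, doublet_ids: list[str]
) -> pd.DataFrame:
    """Re-annotate doublets as their two highest-scoring cell types.

    Ties are broken lexicographically by type label; the pair label is
    canonical (lexicographic order, joined by "-"). Returns a frame indexed
    by cell id with ``pair``, ``type_a``, ``type_b``, ``score_a``,
    ``score_b`` (types in canonical order with their own scores).
    """
    if scores.shape[1] < 2:
        raise ValueError("need scores for at least two cell types")
    missing = [c for c in doublet_ids if c not in scores.index]
    if missing:
        raise ValueError(f"doublet ids absent from score matrix: {missing[:5]}")
    rows = []
    for cid in doublet_ids:
        row = scores.loc[cid]
        ranked = sorted(row.items(), key=lambda kv: (-kv[1], kv[0]))
        top2 = sorted(ranked[:2], key=lambda kv: kv[0])
        (ta, sa), (tb, sb) = top2
        rows.append(
            {
                "cell_id": cid,
                "pair": f"{ta}-{tb}",
                "type_a": ta,
                "type_b": tb,
                "score_a": sa,
                "score_b": sb,
            }
        )
    return pd.DataFrame(rows).set_index("cell_id")


def celltype_proportions(labels) -> pd.Series:
    """Proportion of cells per cell-type label (sums to 1).

    Accepts any iterable of labels (e.g. ``obs["cell_type"]`` or re-annotated
    doublet pair labels) or a mapping label -> count.
    """
    if isinstance(labels, dict):
        counts = pd.Series(labels, dtype=float)
    else:
        counts = pd.Series(list(labels)).value_counts().astype(float)
    total = counts.sum()
    if total == 0:
        raise ValueError("no cells to compute proportions over")
    return (counts / total).sort_index()
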