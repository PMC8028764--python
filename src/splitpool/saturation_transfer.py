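"""Sequencing-saturation curves and correlation-based label transfer.

Saturation: reads are randomly downsampled to nested fractions of the full
depth and UMIs re-collapsed, but the cell set is frozen at the barcodes
called from the full data, so each curve answers "would more sequencing
have yielded more molecules for the cells we already called?".  Nested
subsets (one shared permutation) make per-cell counts exactly monotone in
the fraction.

Label transfer: each query cell's label is borrowed from a reference
expression matrix by top-k Pearson correlation over high-variance
reference features; an assignment is made only when the cell looks more
like the reference than like its own dataset (mean top-k reference
correlation minus mean top-k within-query correlation above a margin).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quant import DigitalExpressionMatrix, collapse_umis

DEFAULT_FRACTIONS = (0.10, 0.25, 0.50, 0.75, 1.00)


@dataclass
class SaturationCurve:
    fractions: list[float]
    table: pd.DataFrame          # fraction, median_umis, median_genes
    per_cell: dict[float, pd.DataFrame]  # fraction -> (barcode, n_umis, n_genes)
    seed: int


def saturation(
    read_assignments: pd.DataFrame,
    fractions=DEFAULT_FRACTIONS,
    fixed_barcodes: list[str] | None = None,
    seed: int = 0,
    collapse: str = "greedy",
) -> SaturationCurve:
    """Downsample the read-level assignment table and recompute per-cell stats.

    ``read_assignments`` columns: ``barcode``, ``gene``, ``umi`` (one row
    per read).  Subsets are nested under a single seeded permutation, so
    for every cell the UMI and gene counts at a smaller fraction never
    exceed those at a larger one.
    """
    fractions = sorted(float(f) for f in fractions)
    for f in fractions:
        if not 0 < f <= 1:
            raise ValueError(f"fraction {f} outside (0, 1]")
    if fixed_barcodes is None:
        fixed_barcodes = sorted(read_assignments["barcode"].unique())

    n = len(read_assignments)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fixed = list(fixed_barcodes)

    rows = []
    per_cell: dict[float, pd.DataFrame] = {}
    for f in fractions:
        take = math.ceil(f * n)
        sub = read_assignments.iloc[perm[:take]]
        umi_reads = (
            sub.groupby(["barcode", "gene", "umi"], sort=False).size().reset_index(name="reads")
        )
        per_gene = (
            umi_reads.groupby(["barcode", "gene"], sort=False)
            .apply(lambda g: collapse_umis(list(zip(g["umi"], g["reads"])), method=collapse),
                   include_groups=False)
            .rename("n_umis")
            .reset_index()
        )
        agg = per_gene.groupby("barcode").agg(
            n_umis=("n_umis", "sum"), n_genes=("gene", "nunique")
        )
        cell_stats = agg.reindex(fixed).fillna(0).astype(int).reset_index()
        cell_stats.columns = ["barcode", "n_umis", "n_genes"]
        per_cell[f] = cell_stats
        rows.append(
            {
                "fraction": f,
                "median_umis": float(cell_stats["n_umis"].median()),
                "median_genes": float(cell_stats["n_genes"].median()),
            }
        )
    return SaturationCurve(
        fractions=fractions, table=pd.DataFrame(rows), per_cell=per_cell, seed=seed
    )


def _normalize_cp10k_log1p(counts: np.ndarray) -> np.ndarray:
    """Counts-per-10k depth normalisation then log1p; cells are columns."""
    depth = counts.sum(axis=0, keepdims=True)
    depth[depth == 0] = 1
    return np.log1p(counts / depth * 1e4)


def label_transfer(
    query: DigitalExpressionMatrix,
    reference: DigitalExpressionMatrix,
    ref_labels: list[str],
    k: int = 20,
    margin: float = 0.0,
    n_features: int = 2000,
) -> pd.DataFrame:
    """Transfer labels from reference cells to query cells by correlation.

    Features are the ``n_features`` highest-variance genes of the
    normalised reference, intersected with the query's genes.  For each
    query cell, ``reference_score`` is the mean of its top-k Pearson
    correlations to reference cells (whose majority label it inherits) and
    ``self_score`` the mean of its top-k correlations to *other* query
    cells; the label is assigned when their difference exceeds ``margin``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(ref_labels) != len(reference.barcodes):
        raise ValueError("ref_labels length does not match reference barcodes")

    shared = sorted(set(query.genes) & set(reference.genes))
    if not shared:
        raise ValueError("query and reference share no gene identifiers")
    q_idx = {g: i for i, g in enumerate(query.genes)}
    r_idx = {g: i for i, g in enumerate(reference.genes)}
    q = _normalize_cp10k_log1p(query.to_dense().astype(float)[[q_idx[g] for g in shared]])
    r = _normalize_cp10k_log1p(reference.to_dense().astype(float)[[r_idx[g] for g in shared]])

    var = r.var(axis=1)
    order = np.argsort(var)[::-1]
    feat = np.sort(order[: min(n_features, len(shared))])
    q, r = q[feat], r[feat]

    def standardize(mat: np.ndarray) -> np.ndarray:
        mat = mat - mat.mean(axis=0, keepdims=True)
        sd = mat.std(axis=0, keepdims=True)
        sd[sd == 0] = 1
        return mat / sd

    qz, rz = standardize(q), standardize(r)
    nf = q.shape[0]
    corr_ref = qz.T @ rz / nf          # query cells x reference cells
    corr_self = qz.T @ qz / nf         # query cells x query cells
    np.fill_diagonal(corr_self, -np.inf)

    labels = np.asarray(ref_labels)
    out = []
    k_ref = min(k, corr_ref.shape[1])
    k_self = min(k, max(1, corr_self.shape[1] - 1))
    for i, barcode in enumerate(query.barcodes):
        top_ref = np.argsort(corr_ref[i])[::-1][:k_ref]
        ref_score = float(corr_ref[i, top_ref].mean())
        top_self = np.argsort(corr_self[i])[::-1][:k_self]
        self_vals = corr_self[i, top_self]
        self_score = float(self_vals[np.isfinite(self_vals)].mean()) if np.isfinite(self_vals).any() else 0.0
        top_labels, counts = np.unique(labels[top_ref], return_counts=True)
        best_label = str(sorted(zip(-counts, top_labels))[0][1])
        out.append(
            {
                "query_barcode": barcode,
                "best_reference_label": best_label,
                "reference_score": ref_score,
                "self_score": self_score,
                "assigned": ref_score - self_score > margin,
            }
        )
    return pd.DataFrame(out)
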