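"""Barnyard species-mixing QC, cell filtering and doublet calibration.

In a two-species mixing experiment a real cell's UMIs come almost entirely
from one species, so a barcode sharing more than a fraction theta (default
0.10, strictly greater-than) of its UMIs with its minority species exposes
either a cross-species doublet or a barcode collision.  Cross-species
events are directly observable; since a doublet pairs species at random,
the total doublet load is the cross-species count scaled by 1/(2*pA*pB).

Cell filtering follows the mixing experiment's accounting: call cells at
>= 125 detected genes, then exclude barcodes with more than 5000 UMIs
(likely aggregates) or flagged as collisions; retained = passed - excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .quant import DigitalExpressionMatrix


@dataclass
class FilterLedger:
    """The cell-filtering accounting identity.

    ``n_retained`` is derived, never stored, so the identity
    ``retained = passed - excluded`` holds by construction.  The combined
    exclusion count mirrors the upstream accounting convention (high-UMI
    and collision exclusions folded together); the two sub-counts are kept
    for diagnostics.
    """

    n_pass_gene_threshold: int
    n_excluded_high_umi_or_collision: int
    n_excluded_high_umi: int = 0
    n_excluded_collision: int = 0
    min_genes: int = 125
    max_umi: int = 5000
    theta: float = 0.10

    @property
    def n_retained(self) -> int:
        return self.n_pass_gene_threshold - self.n_excluded_high_umi_or_collision

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["n_retained"] = self.n_retained
        return d


@dataclass
class DoubletEstimate:
    n_cross_collisions: int
    p_a: float
    p_b: float
    n_barcodes: int
    estimated_total_doublets: float
    estimated_doublet_rate: float
    ci_low_rate: float
    ci_high_rate: float
    undefined: bool = False


def barnyard_from_counts(
    counts: pd.DataFrame, theta: float = 0.10
) -> pd.DataFrame:
    """Barnyard records from a per-barcode two-species UMI table.

    ``counts`` columns: ``barcode`` plus exactly two ``umis_*`` columns.
    Adds ``minority_fraction`` and ``is_collision`` (strictly > theta).
    """
    if not 0 < theta < 0.5:
        raise ValueError("theta must lie in (0, 0.5)")
    umi_cols = [c for c in counts.columns if c.startswith("umis_")]
    if len(umi_cols) != 2:
        raise ValueError("expected exactly two umis_<species> columns")
    a = counts[umi_cols[0]].to_numpy(dtype=float)
    b = counts[umi_cols[1]].to_numpy(dtype=float)
    total = a + b
    keep = total > 0
    rec = counts.loc[keep, ["barcode"] + umi_cols].reset_index(drop=True).copy()
    minority = np.minimum(a[keep], b[keep]) / total[keep]
    rec["minority_fraction"] = minority
    rec["is_collision"] = minority > theta
    return rec


def barnyard(
    matrix_a: DigitalExpressionMatrix,
    matrix_b: DigitalExpressionMatrix,
    theta: float = 0.10,
) -> pd.DataFrame:
    """Barnyard records over the union of the two matrices' barcodes."""
    sp_a, sp_b = matrix_a.species_id, matrix_b.species_id
    ua = dict(zip(matrix_a.barcodes, matrix_a.umis_per_barcode()))
    ub = dict(zip(matrix_b.barcodes, matrix_b.umis_per_barcode()))
    barcodes = sorted(set(ua) | set(ub))
    df = pd.DataFrame(
        {
            "barcode": barcodes,
            f"umis_{sp_a}": [int(ua.get(b, 0)) for b in barcodes],
            f"umis_{sp_b}": [int(ub.get(b, 0)) for b in barcodes],
        }
    )
    return barnyard_from_counts(df, theta=theta)


def apply_filters(
    matrix: DigitalExpressionMatrix,
    barnyard_records: pd.DataFrame,
    min_genes: int = 125,
    max_umi: int = 5000,
    theta: float = 0.10,
) -> tuple[DigitalExpressionMatrix, FilterLedger]:
    """Cell calling and exclusion with full accounting.

    Keeps barcodes detecting >= ``min_genes`` genes in this species'
    matrix, then excludes those with total UMIs > ``max_umi`` or flagged
    as collisions in the barnyard records.
    """
    genes_per = matrix.genes_per_barcode()
    umis_per = matrix.umis_per_barcode()
    collided = set(barnyard_records.loc[barnyard_records["is_collision"], "barcode"])

    passed = [
        (b, int(u)) for b, g, u in zip(matrix.barcodes, genes_per, umis_per)
        if g >= min_genes
    ]
    n_high = sum(1 for b, u in passed if u > max_umi)
    n_coll = sum(1 for b, u in passed if u <= max_umi and b in collided)
    kept = [b for b, u in passed if u <= max_umi and b not in collided]
    ledger = FilterLedger(
        n_pass_gene_threshold=len(passed),
        n_excluded_high_umi_or_collision=n_high + n_coll,
        n_excluded_high_umi=n_high,
        n_excluded_collision=n_coll,
        min_genes=min_genes,
        max_umi=max_umi,
        theta=theta,
    )
    assert ledger.n_retained == len(kept)
    return matrix.subset_barcodes(kept), ledger


def estimate_doublets(
    records: pd.DataFrame,
    proportions: tuple[float, float] | None = None,
) -> DoubletEstimate:
    """Doublet load calibrated from observed cross-species collisions.

    Species proportions default to the majority-species assignment of the
    non-collision barcodes (ties go to the first species column, i.e.
    lexicographically by column order).  The extrapolation divides the
    cross-species count by the probability 2*pA*pB that a random doublet
    pairs the two species; a Clopper-Pearson 95% interval on the collision
    count propagates to the rate.
    """
    if len(records) == 0:
        raise ValueError("no barcodes observed")
    umi_cols = [c for c in records.columns if c.startswith("umis_")]
    a = records[umi_cols[0]].to_numpy(dtype=float)
    b = records[umi_cols[1]].to_numpy(dtype=float)
    n_cross = int(records["is_collision"].sum())
    n_barcodes = len(records)

    if proportions is None:
        singlet = ~records["is_collision"].to_numpy()
        maj_a = (a >= b) & singlet
        maj_b = (b > a) & singlet
        n_sing = maj_a.sum() + maj_b.sum()
        if n_sing == 0:
            proportions = (0.5, 0.5)
        else:
            proportions = (maj_a.sum() / n_sing, maj_b.sum() / n_sing)
    p_a, p_b = proportions

    if p_a * p_b == 0:
        return DoubletEstimate(
            n_cross_collisions=n_cross, p_a=p_a, p_b=p_b, n_barcodes=n_barcodes,
            estimated_total_doublets=float("nan"),
            estimated_doublet_rate=float("nan"),
            ci_low_rate=float("nan"), ci_high_rate=float("nan"), undefined=True,
        )
    scale = 1.0 / (2 * p_a * p_b)
    total = n_cross * scale
    # Clopper-Pearson on the collision fraction among observed barcodes
    if n_cross == 0:
        lo = 0.0
    else:
        lo = scipy.stats.beta.ppf(0.025, n_cross, n_barcodes - n_cross + 1)
    if n_cross == n_barcodes:
        hi = 1.0
    else:
        hi = scipy.stats.beta.ppf(0.975, n_cross + 1, n_barcodes - n_cross)
    return DoubletEstimate(
        n_cross_collisions=n_cross,
        p_a=float(p_a),
        p_b=float(p_b),
        n_barcodes=n_barcodes,
        estimated_total_doublets=total,
        estimated_doublet_rate=total / n_barcodes,
        ci_low_rate=lo * scale,
        ci_high_rate=hi * scale,
    )
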