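"""Barnyard species-mixing QC, filter accounting and doublet calibration."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse

from splitpool.quant import DigitalExpressionMatrix
from splitpool.simulate import make_references, simulate_cells, umi_tallies
from splitpool.species_qc import (
    FilterLedger,
    apply_filters,
    barnyard,
    barnyard_from_counts,
    estimate_doublets,
)

from conftest import clean_config


def counts_df(rows):
    return pd.DataFrame(rows, columns=["barcode", "umis_a", "umis_b"])


class TestBarnyard:
    def test_exactly_ten_percent_is_not_a_collision(self):
        rec = barnyard_from_counts(counts_df([("b1", 90, 10)]))
        assert rec.loc[0, "minority_fraction"] == pytest.approx(0.10)
        assert not rec.loc[0, "is_collision"]

    def test_just_over_ten_percent_is_a_collision(self):
        rec = barnyard_from_counts(counts_df([("b1", 89, 11)]))
        assert rec.loc[0, "is_collision"]

    @pytest.mark.parametrize("theta", [0.0, 0.5, 0.6])
    def test_invalid_threshold_rejected(self, theta):
        with pytest.raises(ValueError):
            barnyard_from_counts(counts_df([("b1", 1, 1)]), theta=theta)

    def test_collision_rate_invariant_under_species_swap(self):
        rng = np.random.default_rng(97)
        rows = [(f"b{i}", int(a), int(b))
                for i, (a, b) in enumerate(zip(rng.poisson(50, 300), rng.poisson(8, 300)))]
        fwd = barnyard_from_counts(counts_df(rows))
        swapped = counts_df([(b, y, x) for b, x, y in rows])
        rev = barnyard_from_counts(swapped)
        assert fwd["is_collision"].sum() == rev["is_collision"].sum()
        assert np.allclose(fwd["minority_fraction"], rev["minority_fraction"])

    def test_raising_theta_never_increases_collisions(self):
        rng = np.random.default_rng(101)
        rows = [(f"b{i}", int(a), int(b))
                for i, (a, b) in enumerate(zip(rng.poisson(40, 200), rng.poisson(10, 200)))]
        counts = [
            barnyard_from_counts(counts_df(rows), theta=t)["is_collision"].sum()
            for t in (0.05, 0.10, 0.20, 0.40)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_matrix_union_includes_barcodes_absent_from_one_species(self):
        ma = DigitalExpressionMatrix(
            "a", ["a_g0"], ["BC1"], scipy.sparse.csr_matrix(np.array([[5]])))
        mb = DigitalExpressionMatrix(
            "b", ["b_g0"], ["BC2"], scipy.sparse.csr_matrix(np.array([[7]])))
        rec = barnyard(ma, mb)
        assert set(rec["barcode"]) == {"BC1", "BC2"}
        assert not rec["is_collision"].any()

    def test_true_cross_species_doublets_are_flagged(self, refs_small):
        """Truth-table oracle: barnyard collision flags agree with a direct
        recomputation of minority fractions from simulated truth."""
        cfg = clean_config(n_cells_per_species=2000, doublet_rate=0.08, seed=103)
        truth = simulate_cells(refs_small, cfg)
        tal = umi_tallies(truth)
        rec = barnyard_from_counts(tal).set_index("barcode")
        a, b = tal.iloc[:, 1].to_numpy(), tal.iloc[:, 2].to_numpy()
        expected = np.minimum(a, b) / (a + b) > 0.10
        assert (rec["is_collision"].to_numpy() == expected).all()
        # balanced cross-species doublets should essentially all be caught
        balanced = truth.cells[truth.cells["is_cross_species"]]
        caught = rec.loc[
            [bc for bc in balanced["barcode"] if bc in rec.index], "is_collision"
        ]
        assert caught.mean() > 0.85


class TestApplyFilters:
    def make_matrix(self, n_cells=30, n_genes=200, seed=0, depth=3000):
        rng = np.random.default_rng(seed)
        counts = rng.multinomial(depth, np.ones(n_genes) / n_genes, size=n_cells).T
        return DigitalExpressionMatrix(
            "a", [f"a_g{i:04d}" for i in range(n_genes)],
            [f"BC{i:03d}" for i in range(n_cells)],
            scipy.sparse.csr_matrix(counts),
        )

    def test_ledger_identity_on_worked_accounting(self):
        assert FilterLedger(19_975, 234).n_retained == 19_741
        assert FilterLedger(14_263, 177).n_retained == 14_086

    def test_all_cells_below_gene_threshold_gives_empty_matrix(self):
        mat = self.make_matrix(n_cells=5, depth=50)
        rec = barnyard_from_counts(counts_df([(b, 50, 0) for b in mat.barcodes]))
        filtered, ledger = apply_filters(mat, rec, min_genes=125)
        assert ledger.n_pass_gene_threshold == 0 and ledger.n_retained == 0
        assert filtered.barcodes == []

    def test_high_umi_and_collision_exclusions_are_separated(self):
        mat = self.make_matrix(n_cells=10, depth=3000, seed=1)
        rows = [(b, 3000, 0) for b in mat.barcodes]
        rows[0] = (mat.barcodes[0], 2000, 1000)  # collision
        rec = barnyard_from_counts(counts_df(rows))
        # inflate one barcode's UMIs above the ceiling
        dense = mat.to_dense()
        dense[:, 1] *= 3  # 9000 UMIs > 5000
        mat2 = DigitalExpressionMatrix("a", mat.genes, mat.barcodes,
                                       scipy.sparse.csr_matrix(dense))
        filtered, ledger = apply_filters(mat2, rec, min_genes=125, max_umi=5000)
        assert ledger.n_excluded_high_umi == 1
        assert ledger.n_excluded_collision == 1
        assert ledger.n_excluded_high_umi_or_collision == 2
        assert ledger.n_retained == 8 == len(filtered.barcodes)

    def test_raising_min_genes_never_increases_pass_count(self):
        mat = self.make_matrix(n_cells=40, depth=300, seed=2)
        rec = barnyard_from_counts(counts_df([(b, 300, 0) for b in mat.barcodes]))
        passes = [
            apply_filters(mat, rec, min_genes=g)[1].n_pass_gene_threshold
            for g in (50, 125, 200, 260)
        ]
        assert passes == sorted(passes, reverse=True)


class TestEstimateDoublets:
    def test_zero_collisions_means_zero_doublets(self):
        rec = barnyard_from_counts(counts_df([("b1", 100, 0), ("b2", 0, 80)]))
        est = estimate_doublets(rec)
        assert est.n_cross_collisions == 0
        assert est.estimated_total_doublets == 0

    def test_balanced_formula(self):
        est_rows = [(f"s{i}", 100, 0) for i in range(500)]
        est_rows += [(f"t{i}", 0, 100) for i in range(500)]
        est_rows += [(f"c{i}", 50, 50) for i in range(50)]
        est = estimate_doublets(barnyard_from_counts(counts_df(est_rows)))
        assert est.n_cross_collisions == 50
        assert est.p_a == pytest.approx(0.5)
        assert est.estimated_total_doublets == pytest.approx(100)

    def test_single_species_estimate_flagged_undefined(self):
        rec = barnyard_from_counts(counts_df([("b1", 100, 0), ("b2", 90, 0)]))
        est = estimate_doublets(rec, proportions=(1.0, 0.0))
        assert est.undefined

    def test_parameter_recovery_at_small_scale(self, refs_small):
        """Mean recovered rate over seeds within 25% of the simulated 5%
        doublet rate (the tighter full-scale check runs in acceptance)."""
        rates = []
        for seed in range(5):
            cfg = clean_config(n_cells_per_species=4000, doublet_rate=0.05, seed=200 + seed)
            truth = simulate_cells(refs_small, cfg)
            rec = barnyard_from_counts(umi_tallies(truth))
            rates.append(estimate_doublets(rec).estimated_doublet_rate)
        assert abs(np.mean(rates) - 0.05) / 0.05 < 0.25
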