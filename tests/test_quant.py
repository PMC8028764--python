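"""Unique-k-mer gene assignment, UMI collapse and matrix construction."""

import random
from collections import Counter

import numpy as np
import pytest

from splitpool.quant import (
    MULTIMAP,
    UNASSIGNED,
    assign_read,
    build_index,
    build_matrix,
    collapse_umis,
)
from splitpool.simulate import SpeciesReference, make_references

from conftest import naive_greedy_collapse, truth_census


class TestBuildIndex:
    def test_identical_references_share_every_kmer(self):
        seq = "ACGTTGCA" * 30
        ra = SpeciesReference("a", [("a_g0", seq)])
        rb = SpeciesReference("b", [("b_g0", seq)])
        index = build_index((ra, rb), k=31)
        assert index.n_kmers == 0

    def test_repetitive_gene_census(self):
        """'ACGT' * 50 has only 4 distinct 31-mers (period-4 repeats);
        verified against a brute-force census."""
        seq = "ACGT" * 50
        other = "".join(random.Random(3).choice("ACGT") for _ in range(200))
        ra = SpeciesReference("a", [("a_g0", seq)])
        rb = SpeciesReference("b", [("b_g0", other)])
        index = build_index((ra, rb), k=31)
        census = Counter(seq[i : i + 31] for i in range(len(seq) - 30))
        shared = {km for km in census if km in other}
        own = {km for km in index.kmer_to_gene if index.kmer_to_gene[km] == "a_g0"}
        assert own == set(census) - shared
        assert len(set(census)) == 4

    def test_disjoint_random_references_nearly_fully_indexed(self):
        refs = make_references(30, (200, 400), seed=5)
        index = build_index(refs, k=31)
        total = sum(
            len(seq) - 30 for ref in refs for _, seq in ref.transcripts
        )
        distinct = len({
            seq[i : i + 31]
            for ref in refs for _, seq in ref.transcripts
            for i in range(len(seq) - 30)
        })
        assert index.n_kmers / distinct >= 0.99
        assert index.n_kmers <= total

    @pytest.mark.parametrize("k", [30, 13, 65])
    def test_invalid_k_rejected(self, k):
        refs = make_references(2, (200, 200), seed=1)
        with pytest.raises(ValueError):
            build_index(refs, k=k)

    def test_k_longer_than_shortest_transcript_rejected(self):
        ra = SpeciesReference("a", [("a_g0", "ACGT" * 10)])  # 40 nt
        rb = SpeciesReference("b", [("b_g0", "TTGGCCAA" * 5)])
        with pytest.raises(ValueError, match="shortest"):
            build_index((ra, rb), k=63)


class TestAssignRead:
    def test_clean_read_assigned_to_source_gene(self, refs_small, clean_run):
        truth_genes = clean_run["read_truth"].set_index("read_id")["gene_id"]
        for t in clean_run["tagged"][:300]:
            assert assign_read(t.cdna_seq, clean_run["index"]) == truth_genes[t.read_id]

    def test_chimeric_half_and_half_read_multimaps(self, refs_small, clean_run):
        (g1, s1), (g2, s2) = refs_small[0].transcripts[0], refs_small[1].transcripts[0]
        chimera = s1[:60] + s2[:60]
        assert assign_read(chimera, clean_run["index"]) == MULTIMAP

    def test_read_without_indexed_kmers_unassigned(self, clean_run):
        assert assign_read("A" * 60, clean_run["index"]) == UNASSIGNED

    def test_agrees_with_substring_scan_oracle_under_errors(self, refs_small, layout, whitelists):
        """At a 1% error rate, unique-k-mer voting agrees with a full
        substring-location oracle on >= 99.9% of assigned reads."""
        from conftest import clean_config
        from splitpool.simulate import generate_reads, simulate_cells
        from splitpool.quant import build_index

        cfg = clean_config(n_cells_per_species=20, error_rate=0.01, seed=73)
        truth = simulate_cells(refs_small, cfg, whitelists=whitelists)
        pairs, read_truth = generate_reads(truth, refs_small, layout, cfg)
        index = build_index(refs_small, k=31)
        truth_genes = read_truth.set_index("read_id")["gene_id"]
        n_assigned = n_correct = 0
        for rid, seq1, *_ in (p[:5] for p in pairs):
            gene = assign_read(seq1, index)
            if gene in (MULTIMAP, UNASSIGNED):
                continue
            n_assigned += 1
            n_correct += gene == truth_genes[rid]
        assert n_assigned > 0
        assert n_correct / n_assigned >= 0.999


class TestCollapseUmis:
    def test_single_umi(self):
        assert collapse_umis([("AAAA", 10)]) == 1

    def test_minor_neighbour_absorbed(self):
        assert collapse_umis([("AAAA", 10), ("AAAT", 1), ("GGGG", 5)]) == 2

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError):
            collapse_umis([("AAAA", 1), ("AAAAA", 1)])

    def test_matches_independent_naive_implementation(self):
        rng = np.random.default_rng(79)
        for _ in range(200):
            n = rng.integers(1, 60)
            umis = [
                "".join("ACGT"[b] for b in rng.integers(0, 4, 4))
                for _ in range(n)
            ]
            counts = rng.geometric(0.3, size=n)
            multiset = list(zip(umis, counts.tolist()))
            assert collapse_umis(multiset) == naive_greedy_collapse(multiset)

    def test_component_collapse_never_exceeds_greedy(self):
        rng = np.random.default_rng(83)
        for _ in range(50):
            n = rng.integers(1, 40)
            multiset = [
                ("".join("ACGT"[b] for b in rng.integers(0, 4, 4)), int(c))
                for c in rng.geometric(0.3, size=n)
            ]
            assert collapse_umis(multiset, "components") <= collapse_umis(multiset, "greedy")


class TestBuildMatrix:
    def test_below_creation_threshold_matrix_is_empty(self):
        rows = [("BC1", "AAAAAAAAAA", "a_g0", "a"),
                ("BC1", "CCCCCCCCCC", "a_g1", "a"),
                ("BC1", "GGGGGGGGGG", "a_g2", "a")]
        mats = build_matrix(rows, creation_min_genes=100)
        assert mats["a"].barcodes == []

    def test_matrix_totals_equal_truth_census_at_threshold_one(self, clean_run):
        mats = build_matrix(clean_run["assigned_rows"], creation_min_genes=1)
        census = truth_census(clean_run["truth"], clean_run["read_truth"])
        got = {}
        for sp, dem in mats.items():
            dense = dem.to_dense()
            for gi, gene in enumerate(dem.genes):
                for bi, bc in enumerate(dem.barcodes):
                    if dense[gi, bi]:
                        got[(sp, bc, gene)] = int(dense[gi, bi])
        assert got == census

    def test_invariant_to_read_order(self, clean_run):
        rows = list(clean_run["assigned_rows"])
        shuffled = list(rows)
        random.Random(89).shuffle(shuffled)
        m1 = build_matrix(rows, creation_min_genes=1)
        m2 = build_matrix(shuffled, creation_min_genes=1)
        for sp in m1:
            assert m1[sp].genes == m2[sp].genes
            assert m1[sp].barcodes == m2[sp].barcodes
            assert (m1[sp].counts != m2[sp].counts).nnz == 0

    def test_umi_counts_never_exceed_read_counts(self, clean_run):
        mats = build_matrix(clean_run["assigned_rows"], creation_min_genes=1)
        reads_per = Counter(
            (sp, bc) for bc, _u, _g, sp in clean_run["assigned_rows"]
        )
        for sp, dem in mats.items():
            for bc, total in zip(dem.barcodes, dem.umis_per_barcode()):
                assert total <= reads_per[(sp, bc)]

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning):
            mats = build_matrix([], creation_min_genes=1)
        assert mats == {}

    def test_mtx_round_trip(self, clean_run, tmp_path):
        from splitpool.quant import DigitalExpressionMatrix

        mats = build_matrix(clean_run["assigned_rows"], creation_min_genes=1)
        sp = sorted(mats)[0]
        mats[sp].save_mtx(tmp_path)
        loaded = DigitalExpressionMatrix.load_mtx(tmp_path, species_id=sp)
        assert loaded.genes == mats[sp].genes
        assert loaded.barcodes == mats[sp].barcodes
        assert (loaded.counts != mats[sp].counts).nnz == 0
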