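"""Shared fixtures: small references, layouts, whitelists and a clean
(zero-corruption) simulated run reused across test modules."""

from __future__ import annotations

from collections import defaultdict

import pandas as pd
import pytest

from splitpool.layout import BarcodeLayout, WhitelistSet
from splitpool.quant import assign_reads, build_index
from splitpool.demux import tag_reads
from splitpool.simulate import (
    SimConfig,
    generate_reads,
    make_references,
    simulate_cells,
)


@pytest.fixture(scope="session")
def layout() -> BarcodeLayout:
    return BarcodeLayout.default()


@pytest.fixture(scope="session")
def whitelists() -> WhitelistSet:
    return WhitelistSet.generate(seed=11)


@pytest.fixture(scope="session")
def refs_small():
    return make_references(40, (200, 600), seed=17)


def clean_config(**overrides) -> SimConfig:
    """A corruption-free configuration (no errors, truncation, chimeras or
    ambient background) for identity-style tests."""
    base = dict(
        n_cells_per_species=40,
        reads_per_cell_mean=80,
        doublet_rate=0.0,
        ambient_fraction=0.0,
        error_rate=0.0,
        truncation_rate=0.0,
        chimera_rate=0.0,
        seed=23,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def clean_run(refs_small, layout, whitelists):
    """Simulate -> demux -> assign a corruption-free batch once per session.

    Returns a dict with the truth table, raw pairs, tagged reads, assigned
    rows and the read-level assignment table used by saturation tests.
    """
    cfg = clean_config()
    truth = simulate_cells(refs_small, cfg, whitelists=whitelists)
    pairs, read_truth = generate_reads(truth, refs_small, layout, cfg)
    tagged = []
    for tag in sorted({p[5] for p in pairs}):
        sub = [p[:5] for p in pairs if p[5] == tag]
        tg, rep = tag_reads(sub, layout, whitelists, tag)
        assert rep.n_tagged == rep.n_input
        tagged.extend(tg)
    index = build_index(refs_small, k=31)
    rows, n_multi, n_un = assign_reads(tagged, index)
    assignments = pd.DataFrame(rows, columns=["barcode", "umi", "gene", "species"])
    return {
        "config": cfg,
        "truth": truth,
        "read_truth": read_truth,
        "pairs": pairs,
        "tagged": tagged,
        "index": index,
        "assigned_rows": rows,
        "n_multimap": n_multi,
        "n_unassigned": n_un,
        "assignments": assignments,
    }


def naive_greedy_collapse(umis_with_counts) -> int:
    """Independent re-implementation of the count-descending Hamming-1
    absorption rule, used as a second-implementation oracle."""
    ordered = sorted(umis_with_counts, key=lambda uc: (-uc[1], uc[0]))
    accepted: list[str] = []
    for umi, _count in ordered:
        absorbed = False
        for kept in accepted:
            mismatches = sum(1 for a, b in zip(umi, kept) if a != b)
            if mismatches <= 1:
                absorbed = True
                break
        if not absorbed:
            accepted.append(umi)
    return len(accepted)


def truth_census(truth, read_truth) -> dict:
    """Expected matrix entries {(species, barcode, gene): n_molecules}
    straight from ground truth, with the same Hamming-1 collapse applied
    by an independent naive implementation."""
    barcode_of = truth.cells.set_index("cell_id")["barcode"]
    reads_per_umi: dict = defaultdict(lambda: defaultdict(int))
    for row in read_truth.itertuples(index=False):
        key = (row.species, barcode_of[row.cell_id], row.gene_id)
        reads_per_umi[key][row.umi] += 1
    return {
        key: naive_greedy_collapse(list(umis.items()))
        for key, umis in reads_per_umi.items()
    }
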