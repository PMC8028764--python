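"""Gene assignment, UMI collapse and digital expression matrices.

Reads are assigned to genes by unique k-mers: the index keeps every k-mer
that occurs in exactly one gene across the concatenated two-species gene
set, so a read voting for one gene is assigned, a read voting for two or
more is a multimapper (dropped), and a read with no indexed k-mer is
unassigned.  Mapping both species together is what makes cross-species
barcode collisions measurable downstream.

UMIs within a (gene, cell barcode) group are collapsed at Hamming
distance <= 1 with the standard digital-expression greedy rule: process
UMIs by descending read support (ties lexicographic) and absorb any UMI
within distance 1 of an already-accepted one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse

from .demux import TaggedRead

UNASSIGNED = "__unassigned__"
MULTIMAP = "__multimap__"


@dataclass
class KmerIndex:
    k: int
    kmer_to_gene: dict[str, str]
    gene_species: dict[str, str]

    @property
    def n_kmers(self) -> int:
        return len(self.kmer_to_gene)


def build_index(refs, k: int = 31) -> KmerIndex:
    """Index k-mers unique to one gene across both references."""
    if k % 2 == 0 or not 15 <= k <= 63:
        raise ValueError("k must be odd and in [15, 63]")
    shortest = min(len(seq) for ref in refs for _, seq in ref.transcripts)
    if k > shortest:
        raise ValueError(f"k={k} exceeds shortest transcript length {shortest}")
    owner: dict[str, str] = {}
    shared: set[str] = set()
    gene_species: dict[str, str] = {}
    for ref in refs:
        for gid, seq in ref.transcripts:
            if gid in gene_species:
                raise ValueError(f"gene id {gid} present in both references")
            gene_species[gid] = ref.species_id
            for i in range(len(seq) - k + 1):
                km = seq[i : i + k]
                if km in shared:
                    continue
                prev = owner.get(km)
                if prev is None:
                    owner[km] = gid
                elif prev != gid:
                    del owner[km]
                    shared.add(km)
    return KmerIndex(k=k, kmer_to_gene=owner, gene_species=gene_species)


def assign_read(cdna_seq: str, index: KmerIndex) -> str:
    """Gene id, or UNASSIGNED / MULTIMAP, by unique-k-mer vote."""
    k = index.k
    if len(cdna_seq) < k:
        return UNASSIGNED
    lookup = index.kmer_to_gene
    hit: str | None = None
    for i in range(len(cdna_seq) - k + 1):
        gene = lookup.get(cdna_seq[i : i + k])
        if gene is None:
            continue
        if hit is None:
            hit = gene
        elif gene != hit:
            return MULTIMAP
    return hit if hit is not None else UNASSIGNED


def _hamming_le1(a: str, b: str) -> bool:
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > 1:
                return False
    return True


def collapse_umis(umis_with_counts, method: str = "greedy") -> int:
    """Number of distinct molecules after Hamming-1 collapse.

    ``greedy`` (default) absorbs into already-accepted UMIs in descending
    read-count order; ``components`` counts connected components of the
    distance-1 graph (for sensitivity analysis).
    """
    items = list(umis_with_counts)
    if not items:
        return 0
    lengths = {len(u) for u, _ in items}
    if len(lengths) != 1:
        raise ValueError("mixed UMI lengths")
    if method == "greedy":
        items.sort(key=lambda uc: (-uc[1], uc[0]))
        accepted: list[str] = []
        for umi, _ in items:
            if not any(_hamming_le1(umi, a) for a in accepted):
                accepted.append(umi)
        return len(accepted)
    if method == "components":
        umis = sorted({u for u, _ in items})
        parent = list(range(len(umis)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(umis)):
            for j in range(i + 1, len(umis)):
                if _hamming_le1(umis[i], umis[j]):
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[rj] = ri
        return len({find(i) for i in range(len(umis))})
    raise ValueError(f"unknown collapse method {method!r}")


@dataclass
class DigitalExpressionMatrix:
    """Genes x cell-barcodes UMI counts for one species."""

    species_id: str
    genes: list[str]
    barcodes: list[str]
    counts: scipy.sparse.csr_matrix  # genes x barcodes
    creation_min_genes: int = 100

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError("counts shape does not match gene/barcode lists")
        if (self.counts.data < 0).any():
            raise ValueError("negative counts")

    @property
    def total_umis(self) -> int:
        return int(self.counts.sum())

    def genes_per_barcode(self) -> np.ndarray:
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def umis_per_barcode(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def subset_barcodes(self, keep: list[str]) -> "DigitalExpressionMatrix":
        index = {b: j for j, b in enumerate(self.barcodes)}
        cols = [index[b] for b in keep]
        return DigitalExpressionMatrix(
            species_id=self.species_id,
            genes=list(self.genes),
            barcodes=list(keep),
            counts=self.counts[:, cols].tocsr(),
            creation_min_genes=self.creation_min_genes,
        )

    def to_dense(self) -> np.ndarray:
        return self.counts.toarray()

    def save_mtx(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(d / "matrix.mtx"), self.counts.tocoo())
        (d / "features.tsv").write_text("".join(g + "\n" for g in self.genes))
        (d / "barcodes.tsv").write_text("".join(b + "\n" for b in self.barcodes))

    @classmethod
    def load_mtx(cls, directory, species_id: str = "") -> "DigitalExpressionMatrix":
        d = Path(directory)
        counts = scipy.sparse.csr_matrix(scipy.io.mmread(str(d / "matrix.mtx")))
        genes = (d / "features.tsv").read_text().split()
        barcodes = (d / "barcodes.tsv").read_text().split()
        return cls(species_id=species_id, genes=genes, barcodes=barcodes,
                   counts=counts, creation_min_genes=0)


def assign_reads(tagged: list[TaggedRead], index: KmerIndex):
    """Assign a tagged batch; returns (assigned rows, n_multimap, n_unassigned).

    Assigned rows are ``(cell_barcode, umi, gene_id, species_id)``.
    """
    rows = []
    n_multi = n_un = 0
    for t in tagged:
        gene = assign_read(t.cdna_seq, index)
        if gene == MULTIMAP:
            n_multi += 1
        elif gene == UNASSIGNED:
            n_un += 1
        else:
            rows.append((t.cell_barcode, t.umi, gene, index.gene_species[gene]))
    return rows, n_multi, n_un


def build_matrix(
    assigned_rows,
    creation_min_genes: int = 100,
    collapse: str = "greedy",
    species_ids: list[str] | None = None,
) -> dict[str, DigitalExpressionMatrix]:
    """Per-species digital expression matrices from assigned reads.

    ``assigned_rows`` are ``(cell_barcode, umi, gene_id, species_id)``
    tuples.  Within each (species, barcode, gene) group, reads per UMI are
    tallied and collapsed; barcodes detecting fewer than
    ``creation_min_genes`` genes are dropped from the matrix.  Gene and
    barcode orderings are lexicographic, so the result is independent of
    read order and of sub-library processing order.
    """
    groups: dict[tuple[str, str, str], dict[str, int]] = {}
    species_seen: dict[str, set[str]] = {}
    for barcode, umi, gene, sp in assigned_rows:
        key = (sp, barcode, gene)
        bucket = groups.setdefault(key, {})
        bucket[umi] = bucket.get(umi, 0) + 1
        species_seen.setdefault(sp, set()).add(gene)
    if species_ids is None:
        species_ids = sorted(species_seen)
    if not groups:
        warnings.warn("build_matrix: empty input, returning empty matrices")

    out: dict[str, DigitalExpressionMatrix] = {}
    for sp in species_ids:
        per_barcode: dict[str, dict[str, int]] = {}
        for (g_sp, barcode, gene), bucket in groups.items():
            if g_sp != sp:
                continue
            n = collapse_umis(list(bucket.items()), method=collapse)
            per_barcode.setdefault(barcode, {})[gene] = n
        kept = sorted(
            b for b, genes in per_barcode.items() if len(genes) >= creation_min_genes
        )
        genes = sorted(species_seen.get(sp, set()))
        gene_idx = {g: i for i, g in enumerate(genes)}
        bc_idx = {b: j for j, b in enumerate(kept)}
        rows, cols, vals = [], [], []
        for b in kept:
            for g, n in per_barcode[b].items():
                rows.append(gene_idx[g])
                cols.append(bc_idx[b])
                vals.append(n)
        counts = scipy.sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(genes), len(kept)), dtype=np.int64
        )
        out[sp] = DigitalExpressionMatrix(
            species_id=sp,
            genes=genes,
            barcodes=kept,
            counts=counts,
            creation_min_genes=creation_min_genes,
        )
    return out
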