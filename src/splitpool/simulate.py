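"""Synthetic two-species split-pool experiment generator.

Emulates a barnyard (species-mixing) SPLiT-seq run at desk scale: two
transcript references with disjoint gene namespaces, cells with
gamma-distributed per-gene expression rates, combinatorial barcode
assignment with natural birthday-problem collisions, cross- and
within-species doublets, ambient background reads, and paired FASTQ output
with per-base substitution errors, read-2 truncation and adapter chimeras.
Every emitted read is traceable to a ground-truth row, which is what makes
parameter-recovery and end-to-end identity tests possible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .layout import (
    ADAPTER_READ1,
    BarcodeLayout,
    WhitelistSet,
    random_seq,
)

AMBIENT_ID = "AMBIENT"
_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SpeciesReference:
    """Transcript-level reference for one species."""

    species_id: str
    transcripts: list[tuple[str, str]]  # (gene_id, sequence)

    def __post_init__(self) -> None:
        ids = [g for g, _ in self.transcripts]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate gene_ids in reference {self.species_id}")
        for gid, seq in self.transcripts:
            if not set(seq) <= set("ACGT"):
                raise ValueError(f"non-ACGT character in {gid}")

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.transcripts]

    @property
    def n_genes(self) -> int:
        return len(self.transcripts)

    def save_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for gid, seq in self.transcripts:
                fh.write(f">{gid}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")


@dataclass
class SimConfig:
    """Study-condition parameters of the simulated experiment.

    ``per_round_retention`` models the cell loss through the three in-cell
    barcoding rounds; the default 0.43 per round gives ~8% overall retention
    (0.43^3 ~ 0.08), so ``n_cells_per_species`` counts cells surviving to
    the final barcoding step while ``starting_cells`` reports the implied
    input pool.  Depth is negative-binomial per cell; expression rates are
    gamma per gene per cell (a gamma-Poisson / NB count model overall).
    """

    n_cells_per_species: int = 1000
    per_round_retention: float = 0.43
    n_barcoding_rounds: int = 3
    doublet_rate: float = 0.05
    ambient_fraction: float = 0.02
    reads_per_cell_mean: float = 100.0
    reads_per_cell_dispersion: float = 2.0
    reads_per_umi_mean: float = 1.8
    expression_shape: float = 0.3
    error_rate: float = 0.005
    truncation_rate: float = 0.01
    chimera_rate: float = 0.005
    adapter1: str = ADAPTER_READ1
    seed: int = 0

    def validate(self) -> list[str]:
        errors = []
        if self.n_cells_per_species < 1:
            errors.append("n_cells_per_species must be >= 1")
        if not 0 < self.per_round_retention <= 1:
            errors.append("per_round_retention must be in (0, 1]")
        for name in ("doublet_rate", "ambient_fraction", "error_rate",
                     "truncation_rate", "chimera_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                errors.append(f"{name} must be in [0, 1]")
        if self.doublet_rate >= 0.5:
            errors.append("doublet_rate >= 0.5 is a nonsensical regime")
        if self.reads_per_cell_mean <= 0:
            errors.append("reads_per_cell_mean must be positive")
        if self.reads_per_cell_dispersion <= 0:
            errors.append("reads_per_cell_dispersion must be positive")
        if self.reads_per_umi_mean < 1:
            errors.append("reads_per_umi_mean must be >= 1")
        if self.expression_shape <= 0:
            errors.append("expression_shape must be positive")
        return errors

    def require_valid(self) -> None:
        errors = self.validate()
        if errors:
            raise ValueError("invalid SimConfig: " + "; ".join(errors))

    @property
    def overall_retention(self) -> float:
        return self.per_round_retention ** self.n_barcoding_rounds

    @property
    def starting_cells(self) -> int:
        return int(round(2 * self.n_cells_per_species / self.overall_retention))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class TruthTable:
    """Ground truth of a simulated run.

    ``cells`` has one row per barcode-bearing unit (singlet or doublet);
    ``members`` one row per underlying cell (a doublet has two members);
    ``reads`` one row per emitted read pair, filled by :func:`generate_reads`
    (ambient reads trace to the reserved ``AMBIENT`` id).  Rate matrices are
    per species, one row per member of that species.
    """

    cells: pd.DataFrame
    members: pd.DataFrame
    config: SimConfig
    whitelists: WhitelistSet
    species_ids: tuple[str, str]
    rates: dict[str, np.ndarray] = field(default_factory=dict)
    member_row: dict[str, int] = field(default_factory=dict)
    reads: pd.DataFrame | None = None

    @property
    def n_units(self) -> int:
        return len(self.cells)


def make_references(
    n_genes: int,
    length_range: tuple[int, int] = (200, 3000),
    seed: int = 0,
    species_ids: tuple[str, str] = ("smed", "djap"),
) -> tuple[SpeciesReference, SpeciesReference]:
    """Two transcript references with species-prefixed, disjoint gene ids.

    Sequences are i.i.d. uniform over {A,C,G,T}; long enough random
    sequences are effectively unique at the k-mer level, which is what the
    downstream unique-k-mer gene assigner relies on.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo, hi = length_range
    if lo > hi or lo < 1:
        raise ValueError("length_range must be a nondecreasing pair of positive ints")
    rng = np.random.default_rng(seed)
    refs = []
    for sp in species_ids:
        transcripts = []
        for i in range(n_genes):
            length = int(rng.integers(lo, hi + 1))
            transcripts.append((f"{sp}_g{i:05d}", random_seq(rng, length)))
        refs.append(SpeciesReference(species_id=sp, transcripts=transcripts))
    return refs[0], refs[1]


def simulate_cells(
    refs: tuple[SpeciesReference, SpeciesReference],
    config: SimConfig,
    whitelists: WhitelistSet | None = None,
) -> TruthTable:
    """Draw cells, doublets, expression rates, depths and barcode combos.

    Doublets merge two cells sampled uniformly without replacement from the
    pooled species mix, so the cross-species fraction among doublets is
    2*p_A*p_B.  Barcode combinations are sampled uniformly *with*
    replacement from the full product space, so distinct units collide at
    the birthday-problem rate.
    """
    config.require_valid()
    ref_a, ref_b = refs
    rng = np.random.default_rng(config.seed)
    if whitelists is None:
        whitelists = WhitelistSet.generate(seed=int(rng.integers(2**31)))

    n = config.n_cells_per_species
    species = [ref_a.species_id] * n + [ref_b.species_id] * n
    n_members = 2 * n

    # per-member expression rates: gamma(shape) per gene, row-normalised
    rates: dict[str, np.ndarray] = {}
    member_row: dict[str, int] = {}
    member_ids = []
    for sp, ref, offset in ((ref_a.species_id, ref_a, 0), (ref_b.species_id, ref_b, n)):
        mat = rng.gamma(config.expression_shape, size=(n, ref.n_genes))
        mat /= mat.sum(axis=1, keepdims=True)
        rates[sp] = mat
        for i in range(n):
            mid = f"{sp}_c{i:06d}"
            member_ids.append(mid)
            member_row[mid] = i

    # per-member depth (reads), then molecule count via mean duplication
    disp = config.reads_per_cell_dispersion
    mean = config.reads_per_cell_mean
    p_nb = disp / (disp + mean)
    n_reads = np.maximum(1, rng.negative_binomial(disp, p_nb, size=n_members))
    n_umis = np.minimum(
        n_reads, np.maximum(1, rng.binomial(n_reads, 1.0 / config.reads_per_umi_mean))
    )

    # doublet pairing: D doublet units leave N - 2D singlets -> unit count U
    r = config.doublet_rate
    n_doublets = int(round(r * n_members / (1 + r)))
    paired = rng.choice(n_members, size=2 * n_doublets, replace=False)
    in_doublet = np.zeros(n_members, dtype=bool)
    in_doublet[paired] = True

    unit_members: list[tuple[int, ...]] = [
        (int(paired[2 * i]), int(paired[2 * i + 1])) for i in range(n_doublets)
    ]
    unit_members += [(int(i),) for i in np.flatnonzero(~in_doublet)]

    n_units = len(unit_members)
    bc1 = rng.integers(0, len(whitelists.round1), size=n_units)
    bc2 = rng.integers(0, len(whitelists.round2), size=n_units)
    bc3 = rng.integers(0, len(whitelists.round3), size=n_units)
    sub = rng.integers(0, len(whitelists.sublib_tags), size=n_units)

    cell_rows = []
    member_rows = []
    for u, members in enumerate(unit_members):
        uid = f"u{u:06d}"
        sps = sorted({species[m] for m in members})
        barcode = (
            whitelists.round1[bc1[u]]
            + whitelists.round2[bc2[u]]
            + whitelists.round3[bc3[u]]
            + whitelists.sublib_tags[sub[u]]
        )
        cell_rows.append(
            {
                "cell_id": uid,
                "species": "+".join(sps),
                "is_doublet": len(members) > 1,
                "is_cross_species": len(sps) > 1,
                "bc1_idx": int(bc1[u]),
                "bc2_idx": int(bc2[u]),
                "bc3_idx": int(bc3[u]),
                "sublib_idx": int(sub[u]),
                "barcode": barcode,
                "n_reads": int(sum(n_reads[m] for m in members)),
                "n_true_umis": int(sum(n_umis[m] for m in members)),
            }
        )
        for m in members:
            member_rows.append(
                {
                    "member_id": member_ids[m],
                    "cell_id": uid,
                    "species": species[m],
                    "n_reads": int(n_reads[m]),
                    "n_umis": int(n_umis[m]),
                }
            )

    return TruthTable(
        cells=pd.DataFrame(cell_rows),
        members=pd.DataFrame(member_rows),
        config=config,
        whitelists=whitelists,
        species_ids=(ref_a.species_id, ref_b.species_id),
        rates=rates,
        member_row=member_row,
    )


def umi_tallies(truth: TruthTable) -> pd.DataFrame:
    """Per-barcode UMI totals by species, straight from ground truth.

    Units sharing a barcode combination (natural collisions) are merged,
    exactly as a sequencer-side observer would see them.  Columns:
    ``barcode``, ``umis_<speciesA>``, ``umis_<speciesB>``.
    """
    sp_a, sp_b = truth.species_ids
    df = truth.members.merge(truth.cells[["cell_id", "barcode"]], on="cell_id")
    wide = (
        df.pivot_table(index="barcode", columns="species", values="n_umis", aggfunc="sum")
        .reindex(columns=[sp_a, sp_b])
        .fillna(0)
        .astype(int)
        .reset_index()
    )
    wide.columns = ["barcode", f"umis_{sp_a}", f"umis_{sp_b}"]
    return wide


def make_type_matrices(
    n_ref_per_type: int = 40,
    n_query: int = 30,
    n_genes: int = 100,
    effect: float = 8.0,
    query_type: str = "t1",
    seed: int = 0,
):
    """Two-cell-type reference + single-type query count matrices.

    A minimal expression model for label-transfer validation: each type
    overexpresses half the genes by ``effect``-fold, counts are Poisson.
    Returns ``(query, reference, ref_labels)`` as digital expression
    matrices with types labelled ``t1`` and ``t2``.
    """
    import scipy.sparse

    from .quant import DigitalExpressionMatrix

    rng = np.random.default_rng(seed)
    genes = [f"g{i:03d}" for i in range(n_genes)]

    def cells(n, hi):
        means = np.ones(n_genes)
        means[hi] = effect
        return rng.poisson(np.tile(means[:, None], (1, n)))

    half = n_genes // 2
    ref_counts = np.hstack(
        [cells(n_ref_per_type, slice(0, half)), cells(n_ref_per_type, slice(half, n_genes))]
    )
    labels = ["t1"] * n_ref_per_type + ["t2"] * n_ref_per_type
    block = slice(0, half) if query_type == "t1" else slice(half, n_genes)
    query = DigitalExpressionMatrix(
        "query", genes, [f"q{i}" for i in range(n_query)],
        scipy.sparse.csr_matrix(cells(n_query, block)),
    )
    reference = DigitalExpressionMatrix(
        "reference", genes, [f"r{i}" for i in range(2 * n_ref_per_type)],
        scipy.sparse.csr_matrix(ref_counts),
    )
    return query, reference, labels


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    n = len(seq)
    k = rng.binomial(n, rate)
    if k == 0:
        return seq
    positions = rng.choice(n, size=k, replace=False)
    chars = list(seq)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def _read2_template(
    layout: BarcodeLayout,
    whitelists: WhitelistSet,
    bc1: int,
    bc2: int,
    bc3: int,
    umi: str,
    rng: np.random.Generator,
    total_len: int = 150,
) -> str:
    chars = list(random_seq(rng, total_len))
    pieces = {
        "UMI": umi,
        "BC1": whitelists.round1[bc1],
        "BC2": whitelists.round2[bc2],
        "BC3": whitelists.round3[bc3],
    }
    for idx, seg in enumerate(layout.segments):
        if seg.kind in ("LINKER", "ANCHOR"):
            seq = layout.linker_seqs[idx]
        else:
            seq = pieces[seg.kind]
        chars[seg.offset : seg.end] = list(seq)
    return "".join(chars)


def generate_reads(
    truth: TruthTable,
    refs: tuple[SpeciesReference, SpeciesReference],
    layout: BarcodeLayout | None = None,
    config: SimConfig | None = None,
) -> tuple[list[tuple], pd.DataFrame]:
    """Emit paired reads plus a per-read truth table.

    Read 1 is a 60-150 nt substring of a transcript drawn from the cell's
    rate vector; read 2 is the layout-ordered UMI + barcode + linker
    concatenation padded to 150 nt.  Corruption: per-base substitutions at
    ``error_rate`` on both mates, read-2 truncation to a uniform length in
    [40, 93] at ``truncation_rate``, adapter embedded in read 1 at
    ``chimera_rate``.  Every molecule receives at least one read; extra
    reads (UMI duplicates) are spread multinomially.

    Returns ``(pairs, read_truth)`` where each pair is
    ``(read_id, seq1, qual1, seq2, qual2, sublib_tag)``.
    """
    if config is None:
        config = truth.config
    if layout is None:
        layout = BarcodeLayout.default()
    if layout.min_span > 150:
        raise ValueError("layout min_span exceeds the 150 nt read length")
    config.require_valid()
    ref_by_sp = {r.species_id: r for r in refs}
    rng = np.random.default_rng(config.seed + 1)  # distinct stream from simulate_cells
    wl = truth.whitelists

    cells = truth.cells.set_index("cell_id")
    pairs: list[tuple] = []
    truth_rows: list[dict] = []
    read_counter = 0

    def emit(cell_id, member_id, species, gene_id, transcript, umi, bc, sublib_tag):
        nonlocal read_counter
        rid = f"r{read_counter:08d}"
        read_counter += 1
        tlen = len(transcript)
        rlen = int(rng.integers(60, 151))
        rlen = min(rlen, tlen)
        start = int(rng.integers(0, tlen - rlen + 1))
        seq1 = transcript[start : start + rlen]
        if config.chimera_rate > 0 and rng.random() < config.chimera_rate:
            pos = int(rng.integers(0, max(1, len(seq1) - len(config.adapter1) + 1)))
            seq1 = seq1[:pos] + config.adapter1 + seq1[pos + len(config.adapter1):]
            seq1 = seq1[:rlen]
        seq1 = _mutate(seq1, rng, config.error_rate)
        seq2 = _read2_template(layout, wl, bc[0], bc[1], bc[2], umi, rng)
        seq2 = _mutate(seq2, rng, config.error_rate)
        if config.truncation_rate > 0 and rng.random() < config.truncation_rate:
            seq2 = seq2[: int(rng.integers(40, 94))]
        pairs.append((rid, seq1, "I" * len(seq1), seq2, "I" * len(seq2), sublib_tag))
        truth_rows.append(
            {
                "read_id": rid,
                "cell_id": cell_id,
                "member_id": member_id,
                "species": species,
                "gene_id": gene_id,
                "umi": umi,
                "sublib": sublib_tag,
            }
        )

    total_cell_reads = 0
    for member in truth.members.itertuples(index=False):
        unit = cells.loc[member.cell_id]
        sp = member.species
        ref = ref_by_sp[sp]
        rate = truth.rates[sp][truth.member_row[member.member_id]]
        bc = (unit["bc1_idx"], unit["bc2_idx"], unit["bc3_idx"])
        tag = wl.sublib_tags[unit["sublib_idx"]]
        n_umis, n_reads = member.n_umis, member.n_reads
        gene_idx = rng.choice(ref.n_genes, size=n_umis, p=rate)
        umis = [random_seq(rng, layout.umi_len) for _ in range(n_umis)]
        extra = rng.multinomial(n_reads - n_umis, np.full(n_umis, 1.0 / n_umis))
        for j in range(n_umis):
            gid, tseq = ref.transcripts[gene_idx[j]]
            for _ in range(1 + extra[j]):
                emit(member.cell_id, member.member_id, sp, gid, tseq, umis[j], bc, tag)
                total_cell_reads += 1

    # ambient background: pooled transcriptome, valid barcode of a real unit
    if config.ambient_fraction > 0 and total_cell_reads > 0:
        f = config.ambient_fraction
        n_ambient = int(round(f / (1 - f) * total_cell_reads))
        sp_weight = truth.members.groupby("species")["n_reads"].sum()
        sp_names = list(sp_weight.index)
        sp_p = sp_weight.to_numpy() / sp_weight.sum()
        pooled = {sp: truth.rates[sp].mean(axis=0) for sp in sp_names}
        for sp in pooled:
            pooled[sp] /= pooled[sp].sum()
        unit_rows = truth.cells
        for _ in range(n_ambient):
            sp = sp_names[rng.choice(len(sp_names), p=sp_p)]
            ref = ref_by_sp[sp]
            gid, tseq = ref.transcripts[rng.choice(ref.n_genes, p=pooled[sp])]
            unit = unit_rows.iloc[int(rng.integers(0, len(unit_rows)))]
            bc = (unit["bc1_idx"], unit["bc2_idx"], unit["bc3_idx"])
            tag = wl.sublib_tags[unit["sublib_idx"]]
            emit(AMBIENT_ID, AMBIENT_ID, sp, gid, tseq,
                 random_seq(rng, layout.umi_len), bc, tag)

    read_truth = pd.DataFrame(truth_rows)
    truth.reads = read_truth
    return pairs, read_truth


def write_run(
    outdir,
    truth: TruthTable,
    pairs: Iterable[tuple],
    refs: tuple[SpeciesReference, SpeciesReference],
    layout: BarcodeLayout,
    config: SimConfig,
) -> dict[str, Path]:
    """Persist a simulated run: per-sub-library FASTQ pairs, truth tables,
    whitelists, references and a YAML echo of the configuration.

    gzip members are written with a zeroed mtime so identical seeds give
    byte-identical files.
    """
    from . import io as spio
    import yaml

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    by_tag: dict[str, list[tuple]] = {}
    for rec in pairs:
        by_tag.setdefault(rec[5], []).append(rec)
    for tag, recs in sorted(by_tag.items()):
        r1 = out / f"reads_{tag}_R1.fastq.gz"
        r2 = out / f"reads_{tag}_R2.fastq.gz"
        spio.write_fastq(r1, ((rid, s1, q1) for rid, s1, q1, _, _, _ in recs))
        spio.write_fastq(r2, ((rid, s2, q2) for rid, _, _, s2, q2, _ in recs))
        written[f"reads_{tag}_R1"] = r1
        written[f"reads_{tag}_R2"] = r2

    truth.cells.to_csv(out / "truth_cells.tsv", sep="\t", index=False)
    written["truth_cells"] = out / "truth_cells.tsv"
    if truth.reads is not None:
        truth.reads.to_csv(out / "truth_reads.tsv", sep="\t", index=False)
        written["truth_reads"] = out / "truth_reads.tsv"

    truth.whitelists.save(out)
    for name, ref in zip(("reference_A.fasta", "reference_B.fasta"), refs):
        ref.save_fasta(out / name)
        written[name] = out / name

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    written["config"] = out / "config.yaml"
    return written
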