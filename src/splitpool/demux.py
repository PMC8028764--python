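"""Barcode extraction and error correction.

Each read 2 carries a UMI and three round barcodes at fixed offsets.  Raw
barcodes are corrected against the round whitelist at Hamming distance <= 1:
an exact match wins outright, a unique distance-1 neighbour is a corrected
hit, two or more distance-1 neighbours are ambiguous (the read is dropped,
never guessed), and anything further is a non-match.  The composite cell
barcode is bc1 + bc2 + bc3 plus a trailing sub-library character (A, T or
C), which keeps identical well combinations from different sub-libraries
distinct after pooling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .layout import BarcodeLayout, WhitelistSet

NO_MATCH = -1
AMBIGUOUS = -2


@dataclass
class TaggedRead:
    read_id: str
    cdna_seq: str
    umi: str
    cell_barcode: str
    corrected_flags: tuple[bool, bool, bool]
    sublib_char: str


@dataclass
class DemuxReport:
    n_input: int = 0
    n_tagged: int = 0
    n_fail_no_match: int = 0
    n_fail_ambiguous: int = 0
    n_fail_umi_n: int = 0
    per_round_correction_counts: list[int] = field(default_factory=lambda: [0, 0, 0])

    def check(self) -> None:
        total = self.n_tagged + self.n_fail_no_match + self.n_fail_ambiguous + self.n_fail_umi_n
        if self.n_input != total:
            raise AssertionError(
                f"demux ledger broken: n_input={self.n_input} != buckets={total}"
            )

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def extract_segments(read2_seq: str, layout: BarcodeLayout) -> tuple[str, str, str, str]:
    """``(umi, raw_bc1, raw_bc2, raw_bc3)`` at the layout's half-open intervals."""
    if len(read2_seq) < layout.min_span:
        raise ValueError(
            f"read 2 length {len(read2_seq)} < layout span {layout.min_span}"
        )
    def cut(kind: str) -> str:
        seg = layout.segment(kind)
        return read2_seq[seg.offset : seg.end]
    return cut("UMI"), cut("BC1"), cut("BC2"), cut("BC3")


def correct_barcode(raw: str, whitelist: list[str], max_hamming: int = 1) -> int:
    """Whitelist index of the corrected barcode, or NO_MATCH / AMBIGUOUS.

    ``N`` mismatches every base.  With a whitelist of pairwise distance
    >= 3, a single substitution always resolves uniquely.
    """
    bc_len = len(whitelist[0])
    if len(raw) != bc_len:
        raise ValueError(f"raw barcode length {len(raw)} != whitelist length {bc_len}")
    hits = []
    for idx, wl in enumerate(whitelist):
        d = 0
        for a, b in zip(raw, wl):
            if a != b:
                d += 1
                if d > max_hamming:
                    break
        if d == 0:
            return idx
        if d <= max_hamming:
            hits.append(idx)
    if not hits:
        return NO_MATCH
    if len(hits) > 1:
        return AMBIGUOUS
    return hits[0]


def tag_reads(
    pairs,
    layout: BarcodeLayout,
    whitelists: WhitelistSet,
    sublib_char: str,
    max_hamming: int = 1,
) -> tuple[list[TaggedRead], DemuxReport]:
    """Demultiplex a batch of curated read pairs from one sub-library.

    Only reads whose three barcodes all resolve (and whose UMI is N-free)
    are emitted.  ``pairs`` elements expose ``read_id``, ``seq1`` and
    ``seq2`` (``readproc.ReadPair`` or compatible tuples).
    """
    if sublib_char not in whitelists.sublib_tags:
        raise ValueError(f"sub-library tag {sublib_char!r} not in whitelist set")
    report = DemuxReport()
    tagged: list[TaggedRead] = []
    rounds = whitelists.rounds
    for pair in pairs:
        if hasattr(pair, "read_id"):
            rid, seq1, seq2 = pair.read_id, pair.seq1, pair.seq2
        else:
            rid, seq1, _, seq2 = pair[0], pair[1], pair[2], pair[3]
        report.n_input += 1
        umi, raw1, raw2, raw3 = extract_segments(seq2, layout)
        if "N" in umi:
            report.n_fail_umi_n += 1
            continue
        results = [correct_barcode(raw, wl, max_hamming)
                   for raw, wl in zip((raw1, raw2, raw3), rounds)]
        if any(r == AMBIGUOUS for r in results):
            report.n_fail_ambiguous += 1
            continue
        if any(r == NO_MATCH for r in results):
            report.n_fail_no_match += 1
            continue
        flags = tuple(
            rounds[i][results[i]] != raw
            for i, raw in enumerate((raw1, raw2, raw3))
        )
        for i, f in enumerate(flags):
            if f:
                report.per_round_correction_counts[i] += 1
        barcode = rounds[0][results[0]] + rounds[1][results[1]] + rounds[2][results[2]] + sublib_char
        tagged.append(TaggedRead(rid, seq1, umi, barcode, flags, sublib_char))
        report.n_tagged += 1
    report.check()
    return tagged, report
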