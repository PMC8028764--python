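"""Raw read-pair curation: quality/adapter/length filtering and barcode
phase verification.

The read-2 filters protect the demultiplexer: a read shorter than the
layout's minimum span (94 nt under the default layout) cannot contain all
three barcodes, and a read whose fixed linkers are out of position has
suffered an indel that would shift every downstream barcode.  Out-of-phase
reads are dropped rather than repaired — retention is conservative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .layout import BarcodeLayout


@dataclass
class ReadPair:
    read_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str


@dataclass
class FilterReport:
    """First-failure accounting of a curation pass.

    Checks run in a fixed order (quality trim, terminal Ns, adapter trim,
    length, phase, pairing) and each dropped pair is charged to the first
    check that doomed it, so ``n_input = n_pass + sum(failures)`` always.
    ``n_malformed`` counts records with mismatched seq/qual lengths, which
    are rejected before any filtering.
    """

    n_input: int = 0
    n_pass: int = 0
    n_fail_short1: int = 0
    n_fail_short2: int = 0
    n_fail_adapter: int = 0
    n_fail_phase: int = 0
    n_fail_unpaired: int = 0
    n_malformed: int = 0

    def check(self) -> None:
        total = (
            self.n_pass
            + self.n_fail_short1
            + self.n_fail_short2
            + self.n_fail_adapter
            + self.n_fail_phase
            + self.n_fail_unpaired
        )
        if self.n_input != total:
            raise AssertionError(
                f"filter ledger broken: n_input={self.n_input} != buckets={total}"
            )

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _phred(qual: str) -> list[int]:
    return [ord(c) - 33 for c in qual]


def quality_trim_3p(seq: str, qual: str, cutoff: int) -> tuple[str, str]:
    """Drop the maximal 3' suffix of bases with Phred < cutoff."""
    end = len(seq)
    scores = _phred(qual)
    while end > 0 and scores[end - 1] < cutoff:
        end -= 1
    return seq[:end], qual[:end]


def strip_terminal_ns(seq: str, qual: str) -> tuple[str, str]:
    start, end = 0, len(seq)
    while start < end and seq[start] == "N":
        start += 1
    while end > start and seq[end - 1] == "N":
        end -= 1
    return seq[start:end], qual[start:end]


def find_adapter(seq: str, adapter: str, min_overlap: int = 6) -> int:
    """Start of an adapter hit, or -1.

    Exact occurrence anywhere wins; otherwise a 3'-terminal prefix of the
    adapter of length >= ``min_overlap`` (partial read-through) is accepted.
    """
    pos = seq.find(adapter)
    if pos >= 0:
        return pos
    max_ov = min(len(adapter) - 1, len(seq))
    for ov in range(max_ov, min_overlap - 1, -1):
        if seq.endswith(adapter[:ov]):
            return len(seq) - ov
    return -1


def trim_and_filter(
    pairs,
    min_len1: int = 60,
    min_len2: int = 94,
    adapter1: str = "AGATCGGAAGAG",
    adapter2: str = "CTGTCTCTTATA",
    qual_cutoff: int = 10,
    report: FilterReport | None = None,
) -> tuple[list[ReadPair], FilterReport]:
    """Quality-trim, N-strip, adapter-trim and length-filter read pairs.

    Read 1 keeps at least ``min_len1`` nt of transcript; read 2 must still
    span all barcodes (``min_len2``).  A pair whose read collapses to
    nothing at the adapter (hit at position 0) is charged to the adapter
    bucket; a pair merely left short is charged to the length bucket.
    """
    if not adapter1 or not adapter2:
        raise ValueError("adapters must be non-empty")
    for ad in (adapter1, adapter2):
        if not set(ad) <= set("ACGTN") or ad != ad.upper():
            raise ValueError("adapters must be uppercase nucleotide strings")

    out: list[ReadPair] = []
    rep = report if report is not None else FilterReport()
    for pair in pairs:
        if not isinstance(pair, ReadPair):
            pair = ReadPair(*pair[:5])
        if len(pair.seq1) != len(pair.qual1) or len(pair.seq2) != len(pair.qual2):
            rep.n_malformed += 1
            continue
        rep.n_input += 1

        s1, q1 = quality_trim_3p(pair.seq1, pair.qual1, qual_cutoff)
        s2, q2 = quality_trim_3p(pair.seq2, pair.qual2, qual_cutoff)
        s2, q2 = strip_terminal_ns(s2, q2)

        pos1 = find_adapter(s1, adapter1)
        if pos1 == 0:
            rep.n_fail_adapter += 1
            continue
        if pos1 > 0:
            s1, q1 = s1[:pos1], q1[:pos1]
        pos2 = find_adapter(s2, adapter2)
        if pos2 == 0:
            rep.n_fail_adapter += 1
            continue
        if pos2 > 0:
            s2, q2 = s2[:pos2], q2[:pos2]

        if len(s1) < min_len1:
            rep.n_fail_short1 += 1
            continue
        if len(s2) < min_len2:
            rep.n_fail_short2 += 1
            continue
        rep.n_pass += 1
        out.append(ReadPair(pair.read_id, s1, q1, s2, q2))
    rep.check()
    return out, rep


def check_phase(
    read2_seq: str,
    layout: BarcodeLayout,
    max_mismatch: int = 1,
) -> bool:
    """True iff every fixed linker/anchor sits at its expected offset.

    Substitutions up to ``max_mismatch`` per linker are tolerated; an indel
    anywhere upstream shifts all later segments and fails the comparison.
    No indel rescue is attempted.
    """
    if len(read2_seq) < layout.min_span:
        raise ValueError(
            f"read 2 length {len(read2_seq)} < layout span {layout.min_span}; "
            "short reads must be filtered before the phase check"
        )
    for seg, ref in layout.linker_segments:
        observed = read2_seq[seg.offset : seg.end]
        mismatches = sum(a != b for a, b in zip(observed, ref))
        if mismatches > max_mismatch:
            return False
    return True


def filter_phase(
    pairs: list[ReadPair],
    layout: BarcodeLayout,
    max_mismatch: int = 1,
    report: FilterReport | None = None,
) -> tuple[list[ReadPair], FilterReport]:
    """Apply :func:`check_phase` across a batch, with ledger accounting."""
    rep = report if report is not None else FilterReport()
    standalone = report is None
    out = []
    for pair in pairs:
        if standalone:
            rep.n_input += 1
        if check_phase(pair.seq2, layout, max_mismatch):
            if standalone:
                rep.n_pass += 1
            out.append(pair)
        else:
            rep.n_fail_phase += 1
            if not standalone:
                rep.n_pass -= 1
    rep.check()
    return out, rep


def retain_paired(ids1, ids2) -> list[str]:
    """Ids present in both mate files, in read-1 order."""
    set2 = set(ids2)
    return [i for i in ids1 if i in set2]
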