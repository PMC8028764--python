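"""Read-2 barcode architecture: segment layout and per-round whitelists.

A split-pool library encodes cell identity in read 2 as a UMI followed by
three round barcodes separated by fixed ligation linkers.  The fourth
"barcode" is the sub-library PCR index, represented downstream as a single
character (A, T or C) appended to the composite cell barcode.  With 48
round-1, 96 round-2 and 96 round-3 barcodes and 3 sub-libraries the barcode
space holds 48 * 96 * 96 * 3 = 1,327,104 combinations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NUCLEOTIDES = "ACGT"

# Fixed arbitrary linker fillers between the ligation barcodes.  Real plates
# use proprietary oligo sequences; any fixed string works because the phase
# check and demultiplexer only require that linkers be known and constant.
DEFAULT_LINKER1 = "GTGGCCGATGTTTCGCATCGGCGTACGACT"
DEFAULT_LINKER2 = "ATCCACGTGCTTGAGAGGCCAGAGCATTCG"

#: Illumina universal adapter (read 1) and Nextera adapter (read 2).
ADAPTER_READ1 = "AGATCGGAAGAG"
ADAPTER_READ2 = "CTGTCTCTTATA"

SUBLIB_TAGS = ("A", "T", "C")


def random_seq(rng: np.random.Generator, n: int) -> str:
    """Uniform random nucleotide string of length ``n``."""
    return "".join(NUCLEOTIDES[i] for i in rng.integers(0, 4, size=n))


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings.

    Raises ``ValueError`` on length mismatch; ``N`` counts as a mismatch
    against any base.
    """
    if len(a) != len(b):
        raise ValueError(f"hamming: length mismatch ({len(a)} vs {len(b)})")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class Segment:
    """One contiguous stretch of read 2 (0-based, half-open interval)."""

    kind: str  # UMI | BC1 | BC2 | BC3 | LINKER | ANCHOR
    offset: int
    length: int

    @property
    def end(self) -> int:
        return self.offset + self.length


@dataclass
class BarcodeLayout:
    """Positional map of UMI, barcode and linker segments in read 2.

    ``min_span`` is the number of leading bases of read 2 needed to cover
    every non-linker segment; reads shorter than this cannot yield a full
    barcode combination and are removed upstream.  The default layout places
    the last barcode so that it ends at offset 94.
    """

    umi_len: int = 10
    bc_len: int = 8
    segments: list[Segment] = field(default_factory=list)
    linker_seqs: dict[int, str] = field(default_factory=dict)  # segment index -> sequence

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("BarcodeLayout requires at least one segment")
        self.validate()

    @classmethod
    def default(cls) -> "BarcodeLayout":
        """UMI(10) BC3(8) LINKER(30) BC2(8) LINKER(30) BC1(86:94)."""
        segs = [
            Segment("UMI", 0, 10),
            Segment("BC3", 10, 8),
            Segment("LINKER", 18, 30),
            Segment("BC2", 48, 8),
            Segment("LINKER", 56, 30),
            Segment("BC1", 86, 8),
        ]
        return cls(
            umi_len=10,
            bc_len=8,
            segments=segs,
            linker_seqs={2: DEFAULT_LINKER1, 4: DEFAULT_LINKER2},
        )

    def validate(self) -> None:
        prev_end = 0
        for seg in self.segments:
            if seg.offset < prev_end:
                raise ValueError(
                    f"segments overlap or unsorted at kind={seg.kind} offset={seg.offset}"
                )
            prev_end = seg.end
        kinds = [s.kind for s in self.segments]
        for required in ("UMI", "BC1", "BC2", "BC3"):
            if kinds.count(required) != 1:
                raise ValueError(f"layout must contain exactly one {required} segment")
        for idx, seq in self.linker_seqs.items():
            seg = self.segments[idx]
            if seg.kind not in ("LINKER", "ANCHOR"):
                raise ValueError(f"linker sequence attached to non-linker segment {idx}")
            if len(seq) != seg.length:
                raise ValueError(
                    f"linker sequence length {len(seq)} != segment length {seg.length}"
                )

    def segment(self, kind: str) -> Segment:
        for seg in self.segments:
            if seg.kind == kind:
                return seg
        raise KeyError(kind)

    @property
    def min_span(self) -> int:
        """End offset of the last non-linker segment."""
        return max(s.end for s in self.segments if s.kind not in ("LINKER", "ANCHOR"))

    @property
    def linker_segments(self) -> list[tuple[Segment, str]]:
        return [
            (self.segments[i], seq) for i, seq in sorted(self.linker_seqs.items())
        ]


@dataclass
class WhitelistSet:
    """Legal barcode sequences for the three split-pool rounds.

    Invariant (checked): within each round all sequences are unique and,
    unless ``enforce_min_dist`` was disabled at generation time, pairwise
    Hamming distance is >= 3 so that radius-1 error correction can never be
    ambiguous for a singly substituted barcode.
    """

    round1: list[str]
    round2: list[str]
    round3: list[str]
    sublib_tags: tuple[str, ...] = SUBLIB_TAGS
    min_pairwise_dist: int = 3

    def __post_init__(self) -> None:
        for name, wl in (("round1", self.round1), ("round2", self.round2), ("round3", self.round3)):
            if len(set(wl)) != len(wl):
                raise ValueError(f"duplicate barcode in {name}")
            lengths = {len(s) for s in wl}
            if len(lengths) != 1:
                raise ValueError(f"mixed barcode lengths in {name}")
        if not all(t in "ATCG" and len(t) == 1 for t in self.sublib_tags):
            raise ValueError("sub-library tags must be single nucleotide characters")

    @property
    def bc_len(self) -> int:
        return len(self.round1[0])

    @property
    def rounds(self) -> tuple[list[str], list[str], list[str]]:
        return (self.round1, self.round2, self.round3)

    @property
    def n_combinations(self) -> int:
        """Size of the combinatorial barcode space (includes sub-libraries)."""
        return len(self.round1) * len(self.round2) * len(self.round3) * len(self.sublib_tags)

    def check_min_distance(self) -> bool:
        """Verify the pairwise Hamming floor in every round (O(n^2), small n)."""
        for wl in self.rounds:
            for i in range(len(wl)):
                for j in range(i + 1, len(wl)):
                    if hamming(wl[i], wl[j]) < self.min_pairwise_dist:
                        return False
        return True

    @classmethod
    def generate(
        cls,
        seed: int,
        sizes: tuple[int, int, int] = (48, 96, 96),
        bc_len: int = 8,
        min_dist: int = 3,
        enforce_min_dist: bool = True,
    ) -> "WhitelistSet":
        """Draw whitelists by rejection sampling.

        Each candidate is a uniform random ``bc_len``-mer; it is kept only if
        its Hamming distance to every barcode already accepted in the same
        round is >= ``min_dist``.  Disabling enforcement samples distinct but
        possibly close barcodes (closer to an arbitrary real plate).
        """
        rng = np.random.default_rng(seed)
        rounds: list[list[str]] = []
        for size in sizes:
            accepted: list[str] = []
            attempts = 0
            while len(accepted) < size:
                attempts += 1
                if attempts > 200_000:
                    raise RuntimeError("whitelist rejection sampling did not converge")
                cand = random_seq(rng, bc_len)
                if enforce_min_dist:
                    if all(hamming(cand, w) >= min_dist for w in accepted):
                        accepted.append(cand)
                else:
                    if cand not in accepted:
                        accepted.append(cand)
            rounds.append(accepted)
        return cls(
            round1=rounds[0],
            round2=rounds[1],
            round3=rounds[2],
            min_pairwise_dist=min_dist if enforce_min_dist else 1,
        )

    def save(self, directory) -> None:
        """Write one plain-text file per round (one sequence per line)."""
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for name, wl in zip(("bc_round1.txt", "bc_round2.txt", "bc_round3.txt"), self.rounds):
            (d / name).write_text("\n".join(wl) + "\n")

    @classmethod
    def load(cls, directory) -> "WhitelistSet":
        from pathlib import Path

        d = Path(directory)
        rounds = [
            [line.strip() for line in (d / name).read_text().splitlines() if line.strip()]
            for name in ("bc_round1.txt", "bc_round2.txt", "bc_round3.txt")
        ]
        return cls(round1=rounds[0], round2=rounds[1], round3=rounds[2])
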