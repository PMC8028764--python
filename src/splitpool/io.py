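"""FASTQ and matrix file helpers shared across the pipeline."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

import pysam


def read_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Yield ``(read_id, seq, qual)`` from a plain or gzipped FASTQ."""
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield entry.name, entry.sequence, entry.quality or ""


def write_fastq(path, records: Iterable[tuple[str, str, str]]) -> int:
    """Write ``(read_id, seq, qual)`` records; gzip if the name ends in .gz.

    gzip members carry mtime=0 and no original filename, so output is a
    pure function of the records (byte-identical re-runs).
    """
    path = Path(path)
    n = 0
    if path.suffix == ".gz":
        raw = open(path, "wb")
        fh = gzip.GzipFile(filename="", fileobj=raw, mode="wb", mtime=0)
    else:
        raw = None
        fh = open(path, "wb")
    try:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n".encode())
            n += 1
    finally:
        fh.close()
        if raw is not None:
            raw.close()
    return n


def read_pairs(path1, path2) -> Iterator[tuple[str, str, str, str, str]]:
    """Yield ``(read_id, seq1, qual1, seq2, qual2)`` from synchronised mates."""
    for (id1, s1, q1), (id2, s2, q2) in zip(read_fastq(path1), read_fastq(path2)):
        if id1 != id2:
            raise ValueError(f"mate id mismatch: {id1} vs {id2}")
        yield id1, s1, q1, s2, q2
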