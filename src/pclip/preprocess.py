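"""Read-level preprocessing for PAR-CLIP libraries.

PAR-CLIP inserts are short and heavily PCR-amplified, so the standard first
step is to collapse exact duplicate reads into a weighted FASTA, strip
fixed-length UMIs, and drop reads too short to map uniquely.  Adapter
trimming is delegated to an external trimmer and is out of scope here.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Sequence

import pysam

VALID_BASES = frozenset("ACGTN")

#: Reads shorter than this are unlikely to map uniquely and are discarded.
DEFAULT_MIN_LENGTH = 13


@dataclass(frozen=True)
class ReadRecord:
    """A collapsed read: one distinct sequence plus its raw multiplicity."""

    read_id: str
    sequence: str
    copy_count: int = 1

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        if self.copy_count < 1:
            raise ValueError(f"read {self.read_id!r}: copy_count must be >= 1")


def collapse_reads(reads: Iterable[tuple[str, str] | str]) -> list[ReadRecord]:
    """Collapse raw reads into one :class:`ReadRecord` per distinct sequence.

    Sequences are uppercased before comparison.  Output is deterministic:
    descending ``copy_count``, ties broken lexicographically by sequence.
    Records are named ``seq<i>_<count>`` so the multiplicity round-trips
    through FASTA.

    Parameters
    ----------
    reads
        Either bare sequence strings or ``(read_id, sequence)`` pairs.
    """
    counts: Counter[str] = Counter()
    for item in reads:
        read_id, seq = item if isinstance(item, tuple) else ("?", item)
        seq = seq.upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise ValueError(
                f"read {read_id!r}: non-nucleotide characters {sorted(bad)}"
            )
        counts[seq] += 1
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        ReadRecord(read_id=f"seq{i}_{n}", sequence=seq, copy_count=n)
        for i, (seq, n) in enumerate(ordered, start=1)
    ]


def trim_umi(record: ReadRecord, umi5_len: int = 0, umi3_len: int = 0) -> ReadRecord:
    """Remove fixed-length UMIs from both ends of a collapsed read.

    ``umi5_len`` leading and ``umi3_len`` trailing bases are dropped;
    the copy count is preserved.
    """
    if umi5_len < 0 or umi3_len < 0:
        raise ValueError("UMI lengths must be non-negative")
    if umi5_len + umi3_len >= len(record.sequence):
        raise ValueError(
            f"read {record.read_id!r}: UMI lengths ({umi5_len}+{umi3_len}) "
            f"consume the whole sequence (length {len(record.sequence)})"
        )
    end = len(record.sequence) - umi3_len
    return replace(record, sequence=record.sequence[umi5_len:end])


def filter_min_length(
    records: Sequence[ReadRecord], min_len: int = DEFAULT_MIN_LENGTH
) -> list[ReadRecord]:
    """Keep records whose sequence is at least ``min_len`` bases, in order."""
    if min_len < 1:
        raise ValueError("min_len must be positive")
    return [r for r in records if len(r.sequence) >= min_len]


def preprocess_reads(
    reads: Iterable[tuple[str, str] | str],
    umi5_len: int = 0,
    umi3_len: int = 0,
    min_len: int = DEFAULT_MIN_LENGTH,
) -> list[ReadRecord]:
    """Collapse, length-filter, UMI-trim, then length-filter again.

    The length filter is applied both before and after UMI trimming, matching
    the upstream pipeline order (collapse happens before trimming, so
    UMI-bearing duplicates may under-collapse; that ordering is kept as is).
    Records whose sequence would be fully consumed by the UMIs are dropped
    rather than raising, since the first filter already enforces a floor.
    """
    records = filter_min_length(collapse_reads(reads), min_len)
    if umi5_len or umi3_len:
        trimmed = []
        for rec in records:
            if umi5_len + umi3_len >= len(rec.sequence):
                continue
            trimmed.append(trim_umi(rec, umi5_len, umi3_len))
        records = filter_min_length(trimmed, min_len)
    return records


def _open_text(path: str, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastx(path: str) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from FASTQ or FASTA, plain or gzipped."""
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield entry.name, entry.sequence


def write_collapsed_fasta(records: Sequence[ReadRecord], path: str) -> None:
    """Write collapsed reads as FASTA; headers carry ``_<copy_count>``."""
    with _open_text(path, "wt") as out:
        for rec in records:
            out.write(f">{rec.read_id}\n{rec.sequence}\n")


def preprocess_file(
    in_path: str,
    out_path: str,
    umi5_len: int = 0,
    umi3_len: int = 0,
    min_len: int = DEFAULT_MIN_LENGTH,
) -> int:
    """File-level driver: FASTQ/FASTA in, collapsed FASTA out.

    Returns the number of records written.
    """
    records = preprocess_reads(read_fastx(in_path), umi5_len, umi3_len, min_len)
    write_collapsed_fasta(records, out_path)
    return len(records)
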