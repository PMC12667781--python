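"""Strand-specific per-base mismatch tracks from an alignment file.

PAR-CLIP crosslinking converts the transcript's 4SU into a base read as C,
so the diagnostic event is a strand-local T-to-C substitution.  This module
walks every quality-passing primary alignment against the reference and
accumulates, per strand and genomic position: read depth, T-to-C count, and
the count of the 11 other substitution types.  Coordinates are 0-based
half-open throughout; minus-strand events are classified after
complementation, so a strand-local T-to-C on the minus strand is a
reference-space A-to-G.

Filters follow the high-confidence settings of the pipeline: mapping
quality >= 55 (uniquely mapped under STAR conventions), base quality >= 20,
secondary alignments excluded on both strands (the forward/reverse FLAG
masks 272 and include-16/exclude-256), duplicates and supplementaries
excluded by default.  Insertions and deletions are ignored; CIGAR N (spliced
gaps) contributes nothing.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pysam

_N = ord("N")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
# strand-local T->C expressed in forward reference space, per strand
_T2C_PAIR = {"+": ("T", "C"), "-": ("A", "G")}

TRACK_KINDS = ("depth", "t2c", "other_mm")


@dataclass(frozen=True)
class PileupColumn:
    """One covered position of a strand-specific mismatch track.

    ``ref_base`` is strand-local (complemented on the minus strand), so
    ``t2c`` can only be non-zero where ``ref_base == 'T'``.
    """

    chrom: str
    pos: int
    strand: str
    ref_base: str
    depth: int
    t2c: int
    other_mm: int


@dataclass
class MismatchTrack:
    """Per-base depth / T-to-C / other-mismatch arrays for one strand.

    Arrays are dense per chromosome (length = chromosome length) and indexed
    in forward genomic coordinates; ``ref`` holds the forward reference as
    uint8 byte arrays when built from a BAM+FASTA, and is ``None`` for
    tracks reconstructed from bedGraph files.
    """

    strand: str
    depth: dict[str, np.ndarray] = field(default_factory=dict)
    t2c: dict[str, np.ndarray] = field(default_factory=dict)
    other_mm: dict[str, np.ndarray] = field(default_factory=dict)
    ref: dict[str, np.ndarray] | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def chroms(self) -> list[str]:
        return sorted(self.depth)

    def columns(self) -> Iterator[PileupColumn]:
        """Yield covered positions as :class:`PileupColumn`, sorted."""
        for chrom in self.chroms:
            depth = self.depth[chrom]
            for pos in np.nonzero(depth)[0]:
                pos = int(pos)
                if self.ref is not None:
                    base = chr(self.ref[chrom][pos])
                    if self.strand == "-":
                        base = _COMPLEMENT.get(base, "N")
                else:
                    base = "N"
                yield PileupColumn(
                    chrom=chrom,
                    pos=pos,
                    strand=self.strand,
                    ref_base=base,
                    depth=int(depth[pos]),
                    t2c=int(self.t2c[chrom][pos]),
                    other_mm=int(self.other_mm[chrom][pos]),
                )

    def total(self, kind: str) -> int:
        arrays = getattr(self, kind)
        return int(sum(a.sum() for a in arrays.values()))


@dataclass
class PileupResult:
    """Raw output of the alignment walk, shared by tracks and QC spectrum.

    ``pairs`` maps (strand, chrom) -> {pos -> {(ref, read): count}} in
    forward reference space; ``depth`` maps the same keys to dense arrays.
    """

    chrom_lengths: dict[str, int]
    ref: dict[str, np.ndarray]
    depth: dict[tuple[str, str], np.ndarray]
    pairs: dict[tuple[str, str], dict[int, dict[tuple[str, str], int]]]
    n_reads: dict[str, int]


def _load_reference(fasta_path: str, chroms: dict[str, int]) -> dict[str, np.ndarray]:
    if not os.path.exists(str(fasta_path) + ".fai"):
        pysam.faidx(str(fasta_path))
    ref: dict[str, np.ndarray] = {}
    with pysam.FastaFile(str(fasta_path)) as fa:
        present = set(fa.references)
        for chrom, length in chroms.items():
            if chrom not in present:
                raise ValueError(f"chromosome {chrom!r} absent from reference FASTA")
            seq = fa.fetch(chrom).upper()
            arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
            if len(arr) < length:
                arr = np.concatenate([arr, np.full(length - len(arr), _N, np.uint8)])
            ref[chrom] = arr
    return ref


def pileup_alignments(
    alignments: str,
    reference: str,
    min_mapq: int = 55,
    min_baseq: int = 20,
    exclude_duplicates: bool = True,
    exclude_supplementary: bool = True,
) -> PileupResult:
    """Walk every passing alignment and accumulate per-base counts.

    Plus-strand reads: FLAG 0x10 clear and 0x100 clear; minus-strand reads:
    0x10 set, 0x100 clear.  A base contributes to depth iff it passes the
    base-quality filter and neither read nor reference base is N; mismatch
    counts come from exactly the depth-eligible bases.
    """
    path = str(alignments)
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode) as af:
        if path.endswith(".bam") and not af.has_index():
            raise FileNotFoundError(f"BAM index missing for {path} (run samtools index)")
        chrom_lengths = dict(zip(af.references, af.lengths))
        ref = _load_reference(reference, chrom_lengths)
        depth: dict[tuple[str, str], np.ndarray] = {}
        pairs: dict[tuple[str, str], dict[int, dict[tuple[str, str], int]]] = {}
        n_reads = {"+": 0, "-": 0}

        for read in af:
            if read.is_unmapped or read.is_secondary:
                continue
            if exclude_duplicates and read.is_duplicate:
                continue
            if exclude_supplementary and read.is_supplementary:
                continue
            if read.mapping_quality < min_mapq:
                continue
            strand = "-" if read.is_reverse else "+"
            chrom = read.reference_name
            key = (strand, chrom)
            if key not in depth:
                depth[key] = np.zeros(chrom_lengths[chrom], dtype=np.int32)
                pairs[key] = {}
            n_reads[strand] += 1
            _accumulate_read(read, ref[chrom], depth[key], pairs[key], min_baseq)

    return PileupResult(
        chrom_lengths=chrom_lengths, ref=ref, depth=depth, pairs=pairs, n_reads=n_reads
    )


def _accumulate_read(read, refarr, depth, pairs, min_baseq) -> None:
    seq = read.query_sequence
    if seq is None:
        return
    quals = read.query_qualities
    cig = read.cigartuples
    if cig is not None and len(cig) == 1 and cig[0][0] == 0:
        # ungapped alignment: vectorised compare of read vs reference slice
        rs = read.reference_start
        q = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        r = refarr[rs : rs + len(q)]
        valid = (q != _N) & (r != _N)
        if quals is not None:
            valid &= np.asarray(quals, dtype=np.int32) >= min_baseq
        idx = np.nonzero(valid)[0]
        depth[rs + idx] += 1
        for i in np.nonzero(valid & (q != r))[0]:
            pos = rs + int(i)
            pair = (chr(r[i]), chr(q[i]))
            col = pairs.setdefault(pos, {})
            col[pair] = col.get(pair, 0) + 1
        return
    # gapped/spliced: per aligned base (indels and N gaps contribute nothing)
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        if quals is not None and quals[qpos] < min_baseq:
            continue
        qb = seq[qpos].upper()
        rb = chr(refarr[rpos])
        if qb == "N" or rb == "N":
            continue
        depth[rpos] += 1
        if qb != rb:
            col = pairs.setdefault(rpos, {})
            col[(rb, qb)] = col.get((rb, qb), 0) + 1


def build_tracks(
    alignments: str,
    reference: str,
    min_mapq: int = 55,
    min_baseq: int = 20,
    exclude_duplicates: bool = True,
    exclude_supplementary: bool = True,
) -> tuple[MismatchTrack, MismatchTrack]:
    """Build the (plus, minus) :class:`MismatchTrack` pair from a BAM/SAM.

    Returns two tracks sharing the same reference; an alignment file with no
    passing reads yields two empty tracks.
    """
    res = pileup_alignments(
        alignments,
        reference,
        min_mapq=min_mapq,
        min_baseq=min_baseq,
        exclude_duplicates=exclude_duplicates,
        exclude_supplementary=exclude_supplementary,
    )
    provenance = {
        "alignments": str(alignments),
        "min_mapq": min_mapq,
        "min_baseq": min_baseq,
        "n_reads": dict(res.n_reads),
        "library_size": res.n_reads["+"] + res.n_reads["-"],
    }
    tracks = {}
    for strand in "+-":
        t2c_pair = _T2C_PAIR[strand]
        track = MismatchTrack(strand=strand, ref=res.ref, provenance=dict(provenance))
        for (s, chrom), depth in res.depth.items():
            if s != strand:
                continue
            t2c = np.zeros_like(depth)
            other = np.zeros_like(depth)
            for pos, col in res.pairs[(s, chrom)].items():
                for pair, n in col.items():
                    if pair == t2c_pair:
                        t2c[pos] += n
                    else:
                        other[pos] += n
            track.depth[chrom] = depth
            track.t2c[chrom] = t2c
            track.other_mm[chrom] = other
        tracks[strand] = track
    return tracks["+"], tracks["-"]


def write_bedgraph(track: MismatchTrack, which: str, out: str) -> None:
    """Write one metric of a track as 4-column bedGraph.

    Zero-valued positions are omitted; adjacent equal-value positions are
    run-length merged, so a write/read round trip reproduces per-base
    values exactly.
    """
    if which not in TRACK_KINDS:
        raise ValueError(f"which must be one of {TRACK_KINDS}, got {which!r}")
    arrays = getattr(track, which)
    with open(out, "w") as fh:
        fh.write(f"track type=bedGraph name={which}_{track.strand}\n")
        for chrom in track.chroms:
            for start, end, value in _runs(arrays[chrom]):
                fh.write(f"{chrom}\t{start}\t{end}\t{value}\n")


def _runs(arr: np.ndarray) -> Iterator[tuple[int, int, int]]:
    """Run-length encode the non-zero stretches of a dense array."""
    if len(arr) == 0:
        return
    change = np.nonzero(np.diff(arr))[0] + 1
    bounds = np.concatenate([[0], change, [len(arr)]])
    for s, e in zip(bounds[:-1], bounds[1:]):
        v = int(arr[s])
        if v != 0:
            yield int(s), int(e), v


def _read_bedgraph(path: str) -> dict[str, list[tuple[int, int, int]]]:
    data: dict[str, list[tuple[int, int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            chrom, start, end, value = parts
            data.setdefault(chrom, []).append((int(start), int(end), int(float(value))))
    for chrom, ivals in data.items():
        ivals.sort()
        for (s1, e1, _), (s2, _, _) in zip(ivals, ivals[1:]):
            if s2 < e1:
                raise ValueError(
                    f"{path}: overlapping intervals on {chrom} at position {s2}"
                )
    return data


def read_bedgraph_pair(
    depth_bg: str, t2c_bg: str, other_bg: str, strand: str
) -> MismatchTrack:
    """Reconstruct a :class:`MismatchTrack` from its three bedGraph files.

    Inverse of :func:`write_bedgraph` on its own outputs.  The t2c/other
    files must only assert counts where depth is positive.
    """
    parsed = {
        "depth": _read_bedgraph(depth_bg),
        "t2c": _read_bedgraph(t2c_bg),
        "other_mm": _read_bedgraph(other_bg),
    }
    chroms: dict[str, int] = {}
    for data in parsed.values():
        for chrom, ivals in data.items():
            if ivals:
                chroms[chrom] = max(chroms.get(chrom, 0), ivals[-1][1])
    track = MismatchTrack(strand=strand, ref=None)
    for chrom, length in chroms.items():
        for kind in TRACK_KINDS:
            arr = np.zeros(length, dtype=np.int32)
            for s, e, v in parsed[kind].get(chrom, []):
                arr[s:e] = v
            getattr(track, kind)[chrom] = arr
    for chrom in track.depth:
        mism = track.t2c[chrom] + track.other_mm[chrom]
        bad = np.nonzero((track.depth[chrom] == 0) & (mism > 0))[0]
        if len(bad):
            raise ValueError(
                f"mismatch counts without depth on {chrom} at position {int(bad[0])}"
            )
    return track
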