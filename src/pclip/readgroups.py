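"""Read groups: candidate RBP interaction intervals derived from coverage.

A read group is a maximal run of positions at or above a minimum depth,
optionally merged with book-ended neighbours and then split so that no
group exceeds a maximum width (default 50 nt, a typical upper bound on an
RBP footprint — unsplit multi-kilobase pileups over repeats would otherwise
dominate the called set).  Each group is then quantified against the
mismatch tracks to obtain its total sequenced bases n_i, observed T-to-C
count O_i and background mismatch count, the inputs of the Poisson test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .tracks import MismatchTrack

DEFAULT_MIN_DEPTH = 3
DEFAULT_MAX_WIDTH = 50


class GenomicInterval(NamedTuple):
    chrom: str
    start: int
    end: int
    strand: str


@dataclass(frozen=True)
class ReadGroup:
    """A candidate interval with its per-group pileup statistics."""

    chrom: str
    start: int
    end: int
    strand: str
    n_bases: int      # sum of column depths over [start, end)
    o_t2c: int        # observed strand-local T->C count
    other_mm: int     # background (non-T->C) mismatch count
    max_depth: int

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


def extract_regions(
    track: MismatchTrack, min_depth: int = DEFAULT_MIN_DEPTH
) -> list[GenomicInterval]:
    """Maximal runs of consecutive positions with depth >= ``min_depth``."""
    if min_depth < 1:
        raise ValueError("min_depth must be positive")
    out: list[GenomicInterval] = []
    for chrom in track.chroms:
        mask = track.depth[chrom] >= min_depth
        padded = np.concatenate([[False], mask, [False]])
        edges = np.nonzero(np.diff(padded.astype(np.int8)))[0]
        for s, e in zip(edges[::2], edges[1::2]):
            out.append(GenomicInterval(chrom, int(s), int(e), track.strand))
    return out


def merge_adjacent(
    intervals: Sequence[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Union intervals on the same chrom/strand whose separation is <= gap."""
    if gap < 0:
        raise ValueError("gap must be non-negative")
    by_key: dict[tuple[str, str], list[GenomicInterval]] = {}
    for iv in intervals:
        by_key.setdefault((iv.chrom, iv.strand), []).append(iv)
    out: list[GenomicInterval] = []
    for (chrom, strand), ivals in sorted(by_key.items()):
        ivals.sort()
        cur_s, cur_e = ivals[0].start, ivals[0].end
        for iv in ivals[1:]:
            if iv.start - cur_e <= gap:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e, strand))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_s, cur_e, strand))
    return out


def split_max_width(
    intervals: Sequence[GenomicInterval], max_width: int = DEFAULT_MAX_WIDTH
) -> list[GenomicInterval]:
    """Tile over-long intervals into ceil(L/max_width) near-equal pieces.

    Pieces within one input are contiguous, differ in width by at most one
    base, and concatenate back to the input exactly.  Equal-sized pieces
    avoid a systematically short (underpowered) terminal fragment.
    """
    if max_width < 1:
        raise ValueError("max_width must be positive")
    out: list[GenomicInterval] = []
    for iv in intervals:
        length = iv.end - iv.start
        if length <= max_width:
            out.append(iv)
            continue
        n = math.ceil(length / max_width)
        base, rem = divmod(length, n)
        pos = iv.start
        for i in range(n):
            w = base + (1 if i < rem else 0)
            out.append(GenomicInterval(iv.chrom, pos, pos + w, iv.strand))
            pos += w
    return out


def quantify_groups(
    intervals: Sequence[GenomicInterval],
    track: MismatchTrack,
    drop_empty: bool = False,
) -> list[ReadGroup]:
    """Sum depth / T->C / other-mismatch columns over each interval.

    Intervals must match the track's strand.  An interval outside the
    covered footprint yields an all-zero group; with ``drop_empty`` those
    are removed.
    """
    groups: list[ReadGroup] = []
    for iv in sorted(intervals):
        if iv.strand != track.strand:
            raise ValueError(
                f"interval strand {iv.strand} does not match track strand {track.strand}"
            )
        depth = track.depth.get(iv.chrom)
        if depth is None:
            g = ReadGroup(iv.chrom, iv.start, iv.end, iv.strand, 0, 0, 0, 0)
        else:
            sl = slice(iv.start, iv.end)
            d = depth[sl]
            g = ReadGroup(
                chrom=iv.chrom,
                start=iv.start,
                end=iv.end,
                strand=iv.strand,
                n_bases=int(d.sum()),
                o_t2c=int(track.t2c[iv.chrom][sl].sum()),
                other_mm=int(track.other_mm[iv.chrom][sl].sum()),
                max_depth=int(d.max()) if len(d) else 0,
            )
        if drop_empty and g.n_bases == 0:
            continue
        groups.append(g)
    return groups


def derive_read_groups(
    plus: MismatchTrack,
    minus: MismatchTrack,
    min_depth: int = DEFAULT_MIN_DEPTH,
    gap: int = 0,
    max_width: int = DEFAULT_MAX_WIDTH,
) -> list[ReadGroup]:
    """Full extract -> merge -> split -> quantify pipeline over both strands.

    Output is sorted by (chrom, start, strand); groups with no sequenced
    bases (possible only with gap-merging across uncovered stretches) are
    dropped.
    """
    groups: list[ReadGroup] = []
    for track in (plus, minus):
        intervals = extract_regions(track, min_depth)
        intervals = merge_adjacent(intervals, gap)
        intervals = split_max_width(intervals, max_width)
        groups.extend(quantify_groups(intervals, track, drop_empty=True))
    groups.sort(key=lambda g: (g.chrom, g.start, g.end, g.strand))
    return groups


def write_groups_bed(groups: Sequence[ReadGroup], out: str, prefix: str = "RG") -> None:
    """Write groups as BED6 + n_bases, o_t2c, other_mm, max_depth columns."""
    with open(out, "w") as fh:
        for i, g in enumerate(groups, start=1):
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{prefix}{i}\t{g.o_t2c}\t{g.strand}"
                f"\t{g.n_bases}\t{g.o_t2c}\t{g.other_mm}\t{g.max_depth}\n"
            )
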