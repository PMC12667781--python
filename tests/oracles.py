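"""Independent brute-force oracles used to cross-check the implementation.

Deliberately written without pysam/scipy/statsmodels: SAM text is parsed by
hand and the CIGAR is walked character by character, so agreement with the
package is a genuine dual-route check.
"""

from __future__ import annotations

import math
import re

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def parse_fasta(path):
    seqs, name, chunks = {}, None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name, chunks = line[1:].split()[0], []
            else:
                chunks.append(line.upper())
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def naive_pileup(sam_path, fasta_path, min_mapq=55, min_baseq=20):
    """Per-read, per-base reference walk over a SAM text file.

    Returns {(strand, chrom, pos): [depth, t2c, other_mm]} using the same
    filter semantics as the package: secondary/duplicate/supplementary and
    unmapped reads skipped entirely, minus-strand T->C = reference-space
    A->G, N bases excluded from everything.
    """
    ref = parse_fasta(fasta_path)
    counts: dict[tuple[str, str, int], list[int]] = {}
    with open(sam_path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            f = line.rstrip("\n").split("\t")
            flag, chrom, pos, mapq = int(f[1]), f[2], int(f[3]) - 1, int(f[4])
            cigar, seq, qual = f[5], f[9], f[10]
            if flag & (0x4 | 0x100 | 0x400 | 0x800):
                continue
            if mapq < min_mapq:
                continue
            strand = "-" if flag & 0x10 else "+"
            qpos, rpos = 0, pos
            for n, op in _CIGAR_RE.findall(cigar):
                n = int(n)
                if op in "M=X":
                    for i in range(n):
                        qb = seq[qpos + i].upper()
                        rb = ref[chrom][rpos + i]
                        bq = 0xFF if qual == "*" else ord(qual[qpos + i]) - 33
                        if bq < min_baseq or qb == "N" or rb == "N":
                            continue
                        key = (strand, chrom, rpos + i)
                        cell = counts.setdefault(key, [0, 0, 0])
                        cell[0] += 1
                        if qb != rb:
                            if strand == "-":
                                rb, qb = _COMP[rb], _COMP[qb]
                            if (rb, qb) == ("T", "C"):
                                cell[1] += 1
                            else:
                                cell[2] += 1
                    qpos += n
                    rpos += n
                elif op in "IS":
                    qpos += n
                elif op in "DN":
                    rpos += n
                # H and P consume nothing we track
    return counts


def track_to_dict(track):
    """Flatten a MismatchTrack into the oracle's representation."""
    out = {}
    for col in track.columns():
        out[(col.strand, col.chrom, col.pos)] = [col.depth, col.t2c, col.other_mm]
    return out


def poisson_upper_tail_oracle(observed: int, lam: float) -> float:
    """P(X >= observed) by direct pmf summation (log-space start, then the
    multiplicative recurrence), independent of the incomplete gamma route."""
    if observed <= 0:
        return 1.0
    if lam == 0:
        return 0.0
    log_term = -lam + observed * math.log(lam) - math.lgamma(observed + 1)
    term = math.exp(log_term)
    total = 0.0
    k = observed
    terms = []
    while True:
        terms.append(term)
        k += 1
        term *= lam / k
        if term < 1e-18 * (sum(terms) + term) or k > observed + 10_000:
            terms.append(term)
            break
    return min(1.0, math.fsum(terms))


def bh_oracle(p_values):
    """Textbook BH: sort ascending, p(i)*m/i, cumulative min from the top."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p_values[i] * m / rank)
        q[i] = running
    return q


def merge_intervals_oracle(intervals, gap=0):
    """Brute-force merge by repeated pairwise union until fixed point."""
    items = [list(iv) for iv in intervals]  # (chrom, start, end, strand)
    changed = True
    while changed:
        changed = False
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                a, b = items[i], items[j]
                if a[0] == b[0] and a[3] == b[3]:
                    if b[1] - a[2] <= gap and a[1] - b[2] <= gap:
                        a[1], a[2] = min(a[1], b[1]), max(a[2], b[2])
                        del items[j]
                        changed = True
                        break
            if changed:
                break
    return sorted(tuple(x) for x in items)
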