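"""QC and comparison utilities: substitution spectrum, normalized mismatch
track export, multi-BED overlap (Venn) matrices, and per-gene T-to-C
correlation across samples.

The 12-type substitution spectrum is the standard sanity check of a
PAR-CLIP library: with effective crosslinking, T-to-C should dominate the
other 11 substitution types by an order of magnitude or more.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import read_bed6
from .tracks import MismatchTrack, pileup_alignments

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
SUBSTITUTION_TYPES = tuple(
    (r, q) for r in "ACGT" for q in "ACGT" if r != q
)  # 12 ordered pairs


@dataclass(frozen=True)
class SubstitutionSpectrum:
    """Counts of the 12 substitution types in strand-local base space."""

    counts: dict[tuple[str, str], int]
    total_bases: int

    def fractions(self) -> dict[tuple[str, str], float]:
        total = sum(self.counts.values())
        if total == 0:
            return {k: 0.0 for k in self.counts}
        return {k: v / total for k, v in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        frac = self.fractions()
        return pd.DataFrame(
            {
                "substitution": [f"{r}>{q}" for r, q in SUBSTITUTION_TYPES],
                "count": [self.counts[p] for p in SUBSTITUTION_TYPES],
                "fraction": [frac[p] for p in SUBSTITUTION_TYPES],
            }
        )


def substitution_spectrum(
    alignments: str,
    reference: str,
    min_depth: int = 0,
    min_mapq: int = 55,
    min_baseq: int = 20,
) -> SubstitutionSpectrum:
    """Count all 12 substitution types over both strands.

    Minus-strand pairs are complemented into strand-local space before
    tallying, so a crosslink event on either strand lands on T>C.  With
    ``min_depth`` > 0 only columns at or above that depth contribute
    (mismatches and the ``total_bases`` denominator alike); by default
    there is no depth restriction.
    """
    res = pileup_alignments(
        alignments, reference, min_mapq=min_mapq, min_baseq=min_baseq
    )
    counts = {p: 0 for p in SUBSTITUTION_TYPES}
    total_bases = 0
    for (strand, chrom), depth in res.depth.items():
        if min_depth > 0:
            eligible = depth >= min_depth
            total_bases += int(depth[eligible].sum())
        else:
            eligible = None
            total_bases += int(depth.sum())
        for pos, col in res.pairs[(strand, chrom)].items():
            if eligible is not None and not eligible[pos]:
                continue
            for (rb, qb), n in col.items():
                if strand == "-":
                    rb, qb = _COMP[rb], _COMP[qb]
                counts[(rb, qb)] += n
    return SubstitutionSpectrum(counts=counts, total_bases=total_bases)


def export_mismatch_track(
    plus: MismatchTrack,
    minus: MismatchTrack,
    which: str = "T2C",
    normalization: str = "CPM",
    library_size: int | None = None,
    out: str = "mismatch.bedGraph",
    chrom_sizes: str | None = None,
) -> str:
    """Write a genome track of T-to-C (or non-T-to-C) mismatch counts.

    Strands are summed per genomic position.  Under CPM every count is
    scaled by 1e6 / library_size, where the library size defaults to the
    number of quality-passing uniquely mapped reads recorded when the
    tracks were built.  Output is bedGraph; when a chromosome-sizes file is
    given and pyBigWig is available, a bigWig is written instead.
    Returns the path written.
    """
    if which not in ("T2C", "nonT2C"):
        raise ValueError("which must be 'T2C' or 'nonT2C'")
    if normalization not in ("raw", "CPM"):
        raise ValueError("normalization must be 'raw' or 'CPM'")
    kind = "t2c" if which == "T2C" else "other_mm"
    if normalization == "CPM":
        if library_size is None:
            library_size = plus.provenance.get("library_size")
        if not library_size or library_size <= 0:
            raise ValueError("CPM normalization requires a positive library_size")
        scale = 1e6 / library_size
    else:
        scale = 1.0

    chroms = sorted(set(plus.depth) | set(minus.depth))
    values: dict[str, np.ndarray] = {}
    for chrom in chroms:
        length = max(
            len(getattr(t, kind).get(chrom, ())) for t in (plus, minus)
        )
        arr = np.zeros(length, dtype=float)
        for t in (plus, minus):
            a = getattr(t, kind).get(chrom)
            if a is not None:
                arr[: len(a)] += a
        values[chrom] = arr * scale

    if chrom_sizes is not None:
        try:
            return _write_bigwig(values, chrom_sizes, out)
        except ImportError:
            warnings.warn("pyBigWig unavailable; writing bedGraph instead")
    with open(out, "w") as fh:
        fh.write(f"track type=bedGraph name={which}_{normalization}\n")
        for chrom in chroms:
            arr = values[chrom]
            nz = np.nonzero(arr)[0]
            for pos in nz:
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{arr[pos]:.6g}\n")
    return out


def _write_bigwig(values: dict[str, np.ndarray], chrom_sizes: str, out: str) -> str:
    import pyBigWig  # optional dependency

    sizes = {}
    with open(chrom_sizes) as fh:
        for line in fh:
            name, size = line.split()[:2]
            sizes[name] = int(size)
    bw = pyBigWig.open(out, "w")
    bw.addHeader([(c, sizes[c]) for c in sorted(values) if c in sizes])
    for chrom in sorted(values):
        arr = values[chrom]
        nz = np.nonzero(arr)[0]
        if len(nz):
            bw.addEntries(
                [chrom] * len(nz),
                [int(p) for p in nz],
                ends=[int(p) + 1 for p in nz],
                values=[float(arr[p]) for p in nz],
            )
    bw.close()
    return out


# ---------------------------------------------------------------------------
# BED overlap (Venn) matrices

@dataclass(frozen=True)
class OverlapMatrix:
    """Membership counts for 2-3 interval (or gene) sets.

    ``region_counts`` maps each non-empty membership combination (a
    frozenset of set names) to counts.  In coordinate mode the value is a
    per-set-perspective dict (how many of *that* set's intervals fall in
    the combination) plus a ``"union"`` entry counting merged union
    regions; in gene mode it is a plain exclusive-combination count.
    """

    set_names: tuple[str, ...]
    region_counts: dict[frozenset, dict[str, int] | int]
    mode: str

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for combo in sorted(self.region_counts, key=lambda c: (len(c), sorted(c))):
            entry = self.region_counts[combo]
            label = "&".join(sorted(combo))
            if isinstance(entry, dict):
                row = {"combination": label, **entry}
            else:
                row = {"combination": label, "count": entry}
            rows.append(row)
        return pd.DataFrame(rows)


def _interval_sets(paths, labels):
    sets = {}
    for label, path in zip(labels, paths):
        df = read_bed6(path)
        sets[label] = [
            (r.chrom, int(r.start), int(r.end), r.strand) for r in df.itertuples()
        ]
    return sets


def _build_trees(intervals):
    from intervaltree import IntervalTree

    trees: dict[tuple[str, str], IntervalTree] = {}
    for chrom, start, end, strand in intervals:
        trees.setdefault((chrom, strand), IntervalTree()).addi(start, end)
    return trees


def compare_beds(
    beds: list[str],
    mode: str = "coordinate",
    labels: list[str] | None = None,
    gene_column: int = 8,
) -> OverlapMatrix:
    """Overlap matrix over 2-3 BED6(+) files.

    Coordinate mode: an interval of set A belongs to the combination of A
    with every other set it overlaps (>= 1 bp, strand-matched); counts are
    reported from each set's perspective, plus a merged-union view where
    overlapping intervals across all sets are unioned and each union
    region is labelled by the sets contributing to it.  Gene mode: plain
    set algebra over the distinct gene names found in ``gene_column``
    (1-based; default 8, the gene-name column of annotated cluster files).
    """
    if not 2 <= len(beds) <= 3:
        raise ValueError("compare_beds accepts 2 or 3 BED files; this is the highest limit")
    if labels is None:
        labels = [f"set{i + 1}" for i in range(len(beds))]
    if mode == "gene":
        return _compare_genes(beds, labels, gene_column)
    if mode != "coordinate":
        raise ValueError("mode must be 'coordinate' or 'gene'")

    sets = _interval_sets(beds, labels)
    trees = {label: _build_trees(ivs) for label, ivs in sets.items()}
    counts: dict[frozenset, dict[str, int]] = {}

    for label, ivs in sets.items():
        for chrom, start, end, strand in ivs:
            members = {label}
            for other, otrees in trees.items():
                if other == label:
                    continue
                tree = otrees.get((chrom, strand))
                if tree is not None and tree.overlap(start, end):
                    members.add(other)
            combo = frozenset(members)
            counts.setdefault(combo, {lbl: 0 for lbl in labels})
            counts[combo][label] += 1

    # merged-union view: union all intervals, label each region by the
    # sets whose intervals overlap it
    union_events: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
    for label, ivs in sets.items():
        for chrom, start, end, strand in ivs:
            union_events.setdefault((chrom, strand), []).append((start, end, label))
    for key, events in union_events.items():
        events.sort()
        cur_s, cur_e, cur_members = events[0][0], events[0][1], {events[0][2]}
        regions = []
        for s, e, label in events[1:]:
            if s < cur_e:
                cur_e = max(cur_e, e)
                cur_members.add(label)
            else:
                regions.append(frozenset(cur_members))
                cur_s, cur_e, cur_members = s, e, {label}
        regions.append(frozenset(cur_members))
        for combo in regions:
            counts.setdefault(combo, {lbl: 0 for lbl in labels})
            counts[combo]["union"] = counts[combo].get("union", 0) + 1
    for entry in counts.values():
        entry.setdefault("union", 0)
    return OverlapMatrix(set_names=tuple(labels), region_counts=counts, mode="coordinate")


def _compare_genes(beds, labels, gene_column):
    gene_sets: dict[str, set[str]] = {}
    for label, path in zip(labels, beds):
        df = read_bed6(path)
        if df.shape[1] < gene_column:
            raise ValueError(
                f"{path}: gene mode needs a column {gene_column}, found {df.shape[1]}"
            )
        col = df.iloc[:, gene_column - 1]
        gene_sets[label] = {g for g in col if g not in (".", "", None)}
    if not any(gene_sets.values()):
        raise ValueError("no gene identifiers found in any input")
    counts: dict[frozenset, int] = {}
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            inside = set.intersection(*(gene_sets[l] for l in combo))
            outside = set.union(
                *(gene_sets[l] for l in labels if l not in combo), set()
            )
            counts[frozenset(combo)] = len(inside - outside)
    return OverlapMatrix(set_names=tuple(labels), region_counts=counts, mode="gene")


# ---------------------------------------------------------------------------
# per-gene T-to-C correlation

def gene_t2c_matrix(
    annotated_beds: list[str],
    sample_names: list[str] | None = None,
    method: str = "spearman",
    gene_id_column: int = 9,
    t2c_column: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene T-to-C totals per sample, plus the sample correlation matrix.

    Inputs are annotated cluster files (BED6 + feature/gene_name/gene_id,
    with the cluster's observed T-to-C count in the score column).  A gene
    absent from a sample counts 0; genes must be present in at least one
    sample.  ``method`` is 'spearman' (rank) or 'pearson' (linear).
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    if sample_names is None:
        sample_names = [f"sample{i + 1}" for i in range(len(annotated_beds))]
    per_sample = {}
    for name, path in zip(sample_names, annotated_beds):
        df = read_bed6(path)
        if df.shape[1] < gene_id_column:
            raise ValueError(f"{path}: expected >= {gene_id_column} columns")
        genes = df.iloc[:, gene_id_column - 1]
        t2c = pd.to_numeric(df.iloc[:, t2c_column - 1])
        keep = ~genes.isin([".", ""])
        per_sample[name] = t2c[keep].groupby(genes[keep]).sum()
    matrix = pd.DataFrame(per_sample).fillna(0.0)
    if matrix.empty:
        raise ValueError("no annotated genes shared across inputs")
    return matrix, matrix.corr(method=method)
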