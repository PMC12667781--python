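"""Assign clusters to genes and genomic features from an ENSEMBL-style GTF.

A cluster overlapping a single protein-coding gene is labelled with the
highest-priority feature it touches, in the order 3'UTR > CDS > 5'UTR >
intron (the convention for CLIP data, where 3'UTR binding is the signal of
primary interest).  A single non-coding gene contributes its biotype as the
label (miRNA, lncRNA, ...).  Overlap with more than one distinct gene is
flagged ``multigenic``; no strand-matched overlap at all is ``intergenic``.
Overlap is strand-matched with a 1 bp minimum by default, consistent with
the strand-specific construction of the clusters.  tRNAs are not assigned
(they are absent from canonical GTFs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
import pyranges
from intervaltree import IntervalTree

FEATURE_PRIORITY = ("3'UTR", "CDS", "5'UTR", "intron")

_GTF_FEATURE_MAP = {
    "three_prime_utr": "3'UTR",
    "CDS": "CDS",
    "five_prime_utr": "5'UTR",
}


@dataclass(frozen=True)
class Annotation:
    """Feature label plus gene identity for one interval."""

    feature: str
    gene_name: str = "."
    gene_id: str = "."


@dataclass
class GeneRecord:
    gene_id: str
    gene_name: str
    biotype: str
    chrom: str
    strand: str
    start: int
    end: int
    # feature label -> list of (start, end), 0-based half-open
    features: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    exons: list[tuple[int, int]] = field(default_factory=list)
    introns: list[tuple[int, int]] = field(default_factory=list)


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivals:
        return []
    ivals = sorted(ivals)
    out = [list(ivals[0])]
    for s, e in ivals[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _subtract(span: tuple[int, int], blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Span minus the union of blocks (used for intron derivation)."""
    out = []
    pos = span[0]
    for s, e in _merge_intervals(blocks):
        s, e = max(s, span[0]), min(e, span[1])
        if s > pos:
            out.append((pos, s))
        pos = max(pos, e)
    if pos < span[1]:
        out.append((pos, span[1]))
    return out


@dataclass
class FeatureIndex:
    """Genes indexed by (chrom, strand) interval trees for overlap queries."""

    genes: dict[str, GeneRecord]
    _trees: dict[tuple[str, str], IntervalTree]

    def overlapping_genes(
        self, chrom: str, start: int, end: int, strand: str | None
    ) -> list[GeneRecord]:
        """Genes whose span overlaps [start, end) by >= 1 bp, strand-matched
        when a strand is given."""
        strands = [strand] if strand in ("+", "-") else ["+", "-"]
        hits: set[str] = set()
        for s in strands:
            tree = self._trees.get((chrom, s))
            if tree is not None:
                hits.update(iv.data for iv in tree.overlap(start, end))
        return [self.genes[g] for g in sorted(hits)]


def build_feature_index(gtf: str) -> FeatureIndex:
    """Parse a GTF (plain or gzipped) into a queryable :class:`FeatureIndex`.

    Requires gene/exon records carrying ``gene_id`` and ``gene_biotype``
    attributes; ``gene_name`` falls back to the gene_id.  A GTF dialect
    that emits plain ``UTR`` records gets its UTRs sided by position
    relative to the gene's CDS on the transcript strand.  Introns are the
    gene span minus the union of that gene's exons.
    """
    df = pyranges.read_gtf(str(gtf)).df
    if df.empty:
        return FeatureIndex(genes={}, _trees={})
    if "gene_id" not in df.columns:
        raise ValueError("GTF lacks gene_id attributes")
    if "gene_biotype" not in df.columns:
        # GENCODE calls it gene_type
        if "gene_type" in df.columns:
            df = df.rename(columns={"gene_type": "gene_biotype"})
        else:
            df["gene_biotype"] = "protein_coding"
    if "gene_name" not in df.columns:
        df["gene_name"] = df["gene_id"]
    df["gene_name"] = df["gene_name"].fillna(df["gene_id"])
    missing = df["gene_id"].isna()
    if missing.any():
        raise ValueError(f"GTF record without gene_id (row {int(missing.idxmax())})")

    genes: dict[str, GeneRecord] = {}
    for gid, sub in df.groupby("gene_id", sort=True):
        first = sub.iloc[0]
        gene_rows = sub[sub["Feature"] == "gene"]
        span_src = gene_rows if len(gene_rows) else sub
        start, end = int(span_src["Start"].min()), int(span_src["End"].max())
        rec = GeneRecord(
            gene_id=str(gid),
            gene_name=str(first["gene_name"]),
            biotype=str(first["gene_biotype"]),
            chrom=str(first["Chromosome"]),
            strand=str(first["Strand"]),
            start=start,
            end=end,
        )
        cds: list[tuple[int, int]] = []
        plain_utr: list[tuple[int, int]] = []
        for _, row in sub.iterrows():
            iv = (int(row["Start"]), int(row["End"]))
            feat = row["Feature"]
            if feat == "exon":
                rec.exons.append(iv)
            elif feat in _GTF_FEATURE_MAP:
                rec.features.setdefault(_GTF_FEATURE_MAP[feat], []).append(iv)
                if feat == "CDS":
                    cds.append(iv)
            elif feat == "UTR":
                plain_utr.append(iv)
        if plain_utr and cds:
            cds_lo = min(s for s, _ in cds)
            cds_hi = max(e for _, e in cds)
            for s, e in plain_utr:
                upstream = e <= cds_lo
                if rec.strand == "+":
                    label = "5'UTR" if upstream else "3'UTR"
                else:
                    label = "3'UTR" if upstream else "5'UTR"
                rec.features.setdefault(label, []).append((s, e))
        rec.exons = _merge_intervals(rec.exons)
        rec.introns = _subtract((rec.start, rec.end), rec.exons)
        rec.features["intron"] = rec.introns
        genes[rec.gene_id] = rec

    trees: dict[tuple[str, str], IntervalTree] = {}
    for rec in genes.values():
        tree = trees.setdefault((rec.chrom, rec.strand), IntervalTree())
        tree.addi(rec.start, rec.end, rec.gene_id)
    return FeatureIndex(genes=genes, _trees=trees)


def _overlaps_any(start: int, end: int, ivals: list[tuple[int, int]]) -> bool:
    return any(s < end and start < e for s, e in ivals)


def annotate_interval(
    chrom: str,
    start: int,
    end: int,
    strand: str,
    index: FeatureIndex,
    stranded: bool = True,
) -> Annotation:
    """Annotate one interval against the index (pure function of both).

    Resolution: >1 overlapping gene -> multigenic; one non-coding gene ->
    its biotype; one coding gene -> highest-priority overlapped feature.
    """
    hits = index.overlapping_genes(chrom, start, end, strand if stranded else None)
    if not hits:
        return Annotation(feature="intergenic")
    if len(hits) > 1:
        return Annotation(
            feature="multigenic",
            gene_name=",".join(g.gene_name for g in hits),
            gene_id=",".join(g.gene_id for g in hits),
        )
    gene = hits[0]
    if gene.biotype != "protein_coding":
        return Annotation(feature=gene.biotype, gene_name=gene.gene_name, gene_id=gene.gene_id)
    for label in FEATURE_PRIORITY:
        if _overlaps_any(start, end, gene.features.get(label, [])):
            return Annotation(feature=label, gene_name=gene.gene_name, gene_id=gene.gene_id)
    # coding gene overlapped but no typed feature (UTR-less dialect): exonic
    return Annotation(feature="exon", gene_name=gene.gene_name, gene_id=gene.gene_id)


def read_bed6(path: str) -> pd.DataFrame:
    """Read a BED6(+) file, validating the first six columns."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected >= 6 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if parts[5] not in ("+", "-", "."):
                raise ValueError(f"{path}:{lineno}: bad strand {parts[5]!r}")
            rows.append([parts[0], start, end, parts[3], parts[4], parts[5]] + parts[6:])
    ncols = max((len(r) for r in rows), default=6)
    names = ["chrom", "start", "end", "name", "score", "strand"] + [
        f"extra{i}" for i in range(1, ncols - 5)
    ]
    return pd.DataFrame(rows, columns=names[:ncols])


def annotate_bed(
    bed: str, gtf: str, out: str, stranded: bool = True
) -> pd.DataFrame:
    """Annotate every BED row, appending feature / gene_name / gene_id.

    Input columns 1-6 and row order are preserved; output rows have exactly
    nine columns.
    """
    index = build_feature_index(gtf)
    df = read_bed6(bed)
    annotations = [
        annotate_interval(r.chrom, r.start, r.end, r.strand, index, stranded=stranded)
        for r in df.itertuples()
    ]
    out_df = df.iloc[:, :6].copy()
    out_df["feature"] = [a.feature for a in annotations]
    out_df["gene_name"] = [a.gene_name for a in annotations]
    out_df["gene_id"] = [a.gene_id for a in annotations]
    out_df.to_csv(out, sep="\t", header=False, index=False)
    return out_df
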