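"""Truth-known PAR-CLIP alignment simulator.

Generates a random reference chromosome, plants non-overlapping crosslink
sites, and emits ungapped single-end reads as a coordinate-sorted SAM file:
reads covering a planted site carry strand-local T-to-C conversions at the
configured rate, and every read base is additionally corrupted by a uniform
substitution process (each of the three alternative bases equally likely).
Under a uniform base composition that error process splits 11:1 between
background mismatches and accidental T-to-C, which makes the caller's
background rate estimate analytically checkable: the estimated per-type
rate converges to error_rate / 12.

Everything is deterministic given the seed; identical configs produce
byte-identical FASTA / SAM / BED / GTF outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_CHROM = "chr1"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic PAR-CLIP experiment.

    Defaults describe a desk-scale experiment: a 200 kb chromosome, 50
    planted 25-nt sites sequenced at 15x with a 30% crosslink conversion
    rate, 8x background coverage, and a 0.1% uniform per-base error rate
    (the order of combined RT + base-calling error after quality
    filtering).
    """

    seed: int = 0
    genome_length: int = 200_000
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    n_sites: int = 50
    site_width: int = 25
    conversion_rate: float = 0.3
    error_rate: float = 0.001
    read_length: int = 30
    site_depth: int = 15
    background_depth: float = 8.0
    minus_strand_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name in ("conversion_rate", "error_rate", "minus_strand_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not self.site_width <= self.read_length <= self.genome_length:
            raise ValueError("need site_width <= read_length <= genome_length")
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base_composition must sum to 1")


@dataclass(frozen=True)
class PlantedSite:
    chrom: str
    start: int
    end: int
    strand: str


def generate_reference(config: SimConfig) -> np.ndarray:
    """Random reference sequence as a uint8 byte array, seeded."""
    rng = np.random.default_rng(config.seed)
    comp = np.asarray(config.base_composition, dtype=float)
    if comp[3] == 0.0 and config.conversion_rate > 0:
        import warnings

        warnings.warn("base composition has no T but conversion_rate > 0")
    idx = rng.choice(4, size=config.genome_length, p=comp)
    return _BASES[idx]


def write_fasta(reference: np.ndarray, path: str, width: int = 70) -> None:
    seq = reference.tobytes().decode("ascii")
    with open(path, "w") as fh:
        fh.write(f">{_CHROM}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


def _strand_local_t_count(reference: np.ndarray, start: int, end: int, strand: str) -> int:
    # strand-local T on the minus strand is a forward-reference A
    target = ord("T") if strand == "+" else ord("A")
    return int(np.count_nonzero(reference[start:end] == target))


def plant_sites(config: SimConfig, reference: np.ndarray) -> list[PlantedSite]:
    """Place non-overlapping sites, each with >= 3 strand-local reference Ts.

    Uses its own seeded stream (offset from the config seed) so reference
    and site placement are independently reproducible.
    """
    rng = np.random.default_rng((config.seed + 1) % 2**31)
    sites: list[PlantedSite] = []
    occupied: list[tuple[int, int]] = []
    max_tries = 200 * max(config.n_sites, 1)
    tries = 0
    while len(sites) < config.n_sites:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                "could not place all sites; reduce n_sites or increase genome_length"
            )
        start = int(rng.integers(0, config.genome_length - config.site_width + 1))
        end = start + config.site_width
        if any(s < end and start < e for s, e in occupied):
            continue
        strand = "-" if rng.random() < config.minus_strand_fraction else "+"
        if _strand_local_t_count(reference, start, end, strand) < 3:
            continue
        occupied.append((start, end))
        sites.append(PlantedSite(_CHROM, start, end, strand))
    sites.sort(key=lambda s: s.start)
    return sites


def write_truth_bed(sites: list[PlantedSite], path: str) -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(sites, start=1):
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\tsite{i}\t0\t{s.strand}\n")


@dataclass(frozen=True)
class SimRead:
    start: int
    strand: str
    seq: str  # forward reference orientation, as stored in SAM


def _apply_errors(seq: np.ndarray, rng: np.random.Generator, error_rate: float) -> None:
    """Uniform substitution: each base flips to one of the 3 others w.p. error_rate."""
    if error_rate == 0:
        return
    hit = np.nonzero(rng.random(len(seq)) < error_rate)[0]
    for i in hit:
        alternatives = _BASES[_BASES != seq[i]]
        seq[i] = alternatives[rng.integers(0, 3)]


def simulate_reads(
    config: SimConfig, reference: np.ndarray, sites: list[PlantedSite]
) -> list[SimRead]:
    """Draw site and background reads with conversions and errors applied.

    Site reads always span their whole site (read_length >= site_width);
    conversions hit strand-local reference-T positions inside the site
    only.  Background reads land uniformly with strand chosen by a fair
    coin.  Sequences are kept in forward reference orientation, ready for
    SAM; the biological (strand-local) read is the reverse complement for
    minus-strand reads.
    """
    rng = np.random.default_rng((config.seed + 2) % 2**31)
    L = config.read_length
    G = config.genome_length
    reads: list[SimRead] = []

    for site in sites:
        lo = max(0, site.end - L)
        hi = min(site.start, G - L)
        if hi < lo:  # site flush against the chromosome end
            lo = hi = max(0, min(site.start, G - L))
        conv_from = ord("T") if site.strand == "+" else ord("A")
        conv_to = ord("C") if site.strand == "+" else ord("G")
        for _ in range(config.site_depth):
            start = int(rng.integers(lo, hi + 1))
            seq = reference[start : start + L].copy()
            in_site = np.arange(max(site.start, start), min(site.end, start + L)) - start
            for i in in_site:
                if seq[i] == conv_from and rng.random() < config.conversion_rate:
                    seq[i] = conv_to
            _apply_errors(seq, rng, config.error_rate)
            reads.append(SimRead(start, site.strand, seq.tobytes().decode("ascii")))

    n_background = int(round(config.background_depth * G / L))
    for _ in range(n_background):
        start = int(rng.integers(0, G - L + 1))
        strand = "-" if rng.random() < 0.5 else "+"
        seq = reference[start : start + L].copy()
        _apply_errors(seq, rng, config.error_rate)
        reads.append(SimRead(start, strand, seq.tobytes().decode("ascii")))

    reads.sort(key=lambda r: (r.start, r.strand, r.seq))
    return reads


def write_sam(config: SimConfig, reads: list[SimRead], path: str) -> None:
    """Coordinate-sorted SAM: primary ungapped alignments, MAPQ 255."""
    L = config.read_length
    qual = "I" * L
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:{_CHROM}\tLN:{config.genome_length}\n")
        for i, r in enumerate(reads, start=1):
            flag = 16 if r.strand == "-" else 0
            fh.write(
                f"read{i:07d}\t{flag}\t{_CHROM}\t{r.start + 1}\t255\t{L}M\t*\t0\t0"
                f"\t{r.seq}\t{qual}\n"
            )


def write_fastq(reads: list[SimRead], path: str) -> None:
    """Reads in sequencing (strand-local) orientation."""
    with open(path, "w") as fh:
        for i, r in enumerate(reads, start=1):
            seq = r.seq if r.strand == "+" else "".join(_COMP[b] for b in reversed(r.seq))
            fh.write(f"@read{i:07d}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# toy annotation

def make_toy_gtf(config: SimConfig, path: str) -> dict:
    """Write a small ENSEMBL-style GTF on the simulated chromosome.

    Layout (0-based half-open, fixed; requires genome_length >= 2000):
    a plus-strand coding gene with 5'UTR / split CDS / 3'UTR and one
    intron, a miRNA gene, an overlapping same-strand coding pair (to
    exercise the multigenic tag), and a minus-strand lncRNA.  Returns the
    truth table of all feature coordinates.
    """
    if config.genome_length < 2000:
        raise ValueError("toy GTF needs genome_length >= 2000")

    truth = {
        "coding": {
            "gene_id": "SIMG1", "gene_name": "CODA", "strand": "+",
            "span": (100, 1100),
            "exons": [(100, 400), (700, 1100)],
            "five_prime_utr": [(100, 200)],
            "cds": [(200, 400), (700, 1000)],
            "three_prime_utr": [(1000, 1100)],
            "introns": [(400, 700)],
        },
        "mirna": {
            "gene_id": "SIMG2", "gene_name": "MIRB", "strand": "+",
            "span": (1200, 1290), "biotype": "miRNA",
        },
        "overlap_pair": [
            {"gene_id": "SIMG3", "gene_name": "OVLC", "strand": "+", "span": (1400, 1600)},
            {"gene_id": "SIMG4", "gene_name": "OVLD", "strand": "+", "span": (1550, 1750)},
        ],
        "lncrna": {
            "gene_id": "SIMG5", "gene_name": "LNCE", "strand": "-",
            "span": (1800, 1900), "biotype": "lncRNA",
        },
    }

    def attrs(gid, name, biotype, tid=None):
        s = f'gene_id "{gid}"; gene_name "{name}"; gene_biotype "{biotype}";'
        if tid:
            s += f' transcript_id "{tid}";'
        return s

    def line(feature, start, end, strand, a):
        # GTF is 1-based closed
        return f"{_CHROM}\tsim\t{feature}\t{start + 1}\t{end}\t.\t{strand}\t.\t{a}\n"

    rows = []
    c = truth["coding"]
    a = lambda f=None: attrs(c["gene_id"], c["gene_name"], "protein_coding", "SIMT1")
    rows.append(line("gene", *c["span"], c["strand"], attrs(c["gene_id"], c["gene_name"], "protein_coding")))
    rows.append(line("transcript", *c["span"], c["strand"], a()))
    for s, e in c["exons"]:
        rows.append(line("exon", s, e, c["strand"], a()))
    for s, e in c["five_prime_utr"]:
        rows.append(line("five_prime_utr", s, e, c["strand"], a()))
    for s, e in c["cds"]:
        rows.append(line("CDS", s, e, c["strand"], a()))
    for s, e in c["three_prime_utr"]:
        rows.append(line("three_prime_utr", s, e, c["strand"], a()))

    for g, biotype in [
        (truth["mirna"], "miRNA"),
        (truth["overlap_pair"][0], "protein_coding"),
        (truth["overlap_pair"][1], "protein_coding"),
        (truth["lncrna"], "lncRNA"),
    ]:
        ga = attrs(g["gene_id"], g["gene_name"], biotype)
        ta = attrs(g["gene_id"], g["gene_name"], biotype, g["gene_id"] + "T")
        rows.append(line("gene", *g["span"], g["strand"], ga))
        rows.append(line("transcript", *g["span"], g["strand"], ta))
        rows.append(line("exon", *g["span"], g["strand"], ta))
        if biotype == "protein_coding":
            rows.append(line("CDS", *g["span"], g["strand"], ta))

    with open(path, "w") as fh:
        fh.writelines(rows)
    return truth


# ---------------------------------------------------------------------------
# driver

def simulate_dataset(config: SimConfig, out_prefix: str, fastq: bool = False) -> dict:
    """Emit <prefix>.fa / .sam / .truth.bed / .gtf / .config.json.

    Returns the paths plus the in-memory reference, sites and reads.
    """
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    reference = generate_reference(config)
    sites = plant_sites(config, reference)
    reads = simulate_reads(config, reference, sites)

    paths = {
        "fasta": f"{prefix}.fa",
        "sam": f"{prefix}.sam",
        "truth_bed": f"{prefix}.truth.bed",
        "gtf": f"{prefix}.gtf",
        "config": f"{prefix}.config.json",
    }
    write_fasta(reference, paths["fasta"])
    write_sam(config, reads, paths["sam"])
    write_truth_bed(sites, paths["truth_bed"])
    truth_gtf = make_toy_gtf(config, paths["gtf"]) if config.genome_length >= 2000 else None
    with open(paths["config"], "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=1, sort_keys=True)
    if fastq:
        paths["fastq"] = f"{prefix}.fastq"
        write_fastq(reads, paths["fastq"])
    return {
        "paths": paths,
        "reference": reference,
        "sites": sites,
        "reads": reads,
        "gtf_truth": truth_gtf,
    }
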