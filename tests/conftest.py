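"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import pytest

from pclip.simulate import SimConfig, simulate_dataset


def write_fasta(path, sequences: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")


def write_sam(path, chrom_lengths: dict[str, int], reads: list[dict]) -> None:
    """Write a minimal coordinate-sorted SAM from read dicts.

    Each read dict: name, flag, chrom, pos (0-based), mapq, cigar, seq,
    qual (optional; defaults to 'I' per base).
    """
    reads = sorted(reads, key=lambda r: (r["chrom"], r["pos"]))
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        for r in reads:
            qual = r.get("qual", "I" * len(r["seq"]))
            fh.write(
                f"{r['name']}\t{r['flag']}\t{r['chrom']}\t{r['pos'] + 1}\t"
                f"{r['mapq']}\t{r['cigar']}\t*\t0\t0\t{r['seq']}\t{qual}\n"
            )


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A small planted-site simulation shared across tests."""
    cfg = SimConfig(seed=11, genome_length=20_000, n_sites=5, error_rate=0.001)
    prefix = tmp_path_factory.mktemp("sim") / "sim"
    return cfg, simulate_dataset(cfg, str(prefix))


@pytest.fixture(scope="session")
def toy_gtf(tmp_path_factory):
    """The simulator's toy GTF plus its truth table."""
    from pclip.simulate import make_toy_gtf

    cfg = SimConfig(seed=1, genome_length=2_500, n_sites=0)
    path = tmp_path_factory.mktemp("gtf") / "toy.gtf"
    truth = make_toy_gtf(cfg, str(path))
    return str(path), truth
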