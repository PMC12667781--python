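"""Strand-specific pileup: hand-checked alignments, filters, bedGraph I/O."""

import random

import numpy as np
import pytest

from conftest import write_fasta, write_sam
from oracles import naive_pileup, track_to_dict
from pclip.tracks import build_tracks, read_bedgraph_pair, write_bedgraph, MismatchTrack


@pytest.fixture
def tiny_ref(tmp_path):
    # chr1: 200 bases, positions 100..103 are C C T C
    seq = "A" * 100 + "CCTC" + "G" * 96
    fa = tmp_path / "ref.fa"
    write_fasta(fa, {"chr1": seq})
    return str(fa), seq


def _one_read_sam(tmp_path, tiny_ref, **kwargs):
    fa, _ = tiny_ref
    read = dict(
        name="r1", flag=0, chrom="chr1", pos=100, mapq=60, cigar="4M", seq="CCCC"
    )
    read.update(kwargs)
    sam = tmp_path / "t.sam"
    write_sam(sam, {"chr1": 200}, [read])
    return str(sam), fa


class TestHandPileups:
    def test_empty_alignment_file(self, tmp_path, tiny_ref):
        fa, _ = tiny_ref
        sam = tmp_path / "empty.sam"
        write_sam(sam, {"chr1": 200}, [])
        plus, minus = build_tracks(str(sam), fa)
        assert list(plus.columns()) == [] and list(minus.columns()) == []

    def test_forward_t2c_at_reference_t(self, tmp_path, tiny_ref):
        # read CCCC over reference CCTC: strand-local T->C at pos 102
        sam, fa = _one_read_sam(tmp_path, tiny_ref)
        plus, minus = build_tracks(sam, fa)
        cols = {c.pos: c for c in plus.columns()}
        assert set(cols) == {100, 101, 102, 103}
        assert cols[102].ref_base == "T"
        assert (cols[102].depth, cols[102].t2c, cols[102].other_mm) == (1, 1, 0)
        for p in (100, 101, 103):
            assert (cols[p].depth, cols[p].t2c, cols[p].other_mm) == (1, 0, 0)
        assert list(minus.columns()) == []

    def test_minus_strand_t2c_is_reference_a_to_g(self, tmp_path):
        # reference A at pos 1, reverse read carries G there: the strand-local
        # read (revcomp) has T->C at the complementary base
        fa = tmp_path / "ref.fa"
        write_fasta(fa, {"chr1": "TATG" + "C" * 96})
        sam = tmp_path / "t.sam"
        write_sam(
            sam, {"chr1": 100},
            [dict(name="r1", flag=16, chrom="chr1", pos=0, mapq=60, cigar="4M", seq="TGTG")],
        )
        plus, minus = build_tracks(str(sam), str(fa))
        assert list(plus.columns()) == []
        cols = {c.pos: c for c in minus.columns()}
        assert cols[1].t2c == 1 and cols[1].other_mm == 0
        assert cols[1].ref_base == "T"  # strand-local: complement of reference A
        assert {p: cols[p].depth for p in cols} == {0: 1, 1: 1, 2: 1, 3: 1}

    def test_non_t2c_mismatch_counted_as_other(self, tmp_path, tiny_ref):
        sam, fa = _one_read_sam(tmp_path, tiny_ref, seq="ACTC")  # C->A at pos 100
        plus, _ = build_tracks(sam, fa)
        cols = {c.pos: c for c in plus.columns()}
        assert cols[100].other_mm == 1 and cols[100].t2c == 0


class TestFilters:
    def test_low_mapq_read_excluded(self, tmp_path, tiny_ref):
        sam, fa = _one_read_sam(tmp_path, tiny_ref, mapq=10)
        plus, minus = build_tracks(sam, fa)
        assert list(plus.columns()) == [] and list(minus.columns()) == []

    def test_secondary_read_excluded_from_both_strands(self, tmp_path, tiny_ref):
        for flag in (0x100, 0x100 | 0x10):
            sam, fa = _one_read_sam(tmp_path, tiny_ref, flag=flag)
            plus, minus = build_tracks(sam, fa)
            assert list(plus.columns()) == [] and list(minus.columns()) == []

    def test_low_baseq_base_excluded_from_depth_and_mismatch(self, tmp_path, tiny_ref):
        # base at pos 102 has quality 5 (ASCII '&'), below the default 20
        sam, fa = _one_read_sam(tmp_path, tiny_ref, qual="II&I")
        plus, _ = build_tracks(sam, fa)
        cols = {c.pos: c for c in plus.columns()}
        assert 102 not in cols
        assert cols[100].depth == 1

    def test_n_bases_excluded(self, tmp_path, tiny_ref):
        sam, fa = _one_read_sam(tmp_path, tiny_ref, seq="CNCC")
        plus, _ = build_tracks(sam, fa)
        cols = {c.pos: c for c in plus.columns()}
        assert 101 not in cols

    def test_raising_thresholds_is_monotone(self, tmp_path, small_sim):
        _, sim = small_sim
        sam, fa = sim["paths"]["sam"], sim["paths"]["fasta"]
        loose_p, loose_m = build_tracks(sam, fa, min_mapq=0, min_baseq=0)
        tight_p, tight_m = build_tracks(sam, fa, min_mapq=255, min_baseq=30)
        for loose, tight in ((loose_p, tight_p), (loose_m, tight_m)):
            assert tight.total("depth") <= loose.total("depth")
            assert tight.total("t2c") <= loose.total("t2c")
            assert tight.total("other_mm") <= loose.total("other_mm")

    def test_missing_chromosome_error_names_it(self, tmp_path):
        fa = tmp_path / "ref.fa"
        write_fasta(fa, {"chrX": "ACGT" * 25})
        sam = tmp_path / "t.sam"
        write_sam(sam, {"chr9": 100},
                  [dict(name="r", flag=0, chrom="chr9", pos=0, mapq=60, cigar="4M", seq="ACGT")])
        with pytest.raises(ValueError, match="chr9"):
            build_tracks(str(sam), str(fa))


def random_sam_fixture(rng, tmp_path, idx, n_reads=None):
    """Random reference + <= 50 random reads, some with indels/clips/splices
    and some failing the flag/quality filters."""
    length = rng.randint(120, 300)
    ref = "".join(rng.choice("ACGT") for _ in range(length))
    fa = tmp_path / f"ref{idx}.fa"
    write_fasta(fa, {"chr1": ref})
    reads = []
    for i in range(n_reads if n_reads is not None else rng.randint(0, 50)):
        pos = rng.randint(0, length - 40)
        flag = rng.choice([0, 0, 0, 16, 16, 0x100, 0x10 | 0x100, 0x400, 0x800])
        mapq = rng.choice([0, 30, 55, 60, 255])
        style = rng.random()
        if style < 0.6:
            span = rng.randint(10, 35)
            cigar = f"{span}M"
            qlen_ops = [("M", span)]
        elif style < 0.75:
            a, b = rng.randint(5, 12), rng.randint(5, 12)
            cigar = f"{a}M{rng.randint(1, 3)}D{b}M"
            qlen_ops = [("M", a), ("D", rng.randint(1, 3)), ("M", b)]
            cigar = "".join(f"{n}{op}" for op, n in qlen_ops)
        elif style < 0.9:
            a, b, ins = rng.randint(5, 12), rng.randint(5, 12), rng.randint(1, 3)
            qlen_ops = [("S", 2), ("M", a), ("I", ins), ("M", b)]
            cigar = "".join(f"{n}{op}" for op, n in qlen_ops)
        else:
            a, b, gap = rng.randint(5, 12), rng.randint(5, 12), rng.randint(5, 20)
            qlen_ops = [("M", a), ("N", gap), ("M", b)]
            cigar = "".join(f"{n}{op}" for op, n in qlen_ops)
        seq, rpos = [], pos
        for op, n in qlen_ops:
            if op in "M":
                for j in range(n):
                    base = ref[rpos + j]
                    if rng.random() < 0.1:
                        base = rng.choice("ACGTN")
                    seq.append(base)
                rpos += n
            elif op in "IS":
                seq.extend(rng.choice("ACGT") for _ in range(n))
            else:
                rpos += n
        if rpos > length:
            continue
        seq = "".join(seq)
        qual = "".join(chr(33 + rng.choice([5, 20, 30, 40])) for _ in seq)
        reads.append(dict(name=f"r{i}", flag=flag, chrom="chr1", pos=pos,
                          mapq=mapq, cigar=cigar, seq=seq, qual=qual))
    sam = tmp_path / f"reads{idx}.sam"
    write_sam(sam, {"chr1": length}, reads)
    return str(sam), str(fa)


class TestOracleEquivalence:
    def test_random_fixtures_match_naive_walk(self, tmp_path):
        rng = random.Random(2024)
        for idx in range(25):
            sam, fa = random_sam_fixture(rng, tmp_path, idx)
            plus, minus = build_tracks(sam, fa)
            got = track_to_dict(plus) | track_to_dict(minus)
            expected = naive_pileup(sam, fa)
            assert got == expected, f"fixture {idx}"

    def test_bam_route_matches_sam_route(self, tmp_path):
        pysam = pytest.importorskip("pysam")
        rng = random.Random(5)
        sam, fa = random_sam_fixture(rng, tmp_path, 99, n_reads=40)
        bam = str(tmp_path / "x.bam")
        pysam.sort("-o", bam, sam)
        pysam.index(bam)
        p1, m1 = build_tracks(sam, fa)
        p2, m2 = build_tracks(bam, fa)
        assert track_to_dict(p1) == track_to_dict(p2)
        assert track_to_dict(m1) == track_to_dict(m2)

    def test_missing_bam_index_errors(self, tmp_path):
        pysam = pytest.importorskip("pysam")
        rng = random.Random(6)
        sam, fa = random_sam_fixture(rng, tmp_path, 98, n_reads=5)
        bam = str(tmp_path / "noindex.bam")
        pysam.sort("-o", bam, sam)
        with pytest.raises(FileNotFoundError, match="index"):
            build_tracks(bam, fa)


class TestBedgraph:
    def _track(self, depths, t2c=None, other=None):
        t = MismatchTrack(strand="+")
        t.depth["chr1"] = np.array(depths, dtype=np.int32)
        t.t2c["chr1"] = np.array(t2c or [0] * len(depths), dtype=np.int32)
        t.other_mm["chr1"] = np.array(other or [0] * len(depths), dtype=np.int32)
        return t

    def test_run_length_merging(self, tmp_path):
        track = self._track([0] * 10 + [3, 3, 1])
        out = tmp_path / "d.bedGraph"
        write_bedgraph(track, "depth", str(out))
        lines = [l for l in out.read_text().splitlines() if not l.startswith("track")]
        assert lines == ["chr1\t10\t12\t3", "chr1\t12\t13\t1"]

    def test_empty_track_header_only(self, tmp_path):
        track = self._track([])
        out = tmp_path / "e.bedGraph"
        write_bedgraph(track, "depth", str(out))
        assert out.read_text().startswith("track")
        assert len(out.read_text().splitlines()) == 1

    def test_roundtrip_exact(self, tmp_path):
        rng = random.Random(3)
        depths = [rng.choice([0, 0, 1, 2, 3, 7]) for _ in range(200)]
        t2c = [rng.randint(0, d) if d else 0 for d in depths]
        other = [rng.randint(0, d - t) if d else 0 for d, t in zip(depths, t2c)]
        track = self._track(depths, t2c, other)
        paths = {}
        for kind in ("depth", "t2c", "other_mm"):
            paths[kind] = str(tmp_path / f"{kind}.bedGraph")
            write_bedgraph(track, kind, paths[kind])
        back = read_bedgraph_pair(paths["depth"], paths["t2c"], paths["other_mm"], "+")
        for kind in ("depth", "t2c", "other_mm"):
            got = getattr(back, kind)["chr1"]
            want = getattr(track, kind)["chr1"][: len(got)]
            assert np.array_equal(got, want)
            # positions beyond the last non-zero are implicitly zero
            assert getattr(track, kind)["chr1"][len(got):].sum() == 0

    def test_overlapping_intervals_rejected(self, tmp_path):
        bad = tmp_path / "bad.bedGraph"
        bad.write_text("chr1\t0\t10\t3\nchr1\t5\t15\t2\n")
        ok = tmp_path / "ok.bedGraph"
        ok.write_text("")
        with pytest.raises(ValueError, match="position 5"):
            read_bedgraph_pair(str(bad), str(ok), str(ok), "+")

    def test_mismatch_without_depth_rejected(self, tmp_path):
        depth = tmp_path / "d.bedGraph"
        depth.write_text("chr1\t0\t5\t3\n")
        t2c = tmp_path / "t.bedGraph"
        t2c.write_text("chr1\t7\t8\t1\n")
        empty = tmp_path / "o.bedGraph"
        empty.write_text("")
        with pytest.raises(ValueError, match="position 7"):
            read_bedgraph_pair(str(depth), str(t2c), str(empty), "+")
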