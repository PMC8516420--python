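import numpy as np
import pytest

from circevo import align_bsj, pipeline
from circevo.align_bsj import (
    BackspliceCandidate,
    GenomeAnchorIndex,
    TranscriptomeIndex,
    UnmappedRead,
    detect_bsj,
    mate_check,
)
from circevo.formats import GenomicInterval, revcomp


def _random_seq(n, seed):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


def _plant_junction(seq, s, e):
    """Install canonical splice motifs around a backsplice [s, e)."""
    seq = list(seq)
    seq[s - 2 : s] = "AG"  # acceptor intron end
    seq[e : e + 2] = "GT"  # donor intron start
    return "".join(seq)


def _junction_read(genome, s, e, k=50, L=100):
    """A read spanning the backsplice with k donor-side bases."""
    return genome[e - k : e] + genome[s : s + L - k]


def _unmapped(seq, rid="r1", mate=1, sample="s1", qual=None):
    return UnmappedRead(rid, mate, seq, qual or "I" * len(seq), sample, None)


@pytest.fixture(scope="module")
def toy_genome():
    g = _random_seq(8000, seed=42)
    g = _plant_junction(g, 2000, 4000)
    return {"chr1": g}


class TestDetectBsj:
    def test_planted_junction_detected_exactly(self, toy_genome):
        g = toy_genome["chr1"]
        pool = [
            _unmapped(_junction_read(g, 2000, 4000, k), rid=f"r{k}")
            for k in (30, 40, 50, 60, 70)
        ]
        cands = detect_bsj(pool, toy_genome)
        assert len(cands) == 1
        iv = cands[0].interval
        assert (iv.start, iv.end, iv.strand) == (2000, 4000, "+")
        assert cands[0].total_support() == 5
        assert cands[0].motif == "GT/AG"

    def test_minus_strand_junction_resolved(self):
        g = _random_seq(8000, seed=43)
        # minus-strand gene: acceptor AC left of donor CT mirror motifs
        lst = list(g)
        lst[1998:2000] = "AC"
        lst[4000:4002] = "CT"
        g = "".join(lst)
        read = _junction_read(g, 2000, 4000, 45)
        cands = detect_bsj([_unmapped(revcomp(read))], {"chr1": g})
        assert len(cands) == 1
        assert cands[0].interval.strand == "-"

    def test_anchor_distance_cap(self):
        g = _random_seq(160_000, seed=44)
        g = _plant_junction(g, 1000, 140_000)
        read = _junction_read(g, 1000, 140_000)
        assert detect_bsj([_unmapped(read)], {"chr1": g}) == []

    def test_three_mismatches_drop_read(self, toy_genome):
        g = toy_genome["chr1"]
        read = list(_junction_read(g, 2000, 4000, 50))
        # mutate mid-read so the anchors still place but extension needs 3 mm
        for pos in (30, 45, 60):
            read[pos] = "A" if read[pos] != "A" else "C"
        cands = detect_bsj([_unmapped("".join(read))], toy_genome)
        assert cands == []

    def test_two_mismatches_tolerated(self, toy_genome):
        g = toy_genome["chr1"]
        read = list(_junction_read(g, 2000, 4000, 50))
        for pos in (30, 60):
            read[pos] = "A" if read[pos] != "A" else "C"
        cands = detect_bsj([_unmapped("".join(read))], toy_genome)
        assert len(cands) == 1
        assert (cands[0].interval.start, cands[0].interval.end) == (2000, 4000)

    def test_constraint_invariants_on_output(self, toy_genome):
        g = toy_genome["chr1"]
        pool = [_unmapped(_junction_read(g, 2000, 4000, 50))]
        for cand in detect_bsj(pool, toy_genome):
            assert cand.interval.start < cand.interval.end
            assert len(cand.interval) <= align_bsj.MAX_ANCHOR_DIST + 200


class TestTrimBreakpoint:
    def test_ambiguity_resolved_to_motif_offset(self):
        """With a slide-ambiguous breakpoint, the split whose flanking
        dinucleotides are a donor/acceptor combination is chosen."""
        g = list(_random_seq(8000, seed=45))
        s, e = 2000, 4000
        # acceptor-side content 'AG' equal to donor-side intron bases makes
        # splits at offsets 0..+2 extension-equivalent; motifs exist at +2
        g[s : s + 2] = "AG"
        g[s + 2] = "C"
        g[s - 2 : s] = "TT"  # offset 0 not motif-consistent
        g[e : e + 2] = "AG"  # slide bases, not a donor
        g[e + 2 : e + 4] = "GT"  # donor at offset +2
        g = "".join(g)
        read = _junction_read(g, s, e, 50)
        cands = detect_bsj([_unmapped(read)], {"chr1": g})
        assert len(cands) == 1
        assert (cands[0].interval.start, cands[0].interval.end) == (s + 2, e + 2)

    def test_two_motif_offsets_leftmost_wins(self):
        g = list(_random_seq(8000, seed=46))
        s, e = 2000, 4000
        # identical 4-mers GTAG on both sides: motif-consistent at 0 and +4
        g[s - 2 : s] = "AG"
        g[s : s + 4] = "GTAG"
        g[e : e + 4] = "GTAG"
        g[e + 4 : e + 6] = "GT"
        g = "".join(g)
        read = _junction_read(g, s, e, 50)
        cands = detect_bsj([_unmapped(read)], {"chr1": g})
        assert len(cands) == 1
        assert (cands[0].interval.start, cands[0].interval.end) == (s, e)

    def test_no_motif_candidate_dropped(self):
        g = list(_random_seq(8000, seed=47))
        s, e = 2000, 4000
        # slide-ambiguous with no allowed motif anywhere in range
        g[s - 2 : s] = "TT"
        g[s : s + 3] = "AAA"
        g[e : e + 3] = "AAA"
        g[e + 3] = "C"
        g[s + 3] = "G"
        g = "".join(g)
        read = _junction_read(g, s, e, 50)
        assert detect_bsj([_unmapped(read)], {"chr1": g}) == []


class TestMateCheck:
    def _candidate(self, key="r1#1", sample="s1"):
        return BackspliceCandidate(
            interval=GenomicInterval("chr1", 2000, 4000, "+"),
            motif="GT/AG",
            breakpoint_resolved=True,
            support={sample: {key}},
        )

    def test_mate_inside_span_kept(self):
        cand = self._candidate()
        pool = [
            UnmappedRead("r1", 1, "A" * 100, "I" * 100, "s1",
                         GenomicInterval("chr1", 2500, 2600))
        ]
        assert mate_check([cand], pool) == [cand]

    def test_mate_downstream_removed(self):
        cand = self._candidate()
        pool = [
            UnmappedRead("r1", 1, "A" * 100, "I" * 100, "s1",
                         GenomicInterval("chr1", 14_000, 14_100))
        ]
        assert mate_check([cand], pool) == []

    def test_mate_unmapped_retained(self):
        cand = self._candidate()
        pool = [UnmappedRead("r1", 1, "A" * 100, "I" * 100, "s1", None)]
        assert mate_check([cand], pool) == [cand]

    def test_mate_on_other_backsplice_removes_candidate(self):
        a = self._candidate(key="r1#1")
        b = BackspliceCandidate(
            interval=GenomicInterval("chr1", 6000, 7000, "+"),
            motif="GT/AG",
            breakpoint_resolved=True,
            support={"s1": {"r1#2"}},
        )
        pool = [
            UnmappedRead("r1", 1, "A" * 100, "I" * 100, "s1", None),
            UnmappedRead("r1", 2, "C" * 100, "I" * 100, "s1", None),
        ]
        assert mate_check([a, b], pool) == []


class TestAlignLibrary:
    def test_exonic_read_maps_and_junction_read_does_not(self, small_truth):
        truth, _, _ = small_truth
        genome = truth.genomes["mouse"]
        genes = truth.genes["mouse"]
        idx = TranscriptomeIndex(genome, genes)
        gene = genes[0]
        exon = gene.collapsed_exons()[0]
        read = genome["chr1"][exon.start : exon.start + 100]
        if gene.strand == "-":
            read = revcomp(read)
        assert idx.place(read) is not None
        circ = truth.circs_of("mouse")[0]
        jread = _junction_read(genome["chr1"], circ.interval.start,
                               circ.interval.end)
        assert idx.place(jread) is None

    def test_low_quality_reads_excluded_from_anchor_pool(self, small_truth):
        truth, _, _ = small_truth
        genome = truth.genomes["mouse"]
        genes = truth.genes["mouse"]
        idx = TranscriptomeIndex(genome, genes)
        circ = truth.circs_of("mouse")[0]
        jread = _junction_read(genome["chr1"], circ.interval.start,
                               circ.interval.end)
        from circevo.synth import Library, LibraryKey

        key = LibraryKey("mouse", "liver", 1, "untreated")
        q_bad = "I" * 50 + "9" + "I" * 49  # one base at Q24
        q_good = "I" * 100
        lib = Library(key, [("p1", jread, q_bad, revcomp(jread), q_good)])
        al = align_bsj.align_library(lib, idx)
        # both mates span the junction and are unmapped, but only the
        # phred>=25 mate enters the anchor pool
        assert [u.mate_index for u in al.unmapped] == [2]


class TestRescue:
    def test_short_overlap_thresholds(self, toy_genome):
        g = toy_genome["chr1"]
        s, e = 2000, 4000
        founding = [
            _unmapped(_junction_read(g, s, e, k), rid=f"f{k}")
            for k in (40, 50, 60)
        ]
        cands = detect_bsj(founding, toy_genome)
        from circevo.synth import Library, LibraryKey

        key = LibraryKey("sp", "liver", 1, "untreated")
        reads = [
            (f"f{k}", _junction_read(g, s, e, k), "I" * 100, "A" * 100, "I" * 100)
            for k in (40, 50, 60)
        ]
        # 9 bases on the donor side: counted; 7 bases: not counted
        reads.append(("short9", _junction_read(g, s, e, 9), "I" * 100,
                      "A" * 100, "I" * 100))
        reads.append(("short7", _junction_read(g, s, e, 7), "I" * 100,
                      "A" * 100, "I" * 100))
        lib = Library(key, reads)
        out = align_bsj.rescue_short_overlap(cands, {key: lib}, toy_genome)
        assert len(out) == 1
        support = out[0].support[key.sample_id]
        assert "short9#1" in support
        assert not any(k.startswith("short7") for k in support)
        assert out[0].total_support() == 4

    def test_rescue_counts_match_string_oracle(self, small_truth):
        """Rescued support equals a brute-force count of reads whose exact
        sequence spans the planted junction with >= 8 bases on each side."""
        truth, _, libs = small_truth
        sp = "mouse"
        slibs = {k: v for k, v in libs.items() if k.species == sp}
        cands, _ = align_bsj.detect_species(slibs, truth.genomes[sp],
                                            truth.genes[sp])
        genome = truth.genomes[sp]["chr1"]
        half = 100 - 8
        for cand in cands:
            s, e = cand.interval.start, cand.interval.end
            ref = genome[e - half : e] + genome[s : s + half]
            oracle = 0
            for key, lib in slibs.items():
                for rid, s1, _, s2, _ in lib.reads:
                    for seq in (s1, s2):
                        if seq in ref or revcomp(seq) in ref:
                            oracle += 1
            assert cand.total_support() == oracle


def test_end_to_end_small_truth(small_truth):
    truth, _, libs = small_truth
    for sp in ("mouse", "rat"):
        slibs = {k: v for k, v in libs.items() if k.species == sp}
        cands, _ = align_bsj.detect_species(slibs, truth.genomes[sp],
                                            truth.genes[sp])
        m = pipeline.detection_metrics(cands, truth, sp)
        assert m["precision"] == 1.0
        assert m["recall"] >= 0.95
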