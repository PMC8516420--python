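"""Spliced read alignment and anchor-based backsplice-junction detection.

The internal aligner places reads along annotated transcripts (ungapped
within exons, splice-aware across annotated junctions) with at most two
mismatches — adequate for synthetic genomes; external alignments can be
substituted by constructing :class:`AlignedLibrary` objects directly.

Backsplice detection follows the anchor strategy: the terminal 20-mers of
each quality-filtered unmapped read are placed on the genome; anchor pairs
on the same chromosome and strand within 100 kb whose 3' anchor lies
upstream of the 5' anchor are extended to the full read length (max two
mismatches), trimmed to a splice-motif-consistent breakpoint, checked
against mate placements, and finally re-supported by scanning all reads
against a junction index (>= 8 bases on each side of the breakpoint).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from circevo.formats import GenomicInterval, GeneModel, min_phred, revcomp
from circevo.synth import Library, LibraryKey

ANCHOR_LEN = 20
MAX_ANCHOR_DIST = 100_000
MAX_MISMATCHES = 2
MIN_ANCHOR_PHRED = 25
MIN_RESCUE_OVERLAP = 8
DONOR_MOTIFS = {"GT", "GC", "AT", "CT"}
ACCEPTOR_MOTIFS = {"AG", "AC"}


def _mm_count(a: str, b: str, limit: int) -> int:
    """Mismatches between equal-length strings, early exit above limit."""
    if a == b:
        return 0
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return limit + 1
    return mm


# ---------------------------------------------------------------------------
# transcriptome alignment


@dataclass
class _Transcript:
    gene_id: str
    chrom: str
    strand: str
    seq: str
    # exon blocks in transcript order: (t_start, g_start, length);
    # for minus-strand genes t-coordinates run antiparallel to the genome
    blocks: list[tuple[int, int, int]]
    boundaries: list[int]  # transcript offsets of splice junctions
    # genomic junction index per boundary (minus-strand genes reverse order)
    boundary_junctions: list[int]

    def genomic_span(self, tpos: int, length: int) -> GenomicInterval:
        lo, hi = None, None
        for t0, g0, n in self.blocks:
            a = max(tpos, t0)
            b = min(tpos + length, t0 + n)
            if a >= b:
                continue
            if self.strand == "+":
                gs, ge = g0 + (a - t0), g0 + (b - t0)
            else:
                ge = g0 + n - (a - t0)
                gs = g0 + n - (b - t0)
            lo = gs if lo is None else min(lo, gs)
            hi = ge if hi is None else max(hi, ge)
        return GenomicInterval(self.chrom, lo, hi, self.strand)


class TranscriptomeIndex:
    """Seed-and-verify index over annotated spliced transcripts."""

    def __init__(self, genome: dict[str, str], genes: list[GeneModel], k: int = 20):
        self.k = k
        self.transcripts: list[_Transcript] = []
        self.kmers: dict[str, list[tuple[int, int]]] = {}
        for gene in genes:
            for tid, exons in gene.transcripts.items():
                chrom_seq = genome[gene.chrom]
                parts = [chrom_seq[a:b] for a, b in exons]
                if gene.strand == "-":
                    seq = revcomp("".join(parts))
                    order = list(reversed(exons))
                else:
                    seq = "".join(parts)
                    order = list(exons)
                blocks = []
                boundaries = []
                t = 0
                for a, b in order:
                    blocks.append((t, a, b - a))
                    t += b - a
                    boundaries.append(t)
                boundaries.pop()  # last offset is the transcript end
                n_j = len(boundaries)
                if gene.strand == "+":
                    boundary_junctions = list(range(n_j))
                else:
                    boundary_junctions = [n_j - 1 - j for j in range(n_j)]
                ti = len(self.transcripts)
                self.transcripts.append(
                    _Transcript(gene.gene_id, gene.chrom, gene.strand, seq,
                                blocks, boundaries, boundary_junctions)
                )
                for pos in range(0, len(seq) - k + 1):
                    self.kmers.setdefault(seq[pos : pos + k], []).append((ti, pos))

    def place(self, read: str, max_mm: int = MAX_MISMATCHES):
        """Unique best spliced placement, or None (unmapped/ambiguous)."""
        L = len(read)
        hits: dict[tuple[int, int, str], int] = {}
        for orient, seq in (("+", read), ("-", revcomp(read))):
            for off in (0, self.k):
                if off + self.k > L:
                    break
                for ti, pos in self.kmers.get(seq[off : off + self.k], ()):
                    tpos = pos - off
                    key = (ti, tpos, orient)
                    if key in hits or tpos < 0:
                        continue
                    tseq = self.transcripts[ti].seq
                    if tpos + L > len(tseq):
                        continue
                    mm = _mm_count(seq, tseq[tpos : tpos + L], max_mm)
                    if mm <= max_mm:
                        hits[key] = mm
        if not hits:
            return None
        best = min(hits.values())
        winners = [k for k, v in hits.items() if v == best]
        if len(winners) != 1:
            return None
        ti, tpos, orient = winners[0]
        return Placement(ti, tpos, orient, best)


@dataclass(frozen=True)
class Placement:
    transcript_index: int
    tpos: int
    orient: str
    mismatches: int


@dataclass
class UnmappedRead:
    read_id: str
    mate_index: int  # 1 or 2
    seq: str
    qual: str
    sample_id: str
    mate_interval: GenomicInterval | None  # singleton placement of the mate


@dataclass
class AlignedLibrary:
    key: LibraryKey
    n_mapped_reads: int
    n_total_reads: int
    junction_counts: dict[tuple[str, int], int]  # (gene_id, junction idx)
    unmapped: list[UnmappedRead]
    pair_modes: dict[str, str] = field(default_factory=dict)  # read_id -> pe|se


def align_library(
    library: Library,
    index: TranscriptomeIndex,
    read_length: int = 100,
) -> AlignedLibrary:
    """Map both mates of every pair; collect the unmapped pool.

    Unmapped reads with any base below phred 25 are excluded from the
    anchor pool (they still count toward library totals).
    """
    n_mapped = 0
    junction_counts: dict[tuple[str, int], int] = {}
    unmapped: list[UnmappedRead] = []
    pair_modes: dict[str, str] = {}
    sample_id = library.key.sample_id
    for rid, s1, q1, s2, q2 in library.reads:
        p1 = index.place(s1)
        p2 = index.place(s2)
        for p in (p1, p2):
            if p is None:
                continue
            n_mapped += 1
            tr = index.transcripts[p.transcript_index]
            for j, b in enumerate(tr.boundaries):
                if p.tpos + MIN_RESCUE_OVERLAP <= b <= p.tpos + read_length - MIN_RESCUE_OVERLAP:
                    gj = tr.boundary_junctions[j]
                    junction_counts[(tr.gene_id, gj)] = (
                        junction_counts.get((tr.gene_id, gj), 0) + 1
                    )
        if p1 is not None and p2 is not None:
            pair_modes[rid] = "pe"
        elif p1 is not None or p2 is not None:
            pair_modes[rid] = "se"
        for mate_idx, (seq, qual, own, other) in enumerate(
            (( s1, q1, p1, p2), (s2, q2, p2, p1)), start=1
        ):
            if own is not None:
                continue
            if min_phred(qual) < MIN_ANCHOR_PHRED:
                continue
            mate_iv = None
            if other is not None:
                tr = index.transcripts[other.transcript_index]
                mate_iv = tr.genomic_span(other.tpos, read_length)
            unmapped.append(
                UnmappedRead(rid, mate_idx, seq, qual, sample_id, mate_iv)
            )
    return AlignedLibrary(
        key=library.key,
        n_mapped_reads=n_mapped,
        n_total_reads=2 * library.n_pairs,
        junction_counts=junction_counts,
        unmapped=unmapped,
        pair_modes=pair_modes,
    )


# ---------------------------------------------------------------------------
# backsplice detection


@dataclass
class BackspliceCandidate:
    interval: GenomicInterval  # [acceptor start, donor end) on the genome
    motif: str  # "donor/acceptor" dinucleotides in gene orientation
    breakpoint_resolved: bool
    support: dict[str, set[str]] = field(default_factory=dict)  # sample -> read ids

    @property
    def counts(self) -> dict[str, int]:
        return {s: len(r) for s, r in self.support.items()}

    def total_support(self) -> int:
        return sum(len(r) for r in self.support.values())


class GenomeAnchorIndex:
    """Exact-match index of all anchor-length k-mers of a genome."""

    def __init__(self, genome: dict[str, str], k: int = ANCHOR_LEN):
        self.k = k
        self.genome = genome
        self.index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in genome.items():
            idx = self.index
            for pos in range(0, len(seq) - k + 1):
                kmer = seq[pos : pos + k]
                if kmer in idx:
                    idx[kmer].append((chrom, pos))
                else:
                    idx[kmer] = [(chrom, pos)]

    def place_unique(self, kmer: str) -> tuple[str, int] | None:
        hits = self.index.get(kmer)
        if hits is None or len(hits) != 1:
            return None  # multi-mapping anchors are dropped entirely
        return hits[0]


def _motif_at(genome: str, s: int, e: int, strand: str) -> tuple[str, str]:
    """Donor/acceptor intronic dinucleotides for a backsplice [s, e).

    The donor motif sits in the intron downstream of the donor exon in
    gene orientation: to the right of ``e`` on the plus strand, to the
    left of ``s`` (reverse-complemented) on the minus strand."""
    if strand == "+":
        donor = genome[e : e + 2]
        acceptor = genome[s - 2 : s] if s >= 2 else ""
    else:
        donor = revcomp(genome[s - 2 : s]) if s >= 2 else ""
        acceptor = revcomp(genome[e : e + 2])
    return donor, acceptor


def _score_breakpoint(genome: str, s: int, e: int) -> tuple[int, str, str]:
    """Motif-based strand resolution for a breakpoint.

    An unstranded paired-end protocol cannot orient a junction read, so
    the strand is taken from the splice motifs: the interpretation whose
    donor/acceptor pair is canonical GT/AG scores 2, any allowed
    combination scores 1.  Ties go to the plus strand."""
    best = (0, "+", "./.")
    for strand in ("+", "-"):
        donor, acceptor = _motif_at(genome, s, e, strand)
        if donor == "GT" and acceptor == "AG":
            score = 2
        elif donor in DONOR_MOTIFS and acceptor in ACCEPTOR_MOTIFS:
            score = 1
        else:
            score = 0
        if score > best[0]:
            best = (score, strand, f"{donor}/{acceptor}")
    return best


def _resolve_breakpoint(
    genome: str, valid_ks: list[int], q5: int, q3e: int, L: int
) -> tuple[int, int, str, str, bool] | None:
    """Choose the breakpoint among extension-consistent splits.

    A single consistent split is accepted as-is; with an ambiguity range
    (sequence repeats at the breakpoint) the motif decides: among splits
    with an allowed donor/acceptor combination the best-scoring, then
    leftmost split wins; no motif-consistent split drops the read.
    """
    def coords(k: int) -> tuple[int, int]:
        return q3e - (L - k), q5 + k  # (acceptor start, donor end)

    if len(valid_ks) == 1:
        # unambiguous split: coordinates stand, but a breakpoint without any
        # allowed splice motif is flagged unresolved (no clear breakpoint)
        s, e = coords(valid_ks[0])
        score, strand, motif = _score_breakpoint(genome, s, e)
        return s, e, strand, motif, score > 0
    scored = []
    for k in sorted(valid_ks):
        s, e = coords(k)
        score, strand, motif = _score_breakpoint(genome, s, e)
        if score > 0:
            scored.append((-score, k, s, e, strand, motif))
    if not scored:
        return None
    _, _, s, e, strand, motif = min(scored)
    return s, e, strand, motif, True


def detect_bsj(
    unmapped: list[UnmappedRead],
    genome: dict[str, str],
    anchor_index: GenomeAnchorIndex | None = None,
    max_dist: int = MAX_ANCHOR_DIST,
    max_mm: int = MAX_MISMATCHES,
) -> list[BackspliceCandidate]:
    """Anchor-based backsplice candidate detection on the unmapped pool."""
    if anchor_index is None:
        anchor_index = GenomeAnchorIndex(genome)
    k = anchor_index.k
    candidates: dict[tuple[str, int, int, str], BackspliceCandidate] = {}

    for read in unmapped:
        L = len(read.seq)
        if L < 2 * k:
            continue
        placements = []
        for strand, R in (("+", read.seq), ("-", revcomp(read.seq))):
            hit5 = anchor_index.place_unique(R[:k])
            hit3 = anchor_index.place_unique(R[-k:])
            if hit5 is None or hit3 is None:
                continue
            (c5, q5), (c3, q3) = hit5, hit3
            if c5 != c3:  # same-chromosome constraint
                continue
            if abs(q5 - q3) > max_dist:  # 100-kb constraint on anchors
                continue
            if q3 + k <= q5:  # backsplice signature: 3' anchor upstream
                placements.append((strand, c5, q5, q3, R))
        if len(placements) != 1:
            continue
        strand, chrom, q5, q3, R = placements[0]
        seq = genome[chrom]
        q3e = q3 + k
        # cumulative mismatches of read prefixes after q5 / suffixes before q3e
        mm_pre = [0] * (L + 1)
        for i in range(L):
            ok = q5 + i < len(seq) and R[i] == seq[q5 + i]
            mm_pre[i + 1] = mm_pre[i] + (0 if ok else 1)
        mm_suf = [0] * (L + 1)
        for i in range(L):
            p = q3e - 1 - i
            ok = p >= 0 and R[L - 1 - i] == seq[p]
            mm_suf[i + 1] = mm_suf[i] + (0 if ok else 1)
        totals = {
            kk: mm_pre[kk] + mm_suf[L - kk] for kk in range(k, L - k + 1)
        }
        best_mm = min(totals.values())
        if best_mm > max_mm:
            continue  # pair not extendable to full read length
        # the ambiguity range is the minimal-mismatch split set: sequence
        # repeats at the breakpoint slide the split without adding mismatches
        valid_ks = [kk for kk, mm in totals.items() if mm == best_mm]
        resolved = _resolve_breakpoint(seq, valid_ks, q5, q3e, L)
        if resolved is None:
            continue
        s, e, strand, motif, ok = resolved
        if s < 0 or e <= s:
            continue
        key = (chrom, s, e, strand)
        cand = candidates.get(key)
        if cand is None:
            cand = BackspliceCandidate(
                interval=GenomicInterval(chrom, s, e, strand),
                motif=motif,
                breakpoint_resolved=ok,
            )
            candidates[key] = cand
        cand.support.setdefault(read.sample_id, set()).add(
            f"{read.read_id}#{read.mate_index}"
        )

    # candidates without a clear (motif-consistent) breakpoint are removed
    out = [c for c in candidates.values() if c.breakpoint_resolved]
    for cand in out:  # structural guarantees
        assert cand.interval.start < cand.interval.end
    return out


def mate_check(
    candidates: list[BackspliceCandidate],
    unmapped: list[UnmappedRead],
) -> list[BackspliceCandidate]:
    """Drop junction support whose singleton mate maps outside the circle
    span; remove candidates whose supporting reads' mates hit another
    backsplice.  Unmapped mates carry no evidence and are retained."""
    mate_iv = {f"{u.read_id}#{u.mate_index}": u.mate_interval for u in unmapped}
    key_to_cand: dict[str, int] = {}
    for ci, cand in enumerate(candidates):
        for reads in cand.support.values():
            for key in reads:
                key_to_cand[key] = ci

    removed: set[int] = set()
    for ci, cand in enumerate(candidates):
        iv = cand.interval
        for sample, reads in cand.support.items():
            keep = set()
            for key in reads:
                rid, _, mi = key.rpartition("#")
                other_key = f"{rid}#{3 - int(mi)}"
                other = key_to_cand.get(other_key)
                if other is not None and other != ci:
                    removed.add(ci)  # mate defines a different backsplice
                    continue
                m = mate_iv.get(key)
                if m is None:
                    keep.add(key)  # mate unmapped: no evidence against
                elif m.chrom == iv.chrom and m.start >= iv.start and m.end <= iv.end:
                    keep.add(key)
            cand.support[sample] = keep
    return [
        c
        for i, c in enumerate(candidates)
        if i not in removed and c.total_support() > 0
    ]


def rescue_short_overlap(
    candidates: list[BackspliceCandidate],
    libraries: dict[LibraryKey, Library],
    genome: dict[str, str],
    read_length: int = 100,
    min_overlap: int = MIN_RESCUE_OVERLAP,
    max_mm: int = MAX_MISMATCHES,
) -> list[BackspliceCandidate]:
    """Re-match every read against breakpoint-spanning junction references.

    Any full-length placement on a reference implies >= ``min_overlap``
    bases on both sides of the breakpoint.  Reads founding one candidate
    that also match a different candidate's reference remove their own
    candidate.  Support sets are replaced by the rescued (superset) counts.
    """
    half = read_length - min_overlap
    refs: list[str] = []
    for cand in candidates:
        seq = genome[cand.interval.chrom]
        s, e = cand.interval.start, cand.interval.end
        left = seq[max(e - half, 0) : e]
        right = seq[s : s + half]
        refs.append(left + right)
    # merge candidates whose junction references are indistinguishable at
    # the mismatch tolerance (breakpoint slippage artefacts): the stronger-
    # supported candidate absorbs the weaker one's support
    drop: set[int] = set()
    order = sorted(
        range(len(candidates)),
        key=lambda i: (-candidates[i].total_support(),
                       candidates[i].interval.start),
    )
    for oi, i in enumerate(order):
        if i in drop:
            continue
        for j in order[oi + 1 :]:
            if j in drop or len(refs[i]) != len(refs[j]):
                continue
            if _mm_count(refs[i], refs[j], max_mm) <= max_mm:
                for sample, reads in candidates[j].support.items():
                    candidates[i].support.setdefault(sample, set()).update(reads)
                drop.add(j)
    candidates = [c for i, c in enumerate(candidates) if i not in drop]
    refs = [r for i, r in enumerate(refs) if i not in drop]
    k = ANCHOR_LEN
    ref_kmers: dict[str, list[tuple[int, int]]] = {}
    for ci, ref in enumerate(refs):
        for pos in range(0, len(ref) - k + 1):
            ref_kmers.setdefault(ref[pos : pos + k], []).append((ci, pos))

    founders = {
        key: ci
        for ci, cand in enumerate(candidates)
        for reads in cand.support.values()
        for key in reads
    }
    new_support: list[dict[str, set[str]]] = [dict() for _ in candidates]
    removed: set[int] = set()

    def _match(seq: str) -> set[int]:
        matched = set()
        for R in (seq, revcomp(seq)):
            for off in (0, k):
                for ci, pos in ref_kmers.get(R[off : off + k], ()):
                    tpos = pos - off
                    if tpos < 0 or tpos + len(R) > len(refs[ci]):
                        continue
                    if _mm_count(R, refs[ci][tpos : tpos + len(R)], max_mm) <= max_mm:
                        matched.add(ci)
        return matched

    for lib in libraries.values():
        sample = lib.key.sample_id
        for rid, s1, _, s2, _ in lib.reads:
            for mi, seq in ((1, s1), (2, s2)):
                matched = _match(seq)
                if not matched:
                    continue
                key = f"{rid}#{mi}"
                home = founders.get(key)
                if home is not None and any(ci != home for ci in matched):
                    removed.add(home)
                for ci in matched:
                    new_support[ci].setdefault(sample, set()).add(key)

    out = []
    for ci, cand in enumerate(candidates):
        if ci in removed:
            continue
        cand.support = new_support[ci]
        if cand.total_support() > 0:
            out.append(cand)
    return out


def detect_species(
    libraries: dict[LibraryKey, Library],
    genome: dict[str, str],
    genes: list[GeneModel],
    read_length: int = 100,
) -> tuple[list[BackspliceCandidate], dict[LibraryKey, AlignedLibrary]]:
    """Full per-species detection: align, detect, trim, mate-check, rescue."""
    index = TranscriptomeIndex(genome, genes)
    aligned = {
        key: align_library(lib, index, read_length) for key, lib in libraries.items()
    }
    pool = [u for al in aligned.values() for u in al.unmapped]
    anchor_index = GenomeAnchorIndex(genome)
    candidates = detect_bsj(pool, genome, anchor_index)
    candidates = mate_check(candidates, pool)
    candidates = rescue_short_overlap(candidates, libraries, genome, read_length)
    return candidates, aligned
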