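"""On-disk formats and interval arithmetic shared by every pipeline stage.

Internally all coordinates are 0-based half-open (BED-style); GTF is the
only 1-based inclusive format and is converted at the I/O boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Malformed record in an on-disk file."""


# ---------------------------------------------------------------------------
# intervals


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval; strand '.' means strand-agnostic."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in "+-.":
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of shared bases; 0 when chromosomes differ."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or book-ended intervals (bedtools-merge semantics).

    The caller is responsible for restricting the input to one
    chromosome/strand group if that separation matters; intervals are
    grouped by chromosome here and the strand of the first member is kept.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda i: (i.start, i.end))
        cur_start, cur_end, cur_strand = ivs[0].start, ivs[0].end, ivs[0].strand
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # book-ended inputs merge too
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end, cur_strand))
                cur_start, cur_end, cur_strand = iv.start, iv.end, iv.strand
        merged.append(GenomicInterval(chrom, cur_start, cur_end, cur_strand))
    return merged


def intersect_fraction(
    a: GenomicInterval, b: GenomicInterval, min_frac_of_a: float
) -> bool:
    """True iff b covers at least ``min_frac_of_a`` of a's bases."""
    if not (0 < min_frac_of_a <= 1):
        raise ValueError("min_frac_of_a must be in (0, 1]")
    return a.overlap(b) >= min_frac_of_a * len(a)


# ---------------------------------------------------------------------------
# gene models


@dataclass
class GeneModel:
    """A gene with one or more transcripts given as sorted exon chains."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: dict[str, list[tuple[int, int]]]
    biotype: str = "protein_coding"
    utr_exons: set[tuple[int, int]] = field(default_factory=set)

    @property
    def start(self) -> int:
        return min(e[0] for exons in self.transcripts.values() for e in exons)

    @property
    def end(self) -> int:
        return max(e[1] for exons in self.transcripts.values() for e in exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    def collapsed_exons(self) -> list[GenomicInterval]:
        """Per-gene exon union over all transcripts (idempotent)."""
        return merge_intervals(
            GenomicInterval(self.chrom, s, e, self.strand)
            for exons in self.transcripts.values()
            for s, e in exons
        )

    def introns(self) -> list[GenomicInterval]:
        """Gaps between collapsed exons."""
        exons = self.collapsed_exons()
        out = []
        for left, right in zip(exons, exons[1:]):
            if right.start > left.end:
                out.append(
                    GenomicInterval(self.chrom, left.end, right.start, self.strand)
                )
        return out


@dataclass(frozen=True)
class RepeatCopy:
    """A repeat copy with its per-mille divergence from the family consensus."""

    interval: GenomicInterval
    family: str
    milli_div: int

    def __post_init__(self):
        if self.milli_div < 0:
            raise ValueError("milliDiv must be >= 0")


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(path, seqs: dict[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def read_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Yield (read_id, sequence, quality) from a phred+33 FASTQ file."""
    with open(path) as fh:
        yield from FastqGeneralIterator(fh)


def write_fastq(path, records: Iterable[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def min_phred(qual: str) -> int:
    """Lowest base quality in a phred+33 string."""
    return min(ord(c) for c in qual) - 33


# ---------------------------------------------------------------------------
# GTF

_GTF_COLS = [
    "seqname", "source", "feature", "start", "end",
    "score", "strand", "frame", "attribute",
]


def _gtf_attrs(field: str) -> dict[str, str]:
    attrs = {}
    for part in field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        attrs[key] = val.strip().strip('"')
    return attrs


def read_gtf(path) -> list[GeneModel]:
    """Parse exon records of a GTF into gene models.

    GTF 1-based inclusive coordinates are converted to 0-based half-open.
    Exons carrying ``exon_type "utr"`` are additionally recorded as UTR.
    """
    genes: dict[str, GeneModel] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF columns")
            if fields[2] != "exon":
                continue
            try:
                start = int(fields[3]) - 1
                end = int(fields[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad coordinates") from exc
            attrs = _gtf_attrs(fields[8])
            gid = attrs["gene_id"]
            tid = attrs.get("transcript_id", gid + ".t1")
            if gid not in genes:
                genes[gid] = GeneModel(
                    gene_id=gid,
                    chrom=fields[0],
                    strand=fields[6],
                    transcripts={},
                    biotype=attrs.get("gene_biotype", "protein_coding"),
                )
            gene = genes[gid]
            gene.transcripts.setdefault(tid, []).append((start, end))
            if attrs.get("exon_type") == "utr":
                gene.utr_exons.add((start, end))
    for gene in genes.values():
        for exons in gene.transcripts.values():
            exons.sort()
    return list(genes.values())


def write_gtf(path, genes: Sequence[GeneModel], source: str = "circevo") -> None:
    with open(path, "w") as fh:
        for gene in genes:
            for tid in sorted(gene.transcripts):
                for start, end in gene.transcripts[tid]:
                    exon_type = "utr" if (start, end) in gene.utr_exons else "cds"
                    attrs = (
                        f'gene_id "{gene.gene_id}"; transcript_id "{tid}"; '
                        f'gene_biotype "{gene.biotype}"; exon_type "{exon_type}";'
                    )
                    fh.write(
                        "\t".join(
                            [
                                gene.chrom, source, "exon",
                                str(start + 1), str(end),
                                ".", gene.strand, ".", attrs,
                            ]
                        )
                        + "\n"
                    )


# ---------------------------------------------------------------------------
# BED / bedGraph / RepeatMasker table


def read_bed(path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            strand = fields[5] if len(fields) >= 6 else "."
            out.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
            )
    return out


def write_bed(path, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def read_repeat_table(path) -> list[RepeatCopy]:
    df = pd.read_csv(path, sep="\t")
    return [
        RepeatCopy(
            GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand),
            r.family,
            int(r.milliDiv),
        )
        for r in df.itertuples()
    ]


def write_repeat_table(path, repeats: Iterable[RepeatCopy]) -> None:
    rows = [
        {
            "chrom": r.interval.chrom,
            "start": r.interval.start,
            "end": r.interval.end,
            "strand": r.interval.strand,
            "family": r.family,
            "milliDiv": r.milli_div,
        }
        for r in repeats
    ]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "family", "milliDiv"]).to_csv(
        path, sep="\t", index=False
    )


def read_bedgraph(path) -> list[tuple[str, int, int, float]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            out.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
    return out


def write_bedgraph(path, records: Iterable[tuple[str, int, int, float]]) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, val in records:
            fh.write(f"{chrom}\t{start}\t{end}\t{val:.6g}\n")


class ConservationTrack:
    """Per-base conservation scores backed by bedGraph records.

    Bases not covered by any record have no score (``None``); downstream
    consumers skip them rather than zero-filling.
    """

    def __init__(self, records: Iterable[tuple[str, int, int, float]]):
        self._by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, val in records:
            self._by_chrom.setdefault(chrom, []).append((start, end, val))
        for recs in self._by_chrom.values():
            recs.sort()

    @classmethod
    def from_file(cls, path) -> "ConservationTrack":
        return cls(read_bedgraph(path))

    def mean_score(self, iv: GenomicInterval) -> float | None:
        """Mean score over the covered bases of ``iv``; None if uncovered."""
        total = 0.0
        covered = 0
        for start, end, val in self._by_chrom.get(iv.chrom, []):
            if end <= iv.start:
                continue
            if start >= iv.end:
                break
            n = min(end, iv.end) - max(start, iv.start)
            total += n * val
            covered += n
        if covered == 0:
            return None
        return total / covered


# ---------------------------------------------------------------------------
# UCSC chain


@dataclass
class _Chain:
    t_chrom: str
    t_size: int
    t_start: int
    q_chrom: str
    q_size: int
    q_start: int
    q_strand: str
    # aligned blocks as (t_start, t_end, q_start) in forward coordinates
    blocks: list[tuple[int, int, int]]
    chain_id: int = 0
    score: int = 1000


class ChainMap:
    """Ordered alignment blocks mapping source ("target" in UCSC chain
    vocabulary) intervals to destination ("query") intervals."""

    def __init__(self, chains: list[_Chain]):
        self.chains = chains

    @classmethod
    def from_blocks(
        cls,
        blocks: Iterable[tuple[str, int, int, str, int]],
        t_sizes: dict[str, int],
        q_sizes: dict[str, int],
    ) -> "ChainMap":
        """Build a one-chain-per-block map from
        (src_chrom, src_start, src_end, dst_chrom, dst_start) tuples."""
        chains = []
        for i, (tc, ts, te, qc, qs) in enumerate(blocks, 1):
            chains.append(
                _Chain(
                    t_chrom=tc, t_size=t_sizes[tc], t_start=ts,
                    q_chrom=qc, q_size=q_sizes[qc], q_start=qs,
                    q_strand="+", blocks=[(ts, te, qs)], chain_id=i,
                )
            )
        return cls(chains)

    @classmethod
    def from_file(cls, path) -> "ChainMap":
        chains: list[_Chain] = []
        cur: _Chain | None = None
        t_off = q_off = 0
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line:
                    cur = None
                    continue
                if line.startswith("chain"):
                    f = line.split()
                    if len(f) != 13:
                        raise FormatError(f"{path}:{lineno}: bad chain header")
                    cur = _Chain(
                        t_chrom=f[2], t_size=int(f[3]), t_start=int(f[5]),
                        q_chrom=f[7], q_size=int(f[8]), q_start=int(f[10]),
                        q_strand=f[9], blocks=[], chain_id=int(f[12]),
                        score=int(f[1]),
                    )
                    t_off, q_off = cur.t_start, cur.q_start
                    chains.append(cur)
                else:
                    if cur is None:
                        raise FormatError(f"{path}:{lineno}: block outside chain")
                    f = line.split()
                    size = int(f[0])
                    cur.blocks.append((t_off, t_off + size, q_off))
                    if len(f) == 3:
                        t_off += size + int(f[1])
                        q_off += size + int(f[2])
        return cls(chains)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for c in self.chains:
                t_end = c.blocks[-1][1]
                q_end = c.blocks[-1][2] + (c.blocks[-1][1] - c.blocks[-1][0])
                fh.write(
                    f"chain {c.score} {c.t_chrom} {c.t_size} + {c.t_start} {t_end} "
                    f"{c.q_chrom} {c.q_size} {c.q_strand} {c.q_start} {q_end} {c.chain_id}\n"
                )
                for i, (ts, te, qs) in enumerate(c.blocks):
                    size = te - ts
                    if i + 1 < len(c.blocks):
                        nts, _, nqs = c.blocks[i + 1]
                        fh.write(f"{size}\t{nts - te}\t{nqs - (qs + size)}\n")
                    else:
                        fh.write(f"{size}\n")
                fh.write("\n")

    def lift(
        self, iv: GenomicInterval, min_match: float = 0.5
    ) -> GenomicInterval | None:
        """Map an interval through the chain blocks.

        Succeeds when at least ``min_match`` of the interval's bases fall
        inside aligned blocks of forward-strand chains on a single
        destination chromosome; the result is the span of the mapped bases.
        """
        covered = 0
        dst_chrom = None
        lo = math.inf
        hi = -math.inf
        for chain in self.chains:
            if chain.t_chrom != iv.chrom:
                continue
            for ts, te, qs in chain.blocks:
                n = min(te, iv.end) - max(ts, iv.start)
                if n <= 0:
                    continue
                if chain.q_strand != "+":
                    return None  # inverted block: lift fails for this interval
                if dst_chrom is None:
                    dst_chrom = chain.q_chrom
                elif dst_chrom != chain.q_chrom:
                    return None
                covered += n
                off = max(ts, iv.start) - ts
                lo = min(lo, qs + off)
                hi = max(hi, qs + off + n)
        if dst_chrom is None or covered < min_match * len(iv):
            return None
        return GenomicInterval(dst_chrom, int(lo), int(hi), iv.strand)
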