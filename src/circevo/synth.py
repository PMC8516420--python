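"""Multi-species synthetic genomes with planted circRNA ground truth.

The generator emulates the study design of a five-species, three-organ
circRNA screen: per-species toy genomes carrying 1:1 orthologous genes of
controlled GC isochore class, intronic transposable-element insertions of
known family and age, planted multi-exon circRNAs with per-tissue
expression, and paired-end 100-nt libraries in which RNase R treatment
depletes linear transcripts while retaining circular ones.  Every planted
object is recorded in a :class:`SyntheticTruth` so that each downstream
stage can be validated against known ground truth.

Orthologous genes share their exon/intron structure exactly (an "ancestral"
layout reused in every species); sequences are drawn independently per
species, so cross-species relationships are carried by emitted chain files,
not by sequence homology.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from circevo.formats import (
    ChainMap,
    GeneModel,
    GenomicInterval,
    RepeatCopy,
    revcomp,
    write_bedgraph,
    write_fasta,
    write_fastq,
    write_gtf,
    write_repeat_table,
)

TISSUES = ("liver", "cerebellum", "testis")

# isochore GC targets are drawn inside these ranges, with a safety margin to
# the class boundaries (37/42/47/52%) so that realized per-gene GC classifies
# back to the planted class despite binomial sampling noise
_ISOCHORE_RANGES = {
    "L1": (0.300, 0.352),
    "L2": (0.378, 0.412),
    "H1": (0.428, 0.462),
    "H2": (0.478, 0.512),
    "H3": (0.530, 0.600),
}


class SizingError(ValueError):
    """Genome length budget too small for the requested gene count."""


class ParameterError(ValueError):
    """Invalid simulation parameter combination."""


@dataclass
class TEFamilyDef:
    """A transposable-element family with an age rank (1=species-specific,
    2=lineage, 3=eutherian, 4=therian) controlling accumulated divergence."""

    family_name: str
    consensus: str
    age_rank: int
    per_copy_divergence_rate: float
    insertion_weight: float = 1.0

    def __post_init__(self):
        if self.age_rank not in (1, 2, 3, 4):
            raise ValueError("age_rank must be in {1,2,3,4}")
        if len(self.consensus) < 50:
            raise ValueError("consensus length must be >= 50")


@dataclass
class SpeciesSpec:
    name: str
    clade: str  # marsupial | rodent | primate
    genome_length: int = 400_000
    n_genes: int = 60
    gc_isochore_mix: dict[str, float] = field(
        default_factory=lambda: {"L1": 0.3, "L2": 0.3, "H1": 0.2, "H2": 0.1, "H3": 0.1}
    )
    te_library: list[TEFamilyDef] = field(default_factory=list)

    def __post_init__(self):
        if abs(sum(self.gc_isochore_mix.values()) - 1.0) > 1e-9:
            raise ValueError("isochore proportions must sum to 1")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")


@dataclass
class CircPlan:
    """How many circRNA-bearing ortholog families to plant per sharing group.

    Group sizes that cannot be satisfied by the species set (e.g. no
    marsupial present) are silently skipped.  Second circRNAs are added to
    already-parental genes, marking them hotspots, until ``n_total_target``
    planted circRNAs exist across all species.
    """

    n_all: int = 10
    n_non_marsupial: int = 8
    n_rodent: int = 6
    n_primate: int = 6
    n_specific_per_species: int = 4
    n_partial_l1: int = 2
    n_partial_l2: int = 2
    n_total_target: int = 200
    min_coverage: float = 20.0
    max_coverage: float = 40.0

    @classmethod
    def scaled_to(cls, n_genes: int, reference_genes: int = 60) -> "CircPlan":
        """Default plan scaled proportionally to a smaller/larger gene set."""
        f = n_genes / reference_genes
        d = cls()
        return cls(
            n_all=max(1, round(d.n_all * f)),
            n_non_marsupial=round(d.n_non_marsupial * f),
            n_rodent=round(d.n_rodent * f),
            n_primate=round(d.n_primate * f),
            n_specific_per_species=round(d.n_specific_per_species * f),
            n_partial_l1=round(d.n_partial_l1 * f),
            n_partial_l2=round(d.n_partial_l2 * f),
            n_total_target=round(d.n_total_target * f),
        )


@dataclass
class PlantedCirc:
    species: str
    gene_id: str
    family: str
    exon_indices: tuple[int, ...]
    interval: GenomicInterval
    tissue_coverage: dict[str, float]
    group: str  # all | non_marsupial | rodent | primate | specific | partial_l1 | partial_l2
    is_hotspot_member: bool = False

    @property
    def circ_id(self) -> str:
        return f"{self.gene_id}:circ{self.exon_indices[0]}-{self.exon_indices[-1]}"


@dataclass
class PlantedRepeat:
    species: str
    copy: RepeatCopy
    gene_id: str
    intron_index: int
    mismatches: int
    consensus_length: int
    age_rank: int


@dataclass
class _FamilyStructure:
    """Ancestral gene structure shared by all orthologs of one family."""

    family: str
    n_exons: int
    exon_lengths: list[int]
    intron_lengths: list[int]
    strand: str
    gc_class: str
    gc_target: float


@dataclass
class SyntheticTruth:
    species_specs: list[SpeciesSpec]
    tissues: tuple[str, ...]
    n_replicates: int
    genomes: dict[str, dict[str, str]]
    genes: dict[str, list[GeneModel]]
    ortho_map: dict[str, dict[str, str]]  # family -> species -> gene_id
    family_structures: dict[str, _FamilyStructure]
    planted_circ: list[PlantedCirc]
    chains: dict[tuple[str, str], ChainMap]
    linear_weight: dict[tuple[str, str, str], float]  # (species, gene, tissue)
    rnase_r_linear_retention: float
    planted_repeats: dict[str, list[PlantedRepeat]] = field(default_factory=dict)

    def circs_of(self, species: str) -> list[PlantedCirc]:
        return [c for c in self.planted_circ if c.species == species]

    def gene_by_id(self, species: str, gene_id: str) -> GeneModel:
        return next(g for g in self.genes[species] if g.gene_id == gene_id)

    def parental_families(self) -> dict[str, str]:
        """family -> sharing group, for families carrying planted circRNAs."""
        return {c.family: c.group for c in self.planted_circ}


def default_te_library(seed: int = 12345) -> list[TEFamilyDef]:
    """Four TE families spanning the age spectrum, with fixed consensuses."""
    rng = np.random.default_rng(seed)
    defs = [
        ("SINE_A", 180, 1, 0.020, 3.0),
        ("SINE_B", 160, 2, 0.020, 2.0),
        ("LINE_C", 220, 3, 0.015, 1.5),
        ("LINE_D", 240, 4, 0.015, 1.0),
    ]
    return [
        TEFamilyDef(name, _random_seq(rng, length, 0.45), rank, rate, weight)
        for name, length, rank, rate, weight in defs
    ]


def default_species_specs(**overrides) -> list[SpeciesSpec]:
    """The canonical five-species set: opossum, mouse, rat, macaque, human."""
    te = default_te_library()
    clades = {
        "opossum": "marsupial",
        "mouse": "rodent",
        "rat": "rodent",
        "macaque": "primate",
        "human": "primate",
    }
    return [
        SpeciesSpec(name=name, clade=clade, te_library=list(te), **overrides)
        for name, clade in clades.items()
    ]


# ---------------------------------------------------------------------------
# sequence helpers

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    r = rng.random(n)
    half = rng.integers(0, 2, n)
    gc_base = np.where(half == 0, ord("G"), ord("C"))
    at_base = np.where(half == 0, ord("A"), ord("T"))
    return np.where(r < gc, gc_base, at_base).astype(np.uint8).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, int]:
    """Substitute bases at the given per-base rate; returns (copy, mismatches)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode(), len(hits)


def count_mismatches(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    return sum(1 for x, y in zip(a, b) if x != y)


# ---------------------------------------------------------------------------
# genome generation


def _build_family_structures(
    rng: np.random.Generator, n_genes: int, gc_mix: dict[str, float]
) -> list[_FamilyStructure]:
    classes = list(gc_mix)
    probs = np.array([gc_mix[c] for c in classes])
    out = []
    for k in range(n_genes):
        n_exons = int(rng.integers(4, 8))
        exon_lengths = [int(rng.integers(120, 181)) for _ in range(n_exons)]
        intron_lengths = [int(rng.integers(400, 701)) for _ in range(n_exons - 1)]
        strand = "+" if rng.random() < 0.5 else "-"
        gc_class = classes[int(rng.choice(len(classes), p=probs))]
        lo, hi = _ISOCHORE_RANGES[gc_class]
        gc_target = float(rng.uniform(lo, hi))
        out.append(
            _FamilyStructure(
                family=f"fam{k:03d}",
                n_exons=n_exons,
                exon_lengths=exon_lengths,
                intron_lengths=intron_lengths,
                strand=strand,
                gc_class=gc_class,
                gc_target=gc_target,
            )
        )
    return out


def _gene_length(fs: _FamilyStructure) -> int:
    return sum(fs.exon_lengths) + sum(fs.intron_lengths)


def _plant_splice_motifs(seq: list[str], gene_start: int, fs: _FamilyStructure):
    """Overwrite intron-edge dinucleotides with canonical donor/acceptor."""
    pos = gene_start
    for i in range(fs.n_exons - 1):
        pos += fs.exon_lengths[i]
        intron_start, intron_end = pos, pos + fs.intron_lengths[i]
        if fs.strand == "+":
            seq[intron_start : intron_start + 2] = "GT"
            seq[intron_end - 2 : intron_end] = "AG"
        else:
            seq[intron_start : intron_start + 2] = "CT"
            seq[intron_end - 2 : intron_end] = "AC"
        pos = intron_end


def _choose_chain(
    rng: np.random.Generator, fs: _FamilyStructure
) -> tuple[int, ...]:
    """A contiguous internal exon chain leaving flanking introns intact."""
    max_len = min(4, fs.n_exons - 2)
    length = int(rng.integers(2, max_len + 1)) if max_len >= 2 else 1
    start = int(rng.integers(1, fs.n_exons - 1 - length + 1))
    return tuple(range(start, start + length))


def make_genomes(
    spec_list: list[SpeciesSpec],
    seed: int,
    plan: CircPlan | None = None,
    n_replicates: int = 1,
    rnase_r_linear_retention: float = 0.05,
    tissues: tuple[str, ...] = TISSUES,
) -> SyntheticTruth:
    """Generate per-species genomes, annotations, chains and planted truth.

    Deterministic for a given seed: repeated calls produce byte-identical
    sequences and identical planted objects.
    """
    if not spec_list:
        raise ValueError("spec_list must be non-empty")
    if plan is None:
        plan = (
            CircPlan()
            if spec_list[0].n_genes >= 60
            else CircPlan.scaled_to(spec_list[0].n_genes)
        )
    rng = np.random.default_rng(seed)
    n_genes = spec_list[0].n_genes
    if any(s.n_genes != n_genes for s in spec_list):
        raise ValueError("all species must request the same number of 1:1 genes")

    structures = _build_family_structures(rng, n_genes, spec_list[0].gc_isochore_mix)

    # --- lay out each species genome ------------------------------------
    genomes: dict[str, dict[str, str]] = {}
    genes: dict[str, list[GeneModel]] = {}
    gene_offsets: dict[str, dict[str, int]] = {}
    for spec in spec_list:
        seq_parts: list[str] = []
        pos = 0
        offsets: dict[str, int] = {}
        models: list[GeneModel] = []
        for fs in structures:
            spacer = int(rng.integers(300, 601))
            seq_parts.append(_random_seq(rng, spacer, 0.42))
            pos += spacer
            glen = _gene_length(fs)
            if pos + glen > spec.genome_length:
                raise SizingError(
                    f"{spec.name}: genome_length {spec.genome_length} too small "
                    f"for {spec.n_genes} genes"
                )
            offsets[fs.family] = pos
            seq_parts.append(_random_seq(rng, glen, fs.gc_target))
            # exon coordinates
            exons = []
            epos = pos
            for i in range(fs.n_exons):
                exons.append((epos, epos + fs.exon_lengths[i]))
                epos += fs.exon_lengths[i]
                if i < fs.n_exons - 1:
                    epos += fs.intron_lengths[i]
            gid = f"{spec.name}.g{fs.family[3:]}"
            # terminal exons carry UTR, mirroring typical annotation
            models.append(
                GeneModel(
                    gene_id=gid,
                    chrom="chr1",
                    strand=fs.strand,
                    transcripts={gid + ".t1": exons},
                    utr_exons={exons[0], exons[-1]},
                )
            )
            pos += glen
        chrom_seq = list("".join(seq_parts))
        for fs in structures:
            _plant_splice_motifs(chrom_seq, offsets[fs.family], fs)
        genomes[spec.name] = {"chr1": "".join(chrom_seq)}
        genes[spec.name] = models
        gene_offsets[spec.name] = offsets

    ortho_map = {
        fs.family: {s.name: f"{s.name}.g{fs.family[3:]}" for s in spec_list}
        for fs in structures
    }

    # --- chain files: one block per orthologous gene span ----------------
    chains: dict[tuple[str, str], ChainMap] = {}
    for a in spec_list:
        for b in spec_list:
            if a.name == b.name:
                continue
            blocks = []
            for fs in structures:
                glen = _gene_length(fs)
                blocks.append(
                    ("chr1", gene_offsets[a.name][fs.family],
                     gene_offsets[a.name][fs.family] + glen,
                     "chr1", gene_offsets[b.name][fs.family])
                )
            sizes_a = {"chr1": len(genomes[a.name]["chr1"])}
            sizes_b = {"chr1": len(genomes[b.name]["chr1"])}
            chains[(a.name, b.name)] = ChainMap.from_blocks(blocks, sizes_a, sizes_b)

    # --- circRNA planting plan -------------------------------------------
    by_clade: dict[str, list[str]] = {}
    for s in spec_list:
        by_clade.setdefault(s.clade, []).append(s.name)
    all_names = [s.name for s in spec_list]
    non_marsupial = [s.name for s in spec_list if s.clade != "marsupial"]

    groups: list[tuple[str, list[str]]] = []
    if len(all_names) >= 2:
        groups += [("all", all_names)] * plan.n_all
    if len(non_marsupial) >= 3 and len(non_marsupial) < len(all_names):
        groups += [("non_marsupial", non_marsupial)] * plan.n_non_marsupial
    if len(by_clade.get("rodent", [])) == 2:
        groups += [("rodent", by_clade["rodent"])] * plan.n_rodent
    if len(by_clade.get("primate", [])) == 2:
        groups += [("primate", by_clade["primate"])] * plan.n_primate
    for s in spec_list:
        groups += [("specific", [s.name])] * plan.n_specific_per_species
    if len(all_names) >= 2:
        groups += [("partial_l1", all_names[:2])] * plan.n_partial_l1
        groups += [("partial_l2", all_names[:2])] * plan.n_partial_l2

    # bias parental-gene choice toward low-GC families (circRNA niche)
    weights = np.array(
        [4.0 if fs.gc_class in ("L1", "L2") else 1.0 for fs in structures]
    )
    # partial groups need >= 6 exons to host two distinct chains
    eligible_partial = [i for i, fs in enumerate(structures) if fs.n_exons >= 6]
    order = list(
        rng.choice(len(structures), size=len(structures), replace=False,
                   p=weights / weights.sum())
    )
    if len(groups) > len(structures):
        raise SizingError("not enough gene families for the circRNA plan")

    planted: list[PlantedCirc] = []
    used: set[int] = set()

    def _take_family(need_partial: bool) -> _FamilyStructure:
        for idx in order:
            if idx in used:
                continue
            if need_partial and idx not in eligible_partial:
                continue
            used.add(idx)
            return structures[idx]
        raise SizingError("ran out of eligible gene families for the plan")

    def _plant(species: str, fs: _FamilyStructure, chain: tuple[int, ...],
               group: str) -> PlantedCirc:
        gene = next(
            g for g in genes[species] if g.gene_id == ortho_map[fs.family][species]
        )
        exons = next(iter(gene.transcripts.values()))
        iv = GenomicInterval(
            gene.chrom, exons[chain[0]][0], exons[chain[-1]][1], gene.strand
        )
        expressed = sorted(
            rng.choice(len(tissues), size=int(rng.integers(1, len(tissues) + 1)),
                       replace=False)
        )
        cov = {
            tissues[t]: float(rng.uniform(plan.min_coverage, plan.max_coverage))
            for t in expressed
        }
        pc = PlantedCirc(
            species=species, gene_id=gene.gene_id, family=fs.family,
            exon_indices=chain, interval=iv, tissue_coverage=cov, group=group,
        )
        planted.append(pc)
        return pc

    for group, members in groups:
        fs = _take_family(group in ("partial_l1", "partial_l2"))
        if group == "partial_l1":
            # same gene, disjoint exon chains: level-1 sharing only
            a, b = members
            _plant(a, fs, (1, 2), group)
            _plant(b, fs, (fs.n_exons - 3, fs.n_exons - 2), group)
        elif group == "partial_l2":
            # overlapping chains with different boundaries: level 1+2, not 3
            a, b = members
            _plant(a, fs, (1, 2, 3), group)
            _plant(b, fs, (2, 3, 4), group)
        else:
            chain = _choose_chain(rng, fs)
            for sp in members:
                _plant(sp, fs, chain, group)

    # --- hotspots: add second, overlapping circRNAs up to the target -----
    n_needed = plan.n_total_target - len(planted)
    if n_needed > 0:
        first_round = list(planted)
        i = 0
        added = 0
        hotspot_keys: set[tuple[str, str]] = set()
        while added < n_needed and i < len(first_round):
            base = first_round[i]
            i += 1
            fs = next(
                f for f in structures if f.family == base.family
            )
            chain = base.exon_indices
            if len(chain) >= 2:
                alt = chain[:-1]  # drop last exon: overlapping, distinct
            elif chain[0] + 1 <= fs.n_exons - 2:
                alt = (chain[0], chain[0] + 1)
            else:
                continue
            pc = _plant(base.species, fs, alt, base.group)
            pc.is_hotspot_member = True
            base.is_hotspot_member = True
            hotspot_keys.add((base.species, base.gene_id))
            added += 1

    # --- linear expression weights ---------------------------------------
    linear_weight = {
        (spec.name, g.gene_id, t): float(rng.gamma(2.0, 1.0))
        for spec in spec_list
        for g in genes[spec.name]
        for t in tissues
    }

    return SyntheticTruth(
        species_specs=spec_list,
        tissues=tuple(tissues),
        n_replicates=n_replicates,
        genomes=genomes,
        genes=genes,
        ortho_map=ortho_map,
        family_structures={fs.family: fs for fs in structures},
        planted_circ=planted,
        chains=chains,
        linear_weight=linear_weight,
        rnase_r_linear_retention=rnase_r_linear_retention,
    )


# ---------------------------------------------------------------------------
# repeat planting


def plant_repeats(
    truth: SyntheticTruth,
    seed: int,
    p_dimer_shared: float = 0.9,
    p_dimer_specific: float = 0.7,
    p_background: float = 0.25,
) -> dict[str, list[RepeatCopy]]:
    """Insert TE copies intronically, overwriting intron sequence in place.

    Introns flanking planted circRNAs of widely shared parental genes
    preferentially receive a reverse-oriented pair of copies of the
    youngest family; species-specific parental genes receive pairs of the
    oldest family instead.  Background copies are scattered by
    insertion_weight.  Coordinates are unchanged (in-place overwrite), so
    the planting order does not perturb any other truth record.
    """
    rng = np.random.default_rng(seed)
    tables: dict[str, list[RepeatCopy]] = {}
    for spec in truth.species_specs:
        sp = spec.name
        if not spec.te_library:
            tables[sp] = []
            truth.planted_repeats[sp] = []
            continue
        chrom_seq = list(truth.genomes[sp]["chr1"])
        occupied: dict[tuple[str, int], list[tuple[int, int]]] = {}
        planted: list[PlantedRepeat] = []

        young = min(spec.te_library, key=lambda f: f.age_rank)
        old = max(spec.te_library, key=lambda f: f.age_rank)

        def _insert(gene: GeneModel, intron_idx: int, fam: TEFamilyDef,
                    orientation: str) -> bool:
            introns = gene.introns()
            if intron_idx < 0 or intron_idx >= len(introns):
                return False
            intron = introns[intron_idx]
            clen = len(fam.consensus)
            lo = intron.start + 10
            hi = intron.end - 10 - clen
            if hi <= lo:
                return False
            key = (gene.gene_id, intron_idx)
            for _ in range(10):
                start = int(rng.integers(lo, hi + 1))
                if all(
                    start + clen <= s or start >= e
                    for s, e in occupied.get(key, [])
                ):
                    break
            else:
                return False
            occupied.setdefault(key, []).append((start, start + clen))
            copy_seq, mm = _mutate(
                rng, fam.consensus, fam.per_copy_divergence_rate * fam.age_rank
            )
            if orientation == "-":
                copy_seq = revcomp(copy_seq)
            chrom_seq[start : start + clen] = copy_seq
            milli_div = round(1000 * mm / clen)
            rc = RepeatCopy(
                GenomicInterval("chr1", start, start + clen, orientation),
                fam.family_name, milli_div,
            )
            planted.append(
                PlantedRepeat(sp, rc, gene.gene_id, intron_idx, mm, clen,
                              fam.age_rank)
            )
            return True

        # dimers into introns flanking planted circRNAs
        for circ in truth.circs_of(sp):
            gene = truth.gene_by_id(sp, circ.gene_id)
            up = circ.exon_indices[0] - 1
            down = circ.exon_indices[-1]
            if circ.group in ("all", "non_marsupial"):
                fam, p = young, p_dimer_shared
            elif circ.group == "specific":
                fam, p = old, p_dimer_specific
            else:
                fam, p = (young, 0.5) if rng.random() < 0.5 else (old, 0.5)
            if rng.random() < p:
                ok1 = _insert(gene, up, fam, "+")
                ok2 = _insert(gene, down, fam, "-")
                del ok1, ok2  # flanking intron may be occupied; best effort

        # background insertions across all introns
        fams = spec.te_library
        fam_w = np.array([f.insertion_weight for f in fams])
        fam_w = fam_w / fam_w.sum()
        for gene in truth.genes[sp]:
            for i in range(len(gene.introns())):
                if rng.random() < p_background:
                    fam = fams[int(rng.choice(len(fams), p=fam_w))]
                    _insert(gene, i, fam, "+" if rng.random() < 0.5 else "-")

        truth.genomes[sp]["chr1"] = "".join(chrom_seq)
        truth.planted_repeats[sp] = planted
        tables[sp] = [p.copy for p in planted]
        tables[sp].sort(key=lambda r: (r.interval.start, r.interval.end))
    return tables


# ---------------------------------------------------------------------------
# read simulation


@dataclass(frozen=True)
class LibraryKey:
    species: str
    tissue: str
    replicate: int
    condition: str  # untreated | treated

    @property
    def sample_id(self) -> str:
        return f"{self.species}:{self.tissue}:r{self.replicate}:{self.condition}"


@dataclass
class Library:
    key: LibraryKey
    reads: list[tuple[str, str, str, str, str]]  # id, seq1, qual1, seq2, qual2

    @property
    def n_pairs(self) -> int:
        return len(self.reads)


def _transcript_seq(genome: str, exons: list[tuple[int, int]], strand: str) -> str:
    s = "".join(genome[a:b] for a, b in exons)
    return revcomp(s) if strand == "-" else s


def _qual_string(rng: np.random.Generator, n: int, low: bool) -> str:
    qual = [chr(33 + 37)] * n
    if low:
        for i in rng.integers(0, n, size=3):
            qual[i] = chr(33 + 20)
    return "".join(qual)


def simulate_reads(
    truth: SyntheticTruth,
    seed: int,
    depth: int = 12_000,
    read_length: int = 100,
    frag_mean: float = 250.0,
    frag_sd: float = 30.0,
    low_quality_fraction: float = 0.05,
) -> dict[LibraryKey, Library]:
    """Simulate paired-end libraries for every (species, tissue, replicate,
    condition).

    Fragment counts are Poisson; in the treated condition linear means are
    multiplied by the RNase R linear retention and all means are then
    rescaled so the library keeps the same expected depth — raw backsplice
    counts therefore rise in treated libraries, as in a real experiment
    sequenced to fixed depth.  Reads are error-free; a configurable
    fraction receives quality strings with bases below phred 25.
    """
    if frag_mean < read_length:
        raise ParameterError("frag_mean must be >= read_length")
    rng = np.random.default_rng(seed)
    retention = truth.rnase_r_linear_retention
    out: dict[LibraryKey, Library] = {}

    for spec in truth.species_specs:
        sp = spec.name
        genome = truth.genomes[sp]["chr1"]
        gene_list = truth.genes[sp]
        circ_list = truth.circs_of(sp)
        lin_seqs = {
            g.gene_id: _transcript_seq(
                genome, next(iter(g.transcripts.values())), g.strand
            )
            for g in gene_list
        }
        circ_seqs = {}
        for c in circ_list:
            gene = truth.gene_by_id(sp, c.gene_id)
            exons = next(iter(gene.transcripts.values()))
            circ_exons = [exons[i] for i in c.exon_indices]
            circ_seqs[c.circ_id] = _transcript_seq(genome, circ_exons, gene.strand)

        for tissue in truth.tissues:
            w = np.array([truth.linear_weight[(sp, g.gene_id, tissue)]
                          for g in gene_list])
            # expected backsplice-spanning reads per fragment ~ 2*(L-16)/C,
            # so the fragment mean that realizes the planted coverage is
            # J * C / (2*(L-16))
            circ_frag_mean = {}
            for c in circ_list:
                cov = c.tissue_coverage.get(tissue, 0.0)
                C = len(circ_seqs[c.circ_id])
                circ_frag_mean[c.circ_id] = cov * C / (2 * (read_length - 16))
            e_circ = sum(circ_frag_mean.values())
            lin_budget = max(depth - e_circ, 0.0)
            lin_mean = w / w.sum() * lin_budget

            for rep in range(1, truth.n_replicates + 1):
                for cond in ("untreated", "treated"):
                    if cond == "treated":
                        lm = lin_mean * retention
                        cm = dict(circ_frag_mean)
                        total = lm.sum() + sum(cm.values())
                        scale = depth / total if total > 0 else 1.0
                        lm = lm * scale
                        cm = {k: v * scale for k, v in cm.items()}
                    else:
                        lm, cm = lin_mean, circ_frag_mean
                    key = LibraryKey(sp, tissue, rep, cond)
                    reads: list[tuple[str, str, str, str, str]] = []
                    idx = 0

                    def _emit(seq: str, circular: bool, origin: str, n: int):
                        nonlocal idx
                        T = len(seq)
                        if T < read_length:
                            return
                        flens = np.clip(
                            rng.normal(frag_mean, frag_sd, n), read_length,
                            T,
                        ).astype(int)
                        if circular:
                            starts = rng.integers(0, T, n)
                            doubled = seq + seq
                        else:
                            starts = rng.integers(0, T - flens + 1)
                        lowq = rng.random(n) < low_quality_fraction
                        for j in range(n):
                            s, f = int(starts[j]), int(flens[j])
                            frag = doubled[s : s + f] if circular else seq[s : s + f]
                            r1 = frag[:read_length]
                            r2 = revcomp(frag[-read_length:])
                            rid = f"{key.sample_id}:{idx}:{origin}"
                            idx += 1
                            q1 = _qual_string(rng, read_length, bool(lowq[j]))
                            q2 = _qual_string(rng, read_length, False)
                            reads.append((rid, r1, q1, r2, q2))

                    for gi, g in enumerate(gene_list):
                        n = int(rng.poisson(lm[gi]))
                        if n:
                            _emit(lin_seqs[g.gene_id], False, g.gene_id, n)
                    for c in circ_list:
                        n = int(rng.poisson(cm[c.circ_id]))
                        if n:
                            _emit(circ_seqs[c.circ_id], True, c.circ_id, n)
                    out[key] = Library(key=key, reads=reads)
    return out


# ---------------------------------------------------------------------------
# conservation track


def emit_conservation(
    truth: SyntheticTruth,
    shift: float = 0.3,
    base: float = 0.4,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> dict[str, list[tuple[str, int, int, float]]]:
    """Per-species bedGraph records: one row per exon, planted circRNA exons
    shifted upward by ``shift`` (scores clipped to [0, 1])."""
    rng = np.random.default_rng(seed)
    out: dict[str, list[tuple[str, int, int, float]]] = {}
    for spec in truth.species_specs:
        sp = spec.name
        circ_exons: set[tuple[str, int]] = set()
        for c in truth.circs_of(sp):
            for i in c.exon_indices:
                circ_exons.add((c.gene_id, i))
        rows = []
        for g in truth.genes[sp]:
            exons = next(iter(g.transcripts.values()))
            for i, (s, e) in enumerate(exons):
                score = base + rng.normal(0.0, noise_sd)
                if (g.gene_id, i) in circ_exons:
                    score += shift
                rows.append((g.chrom, s, e, float(np.clip(score, 0.0, 1.0))))
        rows.sort(key=lambda r: (r[0], r[1]))
        out[sp] = rows
    return out


# ---------------------------------------------------------------------------
# emitters


def write_dataset(
    truth: SyntheticTruth,
    libraries: dict[LibraryKey, Library],
    repeat_tables: dict[str, list[RepeatCopy]],
    conservation: dict[str, list[tuple[str, int, int, float]]],
    outdir: str,
) -> None:
    """Emit the complete dataset: FASTA, GTF, chain, FASTQ, repeat tables,
    bedGraph, plus a truth table of planted circRNAs."""
    os.makedirs(outdir, exist_ok=True)
    for spec in truth.species_specs:
        sp = spec.name
        write_fasta(os.path.join(outdir, f"{sp}.fa"), truth.genomes[sp])
        write_gtf(os.path.join(outdir, f"{sp}.gtf"), truth.genes[sp])
        if sp in repeat_tables:
            write_repeat_table(
                os.path.join(outdir, f"{sp}.repeats.tsv"), repeat_tables[sp]
            )
        if sp in conservation:
            write_bedgraph(
                os.path.join(outdir, f"{sp}.phastcons.bedgraph"), conservation[sp]
            )
    for (a, b), chain in truth.chains.items():
        chain.to_file(os.path.join(outdir, f"{a}To{b}.chain"))
    for key, lib in libraries.items():
        stem = f"{key.species}_{key.tissue}_rep{key.replicate}_{key.condition}"
        write_fastq(
            os.path.join(outdir, stem + "_R1.fastq"),
            ((rid + "/1", s1, q1) for rid, s1, q1, _, _ in lib.reads),
        )
        write_fastq(
            os.path.join(outdir, stem + "_R2.fastq"),
            ((rid + "/2", s2, q2) for rid, _, _, s2, q2 in lib.reads),
        )
    with open(os.path.join(outdir, "truth_circrnas.tsv"), "w") as fh:
        fh.write("species\tgene_id\tchrom\tstart\tend\tstrand\texons\tgroup\thotspot\n")
        for c in truth.planted_circ:
            fh.write(
                f"{c.species}\t{c.gene_id}\t{c.interval.chrom}\t{c.interval.start}"
                f"\t{c.interval.end}\t{c.interval.strand}\t"
                f"{','.join(map(str, c.exon_indices))}\t{c.group}\t"
                f"{int(c.is_hotspot_member)}\n"
            )
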