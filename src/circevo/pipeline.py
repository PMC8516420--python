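"""End-to-end orchestration: synthetic data -> detection -> filters ->
isoforms -> cross-species evolution -> gene models -> TE dimers.

Each stage remains usable on its own; this module wires them together for
whole-study runs on synthetic data with planted ground truth and provides
the truth-evaluation helpers used for validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from circevo import align_bsj, evo, filters, genefeat, isoforms, repeats, synth
from circevo.formats import GeneModel, GenomicInterval
from circevo.genefeat import gc_content
from circevo.synth import Library, LibraryKey, SyntheticTruth


def _species_libs(libraries, species):
    return {k: v for k, v in libraries.items() if k.species == species}


@dataclass
class SpeciesResult:
    species: str
    candidates: list
    aligned: dict
    matrix: filters.JunctionCountMatrix
    factors: pd.Series
    cpm: pd.DataFrame
    report: filters.FilterReport
    circs: list[evo.CircAnnotation]
    isoform_results: dict[str, isoforms.IsoformResult] = field(default_factory=dict)


def assign_gene(iv: GenomicInterval, genes: list[GeneModel]) -> GeneModel | None:
    """Smallest same-strand gene whose span contains the interval."""
    best = None
    for g in genes:
        span = g.span
        if g.strand == iv.strand and span.start <= iv.start and iv.end <= span.end:
            if best is None or len(span) < len(best.span):
                best = g
    return best


def combined_junction_counts(
    aligned: dict[LibraryKey, align_bsj.AlignedLibrary],
    candidates: list[align_bsj.BackspliceCandidate],
) -> pd.DataFrame:
    """Linear splice-junction counts plus backsplice counts per sample.

    Size factors are computed on this combined matrix: common junctions
    are dominated by linear splice junctions, so the factors track the
    depletion of linear RNA in treated libraries."""
    samples = [key.sample_id for key in aligned]
    rows: dict[str, dict[str, int]] = {}
    for key, al in aligned.items():
        sid = key.sample_id
        for (gene, j), n in al.junction_counts.items():
            rows.setdefault(f"lin:{gene}:{j}", {})[sid] = n
    for cand in candidates:
        jid = filters.junction_id(cand.interval)
        for sample, reads in cand.support.items():
            pairs = {k.rpartition("#")[0] for k in reads}
            rows.setdefault(jid, {})[sample] = len(pairs)
    df = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=samples)
    return df.fillna(0).astype(int)


def linear_junction_norm_means(
    aligned: dict[LibraryKey, align_bsj.AlignedLibrary],
    factors: pd.Series,
    genes: list[GeneModel],
) -> tuple[dict, dict]:
    """Per linear junction: normalized (untreated, treated) mean coverage
    and treated coverage for splice-graph edge weights."""
    per_cond: dict[tuple[str, int], dict[str, list[float]]] = {}
    for key, al in aligned.items():
        f = factors[key.sample_id]
        gene_juncs = {g.gene_id: len(g.collapsed_exons()) - 1 for g in genes}
        for gene_id, n_j in gene_juncs.items():
            for j in range(n_j):
                c = al.junction_counts.get((gene_id, j), 0)
                per_cond.setdefault((gene_id, j), {}).setdefault(
                    key.condition, []
                ).append(c / f)
    means = {}
    for key, conds in per_cond.items():
        u = float(np.mean(conds.get("untreated", [0.0])))
        t = float(np.mean(conds.get("treated", [0.0])))
        means[key] = (u, t)
    return means, {k: t for k, (_, t) in means.items()}


def analyze_species(
    truth: SyntheticTruth,
    libraries: dict[LibraryKey, Library],
    species: str,
    read_length: int = 100,
    min_log2: float = filters.DEFAULT_MIN_LOG2_ENRICHMENT,
    min_cpm: float = filters.DEFAULT_MIN_CPM,
) -> SpeciesResult:
    """Detection, filtering and isoform reconstruction for one species."""
    genome = truth.genomes[species]
    genes = truth.genes[species]
    libs = _species_libs(libraries, species)
    candidates, aligned = align_bsj.detect_species(libs, genome, genes, read_length)
    combined = combined_junction_counts(aligned, candidates)
    factors = filters.size_factors(combined)
    matrix = filters.build_matrix(candidates, aligned)
    kept, cpm, report = filters.run_cascade(matrix, factors, min_log2, min_cpm)

    norm_means, _ = linear_junction_norm_means(aligned, factors, genes)
    # global background: junctions outside every detected circRNA span
    gene_by_id = {g.gene_id: g for g in genes}
    inside_keys = set()
    for jid in kept.junction_ids:
        iv = kept.intervals[jid]
        gene = assign_gene(iv, genes)
        if gene is None:
            continue
        exons = gene.collapsed_exons()
        for j in range(len(exons) - 1):
            if iv.start <= exons[j].end and exons[j + 1].start <= iv.end:
                inside_keys.add((gene.gene_id, j))
    global_bg = [
        isoforms.JunctionChange(k, "outside_bsj", float(np.log2(t / u)))
        for k, (u, t) in norm_means.items()
        if u > 0 and t > 0 and k not in inside_keys
    ]
    circs = []
    iso_results = {}
    chrom_seq = genome["chr1"]
    for jid in kept.junction_ids:
        iv = kept.intervals[jid]
        gene = assign_gene(iv, genes)
        if gene is None:
            continue
        iso = isoforms.reconstruct_circ_isoform(
            iv, jid, gene, norm_means, [], global_background=global_bg
        )
        iso_results[jid] = iso
        tissue_cpm = {
            tissue: float(cpm.loc[jid, (species, tissue)])
            for (sp, tissue) in cpm.columns
            if sp == species
        }
        circs.append(
            evo.CircAnnotation(jid, species, gene.gene_id, iso.exons, tissue_cpm)
        )
    del chrom_seq
    return SpeciesResult(
        species, candidates, aligned, matrix, factors, cpm, report, circs,
        iso_results,
    )


# ---------------------------------------------------------------------------
# truth evaluation


def planted_junctions(truth: SyntheticTruth, species: str) -> set[tuple]:
    out = set()
    for c in truth.circs_of(species):
        iv = c.interval
        out.add((iv.chrom, iv.start, iv.end, iv.strand))
    return out


def detection_metrics(
    candidates: list[align_bsj.BackspliceCandidate],
    truth: SyntheticTruth,
    species: str,
) -> dict[str, float]:
    """Breakpoint-exact recall and precision against the planted truth."""
    planted = planted_junctions(truth, species)
    detected = {
        (c.interval.chrom, c.interval.start, c.interval.end, c.interval.strand)
        for c in candidates
    }
    tp = len(planted & detected)
    return {
        "recall": tp / len(planted) if planted else float("nan"),
        "precision": tp / len(detected) if detected else float("nan"),
        "n_planted": len(planted),
        "n_detected": len(detected),
    }


# ---------------------------------------------------------------------------
# dimer pipeline


def dimer_analysis(
    truth: SyntheticTruth,
    repeat_tables: dict[str, list],
    gene_groups: dict[str, dict[str, str]] | None = None,
) -> dict:
    """Species-pooled TE dimer pipeline on parental genes.

    ``gene_groups`` maps species -> gene_id -> 'shared'/'species-specific';
    by default groups come from the planted sharing plan (loci planted in
    more than one species are shared).  Returns the ranking, the pooled
    dimer calls and the per-gene group map used.
    """
    shared_groups = {"all", "non_marsupial", "rodent", "primate",
                     "partial_l1", "partial_l2"}
    if gene_groups is None:
        gene_groups = {}
        for c in truth.planted_circ:
            grp = "shared" if c.group in shared_groups else "species-specific"
            gene_groups.setdefault(c.species, {})[c.gene_id] = grp

    all_shared: list[repeats.DimerCall] = []
    all_specific: list[repeats.DimerCall] = []
    gene_group_flat: dict[str, str] = {}
    n_genes = {"shared": 0, "species-specific": 0}
    age_of_family = {
        f.family_name: f.age_rank
        for spec in truth.species_specs
        for f in spec.te_library
    }
    genome_by_gene: dict[str, str] = {}
    for spec in truth.species_specs:
        sp = spec.name
        genome = truth.genomes[sp]["chr1"]
        table = repeat_tables.get(sp, [])
        for gene_id, grp in gene_groups.get(sp, {}).items():
            gene = truth.gene_by_id(sp, gene_id)
            rvcs, _ = repeats.find_rvc(gene, genome)
            rvcs = repeats.filter_intronic_rvcs(
                [r for r in rvcs if r.orientation == "antisense"], gene
            )
            local = [
                r for r in table
                if r.interval.start >= gene.start and r.interval.end <= gene.end
            ]
            calls = repeats.call_dimers(rvcs, local, age_of_family)
            repeats.correct_cocounts(calls)
            gene_group_flat[gene_id] = grp
            genome_by_gene[gene_id] = genome
            n_genes[grp] += 1
            if grp == "shared":
                all_shared.extend(calls)
            else:
                all_specific.extend(calls)
    ranking = repeats.rank_dimers(
        all_shared, all_specific, n_genes["shared"], n_genes["species-specific"]
    )
    return {
        "ranking": ranking,
        "dimers": all_shared + all_specific,
        "gene_group": gene_group_flat,
        "n_genes": n_genes,
        "genome_by_gene": genome_by_gene,
        "age_of_family": age_of_family,
    }


# ---------------------------------------------------------------------------
# whole-study driver


@dataclass
class StudyResult:
    truth: SyntheticTruth
    species_results: dict[str, SpeciesResult]
    loci: list[evo.CircLocus]
    groups: list[evo.OrthologyGroup]
    hotspots: dict
    dimer: dict
    detection: dict[str, dict[str, float]]


def run_study(
    seed: int,
    specs: list[synth.SpeciesSpec] | None = None,
    plan: synth.CircPlan | None = None,
    depth: int = 12_000,
    read_length: int = 100,
) -> StudyResult:
    """Generate a synthetic multi-species study and run the full pipeline."""
    specs = specs or synth.default_species_specs()
    truth = synth.make_genomes(specs, seed=seed, plan=plan)
    repeat_tables = synth.plant_repeats(truth, seed=seed + 1)
    libraries = synth.simulate_reads(truth, seed=seed + 2, depth=depth,
                                     read_length=read_length)
    species_results = {}
    all_circs: list[evo.CircAnnotation] = []
    detection = {}
    for spec in specs:
        res = analyze_species(truth, libraries, spec.name, read_length)
        species_results[spec.name] = res
        all_circs.extend(res.circs)
        detection[spec.name] = detection_metrics(res.candidates, truth, spec.name)

    loci = evo.collapse_loci(all_circs)
    ortho_family = {
        (sp, gid): fam
        for fam, members in truth.ortho_map.items()
        for sp, gid in members.items()
    }
    clade_of = {s.name: s.clade for s in specs}
    groups = evo.cluster_loci(loci, ortho_family, truth.chains, clade_of)
    hotspots = evo.call_hotspots(all_circs)

    # gene groups for the dimer pipeline from the detected clade labels
    gene_groups: dict[str, dict[str, str]] = {}
    for grp in groups:
        shared = grp.clade_label != "species-specific" and len(grp.member_loci) > 1
        for locus in grp.member_loci:
            gene_groups.setdefault(locus.species, {})[locus.gene_id] = (
                "shared" if shared else "species-specific"
            )
    dimer = dimer_analysis(truth, repeat_tables, gene_groups)
    return StudyResult(
        truth, species_results, loci, groups, hotspots, dimer, detection
    )


# ---------------------------------------------------------------------------
# gene feature table


def predictor_table(
    truth: SyntheticTruth,
    species: str,
    parental_genes: set[str],
    repeat_table: list | None = None,
    conservation=None,
) -> pd.DataFrame:
    """Per-gene predictors for the parental-gene GLM."""
    genome = truth.genomes[species]["chr1"]
    rows = {}
    for gene in truth.genes[species]:
        span = gene.span
        seq = genome[span.start : span.end]
        expr = [
            truth.linear_weight[(species, gene.gene_id, t)] for t in truth.tissues
        ]
        sense = antisense = 0
        if repeat_table:
            for r in repeat_table:
                if r.interval.start >= span.start and r.interval.end <= span.end:
                    if r.interval.strand == gene.strand:
                        sense += 1
                    else:
                        antisense += 1
        row = {
            "genomic_length": len(span),
            "n_exons": len(gene.collapsed_exons()),
            "gc_content": gc_content(seq),
            "repeat_fragments_sense": sense,
            "repeat_fragments_antisense": antisense,
            "mean_expression": float(np.mean(expr)),
            "tau": genefeat.tau(expr),
            "is_parental": int(gene.gene_id in parental_genes),
        }
        rows[gene.gene_id] = row
    return pd.DataFrame.from_dict(rows, orient="index")
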