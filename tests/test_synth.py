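import numpy as np
import pytest

from circevo import synth
from circevo.formats import revcomp, write_fasta
from circevo.genefeat import gc_content
from conftest import make_small_specs, small_plan


class TestMakeGenomes:
    def test_seed_determinism_byte_identical(self, tmp_path):
        specs = make_small_specs()
        t1 = synth.make_genomes(specs, seed=7, plan=small_plan())
        t2 = synth.make_genomes(specs, seed=7, plan=small_plan())
        p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
        write_fasta(p1, t1.genomes["mouse"])
        write_fasta(p2, t2.genomes["mouse"])
        assert p1.read_bytes() == p2.read_bytes()
        assert [c.circ_id for c in t1.planted_circ] == [
            c.circ_id for c in t2.planted_circ
        ]
        t3 = synth.make_genomes(specs, seed=8, plan=small_plan())
        assert t3.genomes["mouse"]["chr1"] != t1.genomes["mouse"]["chr1"]

    def test_ortholog_pairing(self, small_truth):
        truth, _, _ = small_truth
        assert len(truth.ortho_map) == 20
        for fam, members in truth.ortho_map.items():
            assert set(members) == {"mouse", "rat"}

    def test_pure_l1_mix_yields_low_gc_genes(self):
        te = synth.default_te_library()
        specs = [
            synth.SpeciesSpec(
                "mouse", "rodent", n_genes=30, genome_length=300_000,
                gc_isochore_mix={"L1": 1.0}, te_library=te,
            ),
            synth.SpeciesSpec(
                "rat", "rodent", n_genes=30, genome_length=300_000,
                gc_isochore_mix={"L1": 1.0}, te_library=te,
            ),
        ]
        truth = synth.make_genomes(specs, seed=3, plan=small_plan())
        genome = truth.genomes["mouse"]["chr1"]
        for gene in truth.genes["mouse"]:
            gc = gc_content(genome[gene.start : gene.end])
            assert gc < 0.37

    def test_sizing_error(self):
        te = synth.default_te_library()
        specs = [
            synth.SpeciesSpec("mouse", "rodent", genome_length=5_000,
                              n_genes=20, te_library=te),
            synth.SpeciesSpec("rat", "rodent", genome_length=5_000,
                              n_genes=20, te_library=te),
        ]
        with pytest.raises(synth.SizingError):
            synth.make_genomes(specs, seed=1, plan=small_plan())

    def test_ortho_roundtrip_through_chains(self, small_truth):
        """Lifting each gene's exons through the emitted chain recovers the
        partner's exons with overlap ratio 1.0."""
        truth, _, _ = small_truth
        chain = truth.chains[("mouse", "rat")]
        rat_genes = {g.gene_id: g for g in truth.genes["rat"]}
        for fam, members in truth.ortho_map.items():
            mouse_gene = truth.gene_by_id("mouse", members["mouse"])
            rat_gene = rat_genes[members["rat"]]
            m_exons = mouse_gene.collapsed_exons()
            r_exons = rat_gene.collapsed_exons()
            assert len(m_exons) == len(r_exons)
            for me, re_ in zip(m_exons, r_exons):
                lifted = chain.lift(me, min_match=0.5)
                assert lifted is not None
                assert lifted.overlap(re_) == len(re_) == len(lifted)

    def test_planted_circ_invariants(self, truth5):
        truth, _, _ = truth5
        assert len(truth.planted_circ) == 200
        by_gene = {}
        for c in truth.planted_circ:
            gene = truth.gene_by_id(c.species, c.gene_id)
            exons = next(iter(gene.transcripts.values()))
            n = len(exons)
            # chain is a contiguous subsequence of the gene's exons with
            # flanking introns on both sides
            assert all(0 < i < n - 1 for i in c.exon_indices)
            assert list(c.exon_indices) == list(
                range(c.exon_indices[0], c.exon_indices[-1] + 1)
            )
            by_gene.setdefault((c.species, c.gene_id), []).append(c)
        for members in by_gene.values():
            if any(c.is_hotspot_member for c in members):
                assert len({c.exon_indices for c in members}) >= 2


class TestPlantRepeats:
    def test_zero_rate_gives_zero_millidiv(self):
        te = [synth.TEFamilyDef("FROZEN", "ACGT" * 30, 1, 0.0, 1.0)]
        specs = [
            synth.SpeciesSpec("mouse", "rodent", n_genes=10,
                              genome_length=100_000, te_library=te),
            synth.SpeciesSpec("rat", "rodent", n_genes=10,
                              genome_length=100_000, te_library=te),
        ]
        plan = synth.CircPlan(n_all=2, n_rodent=1, n_primate=0,
                              n_non_marsupial=0, n_specific_per_species=1,
                              n_partial_l1=0, n_partial_l2=0, n_total_target=8)
        truth = synth.make_genomes(specs, seed=5, plan=plan)
        tables = synth.plant_repeats(truth, seed=6)
        assert tables["mouse"]
        for rep in tables["mouse"]:
            assert rep.milli_div == 0

    def test_millidiv_matches_recomputation(self, small_truth):
        """Emitted milliDiv equals per-mille mismatches of the genomic copy
        vs. the family consensus, recomputed independently."""
        truth, tables, _ = small_truth
        cons = {
            f.family_name: f.consensus
            for f in truth.species_specs[0].te_library
        }
        checked = 0
        for sp in ("mouse", "rat"):
            genome = truth.genomes[sp]["chr1"]
            for rep in tables[sp]:
                seq = genome[rep.interval.start : rep.interval.end]
                if rep.interval.strand == "-":
                    seq = revcomp(seq)
                mm = synth.count_mismatches(seq, cons[rep.family])
                assert rep.milli_div == round(1000 * mm / len(seq))
                checked += 1
        assert checked > 20

    def test_older_families_more_degraded(self, small_truth):
        truth, tables, _ = small_truth
        by_rank = {}
        for sp, planted in truth.planted_repeats.items():
            for p in planted:
                by_rank.setdefault(p.age_rank, []).append(p.copy.milli_div)
        assert np.median(by_rank[4]) > np.median(by_rank[1])


class TestSimulateReads:
    def test_fragment_parameter_error(self, small_truth):
        truth, _, _ = small_truth
        with pytest.raises(synth.ParameterError):
            synth.simulate_reads(truth, seed=1, frag_mean=50, read_length=100)

    def test_no_op_treatment_preserves_linear_counts(self):
        """With full linear retention, treated and untreated libraries are
        statistically indistinguishable in per-gene linear coverage."""
        truth = synth.make_genomes(
            make_small_specs(), seed=21, plan=small_plan(),
            rnase_r_linear_retention=1.0,
        )
        from scipy import stats

        for seed in (31, 32, 33):
            libs = synth.simulate_reads(truth, seed=seed, depth=3000)
            for tissue in truth.tissues:
                u = t = None
                for key, lib in libs.items():
                    if key.species != "mouse" or key.tissue != tissue:
                        continue
                    counts = {}
                    for rid, *_ in lib.reads:
                        origin = rid.split(":")[-1]
                        if "circ" not in origin:
                            counts[origin] = counts.get(origin, 0) + 1
                    vec = [counts.get(g.gene_id, 0) for g in truth.genes["mouse"]]
                    if key.condition == "untreated":
                        u = vec
                    else:
                        t = vec
                assert stats.mannwhitneyu(u, t).pvalue > 0.01

    def test_zero_expression_circ_yields_no_junction_reads(self, small_truth):
        truth, _, libs = small_truth
        for key, lib in libs.items():
            for c in truth.circs_of(key.species):
                if key.tissue not in c.tissue_coverage:
                    assert not any(
                        rid.split(":")[-1] == c.circ_id for rid, *_ in lib.reads
                    )

    def test_low_quality_fraction(self, small_truth):
        from circevo.formats import min_phred

        _, _, libs = small_truth
        lib = next(iter(libs.values()))
        low = sum(1 for _, _, q1, _, _ in lib.reads if min_phred(q1) < 25)
        frac = low / lib.n_pairs
        assert 0.02 < frac < 0.09  # configured 5%

    def test_treated_enrichment_of_junction_reads(self, small_truth):
        """At fixed depth, backsplice-spanning fragments make up a larger
        share of treated libraries."""
        truth, _, libs = small_truth
        share = {}
        for key, lib in libs.items():
            if key.species != "mouse" or key.tissue != "liver":
                continue
            circ = sum(1 for rid, *_ in lib.reads if "circ" in rid.split(":")[-1])
            share[key.condition] = circ / lib.n_pairs
        assert share["treated"] > 3 * share["untreated"]


class TestConservation:
    def test_scores_bounded_and_shifted(self, small_truth):
        truth, _, _ = small_truth
        tracks = synth.emit_conservation(truth, shift=0.3, seed=1)
        circ_exons = set()
        for c in truth.circs_of("mouse"):
            gene = truth.gene_by_id("mouse", c.gene_id)
            exons = next(iter(gene.transcripts.values()))
            for i in c.exon_indices:
                circ_exons.add(exons[i])
        circ_scores, other_scores = [], []
        for chrom, s, e, v in tracks["mouse"]:
            assert 0.0 <= v <= 1.0
            (circ_scores if (s, e) in circ_exons else other_scores).append(v)
        diff = np.median(circ_scores) - np.median(other_scores)
        assert abs(diff - 0.3) < 0.05

    def test_zero_shift_no_class_difference(self, small_truth):
        from scipy import stats

        truth, _, _ = small_truth
        tracks = synth.emit_conservation(truth, shift=0.0, seed=2)
        circ_exons = set()
        for c in truth.circs_of("mouse"):
            gene = truth.gene_by_id("mouse", c.gene_id)
            exons = next(iter(gene.transcripts.values()))
            for i in c.exon_indices:
                circ_exons.add(exons[i])
        a = [v for _, s, e, v in tracks["mouse"] if (s, e) in circ_exons]
        b = [v for _, s, e, v in tracks["mouse"] if (s, e) not in circ_exons]
        assert stats.mannwhitneyu(a, b).pvalue > 0.01


def test_write_dataset_emits_all_formats(tmp_path, small_truth):
    truth, tables, libs = small_truth
    one_lib = {k: v for k, v in list(libs.items())[:2]}
    cons = synth.emit_conservation(truth, seed=3)
    synth.write_dataset(truth, one_lib, tables, cons, str(tmp_path))
    names = {p.name for p in tmp_path.iterdir()}
    assert {"mouse.fa", "mouse.gtf", "mouse.repeats.tsv",
            "mouse.phastcons.bedgraph", "mouseTorat.chain",
            "truth_circrnas.tsv"} <= names
    assert any(n.endswith("_R1.fastq") for n in names)
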