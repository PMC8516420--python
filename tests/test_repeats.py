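from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from circevo import repeats as rp
from circevo.formats import GeneModel, GenomicInterval, RepeatCopy, revcomp
from circevo.repeats import (
    DimerCall,
    IntronRecord,
    RVC,
    call_dimers,
    cofold_mfe,
    consensus_distance,
    correct_cocounts,
    degradation_analysis,
    find_rvc,
    match_control_introns,
    pairing_score,
    rank_dimers,
    te_enrichment,
)


def _random_seq(n, seed, gc=0.5):
    rng = np.random.default_rng(seed)
    r = rng.random(n)
    half = rng.integers(0, 2, n)
    return "".join(
        ("GC"[h] if x < gc else "AT"[h]) for x, h in zip(r, half)
    )


def _one_exon_gene(genome_len, gene_id="g"):
    return GeneModel(gene_id, "chr1", "+", {gene_id + ".t": [(0, genome_len)]})


class TestFindRvc:
    def test_planted_reverse_complement_pair(self):
        arm = _random_seq(300, seed=1)
        filler1 = _random_seq(3000, seed=2)
        filler2 = _random_seq(3000, seed=3)
        genome = filler1 + arm + filler2 + revcomp(arm) + _random_seq(500, 4)
        gene = _one_exon_gene(len(genome))
        rvcs, frac = find_rvc(gene, genome)
        anti = [r for r in rvcs if r.orientation == "antisense"]
        assert len(anti) >= 1
        best = max(anti, key=lambda r: r.alignment_length)
        assert best.alignment_length >= 300
        assert frac == pytest.approx(600 / len(genome), rel=0.1)
        # segments at the planted positions
        assert best.segment_a.start == pytest.approx(3000, abs=15)
        assert best.segment_b.start == pytest.approx(6300, abs=15)

    def test_random_sequence_low_self_complementarity(self):
        for seed in (10, 11, 12):
            genome = _random_seq(10_000, seed=seed)
            gene = _one_exon_gene(len(genome))
            rvcs, frac = find_rvc(gene, genome)
            anti_len = sum(
                r.alignment_length for r in rvcs if r.orientation == "antisense"
            )
            assert anti_len / len(genome) < 0.05

    def test_no_shared_kmer_no_antisense(self):
        genome = "A" * 400  # revcomp is all T: no shared 12-mer
        gene = _one_exon_gene(400)
        rvcs, _ = find_rvc(gene, genome)
        assert [r for r in rvcs if r.orientation == "antisense"] == []

    def test_sense_duplication_detected(self):
        arm = _random_seq(200, seed=5)
        genome = _random_seq(2000, 6) + arm + _random_seq(2000, 7) + arm
        gene = _one_exon_gene(len(genome))
        rvcs, _ = find_rvc(gene, genome)
        sense = [r for r in rvcs if r.orientation == "sense"]
        assert any(r.alignment_length >= 200 for r in sense)

    def test_intronic_filter(self):
        gene = GeneModel("g", "chr1", "+",
                         {"g.t": [(0, 100), (500, 600), (1000, 1100)]})
        intronic = RVC("g", GenomicInterval("chr1", 150, 250, "+"),
                       GenomicInterval("chr1", 700, 800, "-"), 100, 0.9,
                       "antisense")
        exon_touching = RVC("g", GenomicInterval("chr1", 80, 180, "+"),
                            GenomicInterval("chr1", 700, 800, "-"), 100, 0.9,
                            "antisense")
        assert rp.filter_intronic_rvcs([intronic, exon_touching], gene) == [intronic]


class TestControlIntrons:
    def _introns(self, gcs, lengths, start=0):
        out = []
        pos = start
        for gc, ln in zip(gcs, lengths):
            out.append(IntronRecord(GenomicInterval("chr1", pos, pos + ln), gc))
            pos += ln + 10
        return out

    def test_flanking_pool_reproduces_bins(self):
        rng = np.random.default_rng(1)
        gcs = rng.uniform(0.3, 0.6, 100)
        lens = rng.integers(300, 3000, 100)
        flank = self._introns(gcs, lens)
        out = match_control_introns(flank, flank, seed=2)
        assert len(out.control) == len(out.flanking)
        assert out.p_gc > 0.05 and out.p_length > 0.05

    def test_biased_pool_matched(self):
        rng = np.random.default_rng(3)
        flank = self._introns(rng.normal(0.35, 0.03, 150),
                              rng.integers(400, 900, 150))
        cands = self._introns(
            np.clip(rng.normal(0.45, 0.08, 8000), 0.05, 0.95),
            rng.integers(300, 1200, 8000), start=10**6,
        )
        out = match_control_introns(flank, cands, seed=4)
        assert out.p_gc > 0.05
        assert out.p_length > 0.05

    def test_out_of_grid_flanking_reported(self):
        flank = self._introns([0.3] * 50 + [0.9], [500] * 51)
        out = match_control_introns(flank, flank, seed=5)
        assert len(out.excluded_flanking) >= 1

    def test_te_enrichment_identical_groups(self):
        flank = self._introns([0.4] * 40, [500] * 40)
        ctrl = rp.ControlIntronSet(flank, flank, [], 1.0, 1.0)
        reps = [
            RepeatCopy(GenomicInterval("chr1", iv.interval.start + 10,
                                       iv.interval.start + 100, "+"), "F", 5)
            for iv in flank[::2]
        ]
        df = te_enrichment(flank, ctrl, reps)
        assert df.iloc[0]["enrichment"] == 0.0

    def test_te_enrichment_bias_detected(self):
        rng = np.random.default_rng(6)
        flank = self._introns([0.4] * 200, [800] * 200)
        ctrl_introns = self._introns([0.4] * 200, [800] * 200, start=10**6)
        ctrl = rp.ControlIntronSet(flank, ctrl_introns, [], 1.0, 1.0)
        reps = []
        for iv in flank:
            for _ in range(rng.poisson(2.0)):
                s = iv.interval.start + int(rng.integers(0, 700))
                reps.append(RepeatCopy(GenomicInterval("chr1", s, s + 50, "+"),
                                       "F", 5))
        for iv in ctrl_introns:
            for _ in range(rng.poisson(1.0)):
                s = iv.interval.start + int(rng.integers(0, 700))
                reps.append(RepeatCopy(GenomicInterval("chr1", s, s + 50, "+"),
                                       "F", 5))
        df = te_enrichment(flank, ctrl, reps)
        row = df[df["family"] == "F"].iloc[0]
        assert row["enrichment"] > 0.5
        assert row["p_value"] < 0.01


def _rvc(a0, a1, b0, b1, gene="g"):
    return RVC(gene, GenomicInterval("chr1", a0, a1, "+"),
               GenomicInterval("chr1", b0, b1, "-"), a1 - a0, 0.9, "antisense")


def _rep(s, e, family="F", md=10):
    return RepeatCopy(GenomicInterval("chr1", s, e, "+"), family, md)


class TestDimers:
    def test_simple_pair_called(self):
        rvc = _rvc(100, 400, 1000, 1300)
        reps = [_rep(150, 350, "A"), _rep(1050, 1250, "B")]
        calls = call_dimers([rvc], reps)
        assert len(calls) == 1
        assert calls[0].key == ("A", "B")

    def test_half_overlap_threshold(self):
        rvc = _rvc(100, 400, 1000, 1300)
        # repeat of length 198 with only 98 bases inside segment a (49.5%)
        reps = [_rep(0, 198, "A"), _rep(1050, 1250, "B")]
        assert call_dimers([rvc], reps) == []

    def test_longest_overlap_wins(self):
        rvc = _rvc(100, 500, 1000, 1400)
        reps = [
            _rep(100, 300, "A"),    # overlap 200
            _rep(120, 340, "A2"),   # overlap 220
            _rep(1000, 1180, "B"),  # overlap 180
            _rep(1010, 1170, "B2"), # overlap 160
        ]
        calls = call_dimers([rvc], reps)
        assert calls[0].repeat_a.family == "A2"
        assert calls[0].repeat_b.family == "B"
        assert (calls[0].overlap_a, calls[0].overlap_b) == (220, 180)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(60):
            a0 = int(rng.integers(0, 500))
            rvc = _rvc(a0, a0 + 400, a0 + 2000, a0 + 2400)
            reps = []
            for i in range(int(rng.integers(1, 20))):
                s = int(rng.integers(0, 3000))
                ln = int(rng.integers(50, 400))
                reps.append(_rep(s, s + ln, f"F{i % 4}", int(rng.integers(0, 200))))
            calls = call_dimers([rvc], reps)
            # oracle: exhaustive enumeration of admissible ordered pairs
            best = None
            for ra, rb in (
                (x, y) for x in reps for y in reps if x is not y
            ):
                ova = ra.interval.overlap(rvc.segment_a)
                ovb = rb.interval.overlap(rvc.segment_b)
                if ova < 0.5 * len(ra.interval) or ovb < 0.5 * len(rb.interval):
                    continue
                key = (-(ova + ovb), (ra.milli_div + rb.milli_div) / 2,
                       ra.interval.start, rb.interval.start)
                if best is None or key < best[0]:
                    best = (key, ra, rb)
            if best is None:
                assert calls == []
            else:
                assert calls[0].repeat_a == best[1]
                assert calls[0].repeat_b == best[2]


class TestCocounts:
    def test_unique_participation(self):
        d = DimerCall("g", _rvc(0, 10, 20, 30), _rep(0, 10), _rep(20, 30), 10, 10)
        correct_cocounts([d])
        assert d.corrected_count == 1.0

    def test_formula(self):
        a = _rep(0, 100, "A")
        b1, b2, b3 = _rep(200, 300, "B"), _rep(400, 500, "B"), _rep(600, 700, "B")
        dimers = [
            DimerCall("g", _rvc(0, 100, 200, 300), a, b1, 100, 100),
            DimerCall("g", _rvc(0, 100, 400, 500), a, b2, 100, 100),
            DimerCall("g", _rvc(0, 100, 600, 700), a, b3, 100, 100),
        ]
        correct_cocounts(dimers)
        # repeat a participates in 3 dimers, each partner in 1: factor (3+1)/2
        for d in dimers:
            assert d.corrected_count == pytest.approx(0.5)
        # k unique partners: each dimer corrected by 2/(k+1)
        assert dimers[0].corrected_count == pytest.approx(2 / (3 + 1))

    def test_conservation_inequality(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            n_rep = int(rng.integers(2, 10))
            pool = [_rep(i * 100, i * 100 + 80, f"F{i%3}") for i in range(n_rep)]
            dimers = []
            for _ in range(int(rng.integers(1, 12))):
                i, j = rng.choice(n_rep, 2, replace=False)
                dimers.append(
                    DimerCall("g", _rvc(0, 10, 20, 30), pool[i], pool[j], 5, 5)
                )
            correct_cocounts(dimers)
            total = sum(d.corrected_count for d in dimers)
            assert total <= len(dimers) + 1e-12
            participations = {}
            for d in dimers:
                for r in (d.repeat_a, d.repeat_b):
                    key = (r.interval.start, r.family)
                    participations[key] = participations.get(key, 0) + 1
            if all(v == 1 for v in participations.values()):
                assert total == pytest.approx(len(dimers))


class TestRanking:
    def test_single_class_share_one(self):
        d = DimerCall("g", _rvc(0, 10, 20, 30), _rep(0, 10, "A"),
                      _rep(20, 30, "A"), 10, 10, mean_age=1.0)
        r = rank_dimers([d], [], 1, 1)
        assert r.top5_share == pytest.approx(1.0)

    def test_equal_groups_no_enrichment(self):
        mk = lambda g: DimerCall(g, _rvc(0, 10, 20, 30), _rep(0, 10, "A"),
                                 _rep(20, 30, "B"), 10, 10, mean_age=2.0)
        shared = [mk("g1"), mk("g2")]
        specific = [mk("g3"), mk("g4")]
        r = rank_dimers(shared, specific, 2, 2)
        assert r.table.iloc[0]["log2_enrichment"] == pytest.approx(0.0)


class TestConsensusDistance:
    def test_identical_zero(self):
        m = consensus_distance({"a": "ACGTACGTAA" * 10, "b": "ACGTACGTAA" * 10})
        assert m.loc["a", "b"] == pytest.approx(0.0)
        assert m.loc["a", "a"] == 0.0

    def test_ten_percent_mutation(self):
        rng = np.random.default_rng(13)
        seq = _random_seq(300, seed=14)
        mutated = list(seq)
        for i in rng.choice(300, 30, replace=False):
            mutated[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[i]]
        m = consensus_distance({"a": seq, "b": "".join(mutated)})
        assert m.loc["a", "b"] == pytest.approx(0.10, abs=0.02)
        assert m.loc["a", "b"] == m.loc["b", "a"]


def brute_force_cofold(seq_a, seq_b, min_loop=3):
    """Exhaustive maximum over all valid pairings (lengths <= 24 total)."""
    s = (seq_a + "NNN" + seq_b).upper().replace("U", "T")
    n = len(s)
    weights = {("G", "C"): 3, ("C", "G"): 3, ("A", "T"): 2, ("T", "A"): 2,
               ("G", "T"): 1, ("T", "G"): 1}

    def best(pairs_allowed):
        best_w = 0
        stack = [(0, frozenset(), 0)]
        # recursive enumeration over candidate pairs
        cand = [
            (i, j, weights[(s[i], s[j])])
            for i, j in combinations(range(n), 2)
            if j - i > min_loop and (s[i], s[j]) in weights
        ]

        def rec(idx, used, acc):
            nonlocal best_w
            best_w = max(best_w, acc)
            if idx >= len(cand):
                return
            rem = sum(w for i, j, w in cand[idx:])
            if acc + rem <= best_w:
                return
            i, j, w = cand[idx]
            # pairs must be non-crossing and disjoint
            ok = i not in used and j not in used and all(
                not (a < i < b < j or i < a < j < b)
                for a, b in pairs_allowed
            )
            if ok:
                pairs_allowed.append((i, j))
                rec(idx + 1, used | {i, j}, acc + w)
                pairs_allowed.pop()
            rec(idx + 1, used, acc)

        rec(0, frozenset(), 0)
        return best_w

    return -best([])


class TestCofold:
    def test_poly_a_no_pairs(self):
        assert cofold_mfe("AAAAAAAA", "AAAAAAAA") == 0.0

    def test_perfect_gc_duplex(self):
        a = "G" * 20
        assert cofold_mfe(a, "C" * 20) == -60.0

    def test_dp_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(15)
        for _ in range(25):
            la = int(rng.integers(2, 11))
            lb = int(rng.integers(2, 25 - la - 1))
            a = _random_seq(la, seed=int(rng.integers(1 << 30)))
            b = _random_seq(lb, seed=int(rng.integers(1 << 30)))
            assert cofold_mfe(a, b) == brute_force_cofold(a, b)


class TestPairingScore:
    def _mats(self, seed=0):
        rng = np.random.default_rng(seed)
        names = ["f1", "f2", "f3", "f4"]
        d = rng.uniform(0, 1, (4, 4))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        m = -rng.uniform(10, 200, (4, 4))
        m = (m + m.T) / 2
        return (pd.DataFrame(d, index=names, columns=names),
                pd.DataFrame(m, index=names, columns=names))

    def test_scores_bounded(self):
        d, m = self._mats()
        out = pairing_score(d, m)
        assert (out["score"].values >= 0).all()
        assert (out["score"].values <= 2).all()

    def test_affine_invariance(self):
        d, m = self._mats(1)
        base = pairing_score(d, m)["score"]
        shifted = pairing_score(d * 3 + 0.7, m * 0.2 - 5)["score"]
        assert np.allclose(base.values, shifted.values)

    def test_constant_matrix_error(self):
        d, m = self._mats(2)
        const = pd.DataFrame(0.5, index=d.index, columns=d.columns)
        with pytest.raises(ValueError, match="distance"):
            pairing_score(const, m)


class TestDegradation:
    def test_small_group_skips_energy_test(self):
        dimers = []
        for gi in range(4):
            gene = f"g{gi}"
            dimers.append(
                DimerCall(gene, _rvc(0, 60, 100, 160, gene),
                          _rep(0, 60, "A", 10 + gi), _rep(100, 160, "A", 20),
                          60, 60, mean_age=1.0)
            )
        groups = {"g0": "shared", "g1": "shared", "g2": "species-specific",
                  "g3": "species-specific"}
        genome = _random_seq(600, seed=16)
        out = degradation_analysis(dimers, groups, [("A", "A")], genome)
        assert out["p_mfe"] is None
        assert "fewer than 3" in out["notice"]
        assert out["p_millidiv"] is not None

    def test_planted_millidiv_contrast(self):
        rng = np.random.default_rng(17)
        dimers = []
        groups = {}
        for gi in range(100):
            gene = f"g{gi}"
            shared = gi < 50
            md = int(rng.normal(20 if shared else 80, 5))
            dimers.append(
                DimerCall(gene, _rvc(0, 60, 100, 160, gene),
                          _rep(0, 60, "A", md), _rep(100, 160, "A", md + 2),
                          60, 60, mean_age=1.0)
            )
            groups[gene] = "shared" if shared else "species-specific"
        out = degradation_analysis(dimers, groups, [("A", "A")])
        assert out["p_millidiv"] < 1e-6
        assert np.median(out["millidiv"]["shared"]) < np.median(
            out["millidiv"]["species-specific"]
        )


def test_dimer_pipeline_on_planted_truth(small_truth):
    """Planted young antisense TE pairs in shared parental genes surface as
    young, positively enriched top dimers."""
    from circevo import pipeline

    truth, tables, _ = small_truth
    out = pipeline.dimer_analysis(truth, tables)
    ranking = out["ranking"]
    assert len(out["dimers"]) > 0
    assert ranking.top5_mean_age <= ranking.background_mean_age


def test_dimer_table_and_track(tmp_path):
    d = DimerCall("g1", _rvc(100, 200, 300, 400), _rep(100, 180, "A", 12),
                  _rep(310, 390, "B", 30), 80, 80, mean_age=1.5)
    df = rp.dimer_table([d])
    assert list(df["family_a"]) == ["A"] and list(df["millidiv_b"]) == [30]
    path = tmp_path / "dimers.bed"
    rp.write_dimer_track([d], path)
    line = path.read_text().strip().split("\t")
    assert line[0] == "chr1" and "A+B" in line[3]
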