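# circevo

Circular RNAs (circRNAs) arise when the spliceosome joins a downstream
donor site back to an upstream acceptor ("backsplicing"), producing a
covalently closed transcript whose diagnostic feature is the backsplice
junction (BSJ). Because circRNAs resist the 3'→5' exoribonuclease RNase R
while linear RNA is degraded, sequencing a sample before and after RNase R
treatment separates genuine circRNAs from linear artefacts that merely
resemble BSJs. `circevo` implements a complete analysis chain from such
paired-end libraries to comparative, cross-species conclusions:

1. **Detection** — unmapped, quality-filtered reads are split into 20-bp
   terminal anchors, placed on the genome, and kept when both anchors fall
   on the same chromosome and strand within 100 kb in backsplice order;
   anchor pairs are extended to the full read length (max. two
   mismatches), breakpoints trimmed to splice motifs (donors GT/GC/AT/CT,
   acceptors AG/AC), mate placements checked against the circle span, and
   short-overlap reads (≥ 8 bp on each side) rescued against a junction
   index.
2. **Filter cascade** — four ordered steps: paired/singleton mapping-mode
   consistency between conditions, presence in untreated samples,
   size-factor-normalized log2(treated/untreated) enrichment ≥ 1.5, and
   ≥ 0.05 counts per million (CPM) in at least one tissue, plus an optional
   blacklist of repetitive regions.
3. **Isoform reconstruction** — junctions inside the circle whose
   normalized RNase R log2 change falls outside the central 90% interval of
   the outside-junction background become edges of a weighted acyclic
   splicing graph; the path with the highest mean coverage is the
   reconstructed isoform.
4. **Evolution** — circRNAs are collapsed to per-gene loci, lifted between
   species through chain files (minMatch 0.5), connected at three sharing
   levels (orthologous gene / shared exon / shared start+stop exons),
   clustered with the Markov Cluster algorithm (inflation 2.0) and labelled
   by clade (species-specific, rodent, primate, eutherian, therian);
   hotspot genes (≥ 2 distinct overlapping circRNAs) and highly expressed
   circRNAs (above the per-tissue 90% quantile) are called.
5. **Gene models** — exon classes, conservation medians, GC amplitude
   (last 250 intronic vs. first 50 exonic bases), isochore classes
   (L1 < 37% … H3 > 52% GC), the tau tissue-specificity index, and binomial
   GLMs with cross-validated best-subset selection predicting parental-gene
   and hotspot status.
6. **TE dimers** — reverse-complement regions (RVCs) found by seeded
   ungapped self-alignment (word size 12), repeat dimers called at ≥ 50%
   repeat overlap with co-counting correction, dimer classes ranked by
   corrected frequency and shared-vs-specific enrichment, and degradation
   (milliDiv) and co-fold binding-energy contrasts computed.

Everything is exercised end-to-end on synthetic multi-species data with a
complete planted truth: the first-class `circevo.synth` module generates
five toy mammalian genomes (opossum, mouse, rat, macaque, human) with 1:1
orthologous genes of controlled GC isochore structure, intronic TE
insertions of known family/age/milliDiv, planted multi-exon circRNAs with
per-tissue expression and a clade-sharing plan, chain files, conservation
tracks, and paired-end 100-nt libraries in which RNase R depletes linear
transcripts by a configurable retention factor.

## Worked example

```python
from circevo import pipeline

study = pipeline.run_study(seed=7)

for sp, m in study.detection.items():
    print(sp, f"recall={m['recall']:.2f} precision={m['precision']:.2f}")
print("loci:", len(study.loci))
print("clades:", {g.clade_label for g in study.groups})
r = study.dimer["ranking"]
print(f"top-5 dimer share={r.top5_share:.2f} "
      f"mean age={r.top5_mean_age:.1f} background={r.background_mean_age:.1f}")
```

prints (seed 7, about half a minute on one core):

```
opossum recall=1.00 precision=1.00
mouse recall=1.00 precision=1.00
rat recall=1.00 precision=1.00
macaque recall=1.00 precision=1.00
human recall=1.00 precision=1.00
loci: 134
clades: {'species-specific', 'rodent', 'primate', 'eutherian', 'therian'}
top-5 dimer share=0.83 mean age=2.0 background=2.5
```

All 200 planted backsplice junctions are recovered at exact breakpoint
coordinates with no false positives; the 134 per-gene circRNA loci cluster
into orthology groups covering every clade label; and the dominant dimer
classes are young (age rank 1–2 on the 1–4 scale) and concentrated in
shared loci — the planted evolutionary signal.

A file-based dataset (FASTA/GTF/FASTQ/chain/bedGraph/repeat tables plus a
truth table) can be emitted with the CLI:

```sh
circevo synth --seed 7 --outdir data/
circevo study --seed 7 --outdir results/
```

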