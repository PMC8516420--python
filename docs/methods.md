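# Methods

This note documents the models and procedures implemented in `circevo`,
the defaults they use, what the synthetic data does and does not emulate,
and the numerical choices made where the design was genuinely open.

## Coordinates and formats

All coordinates are 0-based half-open internally (BED-style arithmetic);
GTF is converted to/from 1-based inclusive at the I/O boundary and the
conversion is involutive. Strand `.` is allowed for strand-agnostic
interval work; backsplice candidates, repeats and RVC segments carry
explicit strands. Chain files follow the UCSC format; the generator emits
block-identical chains (one aligned block per orthologous gene span), and
lifting fails explicitly for intervals touching inverted blocks.

## Synthetic data generator

The generator is the package's study design, not a test fixture. Defaults
(chosen once, as what a small-scale but structurally faithful mammalian
comparison looks like):

- **Species**: opossum (marsupial), mouse and rat (rodents), macaque and
  human (primates); one chromosome each, 60 one-to-one orthologous genes,
  genome budget 400 kb.
- **Gene structure**: 4–7 exons of 120–180 bp, introns of 400–700 bp,
  intergenic spacers of 300–600 bp; canonical GT/AG splice motifs are
  written at every intron edge in gene orientation. Orthologs share their
  exon/intron layout exactly (an ancestral structure reused per species);
  sequences are drawn independently per species, so cross-species
  relationships are carried by chain files rather than sequence homology.
  Terminal exons are flagged UTR, mirroring typical annotation.
- **Isochores**: each gene family draws a GC class from the configured mix
  (default L1/L2/H1/H2/H3 = 0.3/0.3/0.2/0.1/0.1) and a target GC inside
  that class with a safety margin to the 37/42/47/52% boundaries so the
  realized per-gene GC classifies back to the planted class despite
  binomial noise on ~3 kb of sequence.
- **circRNA plan**: 200 planted circRNAs across the five species —
  ortholog families shared by all five species, by the four non-marsupials,
  by both rodents, by both primates, single-species families, and two
  "partial" designs (same gene with disjoint exon chains; overlapping
  chains with different boundaries) that separate the three sharing
  levels. Chains are contiguous internal exon runs, leaving flanking
  introns intact. Additional overlapping second circRNAs are planted in
  already-parental genes (marking hotspots) until the 200 target is
  reached. Parental-family choice is biased 4:1 toward low-GC (L1/L2)
  families — the circRNA niche the gene-feature models should detect.
- **Expression**: each circRNA is expressed in 1–3 of the three tissues
  (liver, cerebellum, testis) with a planted junction coverage uniform in
  20–40×; linear per-gene, per-tissue weights are gamma(2) distributed.
- **TE landscape**: four families spanning the age spectrum (age rank 1 =
  species-specific … 4 = therian) with per-copy substitution probability
  `rate x age_rank`, so realized milliDiv (per-mille mismatches to the
  consensus, recomputed exactly from the emitted copy) increases with age.
  Introns flanking circRNAs of widely shared parental genes preferentially
  receive a reverse-oriented pair of the youngest family (probability
  0.9); species-specific parental genes receive pairs of the oldest family
  (0.7); background copies land by insertion weight (0.25 per intron).
  Insertions overwrite intron interiors in place, keeping all coordinates
  stable.
- **Libraries**: paired-end 100-nt reads, fragment length N(250, 30)
  clipped to [read length, transcript length], Poisson fragment counts,
  expected 12 000 pairs per library, one replicate per tissue and
  condition. In the treated condition linear means are multiplied by the
  RNase R linear retention (default 0.05) and all means rescaled to the
  same expected depth — raw backsplice counts therefore rise in treated
  libraries, as in a real experiment sequenced to fixed depth. Reads are
  error-free (realistic error models are out of scope); 5% of first mates
  receive quality strings with bases below phred 25 so the anchor quality
  filter is exercised.
- **Conservation**: one bedGraph row per exon, base score 0.4 ± 0.02 noise,
  planted circRNA exons shifted by +0.3, clipped to [0, 1].

What the generator does *not* emulate — and hence what passing tests do
not show about real data: sequencing errors and indels, multi-transcript
genes and unannotated exons, paralogy and incomplete ortholog maps,
chimeric or inter-chromosomal junctions, GC-content differences between
exons and introns, and genuinely repetitive genomes in which anchor
multi-mapping would be the dominant failure mode.

## Detection

The internal aligner places reads along annotated transcripts (seed-and-
verify with 20-mers, two seed offsets, both read orientations, max. two
mismatches, unique best placement); it is ungapped within exons and
splice-aware only across annotated junctions, which is sufficient for the
synthetic genomes. External alignments can be substituted by constructing
`AlignedLibrary` objects.

Backsplice detection keeps anchor pairs on one chromosome and strand
within 100 kb (applied to anchor placements, before extension) whose 3'
anchor lies upstream of the 5' anchor, and extends them to the full read
length. The ambiguity range for the breakpoint is the *minimal-mismatch*
split set: sequence repeats at the breakpoint slide the split without
adding mismatches, whereas a fixed mismatch budget would make every
neighbouring split "valid" and systematically shift breakpoints. Among
ambiguous splits, the best motif score wins, then the leftmost split on
the forward strand. Because an unstranded paired-end protocol cannot
orient a junction read, the candidate strand is taken from the motifs: an
interpretation reading canonical GT/AG scores above any other allowed
combination, and ties go to the plus strand. Candidates with no
motif-consistent breakpoint are treated as having no clear breakpoint and
dropped. Multi-mapping anchors are discarded entirely (configurable
nowhere on purpose: on repeat-rich real genomes this is the conservative
choice).

Mate checking keeps junction support whose singleton mates map inside the
circle span, retains reads with unmapped mates (no evidence against), and
removes candidates whose supporting pairs define a second backsplice. The
rescue step rebuilds support by matching all reads against
breakpoint-spanning references (≥ 8 bases on each side); references that
are indistinguishable at the mismatch tolerance — breakpoint slippage
artefacts — are merged into the stronger-supported candidate first, so a
weak shifted twin cannot eliminate the true junction via the
"founder matches another backsplice" rule.

## Filter cascade

Steps run strictly in order and the report telescopes. A junction's pe/se
mode in a sample is "pe" when any supporting pair's non-junction mate
mapped; step 1 removes junctions whose untreated/treated samples of a
biological replicate disagree. Step 2 requires ≥ 1 read in ≥ 1 untreated
replicate. Step 3 normalizes by median-of-ratios size factors computed on
the combined linear + backsplice junction matrix (common junctions are
dominated by linear splice junctions, so the factors track linear
depletion in treated libraries), pools a species' samples within each
condition, and keeps log2(treated/untreated) ≥ 1.5. Step 4 computes
per-tissue CPM as replicate-averaged counts over replicate-averaged mapped
totals — generalized to any replicate count rather than a hard-coded
three — and keeps junctions reaching 0.05 CPM (inclusive) in ≥ 1 tissue.
Blacklisting removes junctions overlapping a same-species region by any
amount; the curated repetitive testis regions ship as a fixture table.
No pseudocounts are used anywhere; impossible ratios are structural errors.

Size factors carry an arbitrary common scale; the meaningful invariant —
scaling one sample's counts by a constant scales its factor *relative to
every other sample* by exactly that constant, leaving all enrichment
decisions unchanged — is exact and tested at 1e-9.

## Isoform reconstruction

Per-junction log2 changes use size-factor-normalized means; junctions with
zero treated coverage are "not enriched" (never assigned), junctions with
zero untreated baseline are uninformative and skipped. The background is
the empirical central 90% interval (5th/95th percentiles, linear
interpolation on order statistics) of outside-backsplice junction changes;
when a gene has fewer than 20 outside junctions the background falls back
to the genome-wide pool of junctions outside every detected circle span
(per-chromosome pooling collapses to genome-wide on single-chromosome
genomes). Splicing graphs take their nodes from annotation restricted to
the circle span, in genomic order — path scores are orientation-invariant,
so minus-strand genes need no special casing — with edges weighted by
treated-condition normalized coverage. All source-to-sink paths are
enumerated breadth-first (the graphs are small); the maximal mean-weight
path wins, ties broken toward more exons, then lexicographically smaller
coordinates. With no path, the backsplice boundary exons alone are
returned.

## Cross-species analysis

Loci are per-gene exon unions (bedtools-merge semantics, book-ended
intervals merge). Lifting requires ≥ 50% of an exon's bases inside chain
blocks; a "shared exon" additionally requires reciprocal lift success and
any positional overlap, independent of exon length. Level 1 = 1:1
orthologous parental genes; level 2 = level 1 plus ≥ 1 shared exon (the
default for clade grouping); level 3 = level 2 plus a circRNA pair whose
lifted start and stop exons are the start/stop exons of a circRNA in the
partner species. Levels nest by construction.

The Markov Cluster implementation adds self-loops, column-normalizes,
and alternates expansion (matrix square) with inflation (elementwise power
2.0, renormalize) until the matrix changes by < 1e-8 or 100 iterations
(non-convergence returns the current state with a warning). Clusters are
read off attractors (positive diagonal mass); clusters sharing any node
merge, singleton attractors are allowed, and unassigned nodes become
singletons, so the output is always a partition.

Clade labels: therian = marsupial plus ≥ 3 of the four non-marsupials;
eutherian = ≥ 3 of the four (including all four without the marsupial);
rodent/primate = both species of the lineage; otherwise species-specific.
Hotspots are genes with ≥ 2 distinct, overlapping circRNAs passing the CPM
threshold; tables report the hotspot fraction of loci, the fraction of
circRNAs from hotspots, the mean circRNAs per hotspot and per-tissue
top-1/top-2 expression shares. The high-expression split labels circRNAs
above the per-tissue 90% CPM quantile (among expressed circRNAs) and
unions the per-tissue sets.

## Gene features and GLMs

Isochore boundaries are half-open with the boundary in the upper class
(37.0% is L2, 47.0% is H2). Tissue specificity uses the Yanai index
τ = Σ(1 − x_i/max x)/(n − 1). GC amplitude is log2 of the GC of the first
50 exonic bases over the last 250 intronic bases at each splice site
(windows truncated at feature ends, skipped below 10 bases or when either
window is GC-free), with sites classified as flanking/inside/outside
relative to the gene's circRNA spans. Conservation medians are per-gene,
per-class medians of per-exon mean scores; UTR exons are excluded and
uncovered exons skipped, not zero-filled. Exon-bin tissue frequency uses
FPKM = counts·1e9/(length·depth) on bins ≥ 10 nt with a threshold of 1.

The binomial GLM standardizes predictors to zero mean and unit variance
(so coefficients are standardized log-odds), screens multicollinearity by
variance inflation (threshold 5, report only), and selects the predictor
subset minimizing repeated-random-split cross-validated log-loss on the
80% training fraction. All subsets are scored on the *same* splits so
model comparisons are paired and split noise cancels; the inner fits use a
plain Newton/IRLS solver for speed. Selection is exhaustive up to 10
predictors, greedy forward beyond. The default is 100 random splits; a
lower number is adequate (and used in the validation suite) because paired
comparisons converge quickly. Headline coefficients and p-values come from
a maximum-likelihood fit of the selected model on the full standardized
data; a validation-only refit's coefficients are reported alongside, and
accuracy/sensitivity/specificity are computed on the held-out 20% from a
training-only fit at a probability cut-off of 0.5 (the cut-off is an
assumption; nothing in the pipeline depends on it elsewhere). Separation
is detected (failed or diverging ML fits) and flagged, with ridge-backed
coefficients reported as a fallback. The clade-sharing model is a logistic
fit of hotspot status on clade category with species-specific as the
reference; single-category designs raise a degenerate-design error.

## Repeats and dimers

RVC detection seeds exact 12-mers between the gene sequence (first to last
exon) and itself (sense, self-diagonal excluded) or its reverse complement
(antisense), extends ungapped with +1/−2 match/mismatch scoring and an
X-drop of 12, and reports alignments of length ≥ 50 with identity ≥ 0.8;
symmetric duplicates are canonicalized away and the self-complementarity
fraction is the merged alignment length over the gene length. Dimer
calling restricts to purely intronic RVCs, admits repeats with ≥ 50% of
their own length inside a segment, and picks the pair with the largest
total overlap (ties: lower mean milliDiv, then leftmost). Co-counting
correction divides each dimer by the mean participation count of its two
repeat copies, so corrected totals never exceed raw counts. Dimer classes
are unordered family pairs; enrichment compares mean per-gene corrected
frequency in shared vs. species-specific loci, and the top-5 set is the
most frequent positively enriched classes.

Consensus distances are 1 − identity from global pairwise alignment.
The internal co-fold backend is a Nussinov-style dynamic program on the
concatenation with a non-pairing linker (weights GC 3, AU 2, GU 1, minimum
loop 3); its energy is minus the optimal pair weight — a monotone proxy
for duplex stability, not a thermodynamic free energy — and an external
folding backend with the same call contract can be plugged in for real
data. Pairing scores min-max-standardize the distance and energy matrices
separately (raw energies mapped directly, so stronger pairing maps lower;
the direction is configurable by pre-negating the matrix), sum them into
[0, 2], and classify families by PCA of centered, unscaled score rows.
Degradation analysis compares milliDiv of top-5-dimer copies between gene
groups by rank-sum test and co-folds the least-degraded dimer per gene,
comparing energies by t-test only when both groups have ≥ 3 observations.

Control introns are matched on a GC × length grid (GC bins of 0.01,
length bins of 1000) spanning the flanking set's 5–95% quantiles;
out-of-grid flanking introns are excluded and reported, under-filled bins
borrow from the nearest non-empty candidate bin (Euclidean bin distance,
with a warning), and matching quality is summarized by two-sample KS
p-values on GC and length (the KS test replaces a non-standard test name
in the original description of this step). TE enrichment pairs introns
positionally and uses the Wilcoxon signed-rank test per family.

## Problem sizes

The validation suite and the acceptance script run the default study
(5 species × 60 genes × ~400 kb, 30 libraries of ~12 000 read pairs, 200
planted circRNAs at 20–40× junction coverage) end to end, 1000 random DAGs
against exhaustive path enumeration, 100 random disjoint-component graphs
for MCL, a 120-gene five-species layout for the orthology-level checks, 50
simulation seeds for GLM parameter recovery at n = 5000, and 20 seeds each
for the evolutionary dimer signal and control-intron matching. These sizes
were chosen so the whole suite completes in minutes on a single core while
every stage is still exercised against an independent oracle or the
planted truth.

## Known limitations

- The aligner assumes annotated, single-isoform transcripts and error-free
  reads beyond quality strings; it is not a general-purpose spliced
  aligner.
- Strand assignment of a backsplice relies on splice motifs; a junction
  whose true motifs are non-canonical on both strands is reported on the
  motif-preferred strand.
- The enrichment filter assumes size factors track linear depletion, which
  requires linear junctions to dominate the common-junction set.
- The co-fold energy is a weighted pair count, adequate for ranking and
  contrasts, not for absolute thermodynamics.
- MCL cluster recovery is guaranteed only for well-separated (dense,
  disjoint) components; sparse chain-like components can legitimately
  split at inflation 2.0.
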