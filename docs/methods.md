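# Methods

`numtkit` re-implements, as a tested and reusable pipeline, the analysis
used in cohort studies of NUMTs (nuclear mitochondrial DNA segments) in
mammalian genomes: alignment-based NUMT calling, matched random-interval
background sampling, sequence-descriptor extraction, random-forest
classification, flanking repeat-density profiling against a random null,
and genome-level descriptive statistics. Because real cohort inputs are
hundreds of gigabases of assemblies, the package ships a first-class
synthetic-data generator whose defaults emulate the published study
conditions, so every stage is exercised end to end at desk scale.

## Synthetic cohort generator

**Genome backgrounds.** The mitochondrial genome (default 16,500 bp,
circular) and nuclear chromosomes (default 3 × 500 kb) are sampled from
order-2 Markov chains. The conditional distribution of the next base is a
product of base weights (calibrated so the chain's stationary GC equals
the configured target: 0.38 for mtDNA, 0.42 for nuclear, both matching
typical mammalian values), a dinucleotide modifier, and a homopolymer-run
damping factor (0.7 when the previous two bases equal the candidate).
Calibration bisects the GC weight against the stationary distribution of
the 16-state context chain; observed GC is within ±0.01 of target at the
default lengths.

The nuclear chain carries CpG depletion (C→G transition weight × 0.25);
the mitochondrial chain does not. Mammalian nuclear DNA is strongly
CpG-depleted while mtDNA is not, and this contrast — together with the GC
offset — is the compositional signature that makes NUMT sequences
distinguishable from nuclear background. It is the generator's stand-in
for the real mtDNA/nuclear compositional divide (different codon usage,
strand-asymmetric replication, etc.) that the generator does not model
explicitly.

**NUMT lengths.** Published cohort statistics constrain only three order
statistics of the NUMT length distribution (quartiles 121/632 bp, median
248 bp). No standard two-parameter family matches all three, so lengths
are drawn from a quantile function that interpolates log(length) linearly
in probability between the anchors {0.25: 121, 0.5: 248, 0.75: 632},
extrapolates the tails with the adjacent segment's slope, and clips to
[50 bp, mt length]. Samples of 10,000 reproduce the anchors within a few
percent.

**Planting.** Each NUMT is a contiguous slice of the circular mtDNA (wrap
across the origin allowed), reverse-complemented with probability 0.5,
mutated by per-bp substitutions (default 0.05) and per-bp indel events
(default 0.005, geometric lengths with mean 2, insertion/deletion equally
likely), and spliced into a uniformly random position at least 300 bp from
a chromosome end. Divergence defaults keep detection non-trivial but
reliable — 5% substitution divergence is comfortably inside the seed
aligner's sensitivity range while producing realistic mismatch structure.
Optional extras: one full-length megaNUMT and one tandem double (two
concatenated mtDNA copies). Ground truth (final coordinates, strand, mt
interval, realized mutation counts) is emitted as BED6+.

**Repeat annotations.** Each configured family is placed as an
inhomogeneous Poisson process of starts at `density_per_kb` (default
0.5/kb), with exponential lengths (mean 100 bp). Around planted NUMTs the
intensity is multiplied per the family's behaviour: `enriched_upstream`
(×5 in the 200 bp upstream window), `depleted_near` (×0.2 within ±200 bp),
or `uniform`. These are the three qualitative flank behaviours reported
for repeat families around mammalian NUMTs. Output uses the RepeatMasker
`.out` dialect so real annotations are drop-in replacements.

All generator outputs are pure functions of (config, seed); seeds for the
four stages are spawned from the config seed via `numpy.random.SeedSequence`.

## NUMT detection

Calling is local alignment of the mtDNA query against each chromosome,
replacing an external aligner with a self-contained seed-and-extend
implementation:

1. **Seeding.** Exact 11-mer matches, found via a sorted integer-code
   index over the mtDNA. The query is doubled so seeds and extensions can
   cross the circular origin; windows containing N are skipped. The minus
   strand uses the reverse-complemented doubled query.
2. **Extension.** Banded affine-gap x-drop DP (band half-width 64 around
   the seed diagonal, x-drop 20) in both directions from each seed, with
   scores +1 match, −1 mismatch, gap open −7, gap extend −1 (a gap of
   length ℓ costs 7 + ℓ). N never matches. Seeds falling inside an
   already-accepted HSP's box (same diagonal neighbourhood, either
   representation of the doubled circular coordinate) are skipped.
3. **Filtering.** An HSP is reported when its e-value
   E = K·m·n·e^(−λS) is at most the threshold (default 10⁻³), with m the
   mt length and n the chromosome length. λ is the unique positive root
   of Σᵢⱼ pᵢpⱼ·exp(λ·sᵢⱼ) = 1 for the mt base composition (ln 3 ≈ 1.0986
   for ±1 scoring at uniform composition). K is calibrated once per
   scoring system by a deterministic Monte-Carlo scan: maximal ungapped
   segment counts above a score ladder on random same-composition pairs,
   inverted through the e-value formula (K ≈ 0.27 for ±1 uniform). As is
   standard practice, the ungapped parameters approximate the gapped
   statistics. Merging of nearby same-strand HSPs is available
   (`merge_gap`), off by default so each HSP is reported.

Calls carry 0-based half-open nuclear intervals, strand, mt interval
modulo the mt length (`mt_start > mt_end` marks an origin-wrapping
segment), score, e-value, and identity (1 − edit distance / span of the
reported interval pair, computed with edlib; the x-drop DP performs no
traceback). On the default cohort, recall of planted NUMTs ≥ 100 bp at
≥ 50% reciprocal overlap is 100%, and NUMT-free chromosomes yield zero
chance calls in ≥ 95% of runs.

An exhaustive affine-gap Smith-Waterman (score and intervals via origin
tracking, ≤ 10⁷ DP cells) serves as the test oracle: the seeded caller's
score never exceeds the oracle optimum, and the oracle itself is
cross-checked against an independent reference aligner in the suite.

## Matched negative sampling

For every chromosome, one uniformly random locus per NUMT, with length
equal to that NUMT's length, giving a balanced background class whose
sorted length multiset equals the NUMT multiset exactly. By default,
draws overlapping any NUMT are rejected and redrawn (bounded retries) to
prevent label leakage, as are draws with > 50% N; a no-constraint mode
reproduces the plain protocol.

## Sequence descriptors

All descriptors are computed from first principles on {A,C,G,T}; windows
containing N are excluded from counts and normalizers. Defaults produce
287 features per sequence:

- **NAC** (4): mononucleotide frequencies.
- **Kmer type 1 / type 2** (64 + 64, k = 3): window frequencies / raw
  counts in lexicographic order. The type 1 = normalized, type 2 = raw
  convention is this package's reading of the descriptor-tool naming.
- **RCKmer type 1 / type 2** (32 + 32): counts pooled with the reverse
  complement under the lexicographically smaller canonical key.
- **NMBroto** (18 = 6 properties × 3 lags): the L−1 dinucleotides are
  mapped to standardized property values p₁..p_{L−1} and the lag-d value
  is Σ pᵢ·pᵢ₊d / (#terms). Properties are the six B-DNA step parameters
  (twist, tilt, roll, shift, slide, rise) from protein-DNA crystal
  structure averages, standardized to mean 0 / sd 1 over the 16
  dinucleotides.
- **Z-curve** (9): per codon phase, x = (a+g)−(c+t), y = (a+c)−(g+t),
  z = (a+t)−(g+c); a 3-component global variant is available. The
  phase-specific variant is the default because it subsumes the global
  one.
- **Mismatch profile** (64, k = 3, m = 1): per k-mer, the fraction of
  windows within Hamming distance m.

Every descriptor is verified against an independent brute-force
recomputation to 10⁻¹² in the test suite.

## Classification

A random forest separates NUMT sequences from matched negatives (and,
optionally, the pooled flanks of each). Protocol: stratified 80/20
train/test split; stratified 10-fold cross-validated AUROC on the
training portion; final fit on the training portion scored on the
hold-out at the 0.5 vote threshold (accuracy, per-class confusion counts
and recalls); impurity importances summed per descriptor family (families
never used by a split report exactly 0). Random-search tuning over
n_trees ∈ [3, 200], depth ∈ [2, 12], per-split feature count ∈ [5, all]
is available and records the full trace; the pipeline default skips the
search and uses the known best point (7 trees, depth 3, 50 features per
split — read as `max_features`, the per-split subsampling parameter, not
a feature-selection step). On the default cohort this configuration
reaches mean 10-fold CV AUROC ≈ 0.96 and hold-out accuracy ≈ 0.87;
label-permuted data stays within 0.5 ± 0.08.

## Flank analysis

For each repeat family, occupancy is profiled on a common axis around
each locus: 200 upstream 1-bp bins, the locus interior rescaled to 100
bins, 200 downstream 1-bp bins. Per-bin frequency is the fraction of loci
with at least one overlapping repeat of the family. Positional enrichment
is tested by a two-sample Kolmogorov-Smirnov test on repeat-midpoint
offsets (same axis) around NUMTs vs around the matched random loci —
the matched negatives are the natural null, and the KS test is the
stated positional test; p < 0.05 is called significant. Families with
fewer than 8 offsets on either side are reported untestable (NaN) rather
than aborting.

Calibration: under a uniformly planted family with loci sparse enough
that flank windows rarely overlap, the type-I error at α = 0.05 is
0.02–0.08 over 200 replicates, and ×5 upstream enrichment at 600 loci is
detected with p ≪ 0.05. When loci are dense (windows share repeats),
pooled offsets are positively dependent and the test becomes
anticonservative — a known limitation of pooling offsets across loci.

## Descriptive statistics

GC content is (G+C)/(A+C+G+T) over non-N bases. Relative GC pairs each
NUMT's GC against the whole-genome GC and its mitochondrial counterpart's
GC against the whole-mtDNA GC (counterparts of undiverged planted NUMTs
centre on 1.0). Cohort correlations (genome size and GC vs NUMT count and
cumulative length) are tie-corrected Spearman. Size statistics report
median/quartiles of absolute and mtDNA-relative lengths. The involvement
matrix counts, wrap-aware and with multiplicity, how many NUMTs cover
each mtDNA position per species; cross-species matrices rescale to 1,000
common bins by per-bin mean (no cross-species alignment is attempted).
megaNUMT flags use explicit span thresholds: ≥ 0.99 × mt length =
full-molecule, ≥ 1.95 × = tandem double.

## Determinism and problem sizes

One global seed drives everything: generator stage seeds are spawned via
`SeedSequence`, and downstream stages (negative sampling, CV splits,
forest fits) use stage-specific integers derived by hashing
`"{seed}:{stage}"`. `run-all` reruns are bitwise identical, manifest
checksums included.

Tests run on scaled-down cohorts (60–160 kb chromosomes) except the
classification acceptance path, which uses the full default cohort
(3 × 500 kb, ~600 NUMTs); the whole suite completes in about two minutes
on one CPU.

## Known limitations

- The generator's chains model composition, not biology: no genes, no
  phylogenetic structure across cohort genomes, no chromosome-scale
  rearrangements, no assembly gaps. Passing tests demonstrate the
  pipeline's correctness on compositionally realistic data, not
  classifier performance on real genomes.
- Gapped alignment statistics reuse ungapped (λ, K); e-values are
  approximate (slightly conservative for gapped scores).
- Banded extension (half-width 64) can clip alignments whose cumulative
  indel drift exceeds the band — negligible at default indel rates.
- The KS positional test treats pooled offsets as independent; see the
  density caveat above.
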