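# Methods

## Model and procedure

`senescan` treats target inference as a deterministic chain over four
objects: a differential-expression (DE) table (gene × tissue × comparison,
log2 fold change and p-value), a genome with gene models (contig, strand,
TSS), a motif file (transcription factor gene → IUPAC consensus), and
optional category/signature annotations.

**DE filter.** A gene is differentially expressed in a tissue/comparison when
p ≤ `p_cutoff` (default 0.05; raw p by default, the adjusted column under a
flag) and |log2FC| ≥ `lfc_cutoff` (default 0.4 log2 units). Both boundaries
are inclusive — the conventional reading of a "cut-off at 0.4" — and the
choice is pinned by tests. A log2FC of exactly 0 belongs to neither
direction and counts as inconsistent with any expected direction.

**Promoters.** The window is `promoter_window` bases (default 1000)
immediately upstream of the TSS, excluding the TSS base itself: plus strand
[t − w, t), minus strand [t + 1, t + 1 + w) reverse-complemented, all
coordinates 0-based half-open. Minus-strand promoters are emitted in gene
orientation so the scanner treats all promoters uniformly; strand bookkeeping
then lives entirely in the scanner's both-strand mode. Promoters truncated at
contig edges are retained with their shorter effective length (dropping them
silently would bias backgrounds; an exclusion option exists on the background
computation). Soft-masked bases are upper-cased; hard-masked `N` runs are
kept and can never match.

**Scanner.** Each IUPAC symbol expands to its allowed base set; a hit at
offset *i* requires every position to match. Only literal A/C/G/T in the
*sequence* can match — ambiguity codes in assembled genomes are masking, not
information. Overlapping hits all count (the search is position-complete).
Minus-strand hits are plus-strand hits of the reverse-complemented pattern.
The implementation compiles the pattern to a regular expression of character
classes inside a zero-width lookahead; its contract is exact agreement with a
naive per-offset oracle, which the tests check on hundreds of random
sequence/pattern pairs. A self-reverse-complementary (palindromic) pattern
such as `TGASTCA` therefore counts each site once per strand; per-strand
counts are always retained so either single- or double-counting convention
can be reported.

**Enrichment band.** For each motif, the per-promoter counts over *all*
annotated genes (including the DE genes themselves — they are genes of the
genome; an exclusion flag exists) give mean μ and sample SD σ (n − 1
denominator, n ≥ 2 required). A count is `enriched` iff strictly > μ +
`sd_multiplier`·σ and `depleted` iff strictly < μ − `sd_multiplier`·σ
(default multiplier 1). "Higher or lower than" reads as strict, so counts on
a threshold are typical. The band is applied to raw counts; a per-kilobase
normalization flag is deliberately absent from the default path because
promoters are fixed-width by construction. No multiple-testing correction is
applied: the criterion is a dispersion band, not a test, and the reports say
so.

**TF–target concordance.** For every non-typical call, an assignment is
emitted per (tissue, comparison) in which *both* the TF gene and the target
gene pass the DE filter; it is concordant when their log2FC signs agree.
Direction is never inferred across tissues — the same TF can move in
opposite directions in different organs. The default report keeps
concordant, enriched assignments only; depleted candidates (kept as a
separate class) and discordant assignments are available under flags. A TF
is never reported as its own target.

## Synthetic data

The generator is the package's study-condition bed, not a tuning knob.

*Genomes*: i.i.d. bases at a configurable GC content (default 0.42, a
mammalian-like value), genes in non-overlapping slots so every promoter is
extractable at full length, strands uniform. Motif copies are implanted per
promoter with Poisson(λ_bg) counts (λ_target for designated targets) at
uniform non-overlapping offsets — sampled directly by the sorted-slack
construction, which is uniform over non-overlapping configurations — each on
a uniform strand, degenerate positions resolved uniformly. A truth table
records every implant. Implants never overlap each other; overlaps with
chance background matches are possible and are handled in tests by an oracle
pre-scan of the background.

*Expression*: log2-scale group values Normal(8.0, `noise_sd`) with
±`effect_size` added to the second group for planted genes; log2FC is the
difference of group means and p comes from the equal-variance two-sample
t-test. Defaults — three animals per group, noise SD 0.3 log2 units, effect
1.0 — mirror a small-cohort expression-array design: three biological
replicates per age group, effects comfortably above the 0.4 log2FC cut-off,
per-group SDs of a few tenths of a log2 unit. `noise_sd = 0` degenerates to
exact effects with p ∈ {0, 1}, which makes filter exactness testable.

What the generator does *not* emulate: probe-level microarray noise,
correlated genes, repeat structure, CpG islands, alternative TSSs. Passing
tests therefore demonstrate the correctness and calibration of the inference
chain under its own assumptions, not performance on real tissue data, where
motif occurrence is not Poisson and expression noise is not i.i.d. Gaussian.

## Validation oracles and problem sizes

* **Scanner**: exact agreement (counts and positions) with a naive
  per-offset oracle on 250–300 random pairs (sequences ≤ 500 bp, patterns ≤
  10 IUPAC symbols), plus property tests: both-strand counts invariant under
  reverse-complementing the sequence; palindromic patterns hit both strands
  equally; relaxing a position to `N` is monotone.
* **Promoters**: reverse-complement duality on 50 random genomes against
  direct string manipulation, including truncation lengths at contig edges.
* **Enrichment**: 20 replicates of 2000 promoters (4 contigs, 1000-bp
  windows), background Poisson(1), 100 targets Poisson(5), μ ± 1σ calling.
  The replicate-averaged enriched-call sensitivity and background false-call
  rate must each lie within 5 percentage points of the exact Poisson tails
  P(X > hi) and P(X > hi) + P(X < lo) evaluated at each replicate's realized
  thresholds (integer counts: the strict tails are taken at ⌊hi⌋ and
  ⌈lo⌉ − 1). Averaging over replicates is deliberate: a single replicate's
  100-target sensitivity has a binomial SE near 3.3 points, so a
  per-replicate bound would measure sampling noise rather than the
  implementation. Chance background matches of the 8-mer test motif add
  ≈ 0.03 counts/promoter, an order of magnitude below the tolerance.
* **DE filter**: with `noise_sd = 0` the filtered set equals the planted set
  exactly. With 1000 null genes (noise 0.3, n = 3/group) the p ≤ 0.05 rate
  must sit within 3 binomial SEs of 5%; with 500 planted genes (effect 1.0)
  the detection rate must sit within 5 points of the two-sided noncentral-t
  power (df = 4, noncentrality = effect / (σ·√(2/3))). The filter's extra
  |log2FC| ≥ 0.4 requirement excludes < 1% of significant planted genes at
  these settings, so the plain power oracle is adequate at the stated
  tolerance.
* **Set algebra**: conservation (|A-only| + |common| = |A|) and pairwise
  disjointness on 1000 random set pairs, plus the worked partition 1034
  total with 516 shared ⇒ 518 specific.
* **Determinism**: the bundled fixture pipeline re-run must produce
  byte-identical reports (timings are confined to the manifest).

These sizes keep the full suite under half a minute on one CPU while leaving
every tolerance dominated by the quantity being checked rather than by
sampling error.

## Numerical and design choices

* Internal coordinates are 0-based half-open everywhere; BED6 is native,
  GFF3 converts on read; the TSS is the feature start (plus) or the last
  transcribed base (minus). One convention eliminates off-by-one bug
  classes.
* Duplicate gene_ids in annotations keep the first occurrence with a logged
  warning (transcript-level duplicates are common in RefSeq-style inputs);
  duplicate keys in DE tables are an error (they are data corruption).
* Identifier matching across tables is exact and case-sensitive — silent
  fuzzy matching hides data errors.
* Category percentages are emitted with two denominators (DE genes in the
  category, and all category genes on the analysed table) because either can
  be meant by a "percent down" summary; both are reported rather than
  guessed.
* The aging-signature expected directions are user-supplied input: published
  signature tables mix directional and non-directional annotations, so the
  evaluated denominator is whatever the user's signature marks `up`/`down`.
* All randomness flows from a single integer seed per generator config;
  identical configs give byte-identical outputs.

## Known limitations

One TSS per gene model (no isoform or alternative-TSS resolution); no PWM or
mismatch-tolerant scanning; no conservation filtering; no enrichment
p-values or pathway analysis on the target lists; the synthetic expression
model is gene-independent Gaussian on the log2 scale. The enrichment band
inherits the limitations of a μ ± σ criterion: on heavy-tailed count
distributions it is permissive in the upper tail and can be vacuous in the
lower tail (μ − σ < 0 makes `depleted` unreachable).
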