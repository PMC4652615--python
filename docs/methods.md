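# Methods

This note records the models behind `txsimeval`, the defaults and why
they were chosen, and the numerical decisions that a maintainer would
otherwise have to reverse-engineer from the code.

## Simulation model

The framework is deliberately *neutral*: reads are error-free, carry no
positional, GC or fragmentation bias, and all expressed transcripts
share a single abundance distribution. Any weakness a transcript-set
estimation strategy shows under these favourable conditions is a lower
bound on its weakness under real conditions.

**Pool.** The universe is a transcript pool: genes, each with one or
more isoforms given as exon chains on a genome. Duplicate transcripts —
identical full exon-coordinate chains, which differ at most in
untranslated-region bookkeeping — are collapsed before any simulation,
keeping the lexicographically smallest id (a deterministic choice; the
duplicates are indistinguishable to every downstream stage).
Coordinates are 0-based half-open internally; GTF IO converts from/to
1-based inclusive.

**Expression.** A fraction `f_g` of genes is active; within each active
gene a fraction `f_t` of isoforms is expressed, with a minimum of one
(a gene that expresses nothing is not active in any meaningful sense;
the alternative — allowing rounding to zero — would make `f_g`
unreliable at small isoform counts). Counts are rounded to nearest.
Defaults `f_g = f_t = 0.5` are configurable study conditions. Expressed
transcripts draw abundances i.i.d. from Gamma(shape α = 1.2, rate
β = 0.001) — mean 1200, CV ≈ 0.91 — which spans the orders of magnitude
seen in real samples while keeping a heavy low-expression tail; all
other transcripts are exactly 0.

**Reads.** 75 bp paired-end, FR orientation, constant quality. Insert
size (outer distance) is Normal(μ = 250, σ = 30), rounded, and
rejection-sampled into [read_length, L] for a transcript of spliced
length L — rejection preserves the normal shape on the feasible range.
If the feasible window lies far in the lower tail (L below μ − 4σ) the
sampler falls back to clamping after 200 rejection rounds and a warning
is issued: such transcripts yield inserts pinned near L. Fragment
counts per transcript are multinomial with weights ρ·max(L − μ + 1, 1):
abundance times effective length, which makes the simulated ρ the
FPKM-style estimand that length-normalizing quantifiers report. A
plain-length weighting (ρ·L) is selectable
(`ReadSimConfig(length_weighting="full")`). Coverage is defined as
2·fragments·read_length / (total spliced length of expressed
transcripts), and the fragment count for a coverage target is that
relation inverted and rounded.

**Annotations.** Requested sensitivity `s` and precision `p` translate
into the four counts TP, FN, FP_a (false positives from unexpressed
isoforms of active genes) and FP_s (from silent genes) through four
simultaneous constraints; the closed form is

    TP = s·N_e,  FN = (1−s)·N_e,  FP_s = (1−f_g)·TP/p,  FP_a = TP·(f_g−p)/p.

The stratum-ratio constraint (TP+FP_a)/FP_s = f_g/(1−f_g) encodes the
assumption that curation covers active and silent genes at the same
rate; it makes requests with p > f_g infeasible (FP_a would be
negative) unless p = 1, which is treated as the declared special case
FP_a = FP_s = 0. Rounding order: TP to nearest (minimum 1 when s > 0),
FN derived; FP_s to nearest, FP_a to nearest independently. The
realized (s, p) of a solved/sampled annotation therefore differs from
the request only by integer quantization, roughly 1/(2·TP). Sampling
within each stratum is uniform without replacement — the conservative
choice; expression-weighted annotation probability would make curated
sets look even better.

## Matching

A candidate transcript is admissible for a true transcript when

* the common region is ≥ 80% of the true spliced length,
* the common region contains every inner exon of the true transcript
  (internal splice boundaries recovered exactly), and
* total spliced lengths differ by ≤ 20% of the true length.

Threshold comparisons are exact (≥ / ≤ on integer lengths against
0.8·L and 0.2·L). The mismatch score of an admissible pair is
m = √(d₁² + d₂²), where d₁ and d₂ are the *total* unmatched bases at
the 5′ and 3′ ends — truth-side plus candidate-side — after anchoring
on the common region; counting both sides penalizes truncation and
overextension symmetrically and reduces to the single-sided case when
only one transcript has overhang. Pairs are accepted greedily in
increasing score, ties broken on (true_id, candidate_id), and each id
is used at most once; an independently coded restatement of this
traversal serves as a test oracle.

Backends:

* **Coordinate** (GTF candidates): the common region is the genomic
  exon intersection under exact intron-chain agreement over the true
  transcript's span — every true intron present in the candidate, no
  extra candidate introns inside the span. This is the exact
  coordinate-space analogue of sequence-level common-substring matching
  for error-free data, and O(n log n) instead of all-pairs DP. It is
  marginally stricter than the inner-exon criterion alone for
  candidates with novel splices inside the true *terminal* exons.
* **Sequence** (de novo FASTA candidates): the common region is the
  longest exact common block, found by 31-mer seeding with maximal
  exact extension, in both orientations (assemblies are unstranded).
  Among admissible blocks the one minimizing m is kept. Exact (rather
  than alignment-tolerant) blocks are correct here because reads and
  transcripts are error-free; the k-mer prefilter makes the all-pairs
  scan tractable. Transcripts shorter than ~2k are handled by shrinking
  k to the pair's minimum length.

## Quantification

The built-in quantifier is a deliberately simple exact-match EM — a
stand-in that keeps the pipeline self-contained, not a reimplementation
of a production tool; external estimate tables can be substituted. Each
pair is assigned the transcripts containing mate 1 and the reverse
complement of mate 2 at offsets whose outer distance lies in
[read_length, μ + 4σ]; the lower bound stays at read_length because
short transcripts legitimately produce truncated inserts. Pairs
collapse into equivalence classes by compatible-transcript set, and EM
maximizes the multinomial likelihood over fragment-origin proportions
π (uniform initialization, so the fit is deterministic; convergence at
max |Δπ| < 1e-8 or 1000 iterations; the log-likelihood trace is exposed
and asserted non-decreasing in tests). Estimates are reported as
π·10⁹ / effective length, an FPKM-like unit proportional to the
simulated ρ.

A transcript whose posterior fragment count is numerically zero
(π·N < 10⁻³) reports estimate 0 rather than an underflowed positive
residue. Without this, a truly-expressed transcript that happens to
receive no fragments (the gamma's low tail) can surface as exp(−400)
and single-handedly destroy a log-scale correlation — an artefact of
floating-point EM, not of the quantification problem.

**Metrics.** `corr_tp` is the Pearson correlation of (ln true,
ln estimated) over TP transcripts with positive estimates;
zero-estimate TPs are excluded and counted rather than pseudocounted,
since any pseudocount would dominate exactly the low-expression regime
under study. `FP̄/TP̄` is the ratio of raw-scale means of FP and TP
estimates, 0 meaning false transcripts absorbed no signal. True values
of FP transcripts are zero by definition. Fewer than 3 usable TPs, or
a zero TP mean, raise errors rather than returning NaNs.

## Synthetic pool generator

The generator emulates the structural features that make transcript-set
estimation hard: multi-isoform genes (isoform count ~ 1 + Poisson, mean
4/gene), isoforms sharing their flanking exons and differing in
internal exon subsets (so reads are genuinely ambiguous between
isoforms), multi-exon structure (exon count ~ 1 + Poisson, mean 8;
exon lengths uniform 100–300 bp; introns 200–500 bp), both strands, and
optional verbatim gene-level paralogs to emulate multi-gene read
mapping. Loci are non-overlapping on one synthetic chromosome with a
uniform ACGT background.

It does **not** emulate: sequence composition bias, repeats other than
whole-gene paralogs, overlapping/nested genes, alternative first/last
exons (flanking exons are always shared), real intron length
distributions, or alternative haplotypes. Consequently, passing tests
show that a method behaves correctly under idealized ambiguity, not
that it survives the full repeat structure of a mammalian genome;
absolute sensitivity/precision numbers on real data will be worse.

## Workflow and reproducibility

A master seed fans out via SHA-256 of (seed, stage name, replicate,
cell index), keeping every stage seed independent, reproducible, and
below 2³¹. The pool is built once per experiment; partition,
expression, reads and annotations are resampled per replicate, and grid
cells report arithmetic means over replicates. Infeasible (s, p) cells
are recorded as error cells without aborting the run. Reruns with the
same config and seed are byte-identical down to the FASTQ files.

Default problem sizes — 500-gene pools (~2000 transcripts, ~2 Mb
genome) at coverage 100 (~10⁵–10⁶ fragments) for full-pipeline
experiments, 5·10⁴–10⁵ draws for distribution-recovery checks — were
chosen so the whole suite runs on a laptop-class single core in
minutes while keeping Monte-Carlo error well inside the tolerances the
tests assert.

## Known limitations

* The EM quantifier ignores fragment-length probability within the
  compatibility window and positional multiplicity; it is adequate for
  relative comparisons between transcript-set choices, not a
  replacement for a production quantifier.
* The matcher's sequence backend assumes error-free candidates; a
  noisy assembly would need alignment-tolerant common regions.
* Requested precision above f_g is unrepresentable by construction
  (see the stratum-ratio constraint); grids should respect p ≤ f_g.
* Single-end protocols, stranded libraries, and differential
  expression across conditions are out of scope.
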