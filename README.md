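# txsimeval

A simulation framework for benchmarking **RNA-seq transcript-set
estimation** strategies.

When estimating transcript expression from RNA-seq, the first decision
is which set of transcripts to quantify: a **curated annotation** (e.g.
an Ensembl subset), a **genome-guided assembly** of the reads, or a
**de novo assembly**. Each choice trades sensitivity (how many truly
expressed transcripts the set contains) against precision (how many of
its transcripts are actually expressed), and wrong transcripts in the
set can silently *absorb expression signal* that belongs to the real
ones. `txsimeval` lets you study these trade-offs under fully
controlled conditions, because the true transcript set and the true
expression values are simulated and therefore known exactly.

It is aimed at method developers and bioinformaticians who want to
stress-test quantification pipelines, compare assemblers' outputs
against a known truth, or understand how annotation quality propagates
into expression estimates.

## What it does

1. **Transcript pools** (`txsimeval.pool`) — read/write GTF + genome
   FASTA, collapse duplicate transcripts (identical exon-coordinate
   chains), or generate a fully synthetic pool: random genome, genes
   with multi-exon isoform structures, optional perfect paralogs to
   emulate multi-mapping.
2. **Expression simulation** (`txsimeval.expression`) — designate a
   fraction *f_g* of genes as active and a fraction *f_t* of their
   isoforms as expressed (counts *N_e*, *N_u*, *N_s*), then draw true
   abundances from Gamma(shape α = 1.2, rate β = 0.001), a wide-dynamic-
   range distribution typical of real samples.
3. **Read simulation** (`txsimeval.reads`) — 75 bp paired-end
   error-free reads; insert size (outer mate distance) ~ Normal(μ = 250,
   σ = 30); fragments allocated multinomially with weight
   (abundance × effective length). Coverage is defined as
   2 · fragments · read_length / total expressed length.
4. **Imperfect annotations** (`txsimeval.annotation`) — given requested
   sensitivity *s* and precision *p*, solve

       s = TP/(TP+FN),  p = TP/(TP+FP_a+FP_s),
       N_e = TP+FN,     (TP+FP_a)/FP_s = f_g/(1−f_g)

   in closed form (TP = s·N_e, FP_s = (1−f_g)·TP/p,
   FP_a = TP·(f_g−p)/p; feasible iff p ≤ f_g or p = 1) and sample the
   annotated set from the three strata.
5. **Transcript matching** (`txsimeval.matching`) — a candidate matches
   a true transcript when the common region covers ≥ 80% of the true
   length and all its inner exons, and total lengths differ by ≤ 20%.
   Each admissible pair is scored m = √(d₁² + d₂²) from the unmatched
   end lengths; a greedy traversal in increasing score yields the
   one-to-one TP/FN/FP labelling. Coordinate (GTF) and sequence
   (de novo FASTA) backends are provided.
6. **Quantification & metrics** (`txsimeval.quantify`) — a built-in
   exact-match EM quantifier (or any external tool's id→value table)
   produces FPKM-like estimates; evaluation reports the Pearson
   correlation of log true vs log estimated expression over TP
   transcripts and the signal-absorption ratio
   **FP̄/TP̄** = mean(FP estimates)/mean(TP estimates)
   (0 = perfect separation of true and false transcripts).
7. **Workflows** (`txsimeval.workflow`, `txsimeval` CLI) — one config
   runs pool → partition → expression → reads → annotation/candidates →
   matching → EM → metrics over an (s, p) grid with replicates and a
   deterministic seed fan-out.

## Worked example

```python
from txsimeval.workflow import ExperimentConfig, SyntheticPoolSpec, run_experiment

cfg = ExperimentConfig(
    seed=7, replicates=3,
    synthetic_pool=SyntheticPoolSpec(n_genes=300, isoform_mean=4.0),
    coverage=100.0,
    annotation_grid=((0.2, 0.4), (0.6, 0.4), (1.0, 0.4), (1.0, 1.0)),
)
print(run_experiment(cfg).to_string(index=False))
```

```
      kind        name  sensitivity  precision  corr_tp  fp_tp_ratio
annotation s=0.2,p=0.4     0.198927   0.399128 0.866945     0.082670
annotation s=0.6,p=0.4     0.600026   0.400158 0.836097     0.028765
annotation   s=1,p=0.4     1.000000   0.400084 0.971335     0.002610
annotation     s=1,p=1     1.000000   1.000000 0.972055     0.000000
```

Each row is one simulated-annotation condition, averaged over 3
independent simulations. Reading it: even an annotation containing only
20% of the truly expressed transcripts (s = 0.2) — with 60% of its
entries being false — still gives a TP log-expression correlation of
0.87, and its false entries absorb only ~8% as much estimated
expression as the true ones. With a fully sensitive annotation the
false positives are starved of reads almost entirely (FP̄/TP̄ ≈ 0.003),
which is why annotation *sensitivity* matters far more than annotation
*precision* for expression analysis.

The same grid can score external candidate sets: pass
`candidate_sets=(("cufflinks", "cufflinks.gtf"), ("oases", "oases.fa"))`
and each set is matched against the expressed truth (coordinate or
sequence backend by file type), quantified, and reported in the same
table.

A shell-level pipeline is available through the `txsimeval` CLI
(`pool make`, `expr sample`, `reads`, `annot`, `match`, `quant`,
`run`); see `txsimeval --help`.

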