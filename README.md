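# smallrna-pingpong

Analysis pipeline for germline small-RNA sequencing centered on the piRNA
**ping-pong amplification signature**, plus a synthetic read generator that
emulates the statistical structure the analysis assumes, so every stage can
be validated against known ground truth.

## The problem and who this is for

Piwi-interacting RNAs (piRNAs, 23–29 nt) silence transposable elements (TEs)
in animal germlines. The ping-pong cycle — reciprocal cleavage by
Aub/Ago3-class PIWI proteins — amplifies piRNAs and leaves a diagnostic
footprint: sense/antisense read pairs whose 5′ ends overlap by exactly
10 nt, with the secondary (sense) piRNA carrying an A at position 10 and the
primary (antisense) piRNA a 5′ uridine (the 10A/1U signature). This package
is for researchers who want to quantify that footprint and compare piRNA
abundance between conditions (e.g. wild type vs a germline knockdown) from
small-RNA FASTQ libraries and transcript-level reference sequences.

## The statistics at the core

Reads are clipped, depleted of rRNA/miRNA-hairpin matches (≤1 mismatch,
either strand, end-to-end), classified by length (piRNA 23–29 nt, siRNA
20–22 nt), and placed on transposon/cluster/gene references by ungapped
best-stratum alignment (≤1 substitution, fractional multi-mapper weights).
With a sense read's 5′ end at plus-strand position *s* and an antisense
read's 5′ end at *a*, the 5′–5′ overlap is *o* = *a* − *s* + 1. Per
transposon the pipeline computes:

- the **overlap histogram**: paired weight per overlap bin *o* ∈ [1, 30] —
  ping-pong manifests as a peak at *o* = 10;
- the **qualifying weight**: reads in ≥1 pair with *o* = 10 and
  (sense 10th base = A **or** antisense 1st base = U);
- the **ping-pong ratio** = qualifying weight / total piRNA weight on the
  transposon — a within-library proportion needing no library-size
  normalization;
- **abundances** normalized either per million miRNA-hairpin reads (a
  piRNA-pathway-independent denominator) or as fractions of total library
  reads;
- **differential tests**: per-feature Student's *t* on log2 normalized
  abundance, a global Wilcoxon signed-rank on per-TE fold changes,
  Benjamini–Hochberg adjustment, and calls at >1.5-fold with FDR < 0.1.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (seeded, deterministic):

```bash
python analysis/01_simulate_dataset.py   # 2 conditions x 3 replicates
python analysis/02_run_pipeline.py       # all stages, TSVs + manifest
python analysis/03_pingpong_analysis.py
python analysis/04_differential_analysis.py
```

The simulated design puts a 3-fold transposon-piRNA upregulation in
condition B with the ping-pong pair fraction held at 0.4 in both. The
ping-pong summary prints (abridged):

```
overlap bin-10 enrichment per library:   ~52-55x over background bins
ping-pong ratio by condition:
                 mean    std
upregulated    0.6323 0.0133
wild-type-like 0.6326 0.0201
```

i.e. a strong 10-nt overlap peak in every library and no ratio change
despite the 3-fold abundance shift (comparison p = 0.84) — the ratio is
insensitive to library size and abundance, as intended. The differential
summary prints per-TE fold recovery and calls:

```
8 features called up; transposon median fold 3.02 (design: 3.0)
```

with all six transposons and both piRNA clusters called up (>1.5-fold,
FDR < 0.1) while miRNA-hairpin reads stay flat — the normalizer is
untouched by the upregulation.

Equivalent shell entry points exist: `smallrna-pingpong simulate|run|
preprocess|align|pingpong --help`.

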