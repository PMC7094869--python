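# Methods

## Pipeline model and assumptions

The pipeline treats a small-RNA library as a bag of short cDNA reads drawn
from transcript-level reference sequences: transposon consensus sequences,
piRNA-cluster precursors, genes, miRNA hairpins, and rRNA. All sequence is
held as DNA (U↔T at the boundaries). Stage order is fixed — clip →
deplete → classify → align → count/normalize → ping-pong → differential —
and every stage's read counts reconcile in the run manifest.

**Adapter clipping** truncates at the leftmost exact match of ≥`min_match`
(default 8) bases of the 3′-adapter prefix; inserts shorter than
`min_insert` (default 18 nt) are discarded. These defaults are standard
small-RNA practice and are configuration values, not biological claims.
Quality strings are validated but carry no meaning downstream (no quality
filter is part of the analysis).

**Depletion** removes reads matching any rRNA or miRNA-hairpin reference
end-to-end on either strand with ≤1 substitution (no indels) — the
behavior of ungapped short-read alignment of 20–30-mers at one mismatch.
A read matching both classes counts as miRNA-hairpin; this priority
protects the normalizer and is otherwise arbitrary. The count of
hairpin-depleted reads is the between-library normalizer
(`hairpin_total`); `library_total` is all clipped reads entering
depletion/classification, so `hairpin_total ≤ library_total` always.

**Classification** is purely by length: piRNA 23–29 nt inclusive, siRNA
20–22 nt, everything else `other`. Only piRNA-class reads proceed to
alignment and the ping-pong statistics.

**Alignment** reports all end-to-end placements with ≤`max_mismatch`
(default 1) substitutions on either strand of each feature, then keeps
only the best (minimum-mismatch) stratum across all features. Candidates
are found by pigeonhole seeding — a placement with ≤1 substitution leaves
one read half exact — and verified by Hamming count, which is exhaustive
for substitution-only placement; tests confirm equality with the full
offset×strand scan. Coordinates are 0-based half-open on the plus strand;
an antisense read's biological 5′ end is `start + length − 1`, so the
5′–5′ overlap is the single subtraction `a − s + 1`. Multi-mappers get
weight 1/k over the k best-stratum placements (`fractional`, default,
closest to EM-free read apportioning) or are dropped and counted
(`unique_only`, for sensitivity analysis).

## Ping-pong statistics

Per transposon, with the 5′-end weight maps S(s) and A(a):

- histogram bin *o* accumulates Σ S(s)·A(s+o−1) for *o* ∈ [1, `o_max`]
  (default 30, bounded by read length);
- a (sense, antisense) pair **qualifies** iff *o* = 10 and (sense 10th
  base is A **or** antisense 1st base is U). Both the overlap and the
  base checks use the read's own sequence, not the reference: the
  signature belongs to the piRNA molecule, so a mismatch-bearing read is
  judged by its sequenced 10th/1st base;
- the **numerator** counts each read participating in ≥1 qualifying pair
  once (weighted), which bounds the ratio by 1; a `pairs` mode sums
  weight products over qualifying pairs instead;
- the **denominator** is the feature's total piRNA weight (both
  orientations); a library-wide denominator is available by flag. The
  per-feature choice matches reporting the ratio "of each transposon".

The ratio is a within-library proportion: duplicating every read leaves
it unchanged (tested), which is why no library-size normalization is
needed. Reads shorter than 10 nt in the sense role are excluded with a
warning counter (cannot have a 10th base).

## Normalization and differential analysis

Two normalizers are carried side by side and never mixed silently:
per-million miRNA-hairpin reads (for per-TE abundances and density
tracks) and total library reads (for per-class fractions). Density
profiles default to full-read coverage — the conservation-testable
choice (positional sum = Σ weight×length) — with a 5′-end-only mode,
since published density tracks do not disambiguate the two.

Differential analysis deliberately replaces a negative-binomial Wald
model with a defined, replicate-aware battery on hairpin-normalized
abundances: per-feature equal-variance Student's *t* (Welch by flag) on
log2(abundance + pseudocount 1.0), a global Wilcoxon signed-rank on
per-TE log2 fold changes (exact null for n ≤ 25 with mid-ranked ties and
dropped zeros; normal approximation with continuity correction above),
Benjamini–Hochberg adjustment, and calls at fold > 1.5 with q < 0.1
(both config values; the pseudocount and the normalized-abundance input
are explicit config, since count-model conventions vary). Fewer than 5
nonzero differences leave the Wilcoxon p undefined rather than
misleadingly precise.

## The synthetic generator: what it emulates, what it does not

Defaults describe a wild-type-like germline library at desk scale: 50%
transposon-derived piRNAs, 15% TE-derived siRNAs (20–22 nt), 25%
miRNA-hairpin reads (the normalizer's depth), 10% rRNA fragments; piRNA
lengths peak at 26 nt; antisense piRNAs (and cluster-derived primaries)
start with U with probability exactly `u1_bias` = 0.8; 40% of TE piRNA
reads are emitted as deliberate ping-pong pairs (sense 5′ at *s*,
antisense 5′ at *s*+9, sense 10th base A with probability `a10_bias` =
0.7); 15% of piRNA-class reads come from piRNA-cluster features as
unpaired sense primaries, so the cluster class responds to piRNA-level
fold changes the way repeat classes do. Reads are exact reference
substrings except the single forced signature base, so 1-mismatch
alignment places every read at its emission site and the pipeline can be
checked against truth exactly.

Ground truth records every emission (feature, strand, coordinates, final
sequence). Its qualifying-read count is recomputed by an all-pairs brute
force over the emission table, because unpaired reads also land in exact
10-nt overlap by chance and the statistic's definition does not
distinguish deliberate from chance pairs; the deliberately emitted pair
count is kept separately.

Condition pairs scale each read class's expected emission by its fold
factor and grow the total read count accordingly, holding the absolute
hairpin expectation fixed — modelling deeper piRNA output against an
unchanged normalizer rather than a fixed-depth resampling. Consequently
"miRNA reads unchanged" is measured on absolute hairpin counts, not on
the (necessarily diluted) library fraction. Replicate seeds are derived
by fixed arithmetic (`seed + 1000·condition + replicate`).

**Placement modes.** `uniform` scatters 5′ ends uniformly; it is the
right null for histogram calibration (no systematic bin-10 peak). Real
piRNA 5′ ends, however, cluster heavily at defined positions, and under
uniform placement the chance-pair component of the ratio grows with read
density, making the ratio weakly abundance-sensitive. The `hotspot` mode
(default 25 sites per feature and strand, drawn from the feature name and
`sites_seed` so all libraries over the same references share sites)
reproduces the clustered regime, in which qualifying probability
saturates and the ratio is abundance-invariant — the regime in which the
abundance-change experiment is run. Passing tests therefore show the
statistic behaves correctly under the generator's idealizations (no
sequencing error by default, no adapter chemistry beyond an optional
fixed suffix, no fragmentation bias, uniform base composition); they do
not certify behavior on real libraries with expression-dependent 5′-end
landscapes.

## Numerical and design choices

- Problem sizes in the shipped analysis and tests (20 000–50 000 reads,
  6–8 TEs of 1.5 kb, 3 replicates) are chosen so every stochastic check
  sits far from its decision boundary at desk scale.
- Weights: fractional weights sum to 1 per read (enforced to 1e-9);
  histogram bins are bilinear in strand weights (tested).
- Degenerate inputs: empty depletion set retains everything and flags a
  zero normalizer; hairpin-normalizing a zero-normalizer library is an
  explicit error; a feature with zero weight in either orientation has
  ratio 0; all-zero difference vectors give Wilcoxon p = 1.
- Exact-vs-approximate Wilcoxon switch at n = 25, where the normal
  approximation with continuity correction is within 0.01 of enumeration
  (tested at n = 20).
- Ties in BH are handled by the step-up procedure with monotone
  enforcement; input order never matters (tested by permutation).

## Known limitations

- No indel alignment and no seed-and-extend heuristics; references are
  transcript-level consensus sequences, not genomes.
- No EM redistribution of multi-mappers; fractional weighting is a fixed
  apportioning.
- The generator's chance-pair structure under `uniform` placement is
  denser than real data at equal depth (uniform 5′ ends); interpret
  absolute synthetic ratios (~0.6 at default settings) as properties of
  the simulation, not of any organism.
- The z10-style standardized ping-pong score is out of scope; the
  statistic here is the qualifying-read ratio.
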