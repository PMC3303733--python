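# Methods

## Pair formation and classification

Genes are modelled by their coding-region (CDS) coordinates on 1-based,
closed intervals (the GFF3 convention), with optional transcription start
sites (TSSs). Within each chromosome, genes are sorted by
`(cds_start, cds_end, gene_id)` — the gene_id tie-break makes the pipeline
deterministic on degenerate inputs — and every consecutive sorted pair is a
candidate adjacent pair, so a chromosome with *n* genes yields *n − 1*
candidates. Adjacency is defined on coding-region order, not transcript
boundaries, because TSSs are typically available for only a subset of genes
while CDS coordinates are available for all.

Candidates whose closed CDS intervals intersect are excluded before any
classification; touching-but-not-overlapping neighbours are retained at
distance 0. The survivors are classified by strand: (−,+) → h2h, same
strand → h2t, (+,−) → t2t. Flipping every strand therefore swaps h2h and t2t
counts and fixes h2t — a property the tests exercise — and i.i.d. uniform
strands give expected fractions 25/50/25.

Two distances are reported, both counting bases *strictly between* the
features (touching ⇒ 0):

* CR distance = `right.cds_start − left.cds_end − 1`;
* TSS distance = `|tss_right − tss_left| − 1`, floored at 0 for interleaved
  transcript starts, defined only for h2h pairs with both TSSs known. The
  same base-counting convention is used for both so the two distance
  distributions are comparable; the convention itself is a package choice,
  as upstream descriptions of these distances rarely state one.

Distance histograms use half-open bins `[0,200), [200,400), …` up to
3,000 bp, with values ≥ 3,000 kept in an overflow tally; fractions are over
the full pair count, so displayed bins sum to ≤ 1. A distance of exactly 0
falls in the first bin.

## Co-expression

For one pair, every expression dataset containing both genes contributes
`|PCC|` of the two profiles; the pair's co-expression is the **maximum**
across datasets, so a pair that co-expresses only under one condition still
scores high. Datasets with fewer than 15 samples are excluded up front
(exactly 15 is retained); a dataset where either profile has zero variance
is ignored for that pair, like a missing gene. A pair covered by no dataset
has undefined co-expression — undefined is a value, not an error, and such
pairs are excluded from group means but still counted in group sizes.

## Functional similarity

The score is Resnik information content on the biological-process GO
hierarchy, reported as a negative natural log:

    Sim(a, b) = −ln( min { gene(t) : t shared by a and b } / gene(root) )

`gene(t)` is the number of genes annotated at or below `t` after true-path
propagation (each gene counted once per term even via multiple DAG paths).
Propagation is essential to the formula's semantics: without it the root
count would be near zero and the score unbounded in sign; with it the root
is always a shared term of probability 1, so Sim ≥ 0, and two genes sharing
only the root score exactly 0. Genes with no annotation have undefined
similarity. Only `is_a` edges are followed when reading OBO input
(`part_of` can be enabled); the edge-list TSV reader takes the hierarchy as
given.

The high/low association split labels a pair "high" when its similarity
strictly exceeds the average over all adjacent pairs with defined similarity
(the genome average); ties and undefined values go to "low". The averaging
scope is configurable to h2h-only (`association_scope: h2h`), since either
reading of "genome average" is defensible.

## TF-evidence stratification

Evidence records are `(tf, gene, kind)` with kind ∈ {binding, regulation},
deduplicated. A TF is *common* to a pair when it has evidence of the
requested kind for both genes; mode `either` unions the kinds per gene
before intersecting and is the default for per-TF tables (the combination
rule behind "bound/regulated" summaries is not standardised, so all three
modes are exposed).

Pairs are bucketed by common-TF count 0, 1, 2, …; from the first bucket
smaller than `min_bin_size` (default 90) upward, buckets merge into a final
"≥k" bucket. The trend statistic is the Pearson correlation between bucket
ordinal and bucket mean — one number per column, which is the only reading
consistent with published tables of this analysis; with exactly two buckets
it degenerates to the sign of the difference.

Per-TF statistics are computed over the group of h2h pairs whose common set
contains the TF (a pair with several common TFs joins several groups): the
e-score and f-score are the group means of co-expression and functional
similarity over defined values; `pct_ppi` is the fraction of group pairs
present (unordered) in a protein–protein-interaction list; `pct_h2h` is the
fraction of the TF's distinct targets that belong to any h2h pair. The full
ranked table is emitted rather than a top-k cut, since no principled
selection threshold exists.

## Promoter signals

The bidirectional promoter of an h2h pair is the gap between the two CDSs
(`between_cds`, default — defined for every h2h pair) or between the two
TSSs (`between_tss`, defined only when both TSSs are known). A promoter is
TATA-containing iff at least one TATA-box interval intersects it; partial
overlap counts, and adding boxes can only flip less → containing.

Bendability is computed from a 64-entry tri-nucleotide propensity table
applied to the plus-strand sequence: each window contributes its value to
its three bases and a base takes the mean over its (up to 3) covering
windows. Averaging is the symmetric choice among per-base reductions and is
the documented assumption; windows containing N are invalid, and a base with
no valid window is undefined (NaN). Strand is ignored throughout — both
bendability and nucleosome occupancy are treated as double-strand
properties.

A promoter is *more accessible* iff it contains ≥ 1 run of at least
`min_len` consecutive bases with bendability **and** occupancy strictly
below their genome-wide pooled means (NaN fails the predicate; ties fail —
"lower than" is strict). `min_len` defaults to 8, just under the typical
transcription-factor binding-site length of ~8.6 bp. Genome means are pooled
over all defined bases of all chromosomes, not means of per-chromosome
means; a promoter-wide averaging scope is not implemented beyond passing
custom thresholds, which the API allows. Lowering `min_len` or raising
either threshold can only add accessible segments.

## Synthetic data

The generator emulates each curated input with planted, labelled structure:

* **Layout** — genes laid left-to-right per chromosome with uniform gap
  lengths (the gap equals the CR distance, making the distance histogram
  analytically flat over the gap range), uniform gene lengths, i.i.d.
  strands, and TSSs at uniform upstream offsets for 80% of genes. Defaults:
  16 chromosomes, gene length 300–3,000 bp, gaps 0–1,000 bp — yeast-like
  scales.
* **Association** — a fraction (default 0.5) of h2h pairs is planted with a
  strength c ∈ {1..planted_common_tfs}. A strength-c pair gets c common
  regulation TFs, profile correlation `assoc_expr_corr · c / c_max` via a
  shared latent factor (`x = √ρ·z + √(1−ρ)·ε`, population correlation
  exactly ρ) in the first dataset, and a shared GO term whose specificity
  grows with c (full-strength pairs get private leaf terms; weaker pairs
  share mid-depth terms from a small pool). Association therefore increases
  with planted common-TF count — the monotone structure the bucket-trend
  analysis detects. Later datasets are pure noise and drop a random 5% of
  non-planted genes to exercise the both-genes-present rule.
* **GO** — a tree of depth 5, branching 3 (a separate diamond fixture in the
  tests covers count deduplication); 90% of background genes annotated to a
  depth-1 term.
* **Tracks** — Gaussian noise around fixed means (bendability 5.0 ± 1.0,
  occupancy 0.5 ± 0.15, arbitrary units). Chosen promoters get an inserted
  run (default 12 bp) at values far below both means; every *other* h2h
  promoter gets an above-mean bendability base every `min_len − 1` positions,
  which caps any chance joint-below run at `min_len − 2`. Without this, a
  ~0.25^8 per-base false-positive rate would make planted accessibility
  labels only approximately recoverable; with it they are exact.
* **TATA** — boxes (8 bp) inserted inside a `tata_frac` (default 0.4) subset
  of promoters; since promoter regions of distinct h2h pairs are disjoint,
  labels are exact here too.

All generators run on independent child streams of one seed
(`numpy.random.SeedSequence.spawn`), so outputs are fully deterministic and
adding one component never perturbs another.

What the generator does **not** emulate: real nucleotide composition or
motif content, realistic GO topology or annotation depth, microarray noise
structure (batch effects, heteroskedasticity), correlated TF regulons, or
overlapping genes (layouts are non-overlapping by construction, so the
overlap filter is exercised by hand-built fixtures instead). Passing
recovery tests therefore demonstrates correctness of the computations and
detectability of planted effects at the stated sizes — not performance on
real genomes.

## Problem sizes and numerics

The test suite and the acceptance script use desk-scale sizes chosen to make
the statistics stable: the random-arrangement simulation uses 16 × 640
genes (10,224 pairs; 3 binomial SE ≈ 1.3 points at 25%), oracle-equivalence
suites use 100 random 30-term DAGs and 500 random 200-bp track fixtures,
and the end-to-end recovery study uses 3 × 40 genes with ten 100-sample
datasets at planted correlation 0.8. Correlations are computed directly
from centred dot products with a zero-variance guard; results are clipped
to [−1, 1] against rounding. Pipeline outputs are written with fixed float
formatting, so re-runs on identical inputs are byte-identical.

## Known limitations

* Real-genome results depend entirely on the quality of the supplied
  curated inputs; the package performs no curation, normalisation, TSS
  prediction or motif scanning.
* The bucket-merging rule and the per-base bendability reduction are
  documented assumptions (see above), configurable where ambiguity exists.
* Circular chromosomes and cross-telomere adjacency are not modelled; pairs
  are strictly within-chromosome.
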