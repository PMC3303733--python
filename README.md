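# h2hscan

Genome-wide analysis of **head-to-head (h2h) gene pairs** — adjacent genes on
opposite strands that transcribe divergently from a shared intergenic region,
the *bidirectional promoter* — and of the promoter features that distinguish
associated from non-associated pairs. The package targets compact genomes
(its design point is *Saccharomyces cerevisiae*-scale annotation) and is
aimed at regulatory genomicists who want a reproducible, scriptable version
of this classic analysis.

## What it computes

Given gene annotations, the package forms all adjacent gene pairs per
chromosome, excludes pairs with overlapping coding regions, and classifies
the rest by strand orientation:

* **h2h** (−,+): divergent, sharing a bidirectional promoter
* **h2t** (+,+) or (−,−): same strand, head-to-tail
* **t2t** (+,−): convergent, tail-to-tail

Under random, independent strand assignment the expected class fractions are
25% / 50% / 25%. Two association indices are computed per pair:

* **Co-expression** — the highest absolute Pearson correlation of the two
  genes' expression profiles over all qualifying datasets (datasets with
  fewer than 15 samples, or not covering both genes, are ignored; the
  maximum, not the mean, is taken so that condition-specific co-expression
  is not washed out).
* **Functional similarity** — a Resnik-style score on the biological-process
  GO hierarchy, `Sim(a,b) = −ln( min_t gene(t) / gene(root) )`, minimising
  over the GO terms `t` shared by both genes' propagated annotations;
  `gene(t)` is the propagated per-term gene count. Sharing only the root
  gives 0; a private specific term gives a large score.

Association is then stratified by promoter features: the number of common
transcription factors with *binding* or *regulation* evidence (with per-TF
e-scores/f-scores, protein–protein-interaction fractions and h2h-target
fractions), presence of a TATA box in the bidirectional promoter, and
promoter *accessibility* — whether the promoter contains a run of ≥ 8
consecutive bases whose DNA bendability and nucleosome occupancy are both
below their genome-wide averages.

Because the real analysis needs curated resources (annotation databases,
expression compendia, TF-evidence collections, TATA/nucleosome data), the
package ships a synthetic-data generator that emulates every input with
planted, recoverable structure, so the full pipeline runs and is tested
without any downloads.

## Worked example

Generate a small synthetic study (3 chromosomes × 40 genes, ten
100-sample expression datasets) and run the full pipeline on it:

```sh
cat > synth.yaml <<EOF
n_chroms: 3
genes_per_chrom: 40
samples_per_dataset: 100
EOF
h2hscan synth --seed 7 --config synth.yaml --out-dir demo
h2hscan run --config demo/run.yaml
```

(The same thing in Python: `generate_dataset(SynthConfig(seed=7, n_chroms=3,
genes_per_chrom=40, samples_per_dataset=100))`, then `write_dataset` and
`run_pipeline`.)

`demo/results/` then contains the chromosome summary, distance histograms,
pair scores, TF tables and promoter classifications. The chromosome summary
for this run:

```
  chrom  length_bp  n_genes  density  n_pairs  n_h2h  n_h2t  n_t2t  pct_h2h  pct_h2t  pct_t2t
  chr01      81117       40  4.93115       39      9     20     10  23.0769  51.2821  25.6410
  chr02      90786       40  4.40597       39     11     17     11  28.2051  43.5897  28.2051
  chr03      83364       40  4.79823       39     10     18     11  25.6410  46.1538  28.2051
overall     255267      120  4.70096      117     30     55     32  25.6410  47.0085  27.3504
```

120 genes form 117 adjacent pairs (n−1 per chromosome), none overlapping in
this layout, and the class percentages sit near the 25/50/25 random
expectation. Stratifying the 30 h2h pairs by the number of TFs with
regulation evidence for *both* genes (`table2_regulation.tsv`):

```
pair_class  bin_index label  n_pairs  mean_coexpression  mean_functional_similarity
       h2h          0  0 TF       15           0.221961                    0.330997
       h2h          1  1 TF        7           0.379106                    2.689630
       h2h          2 2 TFs        8           0.743546                    3.728560
```

Both association indices rise strictly with the common-TF count (trend
Pearson correlations 0.975 and 0.976 in `headline.json`) — the pipeline
recovers the planted structure, in which pairs sharing more regulation TFs
were generated with stronger expression correlation and more specific shared
GO terms. `promoters.tsv` classifies each bidirectional promoter
(TATA-containing vs TATA-less, more vs less accessible); in this run 12/30
promoters are TATA-containing and 14/30 are more accessible, exactly the
planted labels.

## Package layout

| module | contents |
| --- | --- |
| `h2hscan.genome_pairs` | annotation readers, pair formation/classification, distances, summaries |
| `h2hscan.association_metrics` | max-\|PCC\| co-expression, GO DAG + Resnik similarity, high/low split |
| `h2hscan.tf_analysis` | common-TF bucketing, e-/f-scores, PPI and h2h-target fractions |
| `h2hscan.promoter_signals` | promoter regions, TATA classes, bendability, accessibility |
| `h2hscan.synthetic_data` | generators for every input, with ground-truth labels |
| `h2hscan.pipeline` / `h2hscan.cli` | orchestration and the `h2hscan` command |

See `docs/methods.md` for the model, parameter and design details.
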