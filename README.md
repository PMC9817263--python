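# ensemblebin

Ensemble metagenomic contig binning. The pipeline:

1. **Features** — per-contig coverage profiles (depth + 0.01 pseudocount,
   per-sample library-size then per-contig L1 normalization) and canonical
   tetranucleotide frequencies (136 reverse-complement-folded 4-mer classes,
   +1 pseudocount), each natural-log transformed, as three matrices:
   combined, coverage-only, composition-only.
2. **Bin number** — the initial bin count `k0` is the ceiling of the third
   quartile of per-marker distinct-contig counts from a single-copy-gene hit
   table; a short grid of candidates above `k0` is scored by mean silhouette
   and the best is kept.
3. **Component binnings** — length-weighted k-means++ with a *partial-seed*
   initialization: contigs carrying a quartile-chosen marker gene fix the
   first initial centers, the rest are drawn by weighted D² sampling. Three
   seeded runs plus one plain run per feature matrix give 12 component
   binnings.
4. **Splitting** — bins with marker-based contamination ≥ 50% and
   completeness ≥ 70% are re-clustered into sub-bins.
5. **Ensemble** — per feature track, greedy selection of the
   highest-scoring high-quality bins (score = 100 × (completeness − 3 ×
   contamination); high quality means score > 10, contamination < 15%,
   completeness > 50%), stripping selected contigs from the remaining
   candidates. The three track results are then pooled with their pairwise
   and triple shared-contig refinements and the same greedy selection
   produces the final bins.

A synthetic-community module generates desk-scale test data (Markov-chain
genomes, lognormal abundances and contig lengths, planted single-copy
markers) with full ground truth, and an evaluation module provides per-bin
purity/completeness, quality-tier counts, and a base-pair-weighted adjusted
Rand index.

## CLI

```bash
# simulate a community with ground truth
ensemblebin simulate --out sim/ --n-genomes 20 --genome-length 200000 \
    --n-samples 10 --n-markers 40 --seed 0

# run the binning pipeline
ensemblebin run --contigs sim/contigs.fa --depth sim/depth.tsv \
    --markers sim/markers.tsv --gene-lengths sim/gene_lengths.tsv \
    --depth-dialect plain --out out/ --min-refined-bp 50000 --seed 1

# evaluate against the gold standard
ensemblebin evaluate --pred out/binning.tsv --gold sim/truth.tsv \
    --lengths lengths.tsv
```

`run` accepts depth tables in either the `jgi_summarize_bam_contig_depths`
dialect (default) or a plain contig × sample matrix (`--depth-dialect
plain`), and a YAML config file (`--config`) mirroring every flag; flags
override the file. Output: `binning.tsv` (contig_id → bin_id), one FASTA
per bin, and `report.json` with k0, K, per-stage bin counts, and per-bin
selection scores.

Marker hits are supplied as a TSV (`marker_id`, `contig_id`, `copy_count`)
with an optional gene-length sidecar TSV used for seed-marker tie-breaking —
produce them with any single-copy-gene annotation workflow.

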