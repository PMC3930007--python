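# adipomir

Genomic context, co-expression and conservation analysis of the miRNAs
expressed in bulk adipose tissue.

Profiling studies of subcutaneous fat (typically a few individuals sampled
at several time points on a miRNA microarray) ask a recurring set of
questions about the detected miRNAs: where do their genes sit relative to
protein-coding genes (intergenic, intronic, exonic, or mirtron), which of
them form genomic clusters, which are conserved across vertebrates versus
specific to the species, how does expression level relate to expression
variability, which miRNAs are co-expressed tightly enough to form relevance
networks, and do intronic miRNAs track their host genes. `adipomir`
implements that analysis as a tested, reusable pipeline, together with a
synthetic-data generator that plants known truth in every one of those
structures so the whole pipeline can be exercised without any download.

## The statistics at the core

* **Location classes.** A precursor is a *mirtron* when it spans an entire
  intron, *exonic* when it overlaps ≥ 1 bp of an exon, *intronic* when it
  lies fully inside an intron, *intergenic* otherwise; precedence is
  mirtron > exonic > intronic, evaluated over all transcripts of all genes.
* **Clusters.** miRNA genes on one chromosome and strand whose consecutive
  inter-gene distance is strictly below 10 kb are chained (single linkage)
  into clusters of ≥ 2 members.
* **Normalization.** Per-array percentile shift: v ↦ log₂v − P₇₅(log₂
  values of the array).
* **Core set.** A miRNA is *core* when every individual detects it in at
  least one of that individual's time points.
* **Mean–CV power law.** Across miRNAs, mean expression y and coefficient
  of variation x follow y = a·x^b, fitted by OLS on the log-log scale; the
  Pearson correlation of (mean, CV) is reported on the original scale.
* **Relevance networks.** Edges connect miRNA pairs with Pearson R² ≥ 0.95
  over all samples (sign retained); the reported networks are the connected
  components with ≥ 2 nodes.
* **Seeds and conservation.** The seed is the first 7 nt at the 5′ end of
  the mature sequence; conservation classes come from a supplied
  TargetScan-style family table, and a seed present in no other species is
  species-specific. Predicted targets are kept at total context+ score
  ≤ −0.3 and counted per unique gene.
* **qPCR.** Technical replicates are averaged; ΔCt = Ct_target −
  Ct_reference, ΔΔCt fold change = 2^(−ΔΔCt); host-gene/miRNA co-expression
  is Pearson R of −ΔCt values with the two-tailed p from
  t = R·√(n−2)/√(1−R²).
* **Enrichment.** Right-tailed Fisher's exact test: p = P(X ≥ k) under
  Hypergeometric(N, m, n) for an overlap of k between an n-gene query and an
  m-gene set in an N-gene universe.

## Worked example

Generate a synthetic study (8 individuals × 3 time points, 155 core + 15
non-core miRNAs, six planted co-expression blocks, three planted genomic
clusters) and run the pipeline over it:

```bash
adipomir --seed 42 --out-dir fixtures simulate
adipomir --out-dir out annotate-context \
    --mirna-gff fixtures/mirna_annotation.gff3 --genes fixtures/gene_models.gff3
adipomir --out-dir out core    --matrix fixtures/expression.tsv \
    --samples fixtures/samples.tsv --no-normalize --detection-floor 0
adipomir --out-dir out stats   --matrix fixtures/expression.tsv \
    --samples fixtures/samples.tsv --no-normalize
adipomir --out-dir out network --matrix fixtures/expression.tsv \
    --samples fixtures/samples.tsv --no-normalize
```

which prints:

```
fixtures (seed 42) → fixtures
155 miRNA genes annotated; 3 clusters → out
155 core miRNAs → out/core_mirnas.txt
fit: mean = 0.637·CV^-0.9669 (r²=0.871, n=170) → out
161 edges, 6 components → out
```

Reading the output: all 155 planted core miRNAs pass the per-individual
detection rule while the 15 planted dropouts fail it; the three genomic
clusters recovered in `out/clusters.tsv` are exactly the planted ones; the
power fit over all 170 rows recovers the planted exponent b = −1 (fitted
−0.97) with mean and CV anti-correlated; and the six network components in
`out/components.json` (sizes 14, 12, 2, 2, 2, 2) are exactly the planted
co-expression blocks. The matrix here is already on the analysis scale, so
normalization is skipped; for raw array intensities drop `--no-normalize`
and the 75th-percentile log₂ shift is applied first.

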