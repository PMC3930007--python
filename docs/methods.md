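# Methods

This note documents the models, conventions and design choices behind each
stage of `adipomir`, the defaults that matter, and what the synthetic-data
generator does and does not emulate.

## Coordinates and annotation parsing

All genomic intervals are held internally as 0-based half-open on an
explicit strand; GFF3/GTF input (1-based inclusive) is converted on read
and back on write, so a round trip reproduces the original integers and an
interval's length always equals `gff_end − gff_start + 1`. Strand `.` is
rejected for miRNA and gene features because both the cluster rule and
host-orientation reporting are meaningless without it.

The miRNA annotation dialect is the miRBase one (precursor records of type
`miRNA_primary_transcript`, matures of type `miRNA` linked by
`Derives_from`). Link resolution is two-pass, so files listing matures
before precursors parse identically — parsing is input-order independent.
Mature products sharing one name across loci are merged into a single
object carrying all coding gene ids (the way a mature coded on two
chromosomes is treated as one miRNA species); the merged record keeps the
lexicographically smallest record ID so the result is order-stable.
Protein-coding gene models go through `gffutils`; GTF files carrying only
exon lines are accepted, with gene and transcript spans inferred from exon
extents.

## Location classification

Classes: **mirtron** (precursor boundaries equal an intron's, within
`mirtron_tolerance`, default 0 nt since a mirtron is *defined* by spanning
the entire intron; the tolerance exists because annotation boundary jitter
is common), **exonic** (≥ 1 bp exon overlap), **intronic** (fully inside an
intron, no exon overlap), **intergenic** (none of the above). Precedence is
mirtron > exonic > intronic, applied across *all* transcripts of all genes:
a precursor intronic in one isoform but overlapping an exon of another is
exonic. Every host qualifying at the winning level is listed — a precursor
inside introns of two overlapping genes reports both hosts. Host strand is
not a requirement for hosting; sense/antisense orientation is recorded per
host. A precursor on a chromosome absent from the gene models is called
intergenic with an `unplaced` flag and a warning rather than failing the
run.

Location tallies are reported with both denominators (precursor genes and
mature products) because the two disagree whenever matures are coded at
multiple loci; published per-class percentages depend on which denominator
was used, so the table shows both rather than reconciling them.

## Cluster detection

Per (chromosome, strand), genes sorted by start are chained when
`next.start − running_max_end < max_gap` (default 10 000 bp, strict `<`;
a gap of exactly 10 kb does not cluster). The running maximum end makes
overlapping or nested precursors (negative gap) always chain. Chaining is
single linkage, i.e. the transitive closure of the pairwise
same-strand-distance relation — the reading under which a long polycistron
is one cluster — and the test suite verifies equality with a brute-force
union-find closure on random fixtures up to 200 genes. The gap metric is
end-to-start distance between precursor intervals; "inter-miRNA distance"
is not otherwise pinned down, and end-to-start is the conservative choice.
`max_gap` is configurable. Cluster ids are assigned after sorting clusters
by (chromosome, span start, strand), so numbering is deterministic.

A mature miRNA is *clustered* when any of its coding loci is in a cluster,
and its location classes are the set over loci.

## Normalization, core set, summaries

Percentile-shift normalization: per sample, intensities are log-transformed
(base 2 by default; non-positive values are masked to missing first) and
shifted so the sample's 75th percentile sits at `offset` (default 0).
Percentiles use linear interpolation between order statistics (numpy's
default, the classic "type 7"); the convention is recorded in the output
metadata because array-suite internals differ. With `log=False` the shift
is applied to an already-log matrix, which makes re-application a no-op.

Core-set rule: the default reading is *per-individual-any-time* — a miRNA
is core iff every individual detects it in at least one of that
individual's samples. The stricter alternative (one common time point at
which all individuals detect it) is available as
`rule="common-timepoint"`; the sentence defining core sets is genuinely
ambiguous between the two, and the default attaches "in at least one time
point" to each individual. Detection is either a supplied flag matrix or
`value > floor` (strict), with `floor` defaulting to the matrix minimum —
arrays exported without detection flags then treat only the floor-valued
(masked) entries as undetected. Raising the floor can only shrink the core
set.

Per-miRNA summaries use the sample standard deviation (n − 1) across all
samples on the normalized (log) scale; CV = sd/mean is flagged undefined
when the mean is ≤ 0. The mean–CV trend y = a·x^b (y mean, x CV) is fitted
by OLS of log mean on log CV over points with mean > 0 and CV > 0; `a` is
the exponentiated intercept, `r²` the log-log coefficient of
determination, and the Pearson R of (mean, CV) is also reported on the
untransformed scale. Degenerate inputs (constant mean, < 3 usable points)
give b = 0 / r² = 0 or an error respectively.

Category comparisons use a pooled-variance two-tailed t-test for two groups
(Welch behind a flag; pooled is the classical default the emulated analyses
used) and one-way ANOVA plus Tukey HSD at α = 0.05 for three or more. With
two groups ANOVA reproduces the t-test (F = t²). Raw p-values are reported
by default; Benjamini–Hochberg is optional where multiple sets are tested
(enrichment output).

## Relevance networks

Edges connect pairs with R² ≥ threshold (default 0.95, inclusive following
the stricter of the two published phrasings; configurable). Negative
correlations qualify and the sign travels with the edge. "Networks" are
connected components (size ≥ 2) of the edge graph, not cliques — chained
co-expression counts — ordered by size descending, then lexicographically.
Zero-variance rows are excluded from the correlation matrix with a warning
naming them. Component reports tally conservation composition, clustered
members and the cluster ids involved; nodes without attributes are counted
as "unknown".

## qPCR and host co-expression

Replicates are aggregated by arithmetic mean per (sample, assay); the
replicate SD is reported and flagged above a configurable limit (default
0.5 cycles) or when undefined (single replicate). Missing (sample, assay)
pairs go to a gap report rather than raising. ΔCt = Ct_target −
Ct_reference per sample; ΔΔCt = ΔCt_sample − ΔCt_calibrator and fold
change 2^(−ΔΔCt). Reference assays are configuration entries defaulting to
bta-miR-181a (miRNA side) and ACTB (gene side).

Correlation runs on **−ΔCt** — lower Ct means more template, so the sign
convention makes positive R mean co-expression; this matters when
comparing against tables whose input scale is unstated. Incomplete sample
pairs are dropped listwise per pair; n ≥ 3 is required. The two-tailed p
comes from the exact t transform t = R·√(n−2)/√(1−R²) on n − 2 df, which
the tests check against both `scipy.stats.pearsonr` and a 10 000-draw
permutation null. At n = 12 the transform reproduces published
host-gene/miRNA p-values from their printed R (0.624 → 0.030, 0.635 →
0.027); for near-zero printed correlations the transform can differ in the
third decimal from published values (rounding of printed R, or missing
samples, in the source — not reconciled here).

## Seeds, conservation, target filtering

The seed defaults to positions 1–7 of the mature sequence (the definition
used in the emulated analysis) even though the common database convention
is 2–8; the window is configurable and echoed in the CLI output so results
are auditable. Sequences are uppercased and DNA→RNA normalized. Matures
sharing a seed are grouped into one slash-joined entry (members sorted
lexicographically).

Conservation classes are *labels copied from a user-supplied seed-family
table* — they are database annotations, not computations — and species
specificity means the seed occurs in no species besides the focal one in
that table; it is therefore always relative to the supplied snapshot. A
species-specific seed is by definition lineage-young, so it is forced to
the poorly conserved class (with a warning if the table disagrees); seeds
absent from the table are called poorly conserved and flagged
out-of-table. Target predictions are filtered at total context+ score
≤ cutoff (default −0.3, inclusive) and counted per unique target gene, so
a gene with several qualifying sites counts once.

## Enrichment

Right-tailed Fisher's exact test, computed as the hypergeometric survival
function P(X ≥ k); the tests pin it to a brute-force binomial-coefficient
summation within 1e-12 for all universes up to 200 genes. The universe is
always explicit — no default universe ships, because any universe
convention (all annotated genes, all mapped genes, …) changes p-values,
and all four counts (k, n, m, N) are reported so the choice can be
audited. Symbol matching is case-insensitive exact; no alias resolution
(a known limitation).

## Synthetic data

The generator emulates the design of the motivating study class: 8
individuals × 3 time points (24 samples, two diet groups), 155 core
miRNAs, a location-class mix of 59.5 % intergenic / 38.7 % intronic /
1.2 % exonic / 0.6 % mirtron (apportioned by largest remainder), three
planted clusters (6, 3 and 2 members with 5/4/8 kb gaps), one mature coded
at two loci, six co-expression blocks of sizes 14/12/2/2/2/2 (34 miRNAs,
matching the published network sizes), a mean–CV power law with a = 0.6,
b = −1 and log-noise σ = 0.2, 15 planted non-core rows, and a 12-sample
qPCR panel with one coupled (ρ = 0.9) and one uncoupled host/miRNA pair
plus near-constant reference assays.

Mechanics worth knowing:

* **Geometry.** Annotation "units" (a host gene with one resident miRNA,
  an intergenic precursor, or a cluster run) are separated by more than
  the 10 kb rule bound, so nothing clusters or gains a host by accident
  and the classifier/cluster detector must recover exactly the planted
  truth — which the acceptance checks assert at 100 %.
* **Expression.** Values are log-normal: for target mean μ and CV c,
  τ² = ln(1 + c²) and v = exp(ln μ − τ²/2 + τz), which keeps intensities
  strictly positive without truncation bias. Block members share z through
  a latent factor (z = √ρ·f + √(1−ρ)·e, ρ = 0.997) and are assigned the
  low-CV/high-expression end (0.05–0.2), as tightly co-expressed panels
  are in real arrays; for those CVs the realized Pearson correlation is
  ≈ ρ and comfortably above √0.95 at n = 24. Non-block rows draw CV
  log-uniformly over 0.05–1.5 (the span seen between the most stable and
  most variable miRNAs in such data) and the mean follows the power law
  with multiplicative log-normal noise. Fitting the emitted data recovers
  the planted exponent within ±0.1 across seeds; mild attenuation (the
  sample CV is itself noisy at n = 24) keeps the recovered slope slightly
  shy of the planted value, which is expected and documented rather than
  corrected.
* **Non-core rows** are zeroed for every sample of one random individual;
  with a detection floor of 0 they fail the core rule by construction.
* **qPCR.** Target and reference assays share a per-sample loading offset
  (RNA input), which ΔCt removes by design; the planted coupling is
  therefore the population correlation of the ΔCt-derived expressions, up
  to replicate scatter (σ = 0.1 cycles over 3 replicates) and a small
  reference-specific noise (σ = 0.1). At n = 12 the sampled correlation
  around a planted 0.9 still varies noticeably between seeds; recovery
  checks use a fixed seed for that reason.
* **Determinism.** One seeded generator per product (annotation,
  expression, qPCR use seed, seed+1, seed+2); the same config and seed
  give byte-identical files, and every emitted file parses back through
  the package's own readers with zero warnings.

What the generator does **not** emulate: probe-sequence (GC) intensity
bias, background/saturation effects of array scanning, heavier-tailed
intensity distributions, diet or time-point effects (none are planted —
group labels are metadata only), and annotation edge cases like
overlapping host genes (covered by handcrafted fixtures in the tests
instead). Passing the planted-truth checks therefore demonstrates
correctness of the algorithms under the stated geometry and noise model,
not robustness to real-array artefacts.

## Problem sizes and bundled data

All tests and the acceptance script run at the study's own scale — 155
miRNAs × 24 samples, clusters of ≤ 6, universes of ≤ 200 genes for the
brute-force cross-checks — chosen because the methods themselves are
desk-scale; everything completes in seconds. Two small published tables
ship as package data (the 23-row bovine-specific miRNA panel and the
core-set composition counts) so the re-tally computations have their
inputs locally. Headline quantities that require the original 24-array
dataset (the 224-detected/155-core split, the exact power-fit
coefficients, the observed mean–CV Pearson R) are not asserted against;
the pipeline computes their analogues on synthetic data, and the CLI
accepts any locally exported intensity matrix and sample sheet for real
data.
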