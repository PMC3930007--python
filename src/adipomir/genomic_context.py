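"""Genomic-context classification and cluster detection for miRNA genes.

Each precursor locus is placed in exactly one of four classes relative to
protein-coding gene models:

* ``mirtron``   — the precursor spans an entire intron (boundaries equal the
  intron's, within a configurable tolerance);
* ``exonic``    — the precursor overlaps ≥1 bp of some exon;
* ``intronic``  — the precursor lies fully inside an intron with no exon
  overlap;
* ``intergenic``— none of the above (outside transcription units).

Precedence is mirtron > exonic > intronic > intergenic, evaluated across all
transcripts of all genes, so a precursor intronic in one isoform but exonic
in another is called exonic.  Host-gene strand is not a requirement for
hosting; the sense/antisense orientation is recorded per host.

Clusters follow the classic genomic-distance rule: miRNA genes on the same
chromosome and strand whose consecutive inter-gene gap is strictly less than
10 kb are chained (single linkage) into one cluster; clusters have ≥2
members.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .io_formats import GeneModel, GenomicInterval, MatureMiRNA, MiRNAGene

logger = logging.getLogger(__name__)

LOCATION_CLASSES = ("intergenic", "intronic", "exonic", "mirtron")
_PRECEDENCE = {"mirtron": 3, "exonic": 2, "intronic": 1, "intergenic": 0}

DEFAULT_MAX_GAP = 10_000  # bp, strict upper bound on inter-miRNA distance


@dataclass
class ContextAnnotation:
    gene_id: str
    location_class: str
    host_gene_ids: list[str] = field(default_factory=list)
    host_orientation: dict[str, str] = field(default_factory=dict)
    cluster_id: str | None = None
    unplaced: bool = False  # precursor chromosome absent from gene models

    def __post_init__(self) -> None:
        if self.location_class not in LOCATION_CLASSES:
            raise ValueError(f"unknown location class {self.location_class!r}")
        if (self.location_class == "intergenic") != (not self.host_gene_ids):
            raise ValueError(
                f"{self.gene_id}: hosts inconsistent with class "
                f"{self.location_class}"
            )


@dataclass
class Cluster:
    cluster_id: str
    gene_ids: list[str]  # ordered by start
    chrom: str
    strand: str
    span: GenomicInterval

    def __post_init__(self) -> None:
        if len(self.gene_ids) < 2:
            raise ValueError("a cluster needs at least 2 members")


@dataclass
class MatureContext:
    """Context of a mature miRNA aggregated over all its coding loci."""

    mature_id: str
    name: str
    location_classes: frozenset[str]
    clustered: bool
    loci: list[tuple[str, str, str | None]]  # (gene_id, class, cluster_id)


# ---------------------------------------------------------------------------
# Introns
# ---------------------------------------------------------------------------

def derive_introns(gene: GeneModel) -> list[tuple[str, list[GenomicInterval]]]:
    """Introns per transcript: the gaps between consecutive exons."""
    out: list[tuple[str, list[GenomicInterval]]] = []
    for tid, exons in gene.transcripts:
        introns = [
            GenomicInterval(prev.chrom, prev.end, cur.start, prev.strand)
            for prev, cur in zip(exons, exons[1:])
            if cur.start > prev.end
        ]
        out.append((tid, introns))
    return out


# ---------------------------------------------------------------------------
# Location classification
# ---------------------------------------------------------------------------

def classify_location(mirna: MiRNAGene, genes: list[GeneModel],
                      mirtron_tolerance: int = 0) -> ContextAnnotation:
    """Classify one precursor against all gene models.

    All hosts qualifying at the winning precedence level are listed, e.g. a
    precursor inside introns of two overlapping genes gets both as hosts.
    """
    locus = mirna.locus
    known_chroms = {g.locus.chrom for g in genes}
    if genes and locus.chrom not in known_chroms:
        logger.warning(
            "precursor %s on chromosome %s absent from gene models; "
            "calling intergenic", mirna.gene_id, locus.chrom
        )
        return ContextAnnotation(mirna.gene_id, "intergenic", unplaced=True)

    hosts_by_class: dict[str, list[GeneModel]] = {
        "mirtron": [], "exonic": [], "intronic": []
    }
    for gene in genes:
        if gene.locus.chrom != locus.chrom or gene.locus.overlap(locus) == 0:
            continue
        gene_class = None
        for _tid, exons in gene.transcripts:
            if any(ex.overlap(locus) > 0 for ex in exons):
                gene_class = _max_class(gene_class, "exonic")
        for _tid, introns in derive_introns(gene):
            for intron in introns:
                if (abs(locus.start - intron.start) <= mirtron_tolerance
                        and abs(locus.end - intron.end) <= mirtron_tolerance):
                    gene_class = _max_class(gene_class, "mirtron")
                elif intron.contains(locus):
                    gene_class = _max_class(gene_class, "intronic")
        if gene_class is not None:
            hosts_by_class[gene_class].append(gene)

    for cls in ("mirtron", "exonic", "intronic"):
        if hosts_by_class[cls]:
            hosts = sorted(hosts_by_class[cls], key=lambda g: g.gene_id)
            return ContextAnnotation(
                mirna.gene_id,
                cls,
                host_gene_ids=[g.gene_id for g in hosts],
                host_orientation={
                    g.gene_id: ("sense" if g.locus.strand == locus.strand
                                else "antisense")
                    for g in hosts
                },
            )
    return ContextAnnotation(mirna.gene_id, "intergenic")


def _max_class(current: str | None, candidate: str) -> str:
    if current is None or _PRECEDENCE[candidate] > _PRECEDENCE[current]:
        return candidate
    return current


# ---------------------------------------------------------------------------
# Cluster detection
# ---------------------------------------------------------------------------

def detect_clusters(mirnas: list[MiRNAGene],
                    max_gap: int = DEFAULT_MAX_GAP) -> list[Cluster]:
    """Chain same-chromosome, same-strand precursors with gap < ``max_gap``.

    The gap between consecutive genes (sorted by start) is
    ``next.start − prev.end`` where ``prev.end`` is the running maximum end,
    so overlapping or nested precursors (negative gap) always chain.
    Maximal chains of ≥2 members become clusters; chaining is single-linkage,
    matching the transitive closure of the pairwise <max_gap relation.
    """
    groups: dict[tuple[str, str], list[MiRNAGene]] = {}
    for g in mirnas:
        groups.setdefault((g.locus.chrom, g.locus.strand), []).append(g)

    clusters: list[Cluster] = []
    for (chrom, strand) in sorted(groups):
        members = sorted(groups[(chrom, strand)],
                         key=lambda g: (g.locus.start, g.locus.end, g.gene_id))
        chain: list[MiRNAGene] = []
        reach_end = None
        for g in members + [None]:  # sentinel flushes the last chain
            if g is not None and chain and g.locus.start - reach_end < max_gap:
                chain.append(g)
                reach_end = max(reach_end, g.locus.end)
                continue
            if len(chain) >= 2:
                span = GenomicInterval(
                    chrom, chain[0].locus.start,
                    max(m.locus.end for m in chain), strand
                )
                clusters.append(Cluster(
                    cluster_id="",  # assigned after global ordering
                    gene_ids=[m.gene_id for m in chain],
                    chrom=chrom, strand=strand, span=span,
                ))
            if g is not None:
                chain = [g]
                reach_end = g.locus.end
    clusters.sort(key=lambda c: (c.chrom, c.span.start, c.strand))
    for i, c in enumerate(clusters, start=1):
        c.cluster_id = f"cluster_{i:03d}"
    return clusters


def assign_clusters(annotations: list[ContextAnnotation],
                    clusters: list[Cluster]) -> None:
    """Fill ``cluster_id`` on annotations in place."""
    member_of = {gid: c.cluster_id for c in clusters for gid in c.gene_ids}
    for ann in annotations:
        ann.cluster_id = member_of.get(ann.gene_id)


def annotate_all(mirnas: list[MiRNAGene], genes: list[GeneModel],
                 max_gap: int = DEFAULT_MAX_GAP,
                 mirtron_tolerance: int = 0,
                 ) -> tuple[list[ContextAnnotation], list[Cluster]]:
    """Classify every precursor and attach cluster membership."""
    annotations = [classify_location(m, genes, mirtron_tolerance)
                   for m in mirnas]
    clusters = detect_clusters(mirnas, max_gap)
    assign_clusters(annotations, clusters)
    return annotations, clusters


# ---------------------------------------------------------------------------
# Mature-level summary
# ---------------------------------------------------------------------------

def mature_context(matures: list[MatureMiRNA],
                   annotations: list[ContextAnnotation]) -> list[MatureContext]:
    """Aggregate per-locus context to mature products.

    A mature is clustered when ANY of its coding loci is in a cluster; its
    location classes are the set over loci (a mature may be intronic on one
    chromosome and intergenic on another).
    """
    ann_by_gene = {a.gene_id: a for a in annotations}
    out: list[MatureContext] = []
    for mat in matures:
        loci: list[tuple[str, str, str | None]] = []
        for gid in mat.gene_ids:
            if gid not in ann_by_gene:
                raise KeyError(
                    f"mature {mat.name}: no context annotation for gene {gid!r}"
                )
            ann = ann_by_gene[gid]
            loci.append((gid, ann.location_class, ann.cluster_id))
        out.append(MatureContext(
            mature_id=mat.mature_id,
            name=mat.name,
            location_classes=frozenset(cls for _, cls, _ in loci),
            clustered=any(cid is not None for _, _, cid in loci),
            loci=loci,
        ))
    return out


# ---------------------------------------------------------------------------
# Tabular reports
# ---------------------------------------------------------------------------

def context_table(mirnas: list[MiRNAGene],
                  annotations: list[ContextAnnotation]) -> pd.DataFrame:
    gene_by_id = {g.gene_id: g for g in mirnas}
    rows = []
    for ann in annotations:
        g = gene_by_id[ann.gene_id]
        rows.append({
            "gene_id": ann.gene_id,
            "name": g.name,
            "chrom": g.locus.chrom,
            "start": g.locus.start,
            "end": g.locus.end,
            "strand": g.locus.strand,
            "location_class": ann.location_class,
            "hosts": ",".join(ann.host_gene_ids) or "-",
            "orientation": ",".join(
                ann.host_orientation[h] for h in ann.host_gene_ids) or "-",
            "cluster_id": ann.cluster_id or "-",
        })
    return pd.DataFrame(rows)


def cluster_table(clusters: list[Cluster]) -> pd.DataFrame:
    rows = [{
        "cluster_id": c.cluster_id,
        "chrom": c.chrom,
        "strand": c.strand,
        "start": c.span.start,
        "end": c.span.end,
        "n_members": len(c.gene_ids),
        "members": ",".join(c.gene_ids),
    } for c in clusters]
    return pd.DataFrame(rows)


def location_tally(annotations: list[ContextAnnotation],
                   matures: list[MatureContext] | None = None) -> pd.DataFrame:
    """Per-gene (and optionally per-mature) location-class tallies.

    Published per-class percentages can differ depending on whether the
    denominator is precursor genes or mature products, so both tallies are
    reported side by side rather than reconciled.
    """
    rows = []
    n_genes = len(annotations)
    for cls in LOCATION_CLASSES:
        k = sum(a.location_class == cls for a in annotations)
        row = {"location_class": cls, "n_genes": k,
               "pct_genes": 100.0 * k / n_genes if n_genes else float("nan")}
        if matures is not None:
            km = sum(cls in m.location_classes for m in matures)
            row["n_matures"] = km
            row["pct_matures"] = (100.0 * km / len(matures)
                                  if matures else float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)
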