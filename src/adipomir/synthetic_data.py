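"""Synthetic annotation, expression and qPCR fixtures with known ground truth.

The generator emulates the design of a bulk adipose-tissue miRNA profiling
study: 8 individuals sampled at 3 time points (24 arrays), a panel of ~155
core miRNAs whose mean expression and coefficient of variation follow an
approximate power law (mean = a·CV^b with b ≈ −1), co-expression blocks
driven by shared latent factors, miRNA genes planted in every genomic
context class (intergenic / intronic / exonic / mirtron) and in sub-10 kb
genomic clusters, and a 12-sample qPCR panel in which host-gene and
intronic-miRNA assays share a latent factor at a configurable coupling.

Construction notes
------------------
* Expression values are log-normal: given a target mean μ and CV c,
  τ² = ln(1 + c²) and values are exp(ln μ − τ²/2 + τ·z).  Block members
  share z through a common factor (z = √ρ·f + √(1−ρ)·e), which keeps all
  values strictly positive (no truncation bias) and puts the within-block
  Pearson correlation at ≈ ρ for the small CVs used in blocks.
* Annotation geometry is laid out as "units" (a host gene, an intergenic
  precursor, or an intergenic cluster run) separated by more than the
  cluster gap limit, so nothing clusters or gains a host by accident.
* qPCR Ct values share a per-sample loading offset between target and
  reference assays; ΔCt against the reference removes it, so the planted
  coupling is the population correlation of the ΔCt-derived expressions.
* All randomness flows through one seeded generator per product; the same
  config and seed give byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    GeneModel,
    GenomicInterval,
    MatureMiRNA,
    MiRNAGene,
    SampleSheet,
    write_gene_models_gff3,
    write_mirna_gff,
)

DEFAULT_SEED = 42

#: fractions of miRNA genes per location class, in the order
#: (intergenic, intronic, exonic, mirtron) — the mix observed in adipose
#: core-miRNA annotation work.
DEFAULT_CLASS_FRACTIONS = (0.595, 0.387, 0.012, 0.006)


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults mirror the emulated study."""

    seed: int = DEFAULT_SEED

    # --- annotation geometry ---
    n_chromosomes: int = 5
    n_mirna_genes: int = 155
    class_fractions: tuple[float, float, float, float] = DEFAULT_CLASS_FRACTIONS
    planted_clusters: tuple[tuple[int, int], ...] = ((6, 5000), (3, 4000),
                                                     (2, 8000))  # (size, gap bp)
    n_background_genes: int = 5    # host-free protein-coding genes
    exons_per_gene: int = 4
    exon_len: int = 300
    intron_len: int = 2000
    precursor_len: int = 80
    n_shared_matures: int = 1      # matures coded at two loci
    max_gap: int = 10_000          # cluster rule bound the geometry respects

    # --- expression ---
    n_individuals: int = 8
    n_timepoints: int = 3
    block_sizes: tuple[int, ...] = (14, 12, 2, 2, 2, 2)
    block_r: float = 0.997         # latent within-block correlation
    block_cv_range: tuple[float, float] = (0.05, 0.2)
    power_a: float = 0.6
    power_b: float = -1.0
    power_sigma: float = 0.2       # log-scale noise around the power law
    cv_range: tuple[float, float] = (0.05, 1.5)
    n_noncore: int = 15            # rows undetected in one individual

    # --- qPCR ---
    n_qpcr_samples: int = 12
    qpcr_replicates: int = 3
    replicate_sd: float = 0.1      # cycles, technical replicate scatter
    qpcr_pairs: tuple[tuple[str, str, float], ...] = (
        ("HOSTA", "sim-miR-hostA", 0.9),
        ("HOSTB", "sim-miR-hostB", 0.0),
    )
    mirna_reference: str = "bta-miR-181a"
    gene_reference: str = "ACTB"
    ct_scale: float = 1.5          # cycles per latent-expression unit
    loading_sd: float = 0.5        # per-sample RNA-input offset, cycles
    reference_noise_sd: float = 0.1  # reference-specific scatter, cycles

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if abs(sum(self.class_fractions) - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1")
        for size, gap in self.planted_clusters:
            if size < 2:
                raise ValueError("planted clusters need ≥2 members")
            if gap >= self.max_gap:
                raise ValueError(
                    f"planted cluster gap {gap} must be < {self.max_gap}"
                )
        if sum(self.block_sizes) > self.n_mirna_genes:
            raise ValueError("block sizes exceed miRNA count")
        if not -1 < self.block_r < 1:
            raise ValueError("block_r must be in (-1, 1)")
        for _, _, r in self.qpcr_pairs:
            if not -1 < r < 1:
                raise ValueError(f"qPCR coupling target {r} outside (-1, 1)")

    @property
    def n_samples(self) -> int:
        return self.n_individuals * self.n_timepoints


@dataclass
class GroundTruth:
    """Planted truth emitted alongside every synthetic artefact."""

    location_class: dict[str, str] = field(default_factory=dict)
    hosts: dict[str, list[str]] = field(default_factory=dict)
    clusters: list[list[str]] = field(default_factory=list)
    mature_of_gene: dict[str, str] = field(default_factory=dict)
    blocks: list[list[str]] = field(default_factory=list)
    power_a: float | None = None
    power_b: float | None = None
    planted_mean: dict[str, float] = field(default_factory=dict)
    planted_cv: dict[str, float] = field(default_factory=dict)
    core: list[str] = field(default_factory=list)
    noncore: list[str] = field(default_factory=list)
    qpcr_coupling: dict[str, float] = field(default_factory=dict)
    qpcr_base_ct: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def _class_counts(n: int, fractions) -> dict[str, int]:
    """Largest-remainder apportionment of n genes to the four classes."""
    classes = ("intergenic", "intronic", "exonic", "mirtron")
    raw = {c: n * f for c, f in zip(classes, fractions)}
    counts = {c: int(math.floor(v)) for c, v in raw.items()}
    short = n - sum(counts.values())
    for c in sorted(classes, key=lambda c: raw[c] - counts[c], reverse=True):
        if short == 0:
            break
        counts[c] += 1
        short -= 1
    return counts


@dataclass
class AnnotationSim:
    mirna_genes: list[MiRNAGene]
    matures: list[MatureMiRNA]
    gene_models: list[GeneModel]
    truth: GroundTruth
    config: SimulationConfig

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        mirna_path = out / "mirna_annotation.gff3"
        genes_path = out / "gene_models.gff3"
        write_mirna_gff(self.mirna_genes, self.matures, mirna_path)
        write_gene_models_gff3(self.gene_models, genes_path)
        return {"mirna_gff": mirna_path, "gene_models": genes_path}


class _ChromLayout:
    """Cursor-based placement keeping units > max_gap apart."""

    def __init__(self, config: SimulationConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        self.cursor = {f"chr{i + 1}": 10_000
                       for i in range(config.n_chromosomes)}
        self.order = sorted(self.cursor)
        self._next = 0

    def place(self, length: int) -> tuple[str, int]:
        """Reserve ``length`` bp on the next chromosome (round-robin)."""
        chrom = self.order[self._next % len(self.order)]
        self._next += 1
        start = self.cursor[chrom]
        margin = self.config.max_gap + 2000 + int(self.rng.integers(0, 3000))
        self.cursor[chrom] = start + length + margin
        return chrom, start


def simulate_annotation(config: SimulationConfig | None = None) -> AnnotationSim:
    """Plant miRNA genes of every context class plus genomic clusters."""
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth()
    layout = _ChromLayout(config, rng)

    counts = _class_counts(config.n_mirna_genes, config.class_fractions)
    n_clustered = sum(size for size, _ in config.planted_clusters)
    if n_clustered > counts["intergenic"]:
        raise ValueError("planted clusters exceed the intergenic allotment")

    mirna_genes: list[MiRNAGene] = []
    gene_models: list[GeneModel] = []
    mature_name: dict[str, str] = {}   # gene_id -> mature name
    serial = 0

    def next_ids() -> tuple[str, str, str]:
        nonlocal serial
        serial += 1
        return (f"SIM{serial:04d}", f"sim-mir-{serial}", f"sim-miR-{serial}")

    def new_host_gene(chrom: str, start: int, strand: str,
                      idx: int) -> GeneModel:
        exons = []
        pos = start
        for _ in range(config.exons_per_gene):
            exons.append(GenomicInterval(chrom, pos, pos + config.exon_len,
                                         strand))
            pos += config.exon_len + config.intron_len
        locus = GenomicInterval(chrom, start, exons[-1].end, strand)
        gid = f"HOST{idx:04d}"
        return GeneModel(gene_id=gid, name=gid, locus=locus,
                         transcripts=[(f"{gid}.t1", exons)])

    host_idx = 0
    gene_len = (config.exons_per_gene * config.exon_len
                + (config.exons_per_gene - 1) * config.intron_len)

    # hosted classes: one miRNA per host gene
    for cls in ("intronic", "exonic", "mirtron"):
        for _ in range(counts[cls]):
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            chrom, start = layout.place(gene_len)
            host_idx += 1
            host = new_host_gene(chrom, start, strand, host_idx)
            gene_models.append(host)
            introns = [
                GenomicInterval(chrom, a.end, b.start, strand)
                for a, b in zip(host.transcripts[0][1],
                                host.transcripts[0][1][1:])
            ]
            gid, gname, mname = next_ids()
            if cls == "intronic":
                intron = introns[int(rng.integers(0, len(introns)))]
                m_start = intron.start + 200
                locus = GenomicInterval(chrom, m_start,
                                        m_start + config.precursor_len, strand)
            elif cls == "mirtron":
                intron = introns[int(rng.integers(0, len(introns)))]
                locus = GenomicInterval(chrom, intron.start, intron.end, strand)
            else:  # exonic: straddle an interior exon boundary
                exon = host.transcripts[0][1][1]
                half = config.precursor_len // 2
                locus = GenomicInterval(chrom, exon.start - half,
                                        exon.start + half, strand)
            mirna_genes.append(MiRNAGene(gid, gname, locus, [mname]))
            mature_name[gid] = mname
            truth.location_class[gid] = cls
            truth.hosts[gid] = [host.gene_id]

    # intergenic clusters
    for size, gap in config.planted_clusters:
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        run_len = size * config.precursor_len + (size - 1) * gap
        chrom, start = layout.place(run_len)
        members = []
        pos = start
        for _ in range(size):
            gid, gname, mname = next_ids()
            locus = GenomicInterval(chrom, pos, pos + config.precursor_len,
                                    strand)
            mirna_genes.append(MiRNAGene(gid, gname, locus, [mname]))
            mature_name[gid] = mname
            truth.location_class[gid] = "intergenic"
            truth.hosts[gid] = []
            members.append(gid)
            pos += config.precursor_len + gap
        truth.clusters.append(members)

    # intergenic singletons
    for _ in range(counts["intergenic"] - n_clustered):
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        chrom, start = layout.place(config.precursor_len)
        gid, gname, mname = next_ids()
        locus = GenomicInterval(chrom, start, start + config.precursor_len,
                                strand)
        mirna_genes.append(MiRNAGene(gid, gname, locus, [mname]))
        mature_name[gid] = mname
        truth.location_class[gid] = "intergenic"
        truth.hosts[gid] = []

    # background genes hosting nothing
    for _ in range(config.n_background_genes):
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        chrom, start = layout.place(gene_len)
        host_idx += 1
        gene_models.append(new_host_gene(chrom, start, strand, host_idx))

    # shared matures: one mature name coded at an intronic and an
    # intergenic, non-clustered locus (multi-locus products exist in real
    # annotations, e.g. a miRNA coded on two chromosomes)
    clustered_ids = {g for c in truth.clusters for g in c}
    intronic_ids = [g for g, c in truth.location_class.items()
                    if c == "intronic"]
    lone_intergenic = [g for g, c in truth.location_class.items()
                       if c == "intergenic" and g not in clustered_ids]
    for k in range(config.n_shared_matures):
        if k >= len(intronic_ids) or k >= len(lone_intergenic):
            break
        shared = f"sim-miR-dual-{k + 1}"
        for gid in (intronic_ids[k], lone_intergenic[k]):
            mature_name[gid] = shared

    matures: dict[str, MatureMiRNA] = {}
    for gene in mirna_genes:
        name = mature_name[gene.gene_id]
        gene.mature_ids = [name]
        mat = matures.setdefault(name, MatureMiRNA(mature_id=name, name=name))
        mat.gene_ids.append(gene.gene_id)
    for mat in matures.values():
        mat.gene_ids.sort()
    truth.mature_of_gene = dict(mature_name)

    mirna_genes.sort(key=lambda g: (g.locus, g.gene_id))
    gene_models.sort(key=lambda g: (g.locus, g.gene_id))
    return AnnotationSim(
        mirna_genes=mirna_genes,
        matures=sorted(matures.values(), key=lambda m: m.name),
        gene_models=gene_models,
        truth=truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

@dataclass
class ExpressionSim:
    matrix: pd.DataFrame          # miRNA × sample, analysis-scale intensities
    sheet: SampleSheet
    truth: GroundTruth
    config: SimulationConfig

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        matrix_path = out / "expression.tsv"
        sheet_path = out / "samples.tsv"
        self.matrix.to_csv(matrix_path, sep="\t", index_label="mirna",
                           float_format="%.6g")
        self.sheet.write(sheet_path)
        return {"expression": matrix_path, "sample_sheet": sheet_path}


def _sample_sheet(config: SimulationConfig) -> SampleSheet:
    rows = []
    half = config.n_individuals // 2
    for i in range(config.n_individuals):
        ind = f"steer{i + 1}"
        group = "control" if i < half else "highfat"
        for t in range(config.n_timepoints):
            rows.append({
                "sample_id": f"{ind}_T{t + 1}",
                "individual_id": ind,
                "time_point": f"T{t + 1}",
                "group": group,
            })
    df = pd.DataFrame(rows).set_index("sample_id")
    return SampleSheet(df)


def simulate_expression(config: SimulationConfig | None = None) -> ExpressionSim:
    """Correlated-block, power-law expression over 8×3 samples.

    Rows follow mean = a·CV^b·exp(σ·ε); block members (assigned the
    low-CV/high-expression end, as co-expressed panels are in real arrays)
    share a latent factor per sample.  ``n_noncore`` extra rows are zeroed
    for every sample of one individual — negative controls for the core
    rule.
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    truth = GroundTruth(power_a=config.power_a, power_b=config.power_b)
    sheet = _sample_sheet(config)
    samples = sheet.sample_ids
    n_core, n_samples = config.n_mirna_genes, len(samples)

    names = [f"sim-miR-{i + 1:04d}" for i in range(n_core)]
    n_block = sum(config.block_sizes)

    # CVs: block members from the narrow low range, the rest log-uniform
    lo, hi = config.block_cv_range
    block_cv = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n_block))
    lo, hi = config.cv_range
    free_cv = np.exp(rng.uniform(math.log(lo), math.log(hi),
                                 size=n_core - n_block))
    cv = np.concatenate([np.sort(block_cv), free_cv])

    noise = rng.normal(0.0, config.power_sigma, size=n_core)
    mean = config.power_a * cv ** config.power_b * np.exp(noise)

    # latent z with block structure
    z = rng.normal(size=(n_core, n_samples))
    start = 0
    rho = config.block_r
    for b, size in enumerate(config.block_sizes):
        factor = rng.normal(size=n_samples)
        idx = slice(start, start + size)
        z[idx, :] = (math.sqrt(rho) * factor
                     + math.sqrt(1 - rho) * z[idx, :])
        truth.blocks.append(names[start:start + size])
        start += size

    tau = np.sqrt(np.log1p(cv ** 2))
    mu = np.log(mean) - tau ** 2 / 2
    values = np.exp(mu[:, None] + tau[:, None] * z)

    truth.core = list(names)
    truth.planted_mean = dict(zip(names, mean.tolist()))
    truth.planted_cv = dict(zip(names, cv.tolist()))

    # non-core rows: fully undetected (zero) in one individual
    nc_names, nc_rows = [], []
    individuals = sheet.individuals
    for k in range(config.n_noncore):
        name = f"sim-miR-nc-{k + 1:02d}"
        nc_names.append(name)
        c = float(np.exp(rng.uniform(math.log(config.cv_range[0]),
                                     math.log(config.cv_range[1]))))
        m = config.power_a * c ** config.power_b
        t = math.sqrt(math.log1p(c ** 2))
        row = np.exp(math.log(m) - t ** 2 / 2
                     + t * rng.normal(size=n_samples))
        dropout = individuals[int(rng.integers(0, len(individuals)))]
        for j, s in enumerate(samples):
            if sheet.samples.loc[s, "individual_id"] == dropout:
                row[j] = 0.0
        nc_rows.append(row)
    truth.noncore = nc_names

    matrix = pd.DataFrame(
        np.vstack([values] + ([np.vstack(nc_rows)] if nc_rows else [])),
        index=names + nc_names,
        columns=samples,
    )
    return ExpressionSim(matrix=matrix, sheet=sheet, truth=truth,
                         config=config)


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

@dataclass
class QpcrSim:
    table: pd.DataFrame           # sample_id, assay, replicate, ct
    pairs: list[tuple[str, str]]  # (gene assay, miRNA assay)
    truth: GroundTruth
    config: SimulationConfig
    true_mean_ct: pd.DataFrame | None = None  # assay × sample, pre-replicate

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / "qpcr_ct.tsv"
        self.table.to_csv(path, sep="\t", index=False, float_format="%.4f")
        return {"qpcr": path}


def simulate_qpcr(config: SimulationConfig | None = None) -> QpcrSim:
    """12-sample Ct table with host/miRNA latent coupling and replicates."""
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed + 2)
    truth = GroundTruth()
    n = config.n_qpcr_samples
    samples = [f"q{i + 1:02d}" for i in range(n)]

    loading = rng.normal(0.0, config.loading_sd, size=n)

    assays: dict[str, np.ndarray] = {}  # assay -> per-sample mean Ct
    for ref in (config.gene_reference, config.mirna_reference):
        base = float(rng.uniform(18, 22))
        assays[ref] = base + loading + rng.normal(
            0.0, config.reference_noise_sd, size=n)
        truth.qpcr_base_ct[ref] = base

    pairs = []
    for gene_assay, mirna_assay, rho in config.qpcr_pairs:
        factor = rng.normal(size=n)
        x_gene = factor
        x_mirna = rho * factor + math.sqrt(1 - rho ** 2) * rng.normal(size=n)
        for assay, x in ((gene_assay, x_gene), (mirna_assay, x_mirna)):
            base = float(rng.uniform(20, 28))
            assays[assay] = base + loading - config.ct_scale * x
            truth.qpcr_base_ct[assay] = base
        pairs.append((gene_assay, mirna_assay))
        truth.qpcr_coupling[f"{gene_assay}/{mirna_assay}"] = rho

    rows = []
    for assay in sorted(assays):
        for i, sample in enumerate(samples):
            for rep in range(1, config.qpcr_replicates + 1):
                ct = assays[assay][i] + rng.normal(0.0, config.replicate_sd)
                rows.append({"sample_id": sample, "assay": assay,
                             "replicate": rep, "ct": float(ct)})
    table = pd.DataFrame(rows, columns=["sample_id", "assay", "replicate",
                                        "ct"])
    true_mean = pd.DataFrame(
        {s: {a: assays[a][i] for a in sorted(assays)}
         for i, s in enumerate(samples)}
    )
    return QpcrSim(table=table, pairs=pairs, truth=truth, config=config,
                   true_mean_ct=true_mean)


# ---------------------------------------------------------------------------

def simulate_all(config: SimulationConfig | None = None,
                 out_dir: str | Path | None = None):
    """Generate every fixture; optionally write them under ``out_dir``."""
    config = config or SimulationConfig()
    ann = simulate_annotation(config)
    expr = simulate_expression(config)
    qpcr = simulate_qpcr(config)
    if out_dir is not None:
        paths = {}
        paths.update(ann.write(out_dir))
        paths.update(expr.write(out_dir))
        paths.update(qpcr.write(out_dir))
        return ann, expr, qpcr, paths
    return ann, expr, qpcr
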