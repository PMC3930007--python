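"""Readers and writers for every external format the pipeline touches.

All genomic input arrives in 1-based inclusive coordinates (GFF3/GTF) and is
converted on read to the single internal convention: 0-based half-open
intervals.  Writers convert back, so a read/write round trip reproduces the
original integers.

The miRNA annotation dialect is the miRBase one: ``miRNA_primary_transcript``
records for precursor hairpins and ``miRNA`` records for mature products,
linked by a ``Derives_from`` attribute.  Mature products sharing one name
across several precursor loci (e.g. miR-378 coded on two chromosomes) are
merged into a single :class:`MatureMiRNA` carrying all coding gene ids.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence
from urllib.parse import unquote

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PRECURSOR_TYPES = {"miRNA_primary_transcript", "pre_miRNA"}
MATURE_TYPES = {"miRNA"}


class ParseError(ValueError):
    """Malformed input; message carries file position where known."""


class LinkError(ValueError):
    """A child record references a parent that does not exist."""


class UsageError(ValueError):
    """Caller asked for something the API does not offer (e.g. bad dialect)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open genomic interval on an explicit strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Overlap in bp; 0 when disjoint or on different chromosomes."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    @classmethod
    def from_gff(cls, chrom: str, start_1based: int, end_1based: int,
                 strand: str) -> "GenomicInterval":
        """Convert 1-based inclusive GFF coordinates to the internal form."""
        return cls(chrom, start_1based - 1, end_1based, strand)

    def to_gff(self) -> tuple[int, int]:
        """Back to 1-based inclusive (start, end)."""
        return self.start + 1, self.end


@dataclass
class MiRNAGene:
    """A precursor (pre-miRNA hairpin) locus."""

    gene_id: str
    name: str
    locus: GenomicInterval
    mature_ids: list[str] = field(default_factory=list)


@dataclass
class MatureMiRNA:
    """A mature miRNA product, possibly coded at several precursor loci."""

    mature_id: str
    name: str
    sequence: str | None = None
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sequence is not None:
            seq = self.sequence.upper().replace("T", "U")
            bad = set(seq) - set("ACGU")
            if bad:
                raise ValueError(
                    f"mature {self.name}: non-RNA symbols {sorted(bad)}"
                )
            self.sequence = seq


@dataclass
class GeneModel:
    """A protein-coding gene with one or more exon-resolved transcripts."""

    gene_id: str
    name: str
    locus: GenomicInterval
    transcripts: list[tuple[str, list[GenomicInterval]]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        for tid, exons in self.transcripts:
            for prev, cur in zip(exons, exons[1:]):
                if cur.start < prev.end:
                    raise ValueError(
                        f"gene {self.gene_id} transcript {tid}: exons overlap "
                        f"or are unsorted at [{cur.start}, {cur.end})"
                    )
            for ex in exons:
                if not self.locus.contains(ex):
                    raise ValueError(
                        f"gene {self.gene_id}: exon outside gene locus"
                    )


@dataclass
class SampleSheet:
    """Sample metadata: one row per array/sample.

    ``samples`` is indexed by sample_id with columns ``individual_id``,
    ``time_point`` and ``group``.
    """

    samples: pd.DataFrame

    REQUIRED = ("individual_id", "time_point", "group")

    def __post_init__(self) -> None:
        if self.samples.index.duplicated().any():
            dups = self.samples.index[self.samples.index.duplicated()].tolist()
            raise ParseError(f"duplicate sample_id(s): {dups}")
        missing = [c for c in self.REQUIRED if c not in self.samples.columns]
        if missing:
            raise ParseError(f"sample sheet missing column(s): {missing}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples.index)

    @property
    def individuals(self) -> list[str]:
        return sorted(self.samples["individual_id"].unique())

    @property
    def time_points(self) -> list:
        return sorted(self.samples["time_point"].unique())

    def samples_of(self, individual_id: str) -> list[str]:
        mask = self.samples["individual_id"] == individual_id
        return list(self.samples.index[mask])

    @classmethod
    def read(cls, path: str | Path) -> "SampleSheet":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if "sample_id" not in df.columns:
            raise ParseError(f"{path}: sample sheet needs a sample_id column")
        return cls(df.set_index("sample_id"))

    def write(self, path: str | Path) -> None:
        self.samples.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# miRBase-dialect GFF3
# ---------------------------------------------------------------------------

def _parse_gff3_attributes(text: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().rstrip(";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            raise ParseError(f"line {lineno}: malformed attribute {chunk!r}")
        key, _, value = chunk.partition("=")
        attrs[key.strip()] = unquote(value.strip())
    return attrs


def _parse_gff3_line(line: str, lineno: int):
    fields = line.rstrip("\n").split("\t")
    if len(fields) != 9:
        raise ParseError(
            f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
        )
    chrom, _source, ftype, start, end, _score, strand, _phase, attr_text = fields
    try:
        start_i, end_i = int(start), int(end)
    except ValueError as exc:
        raise ParseError(f"line {lineno}: non-integer coordinates") from exc
    if start_i > end_i:
        raise ParseError(f"line {lineno}: start {start_i} > end {end_i}")
    if strand not in ("+", "-"):
        # '.' strand is rejected: clustering and host orientation need it.
        raise ParseError(f"line {lineno}: missing/invalid strand {strand!r}")
    attrs = _parse_gff3_attributes(attr_text, lineno)
    locus = GenomicInterval.from_gff(chrom, start_i, end_i, strand)
    return ftype, locus, attrs


def read_mirna_gff(path: str | Path) -> tuple[list[MiRNAGene], list[MatureMiRNA]]:
    """Read a miRBase-dialect GFF3 of precursor and mature miRNA records.

    Resolution of ``Derives_from`` links is two-pass, so mature records may
    precede their precursor in the file.  Matures with the same name at
    different loci come back as one :class:`MatureMiRNA` with several
    ``gene_ids``.
    """
    precursors: list[tuple[GenomicInterval, dict, int]] = []
    matures: list[tuple[GenomicInterval, dict, int]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            ftype, locus, attrs = _parse_gff3_line(line, lineno)
            if ftype in PRECURSOR_TYPES:
                precursors.append((locus, attrs, lineno))
            elif ftype in MATURE_TYPES:
                matures.append((locus, attrs, lineno))
            # other feature types are ignored

    genes: dict[str, MiRNAGene] = {}
    for locus, attrs, lineno in precursors:
        gene_id = attrs.get("ID")
        if gene_id is None:
            raise ParseError(f"line {lineno}: precursor without ID attribute")
        if gene_id in genes:
            raise ParseError(f"line {lineno}: duplicate precursor ID {gene_id!r}")
        genes[gene_id] = MiRNAGene(
            gene_id=gene_id, name=attrs.get("Name", gene_id), locus=locus
        )

    by_name: dict[str, MatureMiRNA] = {}
    for locus, attrs, lineno in matures:
        parents = attrs.get("Derives_from")
        if parents is None:
            raise LinkError(
                f"line {lineno}: mature record without Derives_from"
            )
        mature_id = attrs.get("ID", attrs.get("Name", ""))
        name = attrs.get("Name", mature_id)
        for parent in parents.split(","):
            if parent not in genes:
                raise LinkError(
                    f"line {lineno}: mature {name!r} derives from unknown "
                    f"precursor {parent!r}"
                )
            mature = by_name.setdefault(
                name, MatureMiRNA(mature_id=mature_id, name=name)
            )
            # merged matures keep the lexicographically smallest record ID so
            # the result does not depend on input line order
            mature.mature_id = min(mature.mature_id, mature_id)
            if parent not in mature.gene_ids:
                mature.gene_ids.append(parent)
            if name not in genes[parent].mature_ids:
                genes[parent].mature_ids.append(name)

    # deterministic ordering regardless of input line order
    gene_list = sorted(genes.values(), key=lambda g: (g.locus, g.gene_id))
    for mat in by_name.values():
        mat.gene_ids.sort()
    mature_list = sorted(by_name.values(), key=lambda m: m.name)
    return gene_list, mature_list


def write_mirna_gff(genes: Sequence[MiRNAGene], matures: Sequence[MatureMiRNA],
                    path: str | Path) -> None:
    """Emit the miRBase dialect consumed by :func:`read_mirna_gff`."""
    gene_by_id = {g.gene_id: g for g in genes}
    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda g: (g.locus, g.gene_id)):
        s1, e1 = g.locus.to_gff()
        lines.append(
            f"{g.locus.chrom}\t.\tmiRNA_primary_transcript\t{s1}\t{e1}\t.\t"
            f"{g.locus.strand}\t.\tID={g.gene_id};Name={g.name}"
        )
        for mat in sorted(matures, key=lambda m: m.name):
            if g.gene_id not in mat.gene_ids:
                continue
            # mature placed at the precursor 5' end; position is nominal
            locus = gene_by_id[g.gene_id].locus
            ms, me = locus.to_gff()
            me = min(me, ms + 21)
            lines.append(
                f"{locus.chrom}\t.\tmiRNA\t{ms}\t{me}\t.\t{locus.strand}\t.\t"
                f"ID={mat.mature_id}_{g.gene_id};Name={mat.name};"
                f"Derives_from={g.gene_id}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Protein-coding gene models (GTF / GFF3) via gffutils
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path, dialect: str = "gff3") -> list[GeneModel]:
    """Read gene/transcript/exon models from GTF or GFF3.

    GTF files that carry only exon lines are accepted: gene and transcript
    spans are reconstructed from the exon extents (gffutils inference).
    """
    import gffutils

    if dialect not in ("gtf", "gff3"):
        raise UsageError(f"unknown dialect {dialect!r}; use 'gtf' or 'gff3'")
    force_gtf = dialect == "gtf"
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
        disable_infer_genes=not force_gtf,
        disable_infer_transcripts=not force_gtf,
    )

    genes: list[GeneModel] = []
    claimed_exons: set[str] = set()
    for gf in db.features_of_type("gene"):
        if gf.strand not in ("+", "-"):
            raise ParseError(f"gene {gf.id}: missing strand")
        locus = GenomicInterval.from_gff(gf.seqid, gf.start, gf.end, gf.strand)
        name = (gf.attributes.get("Name") or gf.attributes.get("gene_name")
                or [gf.id])[0]
        transcripts: list[tuple[str, list[GenomicInterval]]] = []
        for tf in db.children(gf, level=1):
            if tf.featuretype not in ("transcript", "mRNA"):
                continue
            exons = []
            for ef in db.children(tf, featuretype="exon", order_by="start"):
                claimed_exons.add(ef.id)
                exons.append(
                    GenomicInterval.from_gff(ef.seqid, ef.start, ef.end,
                                             ef.strand)
                )
            transcripts.append((tf.id, exons))
        transcripts.sort(key=lambda t: t[0])
        genes.append(GeneModel(gene_id=gf.id, name=name, locus=locus,
                               transcripts=transcripts))

    orphans = [ef.id for ef in db.features_of_type("exon")
               if ef.id not in claimed_exons]
    if orphans:
        raise LinkError(f"exon(s) without a transcript parent: {orphans}")
    genes.sort(key=lambda g: (g.locus, g.gene_id))
    return genes


def write_gene_models_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Emit gene models as GFF3 (gene → mRNA → exon with Parent links)."""
    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda g: (g.locus, g.gene_id)):
        s1, e1 = g.locus.to_gff()
        lines.append(
            f"{g.locus.chrom}\t.\tgene\t{s1}\t{e1}\t.\t{g.locus.strand}\t.\t"
            f"ID={g.gene_id};Name={g.name}"
        )
        for tid, exons in g.transcripts:
            if exons:
                ts, te = exons[0].start + 1, exons[-1].end
            else:
                ts, te = s1, e1
            lines.append(
                f"{g.locus.chrom}\t.\tmRNA\t{ts}\t{te}\t.\t{g.locus.strand}\t.\t"
                f"ID={tid};Parent={g.gene_id}"
            )
            for i, ex in enumerate(exons, start=1):
                xs, xe = ex.to_gff()
                lines.append(
                    f"{ex.chrom}\t.\texon\t{xs}\t{xe}\t.\t{ex.strand}\t.\t"
                    f"ID={tid}.exon{i};Parent={tid}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Expression matrix + tabular inputs
# ---------------------------------------------------------------------------

def read_expression(path: str | Path,
                    sample_sheet: str | Path) -> tuple[pd.DataFrame, SampleSheet]:
    """Read a miRNA × sample intensity TSV plus its sample sheet.

    Every matrix column must have a sample-sheet row; missing values stay
    missing (NaN).
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    dup = raw.index[raw.index.duplicated()].unique().tolist()
    if dup:
        raise ParseError(f"{path}: duplicated miRNA row name(s): {dup}")

    matrix = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = raw.index[converted.isna() & raw[col].notna()
                        & ~raw[col].str.strip().isin(["", "NA", "NaN", "nan"])]
        if len(bad):
            raise ParseError(
                f"{path}: non-numeric cell at row {bad[0]!r}, column {col!r}"
            )
        matrix[col] = converted

    sheet = SampleSheet.read(sample_sheet)
    orphans = [c for c in matrix.columns if c not in sheet.samples.index]
    if orphans:
        raise ParseError(f"matrix column(s) missing from sample sheet: {orphans}")
    return matrix, sheet


def read_mature_fasta(path: str | Path) -> dict[str, str]:
    """Mature miRNA sequences keyed by record id, DNA→RNA normalized."""
    from Bio import SeqIO

    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper().replace("T", "U")
    return seqs


def read_seed_families(path: str | Path) -> pd.DataFrame:
    """TargetScan-style seed family table.

    Columns: ``seed`` (7-nt RNA), ``family``, ``species`` (semicolon-joined
    species in which the seed occurs), ``conservation`` (class label).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"seed", "family", "species", "conservation"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: seed table missing column(s) {sorted(missing)}")
    df["seed"] = df["seed"].str.upper().str.replace("T", "U")
    return df


def read_predictions(path: str | Path) -> pd.DataFrame:
    """Target-prediction records: mirna_family, gene, total_context_plus_score."""
    df = pd.read_csv(path, sep="\t", dtype={"mirna_family": str, "gene": str})
    required = {"mirna_family", "gene", "total_context_plus_score"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: predictions missing column(s) {sorted(missing)}")
    scores = pd.to_numeric(df["total_context_plus_score"], errors="coerce")
    if scores.isna().any() or not np.isfinite(scores).all():
        raise ParseError(f"{path}: non-finite context+ score present")
    df["total_context_plus_score"] = scores
    return df


def read_qpcr_table(path: str | Path) -> pd.DataFrame:
    """qPCR Ct table with columns sample_id, assay, replicate, ct."""
    df = pd.read_csv(path, sep="\t",
                     dtype={"sample_id": str, "assay": str})
    required = {"sample_id", "assay", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: qPCR table missing column(s) {sorted(missing)}")
    ct = pd.to_numeric(df["ct"], errors="coerce")
    if ct.isna().any() or (ct <= 0).any() or not np.isfinite(ct).all():
        raise ParseError(f"{path}: Ct values must be finite and > 0")
    df["ct"] = ct
    return df


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, list[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path} line {lineno}: GMT needs ≥3 fields")
            name = fields[0]
            if name in sets:
                raise ParseError(f"{path} line {lineno}: duplicate set {name!r}")
            sets[name] = [g for g in fields[2:] if g]
    return sets


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as handle:
        return [line.strip() for line in handle if line.strip()]


# ---------------------------------------------------------------------------
# Output writing (TSV/JSON) with round-trip readers for key tables
# ---------------------------------------------------------------------------

def write_outputs(result, path: str | Path, format: str = "tsv") -> Path:
    """Write a pipeline result to ``path`` as TSV or JSON.

    ``result`` may be a DataFrame, a mapping (JSON only), or any report
    object exposing ``to_frame()`` (for TSV) / ``to_json_dict()`` (for JSON).
    """
    path = Path(path)
    if format == "tsv":
        if hasattr(result, "to_frame_report"):
            frame = result.to_frame_report()
        elif isinstance(result, pd.DataFrame):
            frame = result
        elif hasattr(result, "to_frame"):
            frame = result.to_frame()
        else:
            raise UsageError(f"cannot render {type(result).__name__} as TSV")
        try:
            frame.to_csv(path, sep="\t", index=False)
        except OSError as exc:
            raise OSError(f"cannot write {path}: {exc}") from exc
    elif format == "json":
        if hasattr(result, "to_json_dict"):
            payload = result.to_json_dict()
        elif isinstance(result, Mapping):
            payload = dict(result)
        else:
            raise UsageError(f"cannot render {type(result).__name__} as JSON")
        try:
            path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        except OSError as exc:
            raise OSError(f"cannot write {path}: {exc}") from exc
    else:
        raise UsageError(f"unknown output format {format!r}")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_edge_list(edges: Iterable[tuple], path: str | Path) -> Path:
    """Edge list TSV: node_a, node_b, r, sign (derived from r)."""
    rows = [
        {"node_a": a, "node_b": b, "r": r, "sign": "+" if r >= 0 else "-"}
        for a, b, r in edges
    ]
    df = pd.DataFrame(rows, columns=["node_a", "node_b", "r", "sign"])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return Path(path)


def read_edge_list(path: str | Path) -> list[tuple[str, str, float, str]]:
    df = pd.read_csv(path, sep="\t")
    return [
        (row.node_a, row.node_b, float(row.r), row.sign)
        for row in df.itertuples(index=False)
    ]
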