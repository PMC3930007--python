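"""Seed extraction, conservation classes, species specificity, target filtering.

The seed is taken as the first 7 nt of the mature miRNA (5′ end); the window
is configurable since the common database convention is positions 2–8.
Conservation classes (highly conserved across most vertebrates / conserved
across most mammals / poorly conserved) come from a user-supplied seed-family
table, not from computation: they are database labels.  A seed present in no
species other than the focal one is species-specific, which by definition
implies the poorly conserved class.

Predicted targets are filtered on the total context+ score (more negative =
stronger predicted repression) with an inclusive cutoff, and counted per
unique target gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

CONSERVATION_CLASSES = ("highly_conserved", "conserved", "poorly_conserved")

DEFAULT_SEED_START = 1  # 1-based position on the mature sequence
DEFAULT_SEED_LEN = 7
DEFAULT_SCORE_CUTOFF = -0.3


@dataclass(frozen=True)
class ConservationCall:
    mature_id: str
    seed: str
    conservation_class: str
    species_specific: bool
    in_table: bool = True

    def __post_init__(self) -> None:
        if self.conservation_class not in CONSERVATION_CLASSES:
            raise ValueError(
                f"unknown conservation class {self.conservation_class!r}"
            )
        if self.species_specific and self.conservation_class != "poorly_conserved":
            raise ValueError(
                f"{self.mature_id}: a species-specific seed must be poorly "
                "conserved"
            )


@dataclass(frozen=True)
class TargetFilterResult:
    entry: str
    retained: tuple[tuple[str, float], ...]  # (gene, score) with score ≤ cutoff
    unique_genes: frozenset[str]

    @property
    def n_targets(self) -> int:
        return len(self.unique_genes)


# ---------------------------------------------------------------------------

def extract_seed(sequence: str, window_start: int = DEFAULT_SEED_START,
                 window_len: int = DEFAULT_SEED_LEN) -> str:
    """Contiguous seed subsequence, uppercased, DNA→RNA normalized."""
    if window_start < 1 or window_len < 1:
        raise ValueError("window_start and window_len must be ≥ 1")
    seq = sequence.upper().replace("T", "U")
    needed = window_start + window_len - 1
    if len(seq) < needed:
        raise ValueError(
            f"sequence of length {len(seq)} too short for seed window "
            f"({window_start}, {window_len})"
        )
    return seq[window_start - 1: window_start - 1 + window_len]


def group_by_seed(seeds_by_mature: dict[str, str]) -> dict[str, list[str]]:
    """Exact-string grouping of matures by seed.

    Returns seed → sorted member names; matures sharing one seed are treated
    downstream as a single slash-joined entry.
    """
    groups: dict[str, list[str]] = {}
    for name, seed in seeds_by_mature.items():
        groups.setdefault(seed, []).append(name)
    return {seed: sorted(members) for seed, members in groups.items()}


def group_entry_name(members: list[str]) -> str:
    """Slash-joined display name for a shared-seed group."""
    return "/".join(sorted(members))


# ---------------------------------------------------------------------------

def classify_conservation(seed: str, table: pd.DataFrame, focal_species: str,
                          mature_id: str = "") -> ConservationCall:
    """Look up a seed's conservation class and species specificity.

    ``table`` is the frame from :func:`adipomir.io_formats.read_seed_families`.
    A seed absent from the table is called poorly conserved and flagged as
    out-of-table; its species specificity then defaults to unknown (False).
    A seed occurring in no species besides ``focal_species`` is
    species-specific and forced to the poorly conserved class (the definition
    of a lineage-specific seed), even if the table's label disagrees.
    """
    focal = focal_species.strip().lower()
    rows = table[table["seed"] == seed]
    if rows.empty:
        return ConservationCall(mature_id, seed, "poorly_conserved",
                                species_specific=False, in_table=False)
    species: set[str] = set()
    for cell in rows["species"]:
        species.update(s.strip().lower() for s in str(cell).split(";") if s.strip())
    specific = bool(species) and species <= {focal}
    label = rows.iloc[0]["conservation"]
    if label not in CONSERVATION_CLASSES:
        raise ValueError(f"seed table: unknown conservation label {label!r}")
    if specific and label != "poorly_conserved":
        logger.warning(
            "seed %s occurs only in %s but is labeled %s; calling it "
            "poorly_conserved", seed, focal_species, label
        )
        label = "poorly_conserved"
    return ConservationCall(mature_id, seed, label, species_specific=specific)


def classify_all(seeds_by_mature: dict[str, str], table: pd.DataFrame,
                 focal_species: str) -> list[ConservationCall]:
    return [
        classify_conservation(seed, table, focal_species, mature_id=name)
        for name, seed in sorted(seeds_by_mature.items())
    ]


# ---------------------------------------------------------------------------

def filter_predictions(records: pd.DataFrame,
                       cutoff: float = DEFAULT_SCORE_CUTOFF,
                       ) -> dict[str, TargetFilterResult]:
    """Keep predictions with total context+ score ≤ cutoff (inclusive).

    Counts are unique target genes per miRNA entry; a gene with several
    qualifying sites is counted once.
    """
    out: dict[str, TargetFilterResult] = {}
    for entry, sub in records.groupby("mirna_family", sort=True):
        kept = sub[sub["total_context_plus_score"] <= cutoff]
        retained = tuple(
            (row.gene, float(row.total_context_plus_score))
            for row in kept.itertuples(index=False)
        )
        out[str(entry)] = TargetFilterResult(
            entry=str(entry),
            retained=retained,
            unique_genes=frozenset(g for g, _ in retained),
        )
    return out


# ---------------------------------------------------------------------------

def seed_report(seeds_by_mature: dict[str, str],
                calls: list[ConservationCall],
                targets: dict[str, TargetFilterResult] | None = None,
                ) -> pd.DataFrame:
    """Per-mature TSV-ready report: seed, class, specificity, target count."""
    call_by_id = {c.mature_id: c for c in calls}
    rows = []
    for name in sorted(seeds_by_mature):
        call = call_by_id[name]
        row = {
            "mature": name,
            "seed": call.seed,
            "conservation_class": call.conservation_class,
            "species_specific": call.species_specific,
            "in_table": call.in_table,
        }
        if targets is not None:
            row["n_targets"] = targets[name].n_targets if name in targets else 0
        rows.append(row)
    return pd.DataFrame(rows)
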