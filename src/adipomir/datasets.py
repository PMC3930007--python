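"""Bundled reference tables from the emulated bovine adipose study.

Two small published tables travel with the package so the desk-scale
re-tallies run without any download:

* the panel of 23 bovine-specific adipose core miRNAs (chromosome, cluster
  membership, location class, host gene, normalized expression mean ± sd,
  predicted-target count after context+ filtering, and 7-nt seed);
* the printed core-set counts: conservation-class sizes of the 155-miRNA
  core panel and the location breakdown of the 60 host-gene-resident
  members.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("adipomir") / "data" / name
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_bovine_specific() -> pd.DataFrame:
    """The 23 bovine-specific adipose core miRNAs (one row per mature)."""
    return _load("bovine_specific_mirnas.tsv")


def load_core_counts() -> pd.DataFrame:
    """Published core-set tallies: conservation classes and hosted locations."""
    return _load("core_set_counts.tsv")
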