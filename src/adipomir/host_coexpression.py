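"""qPCR processing and host-gene / intronic-miRNA co-expression.

Technical replicates are averaged per (sample, assay); relative expression
uses the comparative Ct scheme: ΔCt = Ct_target − Ct_reference per sample,
ΔΔCt = ΔCt_sample − ΔCt_calibrator, fold change = 2^(−ΔΔCt).

Because a lower Ct means more template, "expression" for correlation
purposes is −ΔCt, so a positive Pearson R between a host gene and its
intronic miRNA means co-expression.  The two-tailed p-value comes from the
exact t transform t = R·√(n−2)/√(1−R²) on n−2 degrees of freedom.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

# Reference assays: a uniformly expressed miRNA for miRNA Ct values and a
# housekeeping gene for host-gene Ct values.
DEFAULT_MIRNA_REFERENCE = "bta-miR-181a"
DEFAULT_GENE_REFERENCE = "ACTB"
DEFAULT_SD_LIMIT = 0.5  # replicate-scatter flag threshold, cycles


@dataclass(frozen=True)
class CorrelationResult:
    gene_assay: str
    mirna_assay: str
    n: int
    r: float
    p: float

    def __post_init__(self) -> None:
        if not -1 - 1e-12 <= self.r <= 1 + 1e-12:
            raise ValueError(f"Pearson R out of range: {self.r}")
        if not 0 <= self.p <= 1:
            raise ValueError(f"p-value out of range: {self.p}")


# ---------------------------------------------------------------------------
# Replicate aggregation
# ---------------------------------------------------------------------------

def aggregate_replicates(table: pd.DataFrame, sd_limit: float = DEFAULT_SD_LIMIT,
                         expected: list[tuple[str, str]] | None = None,
                         ) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Mean Ct per (sample, assay) with replicate SD and an outlier flag.

    Returns the aggregate frame plus a gap report: (sample, assay) pairs from
    ``expected`` (default: the full sample × assay grid) that have no
    replicates.  A single replicate yields an undefined (NaN) SD, flagged.
    """
    grouped = table.groupby(["sample_id", "assay"])["ct"]
    agg = grouped.agg(mean_ct="mean", sd_ct=lambda s: s.std(ddof=1),
                      n_replicates="count").reset_index()
    agg["flagged"] = agg["sd_ct"].isna() | (agg["sd_ct"] > sd_limit)

    if expected is None:
        samples = sorted(table["sample_id"].unique())
        assays = sorted(table["assay"].unique())
        expected = [(s, a) for s in samples for a in assays]
    have = set(zip(agg["sample_id"], agg["assay"]))
    gaps = [pair for pair in expected if pair not in have]
    if gaps:
        logger.warning("missing (sample, assay) pair(s): %s", gaps)
    return agg, gaps


# ---------------------------------------------------------------------------
# ΔCt / ΔΔCt
# ---------------------------------------------------------------------------

def delta_ct(ct_target: float, ct_reference: float) -> float:
    """ΔCt = Ct_target − Ct_reference."""
    return ct_target - ct_reference


def delta_ct_table(agg: pd.DataFrame, target_assay: str,
                   reference_assay: str) -> pd.Series:
    """Per-sample ΔCt of one assay against a reference assay."""
    wide = agg.pivot(index="sample_id", columns="assay", values="mean_ct")
    if reference_assay not in wide.columns:
        raise KeyError(f"reference assay {reference_assay!r} absent")
    if target_assay not in wide.columns:
        raise KeyError(f"target assay {target_assay!r} absent")
    missing_ref = wide.index[wide[reference_assay].isna()
                             & wide[target_assay].notna()].tolist()
    if missing_ref:
        raise ValueError(
            f"no reference Ct for sample(s) {missing_ref} "
            f"(reference {reference_assay!r})"
        )
    return wide[target_assay] - wide[reference_assay]


def ddct_fold(delta_ct_sample: float, delta_ct_calibrator: float,
              ) -> tuple[float, float]:
    """ΔΔCt and the associated fold change 2^(−ΔΔCt)."""
    ddct = delta_ct_sample - delta_ct_calibrator
    return ddct, 2.0 ** (-ddct)


# ---------------------------------------------------------------------------
# Correlation with exact t-transform p-value
# ---------------------------------------------------------------------------

def pearson_pvalue(r: float, n: int) -> float:
    """Two-tailed p for a Pearson R at sample size n via the t transform."""
    if n < 3:
        raise ValueError("need n ≥ 3")
    if abs(r) >= 1:
        return 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1 - r * r)
    return float(2 * stats.t.sf(abs(t), df=n - 2))


def correlate_pair(x, y, gene_assay: str = "gene", mirna_assay: str = "mirna",
                   ) -> CorrelationResult:
    """Pearson correlation of two per-sample expression vectors.

    Incomplete sample pairs are dropped listwise; needs ≥3 complete pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError(f"need ≥3 complete pairs, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant vector: Pearson R undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    return CorrelationResult(gene_assay, mirna_assay, n=n, r=r,
                             p=pearson_pvalue(r, n))


def correlate_host_pairs(agg: pd.DataFrame,
                         pairs: list[tuple[str, str]],
                         mirna_reference: str = DEFAULT_MIRNA_REFERENCE,
                         gene_reference: str = DEFAULT_GENE_REFERENCE,
                         ) -> pd.DataFrame:
    """Correlate each (host gene assay, miRNA assay) pair over samples.

    Expression per sample is −ΔCt against the matching reference assay
    (lower Ct = higher expression, so the sign convention makes positive R
    mean co-expression).
    """
    rows = []
    for gene_assay, mirna_assay in pairs:
        gene_expr = -delta_ct_table(agg, gene_assay, gene_reference)
        mirna_expr = -delta_ct_table(agg, mirna_assay, mirna_reference)
        joined = pd.concat({"gene": gene_expr, "mirna": mirna_expr},
                           axis=1).dropna()
        res = correlate_pair(joined["gene"], joined["mirna"],
                             gene_assay=gene_assay, mirna_assay=mirna_assay)
        rows.append({"gene": gene_assay, "mirna": mirna_assay,
                     "n": res.n, "r": res.r, "p": res.p})
    return pd.DataFrame(rows)
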