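"""Normalization, core-set detection, mean/CV summaries and group comparisons.

Normalization is the percentile-shift scheme used for single-colour miRNA
arrays: per sample, intensities are log-transformed and shifted so the
chosen per-sample percentile (default the 75th) sits at a common constant
(default 0).  Percentiles use linear interpolation between order statistics
(numpy's default, the classic "type 7" convention), recorded in the output
metadata.

The core set is the panel of miRNAs detected in every individual in at least
one of that individual's time points — the default reading of an
"expressed in all individuals in at least one time point" rule.  The
alternative reading (one common time point where everyone is detected) is
available behind a flag.

The mean–CV relation across miRNAs is summarised by a power-law fit
y = a·x^b (y mean expression, x CV) obtained by ordinary least squares on
the log-log scale, plus the Pearson correlation of mean and CV on the
original scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_PERCENTILE = 75.0


@dataclass
class NormalizedMatrix:
    """miRNA × sample matrix of normalized log intensities plus metadata."""

    data: pd.DataFrame
    percentile: float = DEFAULT_PERCENTILE
    log_base: float = 2.0
    offset: float = 0.0
    percentile_convention: str = "linear"  # numpy interpolation method


@dataclass
class PowerFit:
    a: float
    b: float
    r2: float
    n_points: int
    pearson_r: float  # mean vs CV on the untransformed scale

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.r2 <= 1 + 1e-9):
            raise ValueError(f"r2 out of [0, 1]: {self.r2}")

    def to_json_dict(self) -> dict:
        return {"a": self.a, "b": self.b, "r2": self.r2,
                "n_points": self.n_points, "pearson_r": self.pearson_r}


@dataclass
class CategoryComparison:
    grouping: str
    groups: pd.DataFrame          # group, n, mean, sd
    test: str                     # "t" or "anova"
    statistic: float
    p_value: float
    tukey: pd.DataFrame | None = None  # group_a, group_b, diff, p_adj, significant

    def to_frame(self) -> pd.DataFrame:
        base = self.groups.copy()
        base.insert(0, "grouping", self.grouping)
        base["test"] = self.test
        base["statistic"] = self.statistic
        base["p_value"] = self.p_value
        return base


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_percentile(raw: pd.DataFrame, percentile: float = DEFAULT_PERCENTILE,
                         log_base: float = 2.0, offset: float = 0.0,
                         log: bool = True) -> NormalizedMatrix:
    """Per-sample percentile-shift normalization on the log scale.

    Non-positive raw intensities cannot be log-transformed and are masked to
    missing before the shift.  A sample with no usable value is an error.
    With ``log=False`` the input is taken as already log-scale and only the
    percentile shift is applied — shifting an already-shifted matrix (offset
    0) is then a no-op.
    """
    values = raw.to_numpy(dtype=float)
    if log:
        masked = np.where(values > 0, values, np.nan)
        logged = np.log(masked) / math.log(log_base)
    else:
        logged = values.copy()

    out = np.empty_like(logged)
    for j, sample in enumerate(raw.columns):
        col = logged[:, j]
        usable = col[np.isfinite(col)]
        if usable.size == 0:
            raise ValueError(f"sample {sample!r}: no positive intensities")
        shift = np.percentile(usable, percentile)  # linear interpolation
        out[:, j] = col - shift + offset
    data = pd.DataFrame(out, index=raw.index, columns=raw.columns)
    return NormalizedMatrix(data=data, percentile=percentile,
                            log_base=log_base, offset=offset)


# ---------------------------------------------------------------------------
# Core-set detection
# ---------------------------------------------------------------------------

def detect_core(matrix, sheet, detection_flags: pd.DataFrame | None = None,
                floor: float | None = None, rule: str = "per-individual",
                ) -> tuple[list[str], pd.DataFrame]:
    """Call the core miRNA set from a detection rule.

    ``matrix`` may be a :class:`NormalizedMatrix` or a plain DataFrame.
    Detection is either an explicit boolean flag matrix or ``value > floor``
    (strict); ``floor`` defaults to the matrix minimum, so only the lowest
    (typically masked/zero) entries are undetected.  Missing values are never
    detected.

    rule="per-individual": core ⇔ every individual has ≥1 detected sample.
    rule="common-timepoint": core ⇔ some time point has every individual
    detected (all of an individual's samples at that time point count).
    """
    data = matrix.data if isinstance(matrix, NormalizedMatrix) else matrix
    for ind in sheet.individuals:
        if not sheet.samples_of(ind):
            raise ValueError(f"individual {ind!r} has no samples")
    orphan = [c for c in data.columns if c not in sheet.samples.index]
    if orphan:
        raise ValueError(f"matrix column(s) missing from sample sheet: {orphan}")

    if detection_flags is not None:
        detected = detection_flags.reindex(index=data.index,
                                           columns=data.columns).fillna(False)
        detected = detected.astype(bool)
    else:
        if floor is None:
            floor = float(np.nanmin(data.to_numpy()))
        detected = data.gt(floor) & data.notna()

    meta = sheet.samples.loc[list(data.columns)]
    core: list[str] = []
    if rule == "per-individual":
        per_ind = {
            ind: detected[meta.index[meta["individual_id"] == ind]].any(axis=1)
            for ind in sheet.individuals
        }
        everywhere = pd.DataFrame(per_ind).all(axis=1)
        core = list(data.index[everywhere])
    elif rule == "common-timepoint":
        ok = pd.Series(False, index=data.index)
        for tp in sheet.time_points:
            tp_samples = meta.index[meta["time_point"] == tp]
            tp_meta = meta.loc[tp_samples]
            per_ind = {
                ind: detected[tp_meta.index[tp_meta["individual_id"] == ind]
                              ].any(axis=1)
                for ind in sheet.individuals
                if (tp_meta["individual_id"] == ind).any()
            }
            if len(per_ind) < len(sheet.individuals):
                continue  # some individual unsampled at this time point
            ok |= pd.DataFrame(per_ind).all(axis=1)
        core = list(data.index[ok])
    else:
        raise ValueError(f"unknown core rule {rule!r}")
    return core, detected


# ---------------------------------------------------------------------------
# Summary statistics and the mean–CV power law
# ---------------------------------------------------------------------------

def summarize(data: pd.DataFrame) -> pd.DataFrame:
    """Per-miRNA mean, sample sd (n−1) and CV = sd/mean across all samples.

    CV is undefined (NaN) when the mean is ≤ 0; such rows are flagged.
    """
    if data.shape[1] < 2:
        raise ValueError("need at least 2 samples to summarize")
    mean = data.mean(axis=1)
    sd = data.std(axis=1, ddof=1)
    cv = sd / mean
    cv[mean <= 0] = np.nan
    return pd.DataFrame({
        "mean": mean,
        "sd": sd,
        "cv": cv,
        "n_samples": data.notna().sum(axis=1),
        "cv_defined": mean > 0,
    })


def fit_power(stats_frame: pd.DataFrame) -> PowerFit:
    """OLS fit of log(mean) on log(CV): mean = a · CV^b.

    Only rows with mean > 0 and CV > 0 enter the fit; r² is the coefficient
    of determination of the log-log regression.  The Pearson correlation of
    (mean, CV) on the original scale is computed over the same rows.
    """
    usable = stats_frame[(stats_frame["mean"] > 0) & (stats_frame["cv"] > 0)]
    if len(usable) < 3:
        raise ValueError(f"need ≥3 usable points, got {len(usable)}")
    x = np.log(usable["cv"].to_numpy())
    y = np.log(usable["mean"].to_numpy())
    res = stats.linregress(x, y)
    rvalue = res.rvalue if np.isfinite(res.rvalue) else 0.0  # constant y
    if usable["cv"].nunique() > 1 and usable["mean"].nunique() > 1:
        pearson = stats.pearsonr(usable["mean"], usable["cv"]).statistic
    else:
        pearson = 0.0  # degenerate: no variation on one axis
    return PowerFit(
        a=float(np.exp(res.intercept)),
        b=float(res.slope),
        r2=float(rvalue ** 2),
        n_points=len(usable),
        pearson_r=float(pearson),
    )


# ---------------------------------------------------------------------------
# Category comparisons (t-test / ANOVA + Tukey)
# ---------------------------------------------------------------------------

def compare_categories(values, labels, grouping: str = "category",
                       alpha: float = 0.05, welch: bool = False,
                       ) -> CategoryComparison:
    """Compare a per-miRNA statistic across categories.

    Two groups → two-tailed t-test (pooled variance by default, Welch behind
    a flag).  Three or more groups → one-way ANOVA with Tukey HSD pairwise
    comparisons at ``alpha``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must align")
    keep = np.isfinite(values)
    values, labels = values[keep], labels[keep]
    names = sorted(set(labels.tolist()))
    groups = [values[labels == name] for name in names]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for name, g in zip(names, groups):
        if g.size < 2:
            raise ValueError(f"group {name!r} has n < 2")

    table = pd.DataFrame({
        "group": names,
        "n": [g.size for g in groups],
        "mean": [g.mean() for g in groups],
        "sd": [g.std(ddof=1) for g in groups],
    })

    if len(groups) == 2:
        res = stats.ttest_ind(groups[0], groups[1], equal_var=not welch)
        return CategoryComparison(grouping, table, "t",
                                  float(res.statistic), float(res.pvalue))

    f_res = stats.f_oneway(*groups)
    hsd = stats.tukey_hsd(*groups)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            p_adj = float(hsd.pvalue[i, j])
            rows.append({
                "group_a": names[i],
                "group_b": names[j],
                "diff": float(groups[i].mean() - groups[j].mean()),
                "p_adj": p_adj,
                "significant": p_adj < alpha,
            })
    return CategoryComparison(grouping, table, "anova",
                              float(f_res.statistic), float(f_res.pvalue),
                              tukey=pd.DataFrame(rows))
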