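"""Negative-binomial Wald differential expression for two-group contrasts.

The model is the standard RNA-seq workhorse in simplified form: per-sample
size factors by median-of-ratios, a single two-level NB GLM per miRNA with
Var = mu + alpha * mu^2, a Wald test on the log2 fold change, and
Benjamini-Hochberg FDR control. A miRNA is called differentially expressed
when |log2FC| > 1 and FDR < 0.05 (both thresholds configurable).

For a saturated two-level design fitted by quasi-likelihood on size-factor-
normalized counts, the MLE of each group's mean is the arithmetic mean of the
normalized counts, so the log2 fold change is exactly log2 of the ratio of
normalized group means, and the expected-information variance of each log-mean
is (1/mu_g + alpha)/n_g. That closed form is used here; there is no Cox-Reid
dispersion adjustment, fold-change shrinkage, independent filtering, or
outlier replacement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

LN2 = math.log(2.0)

#: pseudo-mean (normalized counts) replacing a zero group mean, to keep fold
#: changes finite while preserving direction
ZERO_GROUP_PSEUDO_MEAN = 0.5

DE_COLUMNS = ("baseMean", "log2FoldChange", "lfcSE", "stat", "pvalue",
              "padj", "is_de")


def estimate_size_factors(counts: pd.DataFrame, method: str = "auto"
                          ) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    ``method``: "ratio" uses only miRNAs positive in every sample as the
    reference set; "poscounts" ignores zeros within each miRNA's ratio set
    (robust on sparse matrices); "auto" falls back to poscounts when no miRNA
    is positive everywhere.
    """
    x = counts.to_numpy(dtype=float)
    all_pos = (x > 0).all(axis=1)
    if method == "auto":
        method = "ratio" if all_pos.any() else "poscounts"
    if method == "ratio":
        if not all_pos.any():
            raise ValidationError(
                "no miRNA has positive counts in all samples; "
                "use method='poscounts'")
        ref = x[all_pos]
        log_geo = np.mean(np.log(ref), axis=1)
        ratios = np.log(ref) - log_geo[:, None]
        sf = np.exp(np.median(ratios, axis=0))
    elif method == "poscounts":
        with np.errstate(divide="ignore"):
            logx = np.where(x > 0, np.log(x), np.nan)
        n_pos = (x > 0).sum(axis=1)
        usable = n_pos > 0
        log_geo = np.nanmean(logx[usable], axis=1)
        ratios = logx[usable] - log_geo[:, None]
        sf = np.exp(np.nanmedian(ratios, axis=0))
    else:
        raise ValueError(f"unknown size-factor method {method!r}")
    if np.any(~np.isfinite(sf)) or np.any(sf <= 0):
        raise ValidationError("size-factor estimation produced nonpositive values")
    sf = sf / np.exp(np.mean(np.log(sf)))          # geometric mean 1
    return pd.Series(sf, index=counts.columns, name="size_factor")


def estimate_dispersion(counts: pd.DataFrame, size_factors: pd.Series,
                        groups: pd.Series) -> pd.Series:
    """Per-miRNA NB dispersion by pooled method of moments with trend shrinkage.

    Within-group variances are pooled, alpha_hat = max(0, (s2 - mu)/mu^2) on
    size-factor-normalized counts, then shrunk 50/50 toward a trend fitted by
    regressing alpha_hat on 1/mu.
    """
    groups = pd.Series(groups, index=counts.columns) if not isinstance(
        groups, pd.Series) else groups
    y = counts.to_numpy(dtype=float) / size_factors.to_numpy()[None, :]
    labels = groups.loc[counts.columns].to_numpy()
    num_var = np.zeros(y.shape[0])
    denom = 0.0
    for g in np.unique(labels):
        cols = labels == g
        n_g = int(cols.sum())
        if n_g < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 samples")
        num_var += (n_g - 1) * y[:, cols].var(axis=1, ddof=1)
        denom += n_g - 1
    pooled_var = num_var / denom
    mu = y.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(mu > 0, (pooled_var - mu) / mu ** 2, 0.0)
    raw = np.maximum(raw, 0.0)

    usable = mu > 0
    if usable.sum() >= 2 and np.ptp(1.0 / mu[usable]) > 0:
        X = np.column_stack([np.ones(usable.sum()), 1.0 / mu[usable]])
        beta, *_ = np.linalg.lstsq(X, raw[usable], rcond=None)
        trend = np.zeros_like(raw)
        trend[usable] = np.maximum(X @ beta, 0.0)
    else:
        trend = np.full_like(raw, raw[usable].mean() if usable.any() else 0.0)
    alpha = 0.5 * raw + 0.5 * trend
    return pd.Series(np.maximum(alpha, 0.0), index=counts.index, name="dispersion")


def adjust_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def nb_wald_test(counts: pd.DataFrame, meta: pd.DataFrame, group_a: str,
                 group_b: str, *, group_column: str = "phenotype",
                 size_factors: pd.Series | None = None,
                 dispersion: pd.Series | float | None = None,
                 lfc_threshold: float = 1.0,
                 fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Two-group NB Wald test; log2FC is group_b over group_a.

    Returns a per-miRNA table with DESeq2-style column names (baseMean,
    log2FoldChange, lfcSE, stat, pvalue, padj) plus the boolean call ``is_de``.
    miRNAs with zero counts in every retained sample are excluded.
    """
    ids_a = meta.loc[meta[group_column] == group_a, "sample_id"]
    ids_b = meta.loc[meta[group_column] == group_b, "sample_id"]
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValidationError(
            f"both groups need >= 2 samples (got {group_a}: {len(ids_a)}, "
            f"{group_b}: {len(ids_b)})")
    sub = counts.loc[:, list(ids_a) + list(ids_b)]
    sub = sub.loc[sub.sum(axis=1) > 0]
    if size_factors is None:
        size_factors = estimate_size_factors(sub)
    sf = size_factors.loc[sub.columns]
    labels = pd.Series(
        [group_a] * len(ids_a) + [group_b] * len(ids_b), index=sub.columns)
    if dispersion is None:
        dispersion = estimate_dispersion(sub, sf, labels)
    if np.isscalar(dispersion):
        alpha = np.full(sub.shape[0], float(dispersion))
    else:
        alpha = pd.Series(dispersion).loc[sub.index].to_numpy(dtype=float)

    y = sub.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    in_a = (labels == group_a).to_numpy()
    n_a, n_b = int(in_a.sum()), int((~in_a).sum())
    mean_a = y[:, in_a].mean(axis=1)
    mean_b = y[:, ~in_a].mean(axis=1)
    ma = np.where(mean_a == 0, ZERO_GROUP_PSEUDO_MEAN, mean_a)
    mb = np.where(mean_b == 0, ZERO_GROUP_PSEUDO_MEAN, mean_b)
    log2fc = np.log2(mb / ma)
    var_log_a = (1.0 / ma + alpha) / n_a
    var_log_b = (1.0 / mb + alpha) / n_b
    se = np.sqrt(var_log_a + var_log_b) / LN2
    stat = log2fc / se
    pvalue = 2.0 * stats.norm.sf(np.abs(stat))
    padj = adjust_bh(pvalue)
    is_de = (np.abs(log2fc) > lfc_threshold) & (padj < fdr_threshold)

    return pd.DataFrame({
        "baseMean": y.mean(axis=1),
        "log2FoldChange": log2fc,
        "lfcSE": se,
        "stat": stat,
        "pvalue": pvalue,
        "padj": padj,
        "is_de": is_de,
    }, index=sub.index)


def _round_half_away(x: float, precision: int) -> float:
    scale = 10.0 ** precision
    return math.copysign(math.floor(abs(x) * scale + 0.5) / scale, x)


@dataclass(frozen=True)
class DirectionSummary:
    """Counts and direction-wise mean log2 fold changes of the DE calls."""

    n_up: int
    n_down: int
    mean_log2fc_up: float | None
    mean_log2fc_down: float | None


def summarize_directions(de, precision: int = 2) -> DirectionSummary:
    """Mean log2FC among DE miRNAs, split by direction.

    ``de`` is either a DE table (needs ``log2FoldChange`` and ``is_de``
    columns) or a plain sequence of log2 fold changes, all treated as DE.
    Means are rounded half-away-from-zero to ``precision`` decimals.
    """
    if isinstance(de, pd.DataFrame):
        lfc = de.loc[de["is_de"], "log2FoldChange"].to_numpy(dtype=float)
    else:
        lfc = np.asarray(list(de), dtype=float)
    up = lfc[lfc > 0]
    down = lfc[lfc < 0]
    return DirectionSummary(
        n_up=int(up.size),
        n_down=int(down.size),
        mean_log2fc_up=_round_half_away(float(up.mean()), precision) if up.size else None,
        mean_log2fc_down=_round_half_away(float(down.mean()), precision) if down.size else None,
    )


class DifferentialExpressionModel:
    """Two-group NB differential expression model.

    Parameters
    ----------
    counts : DataFrame
        miRNA x sample integer read counts.
    metadata : DataFrame
        Sample metadata with ``sample_id`` and the grouping column.
    contrast : (str, str)
        (group_a, group_b); fold changes are reported as group_b over group_a.
    group_column : str
        Metadata column holding the group labels (default ``phenotype``).

    Examples
    --------
    >>> model = DifferentialExpressionModel(counts, meta, ("HC", "DD"))
    >>> res = model.fit()
    >>> res.table.head()
    """

    def __init__(self, counts: pd.DataFrame, metadata: pd.DataFrame,
                 contrast: tuple[str, str], group_column: str = "phenotype"):
        self.counts = counts
        self.metadata = metadata
        self.contrast = tuple(contrast)
        self.group_column = group_column

    @classmethod
    def from_study(cls, study, contrast, group_column: str = "phenotype"):
        return cls(study.counts, study.metadata, contrast, group_column)

    def fit(self, lfc_threshold: float = 1.0, fdr_threshold: float = 0.05,
            size_factors: pd.Series | None = None,
            dispersion: pd.Series | float | None = None
            ) -> "DifferentialExpressionResults":
        table = nb_wald_test(
            self.counts, self.metadata, *self.contrast,
            group_column=self.group_column, size_factors=size_factors,
            dispersion=dispersion, lfc_threshold=lfc_threshold,
            fdr_threshold=fdr_threshold)
        return DifferentialExpressionResults(
            model=self, table=table, lfc_threshold=lfc_threshold,
            fdr_threshold=fdr_threshold)


@dataclass(frozen=True)
class DifferentialExpressionResults:
    """Fitted DE results: per-miRNA estimates plus the call rule applied."""

    model: DifferentialExpressionModel
    table: pd.DataFrame
    lfc_threshold: float
    fdr_threshold: float

    @property
    def de_table(self) -> pd.DataFrame:
        return self.table.loc[self.table["is_de"]]

    def direction_summary(self, precision: int = 2) -> DirectionSummary:
        return summarize_directions(self.table, precision=precision)

    def summary(self) -> str:
        a, b = self.model.contrast
        d = self.direction_summary()
        lines = [
            "Negative-binomial Wald differential expression",
            f"  contrast:        {b} vs {a} (log2FC of {b} over {a})",
            f"  miRNAs tested:   {len(self.table)}",
            f"  call rule:       |log2FC| > {self.lfc_threshold}, "
            f"FDR < {self.fdr_threshold}",
            f"  DE miRNAs:       {int(self.table['is_de'].sum())} "
            f"({d.n_up} up, {d.n_down} down)",
        ]
        if d.mean_log2fc_up is not None:
            lines.append(f"  mean log2FC up:   {d.mean_log2fc_up}")
        if d.mean_log2fc_down is not None:
            lines.append(f"  mean log2FC down: {d.mean_log2fc_down}")
        return "\n".join(lines)
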